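"""Named, reproducible random substreams.

All stochastic stages (cohort generation, MAP multi-start, VPC replicates,
residual simulation) derive their generators from a single top-level integer
seed plus a short stream name, so that changing one stage's draw count never
perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is ``[seed, crc32(name)]`` fed to a ``SeedSequence``;
    distinct names give statistically independent streams.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
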