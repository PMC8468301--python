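"""Published external-evaluation bookkeeping for the twelve infliximab models.

Dose-escalation confusion counts (trough target 5 µg/mL) as printed for the
external evaluation of the twelve population-PK models, split by the ADA
status of the trough sample. The "positive" class is "dose escalation
needed" (observed/predicted trough below target). These counts are inputs
for arithmetic checks and worked examples; they are not produced by this
package's estimators.
"""

from __future__ import annotations

__all__ = ["DOSE_ESCALATION_COUNTS", "pooled_counts"]

#: model → ADA group → {TP, FN, TN, FP}
DOSE_ESCALATION_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "aubourg_2015": {
        "ada_negative": {"TP": 48, "FN": 19, "TN": 63, "FP": 4},
        "ada_positive": {"TP": 13, "FN": 10, "TN": 2, "FP": 0},
    },
    "brandse_2016": {
        "ada_negative": {"TP": 62, "FN": 5, "TN": 39, "FP": 28},
        "ada_positive": {"TP": 18, "FN": 5, "TN": 0, "FP": 2},
    },
    "buurman_2015": {
        "ada_negative": {"TP": 38, "FN": 29, "TN": 62, "FP": 5},
        "ada_positive": {"TP": 19, "FN": 4, "TN": 1, "FP": 1},
    },
    "edlund_2017_i": {
        "ada_negative": {"TP": 51, "FN": 16, "TN": 61, "FP": 6},
        "ada_positive": {"TP": 16, "FN": 7, "TN": 2, "FP": 0},
    },
    "edlund_2017_ii": {
        "ada_negative": {"TP": 50, "FN": 17, "TN": 63, "FP": 4},
        "ada_positive": {"TP": 15, "FN": 8, "TN": 1, "FP": 1},
    },
    "edlund_2017_iii": {
        "ada_negative": {"TP": 50, "FN": 17, "TN": 63, "FP": 4},
        "ada_positive": {"TP": 16, "FN": 7, "TN": 1, "FP": 1},
    },
    "fasanmade_2009": {
        "ada_negative": {"TP": 54, "FN": 13, "TN": 58, "FP": 9},
        "ada_positive": {"TP": 17, "FN": 6, "TN": 1, "FP": 1},
    },
    "fasanmade_2011_ac": {
        "ada_negative": {"TP": 60, "FN": 7, "TN": 53, "FP": 14},
        "ada_positive": {"TP": 19, "FN": 4, "TN": 0, "FP": 2},
    },
    "fasanmade_2011_a": {
        "ada_negative": {"TP": 60, "FN": 7, "TN": 53, "FP": 14},
        "ada_positive": {"TP": 19, "FN": 4, "TN": 0, "FP": 2},
    },
    "passot_2016": {
        "ada_negative": {"TP": 44, "FN": 23, "TN": 64, "FP": 3},
        "ada_positive": {"TP": 13, "FN": 10, "TN": 2, "FP": 0},
    },
    "petitcollin_2018": {
        "ada_negative": {"TP": 62, "FN": 5, "TN": 48, "FP": 19},
        "ada_positive": {"TP": 15, "FN": 8, "TN": 0, "FP": 2},
    },
    "xu_2012": {
        "ada_negative": {"TP": 56, "FN": 11, "TN": 52, "FP": 15},
        "ada_positive": {"TP": 18, "FN": 5, "TN": 1, "FP": 1},
    },
}


def pooled_counts(model: str) -> dict[str, int]:
    """ADA-negative + ADA-positive confusion counts pooled for one model."""
    groups = DOSE_ESCALATION_COUNTS[model]
    return {k: groups["ada_negative"][k] + groups["ada_positive"][k]
            for k in ("TP", "FN", "TN", "FP")}
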