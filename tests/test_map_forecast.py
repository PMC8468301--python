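import numpy as np
import pytest

from ifxmipd.map_forecast import (ForecastTask, Observation,
                                  covariate_segments, estimate_ebes,
                                  fit_random_effects, forecast,
                                  make_forecast_task, map_objective)
from ifxmipd.pk_engine import DosingEvent, concentration_profile

from conftest import single_patient_table, toy_1cmt

DOSES = [DosingEvent(0.0, 385.0, 2.0), DosingEvent(1344.0, 385.0, 2.0)]
NO_COV = [(0.0, {"TIME": 0.0})]


def infusion_conc(t, CL_day, Vc, dose=385.0, dur=2.0, t0=0.0):
    """Closed-form single-infusion concentration, written independently."""
    CL = CL_day / 24.0
    k = CL / Vc
    tt = t - t0
    if tt <= 0:
        return 0.0
    if tt <= dur:
        return dose / (dur * CL) * (1 - np.exp(-k * tt))
    return dose / (dur * CL) * (1 - np.exp(-k * dur)) * np.exp(-k * (tt - dur))


class TestMapObjective:
    def test_prior_mode_is_zero(self, toy_model):
        assert map_objective(toy_model, [], [], NO_COV, [0.0]) == 0.0

    def test_quadratic_prior_without_data(self, toy_model):
        # Ω = diag(0.09) → η²/ω²
        assert map_objective(toy_model, [], [], NO_COV, [0.3]) == pytest.approx(1.0)

    def test_hand_evaluated_single_observation(self):
        model = toy_1cmt(sigma_prop=0.1, omega_cl=0.09)
        eta = 0.1
        t_obs, y = 672.0, 10.0
        obs = [Observation(t_obs, y, 0)]
        val = map_objective(model, obs, DOSES[:1], NO_COV, [eta])
        # independent evaluation of f, g² and the objective
        f = infusion_conc(t_obs, 0.3 * np.exp(eta), 3.5)
        g2 = (0.1 * f) ** 2
        expected = (y - f) ** 2 / g2 + np.log(g2) + eta ** 2 / 0.09
        assert val == pytest.approx(expected, rel=1e-10)

    def test_kappa_requires_iov(self, toy_model):
        with pytest.raises(ValueError, match="without IOV"):
            map_objective(toy_model, [], [], NO_COV, [0.0], {0: 0.1})

    def test_iov_penalty_term(self):
        model = toy_1cmt(iov=0.04)
        val = map_objective(model, [], [], NO_COV, [0.0], {0: 0.2})
        assert val == pytest.approx(0.2 ** 2 / 0.04)


class TestEstimation:
    def test_vanishing_omega_pins_eta_at_zero(self):
        model = toy_1cmt(omega_cl=1e-10)
        obs = [Observation(672.0, 25.0, 0)]     # far from the typical profile
        est = fit_random_effects(model, obs, DOSES[:1], NO_COV)
        assert abs(est.eta["CL"]) < 1e-3

    def test_noise_free_inversion_recovers_eta(self):
        model = toy_1cmt(sigma_prop=0.01, omega_cl=4.0)
        eta_true = 0.3
        y = infusion_conc(672.0, 0.3 * np.exp(eta_true), 3.5)
        est = fit_random_effects(model, [Observation(672.0, y, 0)],
                                 DOSES[:1], NO_COV)
        assert est.converged
        assert est.eta["CL"] == pytest.approx(eta_true, abs=1e-3)

    def test_matches_dense_grid_search(self):
        """2-parameter MAP estimate vs an exhaustive grid oracle."""
        model = toy_1cmt(sigma_prop=0.1, omega_cl=0.09, omega_vc=0.0625)
        t1, t2 = 336.0, 1320.0
        eta_true = np.array([0.25, -0.15])
        y1 = infusion_conc(t1, 0.3 * np.exp(eta_true[0]), 3.5 * np.exp(eta_true[1]))
        y2 = 1.07 * infusion_conc(t2, 0.3 * np.exp(eta_true[0]),
                                  3.5 * np.exp(eta_true[1]))
        obs = [Observation(t1, y1, 0), Observation(t2, y2, 0)]

        step = 1e-3
        g = np.arange(-0.6, 0.6 + step / 2, step)
        E1, E2 = np.meshgrid(g, g, indexing="ij")
        total = E1 ** 2 / 0.09 + E2 ** 2 / 0.0625
        for t, y in ((t1, y1), (t2, y2)):
            CL = 0.3 / 24.0 * np.exp(E1)
            k = CL / (3.5 * np.exp(E2))
            f = 385.0 / (2.0 * CL) * (1 - np.exp(-k * 2.0)) * np.exp(-k * (t - 2.0))
            g2 = (0.1 * f) ** 2
            total += (y - f) ** 2 / g2 + np.log(g2)
        i, j = np.unravel_index(np.argmin(total), total.shape)
        grid_opt = np.array([g[i], g[j]])

        est = fit_random_effects(model, obs, DOSES[:1], NO_COV)
        fitted = np.array([est.eta["CL"], est.eta["Vc"]])
        assert np.all(np.abs(fitted - grid_opt) <= 2 * step)

    def test_shrinkage_monotone_in_sigma(self):
        y = infusion_conc(672.0, 0.3 * np.exp(0.4), 3.5)
        norms = []
        for sp in (0.05, 0.1, 0.2, 0.4):
            model = toy_1cmt(sigma_prop=sp, omega_cl=0.09)
            est = fit_random_effects(model, [Observation(672.0, y, 0)],
                                     DOSES[:1], NO_COV)
            norms.append(abs(est.eta["CL"]))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_estimate_never_above_prior_mode(self, ref_model, small_cohort):
        clean, _ = small_cohort
        for pid in clean.patients()[:5]:
            task = make_forecast_task(clean, pid)
            est = estimate_ebes(ref_model, task, n_starts=2)
            segs = covariate_segments(ref_model, clean, pid,
                                      anchor_h=task.anchor.time_h)
            f0 = map_objective(ref_model, [task.anchor], task.doses, segs,
                               np.zeros(len(ref_model.eta_names)),
                               {task.anchor.occasion: 0.0})
            assert est.ofv <= f0 + 1e-9


class TestForecast:
    def make_task(self, table, policy="locf_at_anchor"):
        return make_forecast_task(table, "P1", policy=policy)

    def test_forecast_without_iov_equals_profile_with_eta_hat(self, toy_model):
        table = single_patient_table(
            [(672.0, 10.0), (2000.0, 6.0)],
            doses=((0.0, 385.0, 2.0), (1344.0, 385.0, 2.0)))
        task = self.make_task(table)
        est = estimate_ebes(toy_model, task)
        recs = forecast(toy_model, est, task)
        from ifxmipd.pk_engine import individual_parameters
        p = individual_parameters(toy_model, {}, eta=est.eta)
        expected = concentration_profile(task.doses, [(0.0, p)], [2000.0], 1)[0]
        pred = [r for r in recs if not r.anchor][0]
        assert pred.y == pytest.approx(expected, rel=1e-10)

    def test_doubling_all_doses_doubles_predictions(self, toy_model):
        table = single_patient_table(
            [(672.0, 10.0), (2000.0, 6.0)],
            doses=((0.0, 385.0, 2.0), (1344.0, 385.0, 2.0)))
        task = self.make_task(table)
        est = estimate_ebes(toy_model, task)
        y1 = [r.y for r in forecast(toy_model, est, task) if not r.anchor]
        doubled = ForecastTask(
            patient_id=task.patient_id,
            doses=[DosingEvent(d.time_h, 2 * d.amount_mg, d.duration_h)
                   for d in task.doses],
            anchor=task.anchor, targets=task.targets, table=task.table,
            policy=task.policy)
        y2 = [r.y for r in forecast(toy_model, est, doubled) if not r.anchor]
        np.testing.assert_allclose(y2, np.array(y1) * 2, rtol=1e-12)

    def test_locf_freezes_ada_at_anchor_value(self, ref_model):
        # ADA turns positive after the anchor: frozen-covariate predictions
        # must follow the ADA-negative trajectory
        obs = [(672.0, 10.0), (2000.0, 5.0), (3000.0, 3.0)]
        table = single_patient_table(
            obs, doses=tuple((k * 1344.0, 385.0, 2.0) for k in range(3)),
            ada=[1.0, 30.0, 40.0])
        task = self.make_task(table)
        est = estimate_ebes(ref_model, task, n_starts=2)
        recs = {r.time_days * 24: r.y for r in forecast(ref_model, est, task)
                if not r.anchor}

        from ifxmipd.map_forecast import individual_trajectory
        segs_neg = [(0.0, {"WT": 70.0, "ALB": 4.35, "ADA_POS": 0.0, "TIME": 0.0})]
        traj = individual_trajectory(ref_model, segs_neg,
                                     [d.time_h for d in task.doses],
                                     est.eta_vector(ref_model), None)
        expected = concentration_profile(task.doses, traj, [2000.0, 3000.0], 2)
        assert recs[2000.0] == pytest.approx(expected[0], rel=1e-10)
        assert recs[3000.0] == pytest.approx(expected[1], rel=1e-10)

        # with the full covariate time course the ADA clearance bump kicks in
        task_full = self.make_task(table, policy="full")
        recs_full = {r.time_days * 24: r.y
                     for r in forecast(ref_model, est, task_full)
                     if not r.anchor}
        assert recs_full[3000.0] < recs[3000.0]

    def test_prediction_time_before_anchor_rejected(self, toy_model):
        table = single_patient_table([(672.0, 10.0)])
        task = make_forecast_task(table, "P1")
        with pytest.raises(ValueError, match="anchor"):
            ForecastTask(patient_id="P1", doses=task.doses, anchor=task.anchor,
                         targets=[Observation(100.0, 5.0, 0)],
                         table=table, policy="locf_at_anchor")

    def test_records_carry_strata_fields(self, ref_model, small_cohort):
        clean, _ = small_cohort
        pid = clean.patients()[0]
        task = make_forecast_task(clean, pid)
        est = estimate_ebes(ref_model, task, n_starts=2)
        recs = forecast(ref_model, est, task)
        assert recs[0].anchor and recs[0].dt_anchor_days == 0.0
        for r in recs[1:]:
            assert r.dt_anchor_days > 0
            assert isinstance(r.trough, bool)
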