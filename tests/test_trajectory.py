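"""ODE integration, control anchoring, z-scores and summary quantities."""

import numpy as np
import pytest

from pdtraj import (
    ControlReference,
    DivergenceError,
    Trajectory,
    anchor_control_trajectory,
    compute_kinetics,
    find_crossing,
    fit_rate_model,
    heun_step,
    integrate_trajectory,
    midpoint_step,
    onset_anchor,
    percent_change,
    to_zscores,
)
from pdtraj.synthetic import ABETA, TruthDynamics, generate_cohort

from conftest import single_marker_config


def make_ref(mu=1000.0, sd=100.0, ctrl_age=60.0, aao=60.0):
    return ControlReference(means={ABETA: mu}, sds={ABETA: sd},
                            median_baseline_age=ctrl_age, median_pd_aao=aao)


def linear_traj(slope=1.0, intercept=-5.0):
    t = np.linspace(-5, 30, 3501)
    return Trajectory(marker=ABETA, group="pd_all", times=t,
                      levels=slope * t + intercept, anchor_level=intercept)


class TestSteppers:
    def test_heun_hand_step(self):
        # f(X) = -X, x=1, h=0.1: 1 + 0.05(-1 - 0.9) = 0.905
        assert heun_step(1.0, 0.1, lambda x: -x) == pytest.approx(0.905, abs=1e-15)

    @pytest.mark.parametrize("step", [heun_step, midpoint_step])
    def test_constant_rate_is_exact(self, step):
        assert step(3.0, 0.25, lambda x: 4.0) == pytest.approx(4.0, abs=1e-15)
        assert step(3.0, -0.25, lambda x: 4.0) == pytest.approx(2.0, abs=1e-15)

    @pytest.mark.parametrize("step", [heun_step, midpoint_step])
    def test_zero_rate_leaves_state(self, step):
        assert step(7.0, 0.1, lambda x: 0.0) == 7.0

    def test_nonfinite_rate_aborts(self):
        with pytest.raises(DivergenceError):
            heun_step(1.0, 0.1, lambda x: np.inf)


class TestIntegrateTrajectory:
    @pytest.mark.parametrize("method", ["heun", "midpoint"])
    def test_exponential_decay_vs_closed_form(self, method):
        traj = integrate_trajectory(lambda x: -0.1 * x, 100.0, t_min=0.0,
                                    t_max=30.0, h=0.01, method=method)
        exact = 100.0 * np.exp(-0.1 * traj.times)
        rel = np.abs(traj.levels - exact) / exact
        assert rel.max() < 1e-3
        assert traj.level_at(10.0) == pytest.approx(100.0 * np.exp(-1.0), rel=1e-3)

    @pytest.mark.parametrize("method", ["heun", "midpoint"])
    def test_second_order_convergence(self, method):
        exact = lambda t: 100.0 * np.exp(-0.1 * t)
        errs = []
        for h in (0.2, 0.1):
            traj = integrate_trajectory(lambda x: -0.1 * x, 100.0, t_min=0.0,
                                        t_max=30.0, h=h, method=method)
            errs.append(np.max(np.abs(traj.levels - exact(traj.times))))
        assert 3.5 <= errs[0] / errs[1] <= 4.5

    def test_constant_rate_linear_including_premotor(self):
        traj = integrate_trajectory(lambda x: 2.0, 0.0, h=0.01)
        assert np.allclose(traj.levels, 2.0 * traj.times, atol=1e-9)
        assert traj.level_at(-5.0) == pytest.approx(-10.0, abs=1e-9)

    def test_anchor_exact_at_time_zero(self):
        traj = integrate_trajectory(lambda x: np.sin(x), 123.456, h=0.05)
        assert traj.level_at(0.0) == 123.456

    def test_monotone_approach_never_crosses_stable_root(self):
        traj = integrate_trajectory(lambda x: -0.5 * (x - 40.0), 100.0, h=0.01)
        fwd = traj.levels[traj.times >= 0]
        assert np.all(np.diff(fwd) <= 1e-12)
        assert np.all(fwd >= 40.0)

    def test_forward_then_backward_returns_to_anchor(self):
        f = lambda x: -0.1 * x
        h = 0.05
        x = 100.0
        for _ in range(200):
            x = heun_step(x, h, f)
        for _ in range(200):
            x = heun_step(x, -h, f)
        assert x == pytest.approx(100.0, abs=100 * h**2)

    def test_divergence_aborts_with_diagnostics(self):
        with pytest.raises(DivergenceError, match="divergence"):
            integrate_trajectory(lambda x: 10.0 * x, 1.0, t_min=0.0, t_max=10.0, h=0.05)

    def test_reporting_grid_invariance(self):
        traj = integrate_trajectory(lambda x: -0.1 * (x - 50.0), 100.0, h=0.01)
        coarse = traj.to_frame(every=0.5)
        fine = traj.to_frame(every=0.1)
        merged = coarse.merge(fine, on="duration_years", suffixes=("_c", "_f"))
        assert np.max(np.abs(merged["level_c"] - merged["level_f"])) < 1e-6

    def test_rate_clamped_outside_corridor(self):
        levels = np.linspace(900.0, 1100.0, 120)
        model = fit_rate_model(levels, -0.5 * (levels - 1000.0), marker=ABETA,
                               group="pd_all")
        traj = integrate_trajectory(model, 200.0)  # anchor far below fit range
        assert any(d["event"] == "rate_clamped" for d in traj.diagnostics)


class TestControlAnchoring:
    def test_zero_rate_control_is_flat_at_mu(self):
        ref = make_ref(mu=1022.6, ctrl_age=61.0, aao=60.0)
        traj = anchor_control_trajectory(lambda x: 0.0, ref, ABETA, h=0.01)
        assert np.allclose(traj.levels, 1022.6, atol=1e-12)
        assert traj.times.min() == pytest.approx(-5.0, abs=0.02)
        assert traj.times.max() == pytest.approx(30.0, abs=0.02)

    def test_duration_equals_age_minus_median_aao(self):
        ref = make_ref(ctrl_age=60.0, aao=60.0)
        traj = anchor_control_trajectory(lambda x: 0.0, ref, ABETA)
        # anchor age == median AAO -> anchor sits at duration 0 exactly
        assert traj.anchor_time == 0.0
        assert np.any(traj.times == 0.0)
        ref2 = make_ref(ctrl_age=63.5, aao=60.0)
        traj2 = anchor_control_trajectory(lambda x: 0.0, ref2, ABETA)
        assert traj2.anchor_time == pytest.approx(3.5)

    def test_linear_drift_slope_preserved_after_reindexing(self):
        # control truth drifts at +0.5/yr: re-indexed trajectory keeps that slope
        ref = make_ref(mu=100.0, ctrl_age=62.0, aao=60.0)
        traj = anchor_control_trajectory(lambda x: 0.5, ref, ABETA, h=0.01)
        slope = np.polyfit(traj.times, traj.levels, 1)[0]
        assert slope == pytest.approx(0.5, rel=1e-10)
        assert traj.level_at(2.0) == pytest.approx(100.0, abs=1e-9)

    def test_missing_reference_fields_rejected(self):
        ref = make_ref()
        with pytest.raises(ValueError, match="lacks baseline mean"):
            anchor_control_trajectory(lambda x: 0.0, ref, "nope")
        bad = ControlReference(means={ABETA: 1.0}, sds={ABETA: 1.0},
                               median_baseline_age=float("nan"), median_pd_aao=60.0)
        with pytest.raises(ValueError, match="median_baseline_age"):
            anchor_control_trajectory(lambda x: 0.0, bad, ABETA)


class TestZScores:
    def test_identities(self):
        ref = make_ref(mu=1000.0, sd=100.0)
        traj = linear_traj()
        traj = to_zscores(Trajectory(marker=ABETA, group="pd_all",
                                     times=traj.times,
                                     levels=np.full_like(traj.times, 1000.0)), ref)
        assert np.allclose(traj.z_scores, 0.0)
        traj2 = to_zscores(Trajectory(marker=ABETA, group="pd_all",
                                      times=traj.times,
                                      levels=np.full_like(traj.times, 1100.0)), ref)
        assert np.allclose(traj2.z_scores, 1.0)

    def test_control_baseline_standardizes_to_unit_moments(self, rng):
        base = rng.normal(1000.0, 80.0, 150)
        ref = ControlReference(means={ABETA: float(base.mean())},
                               sds={ABETA: float(base.std(ddof=1))},
                               median_baseline_age=60.0, median_pd_aao=60.0)
        z = (base - ref.means[ABETA]) / ref.sds[ABETA]
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ControlReference(means={ABETA: 1.0}, sds={ABETA: 0.0},
                             median_baseline_age=60.0, median_pd_aao=60.0)


class TestSummaries:
    def test_percent_change_values(self):
        t = np.array([0.0, 15.0, 30.0])
        traj = Trajectory(marker=ABETA, group="pd_all", times=t,
                          levels=np.array([100.0, 95.0, 88.0]))
        assert percent_change(traj) == pytest.approx(-12.0)
        flat = Trajectory(marker=ABETA, group="pd_all", times=t,
                          levels=np.full(3, 7.0))
        assert percent_change(flat) == 0.0

    def test_percent_change_exponential_closed_form(self):
        dyn = TruthDynamics("exponential_approach", k=0.1, plateau=600.0,
                            onset_level=1000.0)
        t = np.linspace(0, 30, 301)
        traj = Trajectory(marker=ABETA, group="truth", times=t, levels=dyn.level(t))
        expected = 100.0 * (600 + 400 * np.exp(-3.0) - 1000.0) / 1000.0  # -38.008
        assert percent_change(traj) == pytest.approx(expected, abs=1e-9)

    def test_percent_change_zero_start_undefined(self):
        traj = linear_traj(slope=1.0, intercept=0.0)
        with pytest.raises(ZeroDivisionError):
            percent_change(traj, 0.0, 30.0)

    def test_crossing_of_line_with_zero(self):
        assert find_crossing(linear_traj(), 0.0) == pytest.approx(5.0, abs=1e-9)

    def test_no_crossing_when_always_below(self):
        traj = linear_traj(slope=0.0, intercept=-1.0)
        assert find_crossing(traj, 0.0) is None

    def test_identical_curves_no_crossing(self):
        a = linear_traj()
        assert find_crossing(a, a) is None

    def test_exponential_crossing_closed_form(self):
        t = np.linspace(-5, 30, 3501)
        a = Trajectory(marker=ABETA, group="a", times=t,
                       levels=100.0 * np.exp(-0.1 * t))
        assert find_crossing(a, 50.0) == pytest.approx(10 * np.log(2), abs=1e-3)

    def test_crossing_between_two_trajectories(self):
        t = np.linspace(-5, 30, 3501)
        a = Trajectory(marker=ABETA, group="a", times=t, levels=t * 1.0)
        b = Trajectory(marker=ABETA, group="b", times=t, levels=np.full_like(t, 19.0))
        assert find_crossing(a, b) == pytest.approx(19.0, abs=1e-9)


class TestEndToEndRecovery:
    def test_zero_noise_constant_cohort_recovers_flat_truth(self):
        dyn = {ABETA: TruthDynamics("constant", onset_level=500.0)}
        cfg = single_marker_config(dynamics=dyn, control_dynamics=dyn,
                                   onset_level_sd={ABETA: 30.0}, seed=3)
        visits, _, truth = generate_cohort(cfg)
        kin, _ = compute_kinetics(visits)
        kin_pd = kin[kin["group"] == "PD"]
        model = fit_rate_model(kin_pd["baseline_level"], kin_pd["rate"],
                               n_subjects=len(kin_pd), marker=ABETA, group="pd_all")
        traj = integrate_trajectory(model, onset_anchor(kin_pd))
        assert np.ptp(traj.levels) < 1e-6 * 500.0
        # constant dynamics: the anchor is exactly the sample mean of the
        # hidden per-subject onset levels
        true_onsets = truth[(truth["kind"] == "onset_level")
                            & truth["subject_id"].str.startswith("PD")]["value"]
        assert traj.anchor_level == pytest.approx(true_onsets.mean(), rel=1e-9)
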