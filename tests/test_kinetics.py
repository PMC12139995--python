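"""Trajectory construction, decay fitting, AIC selection, half-lives."""

import numpy as np
import pytest
from scipy import optimize

from pulsechase import (
    DegradationTrajectory,
    SimConfig,
    aic,
    build_trajectories,
    fit_one_level,
    fit_trajectory,
    fit_two_level,
    half_life,
    half_life_fold_changes,
    interpolate_half_life_direct,
    passing,
    regional_vulnerability,
    select_model,
    simulate_plex,
    two_level_curve,
)
from pulsechase.kinetics import KineticFit, exclusion_counts
from conftest import CHASE_TIMES, toy_matrix


def _plex(rep_means_by_protein: dict, bg_mean: float = 1.0, n_rep: int = 2):
    """Build a raw plex where each timepoint's replicates equal the given mean."""
    tps = [0.0, 1.0, 2.0, 3.0]
    values, groups, timepoints = {}, {}, {}
    for j, t in enumerate(tps):
        for r in range(n_rep):
            s = f"tp{j}_r{r}"
            groups[s] = "labeled"
            timepoints[s] = t
    for r in range(n_rep):
        groups[f"bg_r{r}"] = "background"
    for pid, means in rep_means_by_protein.items():
        row = {}
        for j, mmean in enumerate(means):
            for r in range(n_rep):
                row[f"tp{j}_r{r}"] = mmean
        for r in range(n_rep):
            row[f"bg_r{r}"] = bg_mean
        values[pid] = row
    return toy_matrix(values, groups, timepoints)


class TestBuildTrajectories:
    def test_forced_ratios_give_percent_remaining(self):
        m = _plex({"p": (200.0, 160.0, 120.0, 80.0)})
        (traj,) = build_trajectories(m)
        assert traj.passed_filters
        np.testing.assert_allclose(traj.percent_remaining, [100, 80, 60, 40])
        assert traj.times[0] == 0.0

    def test_rise_of_six_points_excluded(self):
        m = _plex({"p": (100.0, 90.0, 96.0, 70.0)})
        (traj,) = build_trajectories(m)
        assert not traj.passed_filters
        assert "rise_above_threshold" in traj.reasons

    def test_rise_of_four_points_retained(self):
        m = _plex({"p": (100.0, 90.0, 94.0, 70.0)})
        (traj,) = build_trajectories(m)
        assert traj.passed_filters

    def test_tp1_gate_discards_weakly_enriched(self):
        # log2(2.0/1.0) = 1 <= 1.5 → gate fails; log2(4/1) = 2 > 1.5 → passes
        m = _plex({"weak": (2.0, 1.5, 1.0, 0.5), "strong": (4.0, 3.0, 2.0, 1.0)})
        trajs = {t.protein_id: t for t in build_trajectories(m)}
        assert not trajs["weak"].passed_filters
        assert "tp1_gate" in trajs["weak"].reasons
        assert trajs["strong"].passed_filters

    def test_tp1_zero_never_divides(self):
        m = _plex({"z": (0.0, 0.0, 0.0, 0.0)})
        (traj,) = build_trajectories(m)
        assert not traj.passed_filters
        assert "tp1_zero" in traj.reasons

    def test_scale_invariance(self):
        """Multiplying the whole plex by a constant changes no trajectory."""
        means = {"a": (200.0, 160.0, 120.0, 80.0), "b": (400.0, 100.0, 50.0, 25.0)}
        t1 = build_trajectories(_plex(means, bg_mean=1.0))
        scaled = {k: tuple(7.3 * x for x in v) for k, v in means.items()}
        t2 = build_trajectories(_plex(scaled, bg_mean=7.3))
        for a, b in zip(t1, t2):
            np.testing.assert_allclose(a.percent_remaining, b.percent_remaining, rtol=1e-12)
            assert a.passed_filters == b.passed_filters

    def test_exclusion_counts_partition_input(self):
        cfg = SimConfig(n_proteins=100, noise_cv=0.3, dropout_rate=0.1, seed=13)
        m, _ = simulate_plex(cfg)
        trajs = build_trajectories(m)
        counts = exclusion_counts(trajs)
        assert len(passing(trajs)) + sum(counts.values()) == len(trajs)


class TestFitOneLevel:
    def test_noiseless_recovers_rate_and_halflife(self, chase_times):
        k = np.log(2) / 5.0
        y = 100 * np.exp(-k * chase_times)
        fit = fit_one_level(DegradationTrajectory("p", chase_times, y))
        assert fit.k_a == pytest.approx(k, rel=1e-4)
        assert fit.half_life_days == pytest.approx(5.0, rel=1e-4)

    def test_constant_trajectory_flagged_nondecaying(self, chase_times):
        fit = fit_one_level(DegradationTrajectory("p", chase_times, np.full(4, 100.0)))
        assert fit.k_a == 0.0
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(fit.half_life_days)
        assert "no_decay" in fit.flags

    def test_recovery_under_noise(self):
        """Median relative half-life error < 15% at noise_cv 0.1."""
        cfg = SimConfig(n_proteins=300, noise_cv=0.1, seed=21)
        m, gt = simulate_plex(cfg)
        errs = []
        for traj in passing(build_trajectories(m)):
            fit = fit_one_level(traj)
            true = gt.loc[traj.protein_id, "half_life_days"]
            errs.append(abs(fit.half_life_days - true) / true)
        assert len(errs) > 200
        assert np.median(errs) < 0.15

    def test_estimated_rate_monotone_in_true_halflife(self, chase_times):
        """Slower true decay → smaller fitted kA, across a noiseless sweep."""
        ks = []
        for hl in np.logspace(-0.5, 1.5, 12):
            y = 100 * np.exp(-(np.log(2) / hl) * chase_times)
            ks.append(fit_one_level(DegradationTrajectory("p", chase_times, y)).k_a)
        assert all(b < a for a, b in zip(ks, ks[1:]))


class TestFitTwoLevel:
    def test_selfconsistency_round_trip(self, chase_times):
        y = two_level_curve(chase_times, 0.2, 1.0, 0.4)
        fit = fit_two_level(DegradationTrajectory("p", chase_times, 100 * y))
        assert fit.converged
        assert fit.rss < 1e-10
        assert fit.k_a == pytest.approx(0.2, abs=1e-3)
        assert fit.k_b == pytest.approx(1.0, abs=1e-2)
        assert fit.k_ab == pytest.approx(0.4, abs=1e-2)

    def test_curve_is_one_at_time_zero(self):
        assert two_level_curve(np.array([0.0]), 0.3, 1.2, 0.5)[0] == pytest.approx(1.0)

    def test_fitted_curves_monotone_decreasing_over_chase(self, chase_times):
        """Accepted fits stay monotone over the chase window."""
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 13.333, 200)
        for _ in range(10):
            ka = rng.uniform(0.05, 0.5)
            y = two_level_curve(chase_times, ka, ka * rng.uniform(3, 8), ka * rng.uniform(1, 4))
            fit = fit_two_level(DegradationTrajectory("p", chase_times, 100 * y))
            if not fit.converged or "non_monotone" in fit.flags:
                continue
            curve = fit.curve(grid)
            # rises below 1e-6 are optimizer noise on a curve of scale 1
            assert np.all(np.diff(curve) <= 1e-6)

    def test_degenerate_rates_return_nan_curve(self):
        out = two_level_curve(np.array([0.0, 1.0]), 0.5, 0.5, 0.2)
        assert np.isnan(out).all()


class TestModelSelection:
    def test_aic_printed_formula(self):
        assert aic(4, 0.01, 1) == pytest.approx(4 * np.log(0.0025) + 2)
        assert aic(4, 0.01, 1) == pytest.approx(-21.97, abs=0.01)

    def test_equal_rss_prefers_fewer_parameters(self):
        f1 = KineticFit("p", "one_level", 0.1, rss=0.05, n_points=4, aic=aic(4, 0.05, 1))
        f2 = KineticFit("p", "two_level", 0.1, k_b=1.0, k_ab=0.3, rss=0.05, n_points=4, aic=aic(4, 0.05, 3))
        assert select_model(f1, f2).model == "one_level"

    def test_failed_two_level_falls_back(self):
        f1 = KineticFit("p", "one_level", 0.1, rss=0.05, n_points=4, aic=aic(4, 0.05, 1))
        f2 = KineticFit("p", "two_level", np.nan, rss=np.inf, n_points=4, aic=np.inf, converged=False)
        assert select_model(f1, f2).model == "one_level"

    def test_two_level_never_selected_with_worse_rss(self, chase_times):
        """AIC with k=3 cannot beat k=1 unless RSS is strictly smaller."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            rss1 = rng.uniform(1e-4, 0.1)
            rss2 = rss1 * rng.uniform(1.0, 3.0)
            assert aic(4, rss2, 3) > aic(4, rss1, 1)

    def test_pure_one_level_data_mostly_selected_one_level(self):
        cfg = SimConfig(n_proteins=100, noise_cv=0.05, seed=17)
        m, _ = simulate_plex(cfg)
        fits = [fit_trajectory(t) for t in passing(build_trajectories(m))]
        frac = np.mean([f.model == "one_level" for f in fits])
        assert frac >= 0.9


class TestHalfLife:
    def test_rate_of_ln2_gives_one_day(self):
        f = KineticFit("p", "one_level", np.log(2))
        assert half_life(f) == pytest.approx(1.0)

    def test_small_rate(self):
        f = KineticFit("p", "one_level", 0.0693)
        assert half_life(f) == pytest.approx(10.0, abs=0.01)

    def test_zero_rate_nonfinite(self):
        assert np.isinf(half_life(KineticFit("p", "one_level", 0.0)))

    def test_two_level_interpolation_matches_root_finder(self):
        fit = KineticFit("p", "two_level", 0.2, k_b=1.0, k_ab=0.4)
        hl = half_life(fit)
        root = optimize.brentq(
            lambda t: two_level_curve(np.array([t]), 0.2, 1.0, 0.4)[0] - 0.5, 1e-6, 7.0
        )
        assert hl == pytest.approx(root, abs=0.05)


class TestDirectInterpolation:
    def test_exact_hit_at_grid_point(self, chase_times):
        traj = DegradationTrajectory("p", chase_times, np.array([100.0, 75, 50, 25]))
        assert interpolate_half_life_direct(traj) == pytest.approx(6.333)

    def test_never_reaching_half_is_undefined(self, chase_times):
        traj = DegradationTrajectory("p", chase_times, np.array([100.0, 80, 60, 55]))
        assert np.isnan(interpolate_half_life_direct(traj))

    def test_hand_interpolated_crossing(self, chase_times):
        traj = DegradationTrajectory("p", chase_times, np.array([100.0, 60, 40, 30]))
        expect = 2.333 + 4.0 * (60 - 50) / (60 - 40)
        assert interpolate_half_life_direct(traj) == pytest.approx(expect, abs=1e-9)

    def test_agrees_with_model_on_noiseless_one_level(self, chase_times):
        """Where the curve crosses 50%, the interpolated half-life brackets
        the modeled one on the chase grid, and converges to it as the grid
        densifies (the interpolation-error limit)."""
        for hl in (1.0, 3.0, 6.0):
            k = np.log(2) / hl
            y = 100 * np.exp(-k * chase_times)
            traj = DegradationTrajectory("p", chase_times, y)
            direct = interpolate_half_life_direct(traj)
            modeled = fit_one_level(traj).half_life_days
            # crossing lies in the bracketing interval of the sparse grid
            below = np.nonzero(y <= 50.0)[0]
            lo = chase_times[below[0] - 1] if below[0] > 0 else 0.0
            hi = chase_times[below[0]]
            assert lo <= modeled <= hi
            assert lo <= direct <= hi
            # dense grid: interpolation error vanishes, estimates coincide
            t_dense = np.linspace(0, 14, 400)
            dense = DegradationTrajectory("p", t_dense, 100 * np.exp(-k * t_dense))
            assert interpolate_half_life_direct(dense) == pytest.approx(hl, rel=0.01)


class TestFoldChanges:
    def _fits(self, hl: dict):
        return [
            KineticFit(pid, "one_level", np.log(2) / h, half_life_days=h)
            for pid, h in hl.items()
        ]

    def test_doubling_gives_log2fc_one(self):
        table, summary = half_life_fold_changes(
            self._fits({"a": 5.0}), self._fits({"a": 10.0})
        )
        assert table.loc["a", "log2fc"] == pytest.approx(1.0)

    def test_nonfinite_halflives_excluded(self):
        table, summary = half_life_fold_changes(
            self._fits({"a": 5.0, "b": np.inf}), self._fits({"a": 10.0, "b": 4.0})
        )
        assert list(table.index) == ["a"]
        assert summary["n_excluded_nonfinite"] == 1

    def test_no_common_proteins_errors(self):
        with pytest.raises(ValueError, match="common"):
            half_life_fold_changes(self._fits({"a": 5.0}), self._fits({"b": 5.0}))

    def test_identical_regions_yield_no_vulnerable_flags(self):
        """Same kinetics in two regions → zero regionally vulnerable proteins."""
        import pandas as pd

        rng = np.random.default_rng(2)
        fc = pd.DataFrame({"log2fc": rng.normal(1, 0.02, 50)},
                          index=[f"p{i}" for i in range(50)])
        fc2 = fc + rng.normal(0, 0.02, (50, 1))
        table = regional_vulnerability({"r1": fc, "r2": fc2})
        assert not table["vulnerable"].any()


class TestAgedRecoveryPipeline:
    def test_doubled_halflives_recover_log2fc_one(self):
        """aged_halflife_fold=2 → mean recovered log2 FC ≈ 1."""
        cfg = SimConfig(n_proteins=300, noise_cv=0.1, aged_halflife_fold=2.0, seed=31)
        young, ygt = simulate_plex(cfg, "young")
        aged, agt = simulate_plex(cfg, "aged")
        fy = [fit_one_level(t) for t in passing(build_trajectories(young))]
        fa = [fit_one_level(t) for t in passing(build_trajectories(aged))]
        table, summary = half_life_fold_changes(fy, fa)
        assert summary["n"] > 200
        assert summary["mean_log2fc"] == pytest.approx(1.0, abs=0.15)
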