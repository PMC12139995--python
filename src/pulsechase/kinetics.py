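"""Degradation trajectories, decay-model fitting and half-life estimation.

The chase design: labeled protein is quantified at a handful of timepoints
after the pulse; the first timepoint (maximal labeling) is mapped to t = 0
and defines 100% remaining. Trajectories are gated on enrichment of the
first timepoint over wildtype background (log2 FC > 1.5 by default) and on
monotonicity (rises above 5 percentage points between consecutive
timepoints are attributed to measurement noise and the protein excluded).

Two decay models are fitted by bounded least squares:

* one-level: ``Λ1(t) = exp(-kA t)`` — single exponential loss, half-life
  ``ln 2 / kA``;
* two-level: label flows through a precursor pool before degradation,
  ``G(t) = kAB/(kAB+kA) · exp(-kB t) + kB/(kA-kB) · exp(-(kAB+kA) t)`` and
  ``Λ2(t) = (G(t) - G(pulse+tp)) / (G(0) - G(pulse+tp))``, normalized to 1
  at t = 0; half-life by linear interpolation of the fitted curve.

The model with the lower AIC, ``n·ln(RSS/n) + 2k``, is selected; ties and
failed two-level fits fall back to the one-level model (parsimony).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)

RSS_FLOOR = 1e-12
RATE_SEPARATION = 1e-4  # minimal |kA - kB| for the two-level curve
HALF_LIFE_HORIZON = 200.0  # days searched for the 50% crossing


@dataclass
class DegradationTrajectory:
    """Percent-remaining time course of one protein (TP1 = 100%)."""

    protein_id: str
    times: np.ndarray  # days, first element 0
    percent_remaining: np.ndarray  # first element 100
    age: str = "n/a"
    region: str = "n/a"
    tp1_abs_days: float = 0.0  # absolute chase time of TP1, kept as metadata
    passed_filters: bool = True
    reasons: tuple = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.percent_remaining = np.asarray(self.percent_remaining, dtype=float)
        if self.times.shape != self.percent_remaining.shape:
            raise ValueError("times and values must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def fraction_remaining(self) -> np.ndarray:
        return self.percent_remaining / 100.0


@dataclass
class KineticFit:
    """Fitted decay model for one trajectory."""

    protein_id: str
    model: str  # "one_level" | "two_level"
    k_a: float
    k_b: float | None = None
    k_ab: float | None = None
    pulse_days: float = 7.0
    tp_offset: float = 0.0
    rss: float = np.nan
    n_points: int = 0
    aic: float = np.nan
    half_life_days: float = np.nan
    method: str = "rate"  # "rate" | "interpolation"
    converged: bool = True
    flags: tuple = ()

    def curve(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "one_level":
            return np.exp(-self.k_a * t)
        return two_level_curve(
            t, self.k_a, self.k_b, self.k_ab, self.pulse_days, self.tp_offset
        )


# ---------------------------------------------------------------------------
# trajectory construction


def build_trajectories(
    matrix: AbundanceMatrix,
    background: AbundanceMatrix | None = None,
    tp1_log2fc_gate: float = 1.5,
    max_rise: float = 5.0,
    relative_rise: bool = False,
    require_complete: bool = False,
) -> list[DegradationTrajectory]:
    """Build percent-remaining trajectories with enrichment and rise filters.

    Works on non-normalized abundances. Per protein: (1) the log2 fold
    change of the TP1 replicate mean over the wildtype background mean must
    exceed ``tp1_log2fc_gate`` (else the protein is background and
    discarded); (2) percent remaining at TPk is ``100 · mean(TPk) /
    mean(TP1)``; (3) any rise between consecutive timepoints above
    ``max_rise`` percentage points excludes the trajectory as
    noise-dominated (``relative_rise=True`` switches to a 5%-of-previous-
    value rule). ``require_complete`` additionally demands a value in every
    labeled replicate (the stringent cross-age comparison filter).

    All proteins are returned with ``passed_filters``/``reasons`` set;
    use :func:`passing` to keep only the clean ones.
    """
    if matrix.log2_scale:
        raise ValueError("trajectories are built from raw (non-log) abundances")
    if background is None:
        background = matrix
    bg_cols = background.sample_names(group="background")
    if not bg_cols:
        raise ValueError("no background samples found")
    tps = matrix.timepoints()
    if len(tps) < 2:
        raise ValueError("need at least 2 chase timepoints")
    tp_cols = [matrix.sample_names(group="labeled", timepoint_days=t) for t in tps]
    if any(not c for c in tp_cols):
        raise ValueError("every timepoint needs labeled replicates")
    rel_times = np.asarray(tps) - tps[0]

    ages = matrix.samples.loc[matrix.samples["group"] == "labeled", "age"].unique()
    regions = matrix.samples.loc[matrix.samples["group"] == "labeled", "region"].unique()
    age = ages[0] if len(ages) == 1 else "n/a"
    region = regions[0] if len(regions) == 1 else "n/a"

    bg = background.data.reindex(matrix.data.index)[bg_cols]
    bg_mean = bg.mean(axis=1)

    out: list[DegradationTrajectory] = []
    for pid in matrix.data.index:
        reasons: list[str] = []
        row = matrix.data.loc[pid]
        means = np.array([row[cols].mean() for cols in tp_cols])
        tp1 = means[0]
        if not np.isfinite(tp1) or tp1 <= 0:
            reasons.append("tp1_zero")
        else:
            b = bg_mean.loc[pid]
            if np.isfinite(b) and b > 0:
                log2fc = np.log2(tp1 / b)
            else:
                log2fc = np.inf  # undetected in background: maximal enrichment
            if not log2fc > tp1_log2fc_gate:
                reasons.append("tp1_gate")
        if require_complete:
            all_cols = [c for cols in tp_cols for c in cols]
            if row[all_cols].isna().any():
                reasons.append("incomplete_replicates")
        if np.isnan(means).any():
            reasons.append("missing_timepoint")

        if reasons:
            pct = np.full(len(tps), np.nan)
            pct[0] = 100.0
            if not np.isnan(means).any() and np.isfinite(tp1) and tp1 > 0:
                pct = 100.0 * means / tp1
            out.append(
                DegradationTrajectory(
                    pid, rel_times, pct, age, region, tps[0], False, tuple(reasons)
                )
            )
            continue

        pct = 100.0 * means / tp1
        rises = np.diff(pct)
        limit = 0.05 * pct[:-1] if relative_rise else max_rise
        if np.any(rises > limit):
            reasons.append("rise_above_threshold")
        out.append(
            DegradationTrajectory(
                pid, rel_times, pct, age, region, tps[0],
                passed_filters=not reasons, reasons=tuple(reasons),
            )
        )
    n_pass = sum(t.passed_filters for t in out)
    logger.info(
        "build_trajectories: %d/%d passed (%s)",
        n_pass,
        len(out),
        exclusion_counts(out),
    )
    return out


def passing(trajs: list[DegradationTrajectory]) -> list[DegradationTrajectory]:
    return [t for t in trajs if t.passed_filters]


def exclusion_counts(trajs: list[DegradationTrajectory]) -> dict[str, int]:
    """Count excluded proteins by first reason code (retained + Σ = input)."""
    counts: dict[str, int] = {}
    for t in trajs:
        if not t.passed_filters:
            counts[t.reasons[0]] = counts.get(t.reasons[0], 0) + 1
    return counts


def trajectories_to_frame(trajs: list[DegradationTrajectory]) -> pd.DataFrame:
    rows = []
    for t in trajs:
        for ti, v in zip(t.times, t.percent_remaining):
            rows.append(
                {
                    "protein_id": t.protein_id,
                    "time_days": ti,
                    "percent_remaining": v,
                    "age": t.age,
                    "region": t.region,
                    "passed_filters": t.passed_filters,
                    "reasons": ";".join(t.reasons),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decay models


def two_level_curve(
    t, k_a: float, k_b: float, k_ab: float, pulse_days: float = 7.0, tp: float = 0.0
) -> np.ndarray:
    """Two-pool label decay, normalized to 1 at t = 0.

    ``G(t) = kAB/(kAB+kA) e^{-kB t} + kB/(kA-kB) e^{-(kAB+kA) t}`` and the
    observable curve ``(G(t) - G(pulse+tp)) / (G(0) - G(pulse+tp))``. The
    normalization pins the curve to 1 at the chase origin and to 0 at
    ``t = pulse + tp``.
    """
    t = np.asarray(t, dtype=float)
    if abs(k_a - k_b) < RATE_SEPARATION or (k_ab + k_a) <= 0:
        return np.full_like(t, np.nan)

    def g(x):
        return k_ab / (k_ab + k_a) * np.exp(-k_b * x) + k_b / (k_a - k_b) * np.exp(
            -(k_ab + k_a) * x
        )

    g_end = g(pulse_days + tp)
    denom = g(0.0) - g_end
    if denom == 0 or not np.isfinite(denom):
        return np.full_like(t, np.nan)
    return (g(t) - g_end) / denom


def _start_rates(n: int = 8) -> np.ndarray:
    """Multi-start grid: rates spanning half-lives 0.1–100 days."""
    return np.log(2.0) / np.logspace(np.log10(0.1), np.log10(100.0), n)


def fit_one_level(traj: DegradationTrajectory) -> KineticFit:
    """Least-squares single-exponential fit; half-life from the rate.

    The 1-D objective is scanned on a dense rate grid (half-lives 0.01–1000
    days plus kA = 0) and polished by bounded scalar minimization, so the
    global optimum is found without multi-start stochasticity.
    """
    t = traj.times
    y = traj.fraction_remaining
    if abs(y[0] - 1.0) > 1e-9:
        raise ValueError("trajectory must be normalized to 1 at t = 0")

    def rss_of(k):
        return float(np.sum((np.exp(-k * t) - y) ** 2))

    grid = np.concatenate([[0.0], np.log(2.0) / np.logspace(-2.0, 3.0, 120)[::-1]])
    rss_grid = np.sum((np.exp(-np.outer(grid, t)) - y) ** 2, axis=1)
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    k_a, rss = float(grid[i]), float(rss_grid[i])
    if hi > lo:
        sol = optimize.minimize_scalar(rss_of, bounds=(lo, hi), method="bounded")
        if sol.fun < rss:
            k_a, rss = float(sol.x), float(sol.fun)
    n = len(t)
    fit = KineticFit(
        traj.protein_id,
        "one_level",
        k_a,
        rss=rss,
        n_points=n,
        aic=aic(n, rss, 1),
        method="rate",
    )
    if k_a <= 0:
        fit.half_life_days = np.inf
        fit.flags = ("no_decay",)
    else:
        fit.half_life_days = np.log(2.0) / k_a
    return fit


def fit_two_level(
    traj: DegradationTrajectory,
    pulse_days: float = 7.0,
    tp: float = 0.0,
    n_starts: int = 8,
    seed: int = 0,
    k_a_hint: float | None = None,
) -> KineticFit:
    """Least-squares two-pool fit over (kA, kB, kAB); half-life interpolated.

    Multi-start local optimization over a fixed start grid; ``k_a_hint``
    (e.g. the one-level rate) centers the grid on plausible rates,
    otherwise starts span half-lives of 0.1–100 days. The fit is fully
    deterministic; ``seed`` is accepted for interface uniformity with the
    stochastic stages.
    """
    t = traj.times
    y = traj.fraction_remaining
    if abs(y[0] - 1.0) > 1e-9:
        raise ValueError("trajectory must be normalized to 1 at t = 0")

    def resid(params):
        k_a, k_b, k_ab = params
        curve = two_level_curve(t, k_a, k_b, k_ab, pulse_days, tp)
        if np.any(~np.isfinite(curve)):
            return np.full(len(t), 1e3)
        return curve - y

    dense = np.linspace(t[0], t[-1], 80)

    def is_monotone(params) -> bool:
        # rises below 1e-6 (curve scale 1) are numerical noise, not shape
        curve = two_level_curve(dense, *params, pulse_days, tp)
        return bool(np.all(np.isfinite(curve)) and np.all(np.diff(curve) <= 1e-6))

    lb = np.full(3, 1e-6)
    ub = np.full(3, 50.0)
    # a pulse-chase curve cannot rise: among local optima, monotone solutions
    # are preferred over (spurious) non-monotone ones at any RSS
    best, best_rss, best_mono, best_mono_rss = None, np.inf, None, np.inf
    if k_a_hint is not None and np.isfinite(k_a_hint) and k_a_hint > 0:
        base_rates = np.array([k_a_hint, 0.3 * k_a_hint, 3.0 * k_a_hint])
        kab_mults = (1.0,)
        ratios = (4.0, 0.25)
    else:
        base_rates = _start_rates(n_starts)
        kab_mults = (0.5, 2.0)
        ratios = (8.0, 4.0, 0.25)
    starts = [
        (k0, ratio, km)
        for k0 in base_rates
        for ratio in ratios
        for km in kab_mults
    ]
    for k0, ratio, km in starts:
        x0 = np.array([k0, min(k0 * ratio, 40.0), k0 * km])
        x0 = np.clip(x0, lb * 2, ub / 2)
        if abs(x0[0] - x0[1]) < RATE_SEPARATION:
            continue
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lb, ub))
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        rss = float(np.sum(sol.fun**2))
        if not np.isfinite(rss):
            continue
        if rss < best_rss:
            best, best_rss = sol, rss
        if rss < best_mono_rss and is_monotone(sol.x):
            best_mono, best_mono_rss = sol, rss
        if best_mono_rss < 1e-14:  # perfect monotone fit; stop searching
            break
    # take the monotone optimum unless it fits materially worse
    extra_flags: tuple = ()
    if best_mono is not None and best_mono_rss <= 4 * best_rss + 1e-12:
        best, best_rss = best_mono, best_mono_rss
    elif best is not None and not is_monotone(best.x):
        extra_flags = ("non_monotone",)

    n = len(t)
    if best is None or abs(best.x[0] - best.x[1]) < RATE_SEPARATION or best_rss >= 1e3:
        fit = KineticFit(
            traj.protein_id,
            "two_level",
            np.nan,
            k_b=np.nan,
            k_ab=np.nan,
            pulse_days=pulse_days,
            tp_offset=tp,
            rss=np.inf,
            n_points=n,
            aic=np.inf,
            method="interpolation",
            converged=False,
            flags=("fit_failed",),
        )
        return fit
    k_a, k_b, k_ab = (float(v) for v in best.x)
    fit = KineticFit(
        traj.protein_id,
        "two_level",
        k_a,
        k_b=k_b,
        k_ab=k_ab,
        pulse_days=pulse_days,
        tp_offset=tp,
        rss=best_rss,
        n_points=n,
        aic=aic(n, best_rss, 3),
        method="interpolation",
        flags=extra_flags,
    )
    fit.half_life_days = _curve_half_life(fit)
    return fit


def aic(n: int, rss: float, k: int, rss_floor: float = RSS_FLOOR) -> float:
    """Akaike information criterion ``n·ln(RSS/n) + 2k`` (RSS floored)."""
    if rss < rss_floor:
        logger.debug("aic: RSS %.3g floored at %.1g", rss, rss_floor)
        rss = rss_floor
    return n * np.log(rss / n) + 2 * k


def select_model(fit1: KineticFit, fit2: KineticFit) -> KineticFit:
    """Pick the lower-AIC fit; ties and failed two-level fits → one-level."""
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits must be computed on identical points")
    if not fit2.converged:
        return fit1
    return fit2 if fit2.aic < fit1.aic else fit1


def _curve_half_life(fit: KineticFit, horizon: float = HALF_LIFE_HORIZON) -> float:
    """50% crossing of the fitted curve by linear interpolation on a grid."""
    grid = np.linspace(0.0, horizon, 4001)
    curve = fit.curve(grid)
    below = np.nonzero(curve <= 0.5)[0]
    if len(below) == 0:
        return np.inf
    j = int(below[0])
    if j == 0:
        return 0.0
    t0, t1 = grid[j - 1], grid[j]
    y0, y1 = curve[j - 1], curve[j]
    return float(t0 + (y0 - 0.5) / (y0 - y1) * (t1 - t0))


def half_life(fit: KineticFit) -> float:
    """Half-life in days: ln2/kA (one-level) or curve interpolation (two-level)."""
    if fit.model == "one_level":
        if fit.k_a <= 0:
            return np.inf
        return np.log(2.0) / fit.k_a
    if not fit.converged:
        return np.nan
    return _curve_half_life(fit)


def interpolate_half_life_direct(traj: DegradationTrajectory) -> float:
    """Model-free half-life: first downward crossing of 50% remaining.

    Returns NaN when the trajectory never reaches 50%.
    """
    pct = traj.percent_remaining
    t = traj.times
    for i in range(1, len(pct)):
        if pct[i] <= 50.0 < pct[i - 1]:
            if pct[i] == 50.0:
                return float(t[i])
            return float(
                t[i - 1] + (t[i] - t[i - 1]) * (pct[i - 1] - 50.0) / (pct[i - 1] - pct[i])
            )
    return np.nan


def fit_trajectory(
    traj: DegradationTrajectory,
    pulse_days: float = 7.0,
    tp: float = 0.0,
    seed: int = 0,
) -> KineticFit:
    """Fit both models and return the AIC-selected one."""
    f1 = fit_one_level(traj)
    f2 = fit_two_level(traj, pulse_days=pulse_days, tp=tp, seed=seed, k_a_hint=f1.k_a)
    return select_model(f1, f2)


def fits_to_frame(fits: list[KineticFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "protein_id": f.protein_id,
                "model": f.model,
                "k_a": f.k_a,
                "k_b": f.k_b,
                "k_ab": f.k_ab,
                "rss": f.rss,
                "n_points": f.n_points,
                "aic": f.aic,
                "half_life_days": f.half_life_days,
                "method": f.method,
                "converged": f.converged,
                "flags": ";".join(f.flags),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


# ---------------------------------------------------------------------------
# cross-age / cross-region comparisons


def half_life_fold_changes(
    fits_young: list[KineticFit] | pd.DataFrame,
    fits_aged: list[KineticFit] | pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-protein log2 fold change of half-life (aged / young).

    Non-finite half-lives are excluded (count logged). Returns the paired
    table and a summary with the mean log2 FC and a paired t-test on the
    log2 half-lives between ages.
    """
    hy = _halflife_series(fits_young)
    ha = _halflife_series(fits_aged)
    common = hy.index.intersection(ha.index)
    if len(common) == 0:
        raise ValueError("no common proteins between ages")
    hy, ha = hy.loc[common], ha.loc[common]
    finite = np.isfinite(hy) & np.isfinite(ha) & (hy > 0) & (ha > 0)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("half_life_fold_changes: %d non-finite pairs excluded", n_dropped)
    hy, ha = hy[finite], ha[finite]
    table = pd.DataFrame(
        {
            "half_life_young": hy,
            "half_life_aged": ha,
            "log2fc": np.log2(ha / hy),
        }
    )
    if len(table) >= 2:
        tt = stats.ttest_rel(np.log2(ha), np.log2(hy))
        p = float(tt.pvalue)
    else:
        p = np.nan
    summary = {
        "n": int(len(table)),
        "n_excluded_nonfinite": n_dropped,
        "mean_log2fc": float(table["log2fc"].mean()),
        "median_log2fc": float(table["log2fc"].median()),
        "paired_t_p": p,
    }
    return table, summary


def _halflife_series(fits) -> pd.Series:
    if isinstance(fits, pd.DataFrame):
        return fits["half_life_days"]
    return pd.Series(
        {f.protein_id: f.half_life_days for f in fits}, name="half_life_days"
    )


def regional_vulnerability(
    fc_by_region: dict[str, pd.DataFrame], threshold: float = 1.0
) -> pd.DataFrame:
    """Flag proteins whose half-life fold change diverges between regions.

    For every region pair, a protein with ``|log2FC_r1 - log2FC_r2| >
    threshold`` is regionally vulnerable.
    """
    regions = sorted(fc_by_region)
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    rows = []
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1 :]:
            a = fc_by_region[r1]["log2fc"]
            b = fc_by_region[r2]["log2fc"]
            common = a.index.intersection(b.index)
            diff = (a.loc[common] - b.loc[common]).abs()
            for pid in common:
                rows.append(
                    {
                        "protein_id": pid,
                        "region_1": r1,
                        "region_2": r2,
                        "abs_log2fc_diff": float(diff.loc[pid]),
                        "vulnerable": bool(diff.loc[pid] > threshold),
                    }
                )
    return pd.DataFrame(rows)
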