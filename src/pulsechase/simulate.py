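"""Synthetic pulse-chase plex generator with known ground truth.

Emulates a multiplexed (TMT-style) pulse-chase degradation experiment: a
cohort of labeled proteins decays exponentially (or through a two-pool
precursor model) over a chase sampled at a handful of timepoints with a few
biological replicates each, alongside low-abundance wildtype background
channels that carry no label. Measurement noise is multiplicative
log-normal and missingness is missing-at-random. Every simulated protein
comes with its true decay rates, half-life and planted cluster label so
that downstream estimators can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, make_sample_sheet

#: default chase sampling: 16 h, 3 d, 7 d, 14 d after the start of the chase
DEFAULT_TIMEPOINTS = (16.0 / 24.0, 3.0, 7.0, 14.0)


@dataclass
class SimConfig:
    """Design and noise parameters of a simulated pulse-chase plex.

    Attributes
    ----------
    n_proteins : int
        Number of labeled proteins in the plex.
    timepoints_days : tuple of float
        Absolute chase times (days). The first timepoint is the origin of
        decay evaluation (decay is computed at ``t - timepoints[0]``); the
        absolute offset is retained in the sample sheet.
    n_replicates : int
        Biological replicates per timepoint (and background channels).
    halflife_median_days, halflife_dispersion : float
        Log-normal half-life distribution: median in days and standard
        deviation of the natural log.
    aged_halflife_fold : float
        Multiplicative shift applied to every half-life when simulating the
        aged condition of the same cohort.
    noise_cv : float
        Coefficient of variation of the multiplicative log-normal
        measurement noise.
    background_level : float
        Mean wildtype-channel abundance as a fraction of the labeled TP1
        abundance.
    dropout_rate : float
        Per-measurement probability of a missing value (MAR).
    n_clusters : int
        Planted kinetic clusters; cluster half-life medians are log-spaced
        over ``median / cluster_span .. median * cluster_span``.
    cluster_span : float
        Fold-range of planted cluster medians around the global median.
    two_pool_fraction : float
        Fraction of proteins whose label decays through the two-pool
        (precursor) model instead of a single exponential.
    baseline_median, baseline_dispersion : float
        Log-normal distribution of per-protein TP1 abundance.
    """

    n_proteins: int = 500
    timepoints_days: tuple = DEFAULT_TIMEPOINTS
    n_replicates: int = 4
    halflife_median_days: float = 5.0
    halflife_dispersion: float = 0.5
    aged_halflife_fold: float = 1.0
    noise_cv: float = 0.1
    background_level: float = 0.1
    dropout_rate: float = 0.0
    n_clusters: int = 1
    cluster_span: float = 3.0
    two_pool_fraction: float = 0.0
    baseline_median: float = 1e6
    baseline_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints_days)
        if len(tps) < 2:
            raise ValueError("invalid design: at least 2 chase timepoints required")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints_days = tps
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for name in ("dropout_rate", "two_pool_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_cv < 0 or self.background_level < 0:
            raise ValueError("noise_cv and background_level must be non-negative")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints_days"] = list(self.timepoints_days)
        return d


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def two_pool_curve(t, k_a: float, k_b: float, k_ab: float) -> np.ndarray:
    """Fraction of label remaining under the two-pool (precursor) model.

    G(t) = kAB/(kAB+kA) * exp(-kB t) + kB/(kA-kB) * exp(-(kAB+kA) t),
    shifted and scaled so the curve equals 1 at t = 0 and ~0 at the end of
    the modeled window (see :mod:`pulsechase.kinetics` for the fitted form).
    Here the generative version with pulse offset 0 is used.
    """
    from .kinetics import two_level_curve

    return two_level_curve(np.asarray(t, dtype=float), k_a, k_b, k_ab)


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    clusters = rng.integers(0, config.n_clusters, size=n)
    if config.n_clusters > 1:
        span = np.log(config.cluster_span)
        offsets = np.linspace(-span, span, config.n_clusters)
    else:
        offsets = np.zeros(1)
    log_median = np.log(config.halflife_median_days) + offsets[clusters]
    halflife = np.exp(rng.normal(log_median, config.halflife_dispersion))
    k_a = np.log(2.0) / halflife
    two_pool = rng.random(n) < config.two_pool_fraction
    # precursor pool turns over faster than the protein itself
    k_b = np.where(two_pool, k_a * rng.uniform(3.0, 8.0, size=n), np.nan)
    k_ab = np.where(two_pool, k_a * rng.uniform(1.0, 4.0, size=n), np.nan)
    baseline = np.exp(
        rng.normal(np.log(config.baseline_median), config.baseline_dispersion, size=n)
    )
    return pd.DataFrame(
        {
            "protein_id": ids,
            "k_a": k_a,
            "k_b": k_b,
            "k_ab": k_ab,
            "two_pool": two_pool,
            "half_life_days": halflife,
            "cluster": clusters,
            "baseline": baseline,
        }
    ).set_index("protein_id")


def _decay_values(truth: pd.DataFrame, rel_times: np.ndarray, fold: float) -> np.ndarray:
    """Noiseless fraction remaining, proteins × timepoints.

    ``fold`` > 1 slows every protein down (the aged condition); for two-pool
    proteins all three rates are scaled so the curve stretches in time.
    """
    out = np.empty((len(truth), len(rel_times)))
    k_a = truth["k_a"].to_numpy() / fold
    for i, (tp, ka, kb, kab) in enumerate(
        zip(truth["two_pool"], k_a, truth["k_b"] / fold, truth["k_ab"] / fold)
    ):
        if tp:
            # label is fully chased out once the curve hits its zero at
            # t = pulse; clip so abundances stay physical
            out[i] = np.clip(two_pool_curve(rel_times, ka, kb, kab), 0.0, None)
        else:
            out[i] = np.exp(-ka * rel_times)
    return out


def _true_halflife(truth: pd.DataFrame, fold: float, horizon: float = 500.0) -> np.ndarray:
    """Half-life of each protein's noiseless curve under the given fold."""
    hl = truth["half_life_days"].to_numpy() * fold
    if truth["two_pool"].any():
        grid = np.linspace(0.0, horizon, 20001)
        for i, (tp, ka, kb, kab) in enumerate(
            zip(
                truth["two_pool"],
                truth["k_a"] / fold,
                truth["k_b"] / fold,
                truth["k_ab"] / fold,
            )
        ):
            if not tp:
                continue
            curve = two_pool_curve(grid, ka, kb, kab)
            below = np.nonzero(curve <= 0.5)[0]
            if len(below) == 0:
                hl[i] = np.inf
                continue
            j = below[0]
            if j == 0:
                hl[i] = 0.0
            else:
                t0, t1 = grid[j - 1], grid[j]
                y0, y1 = curve[j - 1], curve[j]
                hl[i] = t0 + (y0 - 0.5) / (y0 - y1) * (t1 - t0)
    return hl


def simulate_plex(
    config: SimConfig, condition: str = "young", region: str = "ctx"
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Simulate one plex (one region × age) and return matrix + ground truth.

    The same ``config.seed`` draws the same protein cohort (rates, baselines,
    clusters) for every condition, so ``young`` and ``aged`` plexes from one
    config are biologically paired; measurement noise and dropout are
    independent between conditions. ``condition='aged'`` multiplies every
    half-life by ``config.aged_halflife_fold``.
    """
    if condition not in ("young", "middle", "aged"):
        raise ValueError(f"unknown condition {condition!r}")
    truth_rng = np.random.default_rng([config.seed, 0])
    cond_idx = ("young", "middle", "aged").index(condition)
    noise_rng = np.random.default_rng([config.seed, 1 + cond_idx])

    truth = _draw_truth(config, truth_rng)
    fold = config.aged_halflife_fold if condition == "aged" else 1.0

    tps = np.asarray(config.timepoints_days)
    rel_times = tps - tps[0]  # TP1 is the decay origin
    frac = _decay_values(truth, rel_times, fold)
    baseline = truth["baseline"].to_numpy()[:, None]

    n, r = config.n_proteins, config.n_replicates
    cols, values, meta_rows = [], [], []
    for j, t in enumerate(tps):
        for rep in range(1, r + 1):
            name = f"{condition}_{region}_tp{j + 1}_r{rep}"
            cols.append(name)
            noise = _lognormal_multiplier(noise_rng, config.noise_cv, n)
            values.append(baseline[:, 0] * frac[:, j] * noise)
            meta_rows.append(
                {
                    "sample": name,
                    "group": "labeled",
                    "replicate": rep,
                    "timepoint_days": float(t),
                    "age": condition,
                    "region": region,
                }
            )
    for rep in range(1, r + 1):
        name = f"{condition}_{region}_bg_r{rep}"
        cols.append(name)
        noise = _lognormal_multiplier(noise_rng, config.noise_cv, n)
        values.append(baseline[:, 0] * config.background_level * noise)
        meta_rows.append(
            {
                "sample": name,
                "group": "background",
                "replicate": rep,
                "timepoint_days": np.nan,
                "age": condition,
                "region": region,
            }
        )

    data = pd.DataFrame(
        np.column_stack(values), index=truth.index, columns=cols
    )
    if config.dropout_rate > 0:
        drop = noise_rng.random(data.shape) < config.dropout_rate
        data = data.mask(drop)

    gt = truth.copy()
    gt["condition"] = condition
    gt["half_life_days"] = _true_halflife(truth, fold)
    gt["k_a"] = gt["k_a"] / fold
    gt["k_b"] = gt["k_b"] / fold
    gt["k_ab"] = gt["k_ab"] / fold

    return AbundanceMatrix(data, make_sample_sheet(meta_rows)), gt


def simulate_age_pair(
    config: SimConfig, region: str = "ctx"
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, pd.DataFrame]:
    """Paired young and aged plexes of the same protein cohort."""
    young, gt_young = simulate_plex(config, "young", region)
    aged, gt_aged = simulate_plex(config, "aged", region)
    return young, aged, gt_young, gt_aged


# ---------------------------------------------------------------------------
# protein-set fixtures for overlap analyses


def simulate_protein_sets(
    background_n: int,
    set_sizes: list[int],
    planted_overlaps,
    seed: int = 0,
    set_names: list[str] | None = None,
) -> tuple[dict[str, set], list[str]]:
    """Draw protein sets from a synthetic universe with an exact overlap plan.

    Parameters
    ----------
    background_n
        Size of the background universe.
    set_sizes
        Size of each requested set.
    planted_overlaps
        For two sets, an int: the intersection size. In general, a mapping
        from tuples of set indices (length >= 2) to *exclusive* Venn-region
        counts, e.g. ``{(0, 1): 72, (1, 2): 40, (0, 1, 2): 67}``; regions
        not listed are empty.
    seed
        Shuffles which universe ids land in which region.

    Returns
    -------
    (sets, universe)
        ``sets`` maps set name to a python set of ids; ``universe`` is the
        full background id list.
    """
    k = len(set_sizes)
    if k < 1:
        raise ValueError("need at least one set")
    if isinstance(planted_overlaps, int):
        if k != 2:
            raise ValueError("an integer overlap plan requires exactly 2 sets")
        planted_overlaps = {(0, 1): planted_overlaps}
    regions: dict[tuple, int] = {}
    for key, count in planted_overlaps.items():
        key = tuple(sorted(set(key)))
        if len(key) < 2 or any(i < 0 or i >= k for i in key):
            raise ValueError(f"bad region key {key}")
        if count < 0:
            raise ValueError("region counts must be non-negative")
        regions[key] = regions.get(key, 0) + count

    # exclusive-only counts per set, after removing shared-region members
    shared_per_set = [0] * k
    for key, count in regions.items():
        for i in key:
            shared_per_set[i] += count
    only = []
    for i in range(k):
        rest = set_sizes[i] - shared_per_set[i]
        if rest < 0:
            raise ValueError(
                f"infeasible overlap structure: set {i} of size {set_sizes[i]} "
                f"cannot contain {shared_per_set[i]} shared members"
            )
        only.append(rest)
    total = sum(regions.values()) + sum(only)
    if total > background_n:
        raise ValueError(
            f"infeasible overlap structure: {total} distinct ids exceed "
            f"background of {background_n}"
        )

    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(background_n)]
    order = rng.permutation(background_n)
    names = set_names or [chr(ord("A") + i) for i in range(k)]
    sets: dict[str, set] = {nm: set() for nm in names}
    pos = 0
    for key, count in regions.items():
        ids = [universe[order[pos + j]] for j in range(count)]
        pos += count
        for i in key:
            sets[names[i]].update(ids)
    for i in range(k):
        ids = [universe[order[pos + j]] for j in range(only[i])]
        pos += only[i]
        sets[names[i]].update(ids)
    return sets, universe
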