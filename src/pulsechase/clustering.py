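"""Fuzzy c-means clustering of degradation trajectories and aging scores.

Young-age trajectory shapes are clustered with fuzzy c-means (soft
memberships, fuzzifier m); the cluster number is chosen from an elbow in
the minimum pairwise centroid distance across candidate c. Older ages are
projected onto the young clusters by protein identity so that per-cluster
aging effects can be scored: the trapezoidal area under each trajectory,
the delta integral (aged minus young area; positive = slower degradation
with age), and the least-squares slope of each trajectory, compared across
clusters by one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import DegradationTrajectory

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fuzzy c-means core


def _fcm_memberships(dist2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared point-centroid distances (n × c)."""
    # points sitting exactly on a centroid get full membership there
    exact = dist2 <= 1e-300
    u = np.zeros_like(dist2)
    hit = exact.any(axis=1)
    if hit.any():
        u[hit] = exact[hit] / exact[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        d = dist2[rest] ** (1.0 / (m - 1.0))
        u[rest] = (1.0 / d) / (1.0 / d).sum(axis=1, keepdims=True)
    return u


def fuzzy_c_means(
    x: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-7,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Standard fuzzy c-means on the rows of ``x``.

    Iterates membership/centroid updates until the objective
    ``Σ_ij u_ij^m ||x_i - v_j||²`` changes by less than ``tol``. Returns
    ``(memberships n×c, centroids c×p, objective history)``. Deterministic
    under ``seed`` (random membership initialization). Raises on
    non-convergence.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if c < 2:
        raise ValueError("c must be >= 2")
    if n < c:
        raise ValueError(f"need at least c={c} points, got {n}")
    if m <= 1.0:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        um = u**m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        dist2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        obj = float((um * dist2).sum())
        history.append(obj)
        u = _fcm_memberships(dist2, m)
        if abs(prev - obj) < tol:
            return u, centroids, history
        prev = obj
    raise RuntimeError(
        f"fuzzy c-means did not converge in {max_iter} iterations "
        f"(last objective {history[-1]:.4g}, c={c}, m={m})"
    )


def min_centroid_distance(centroids: np.ndarray) -> float:
    """Smallest pairwise Euclidean distance between centroids."""
    c = centroids.shape[0]
    return min(
        float(np.linalg.norm(centroids[i] - centroids[j]))
        for i, j in itertools.combinations(range(c), 2)
    )


@dataclass
class ClusterModel:
    """Fitted fuzzy clustering of a set of trajectories."""

    protein_ids: list[str]
    times: np.ndarray
    n_clusters: int
    fuzzifier: float
    memberships: pd.DataFrame  # proteins × clusters, rows sum to 1
    centroids: np.ndarray  # clusters × timepoints
    elbow: pd.DataFrame  # candidate c → min centroid distance
    seed: int

    @property
    def hard_labels(self) -> pd.Series:
        """Argmax membership; ties broken toward the lowest cluster index."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
            name="cluster",
        )


def _traj_matrix(trajs: list[DegradationTrajectory]) -> tuple[list[str], np.ndarray, np.ndarray]:
    times = trajs[0].times
    for t in trajs:
        if not np.array_equal(t.times, times):
            raise ValueError("trajectories must share one time grid")
    ids = [t.protein_id for t in trajs]
    x = np.vstack([t.percent_remaining for t in trajs])
    return ids, times, x


def choose_c_elbow(elbow: pd.DataFrame, frac: float = 0.25) -> int:
    """Elbow rule on minimum-centroid-distance vs candidate c.

    The distance stays large while added centroids still claim distinct
    real clusters and collapses once two centroids must share one: the
    collapse happens going *from* the true c to c+1. The chosen c is
    therefore the left endpoint of the last drop that reaches ``frac`` of
    the largest observed drop; drops below that fraction are treated as
    plateau jitter.
    """
    cs = elbow["c"].to_numpy()
    d = elbow["min_centroid_distance"].to_numpy()
    if len(cs) == 1:
        return int(cs[0])
    drops = -np.diff(d)
    biggest = drops.max()
    if biggest <= 0:
        return int(cs[0])
    big = [i for i, drop in enumerate(drops) if drop >= frac * biggest]
    return int(cs[big[-1]])


def cluster_young(
    trajs: list[DegradationTrajectory],
    c_candidates=range(2, 9),
    m: float = 2.0,
    seed: int = 0,
    elbow_frac: float = 0.25,
    c_override: int | None = None,
    standardize: bool = False,
) -> ClusterModel:
    """Cluster young trajectory shapes and pick c at the elbow.

    Trajectories are clustered on raw percent-remaining values (the shared
    100% origin already aligns them); ``standardize=True`` z-scores each
    timepoint first. ``c_override`` skips the elbow rule.
    """
    ids, times, x = _traj_matrix(trajs)
    feat = x.copy()
    if standardize:
        feat = (feat - feat.mean(axis=0)) / feat.std(axis=0, ddof=0)
    runs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    elbow_rows = []
    for c in c_candidates:
        if c > len(ids):
            break
        u, centroids, _ = fuzzy_c_means(feat, c, m=m, seed=seed)
        runs[c] = (u, centroids)
        elbow_rows.append({"c": c, "min_centroid_distance": min_centroid_distance(centroids)})
    if not runs:
        raise ValueError("no feasible cluster number candidates")
    elbow = pd.DataFrame(elbow_rows)
    c_chosen = c_override if c_override is not None else choose_c_elbow(elbow, elbow_frac)
    if c_chosen not in runs:
        raise ValueError(f"c_override={c_chosen} not among candidates")
    u, centroids = runs[c_chosen]
    logger.info("cluster_young: chose c=%d from %s", c_chosen, list(runs))
    return ClusterModel(
        ids,
        times,
        c_chosen,
        m,
        pd.DataFrame(u, index=pd.Index(ids, name="protein_id")),
        centroids,
        elbow,
        seed,
    )


def project_onto_reference(
    model: ClusterModel, trajs_other_age: list[DegradationTrajectory]
) -> pd.Series:
    """Assign each older-age protein its young-model hard cluster label.

    Proteins absent from the young model are excluded (count logged).
    """
    ref = model.hard_labels
    ids = [t.protein_id for t in trajs_other_age]
    shared = [pid for pid in ids if pid in ref.index]
    if not shared:
        raise ValueError("no proteins shared with the reference cluster model")
    dropped = len(ids) - len(shared)
    if dropped:
        logger.info("project_onto_reference: %d proteins not in reference", dropped)
    return ref.loc[shared]


# ---------------------------------------------------------------------------
# integrals, delta integrals, slopes


def trajectory_integral(traj: DegradationTrajectory) -> float:
    """Area under the trajectory by composite trapezoid (percent · days)."""
    if len(traj.times) < 2:
        raise ValueError("integral needs at least 2 points")
    return float(np.trapezoid(traj.percent_remaining, traj.times))


@dataclass
class IntegralScore:
    """Delta-integral aging scores per protein and per cluster."""

    per_protein: pd.DataFrame  # integral_young, integral_aged, delta, cluster
    per_cluster: pd.DataFrame  # cluster → mean delta, n
    anova_p: float
    tukey: pd.DataFrame | None


def _anova_tukey(values: pd.Series, groups: pd.Series) -> tuple[float, pd.DataFrame | None]:
    """One-way ANOVA across groups plus Tukey HSD (groups of size < 2 dropped)."""
    ok = [g for g, v in values.groupby(groups) if len(v) >= 2]
    if len(ok) < 2:
        return np.nan, None
    arrays = [values[groups == g].to_numpy() for g in ok]
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(ok)), 2):
        rows.append(
            {
                "group_1": ok[i],
                "group_2": ok[j],
                "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return anova_p, pd.DataFrame(rows)


def delta_integrals(
    young_trajs: list[DegradationTrajectory],
    aged_trajs: list[DegradationTrajectory],
    labels: pd.Series,
) -> IntegralScore:
    """Per-protein aged-minus-young trajectory areas, summarized by cluster.

    A positive delta means more area under the aged curve, i.e. slower
    degradation with age. Clusters with fewer than 2 members keep their
    average but are excluded from the ANOVA (warning logged).
    """
    young = {t.protein_id: t for t in young_trajs}
    aged = {t.protein_id: t for t in aged_trajs}
    common = [pid for pid in labels.index if pid in young and pid in aged]
    if not common:
        raise ValueError("no paired proteins between ages")
    rows = []
    for pid in common:
        iy = trajectory_integral(young[pid])
        ia = trajectory_integral(aged[pid])
        rows.append(
            {
                "protein_id": pid,
                "integral_young": iy,
                "integral_aged": ia,
                "delta": ia - iy,
                "cluster": labels.loc[pid],
            }
        )
    per_protein = pd.DataFrame(rows).set_index("protein_id")
    per_cluster = (
        per_protein.groupby("cluster")["delta"]
        .agg(mean_delta="mean", n="size")
        .reset_index()
    )
    small = per_cluster.loc[per_cluster["n"] < 2, "cluster"].tolist()
    if small:
        logger.warning("delta_integrals: clusters %s have < 2 members", small)
    anova_p, tukey = _anova_tukey(per_protein["delta"], per_protein["cluster"])
    return IntegralScore(per_protein, per_cluster, anova_p, tukey)


def cluster_slopes(
    trajs: list[DegradationTrajectory], labels: pd.Series
) -> tuple[pd.DataFrame, float, pd.DataFrame | None]:
    """Least-squares slope (percent/day) of each trajectory, by cluster."""
    rows = []
    for t in trajs:
        if t.protein_id not in labels.index:
            continue
        slope = float(np.polyfit(t.times, t.percent_remaining, 1)[0])
        rows.append(
            {
                "protein_id": t.protein_id,
                "slope": slope,
                "cluster": labels.loc[t.protein_id],
            }
        )
    if not rows:
        raise ValueError("no labeled trajectories")
    table = pd.DataFrame(rows).set_index("protein_id")
    anova_p, tukey = _anova_tukey(table["slope"], table["cluster"])
    return table, anova_p, tukey
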