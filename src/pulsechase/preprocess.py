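"""Enrichment-over-background preprocessing and hit calling.

Implements the standard fold-change-over-background workflow for metabolic
labeling experiments: log2 transform of non-normalized intensities,
valid-value filtering per sample group, left-shifted Gaussian imputation of
missing values (per sample column, parameterized by a width and downshift
in units of the column standard deviation), and per-protein two-tailed
t-tests of labeled vs wildtype background channels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)


def _parse_min_valid(min_valid) -> tuple[float, int | None]:
    """Accept a fraction or a 'k/n' preset; return (fraction, explicit_k)."""
    if isinstance(min_valid, str):
        k, n = (int(x) for x in min_valid.split("/"))
        if not 0 < k <= n:
            raise ValueError(f"bad min-valid preset {min_valid!r}")
        return k / n, k
    frac = float(min_valid)
    if not 0 < frac <= 1:
        raise ValueError("min_valid_fraction must be in (0, 1]")
    return frac, None


def filter_valid_values(
    matrix: AbundanceMatrix, min_valid=0.51, scope: str = "per-group"
) -> AbundanceMatrix:
    """Keep proteins quantified in enough replicates of at least one group.

    A protein is retained when at least ``ceil(fraction * group size)``
    samples of some group carry a value. The default fraction (0.51, just
    above half) reproduces the usual per-experiment rules: 3 of 4, 2 of 3,
    2 of 2. ``min_valid`` also accepts a "k/n" preset string, in which case
    exactly k present values are required in a group of matching size.
    """
    frac, explicit_k = _parse_min_valid(min_valid)
    if matrix.n_proteins == 0:
        logger.warning("filter_valid_values: empty matrix")
        return matrix
    if scope not in ("per-group", "global"):
        raise ValueError(f"unknown scope {scope!r}")

    present = matrix.data.notna()
    if scope == "global":
        group_cols = {"all": list(matrix.data.columns)}
    else:
        group_cols = {
            g: matrix.sample_names(group=g)
            for g in matrix.samples["group"].unique()
        }
    keep = pd.Series(False, index=matrix.data.index)
    for g, cols in group_cols.items():
        if not cols:
            continue
        need = explicit_k if explicit_k is not None else math.ceil(frac * len(cols))
        need = min(need, len(cols))
        keep |= present[cols].sum(axis=1) >= need
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_valid_values: dropped %d proteins", dropped)
    return AbundanceMatrix(
        matrix.data.loc[keep].copy(), matrix.samples.copy(), matrix.log2_scale
    )


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Log2-transform abundances; zeros become missing (counted in the log)."""
    if matrix.log2_scale:
        raise ValueError("matrix is already log2 scale")
    vals = matrix.data.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative abundances cannot be log-transformed")
    n_zero = int(np.nansum(vals == 0))
    if n_zero:
        logger.info("log2_transform: %d zero cells coerced to missing", n_zero)
    with np.errstate(divide="ignore"):
        out = np.where(np.isnan(vals) | (vals == 0), np.nan, np.log2(vals))
    return AbundanceMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        matrix.samples.copy(),
        log2_scale=True,
    )


def impute_missing(
    matrix: AbundanceMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | None = 0,
    per_column: bool = True,
) -> AbundanceMatrix:
    """Replace missing log2 values by draws from a down-shifted Gaussian.

    Each missing cell in sample column *s* is drawn from
    ``Normal(mean_s - downshift * sd_s, (width * sd_s)^2)`` where the mean
    and sd are computed from the column's present values — the convention
    that emulates the left-censored tail of sub-detection-limit proteins.
    With ``per_column=False`` the whole-matrix mean/sd are used instead.
    """
    if not matrix.log2_scale:
        raise ValueError("impute_missing expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    if not data.isna().any().any():
        return AbundanceMatrix(data, matrix.samples.copy(), True)

    if per_column:
        stats_cols = {}
        for col in data.columns:
            present = data[col].dropna()
            if len(present) < 2:
                raise ValueError(
                    f"column {col!r} has fewer than 2 present values; "
                    "cannot estimate imputation moments (use per_column=False "
                    "to fall back to whole-matrix statistics)"
                )
            stats_cols[col] = (present.mean(), present.std(ddof=1))
        for col in data.columns:
            miss = data[col].isna()
            if not miss.any():
                continue
            mu, sd = stats_cols[col]
            draws = rng.normal(mu - downshift * sd, width * sd, size=int(miss.sum()))
            data.loc[miss, col] = draws
    else:
        flat = data.to_numpy(dtype=float)
        present = flat[~np.isnan(flat)]
        if present.size < 2:
            raise ValueError("fewer than 2 present values in the whole matrix")
        mu, sd = present.mean(), present.std(ddof=1)
        miss = np.isnan(flat)
        flat[miss] = rng.normal(mu - downshift * sd, width * sd, size=int(miss.sum()))
        data = pd.DataFrame(flat, index=data.index, columns=data.columns)
    return AbundanceMatrix(data, matrix.samples.copy(), True)


@dataclass
class HitTable:
    """Per-protein fold change over background with t-test p values."""

    table: pd.DataFrame  # columns: log2fc, p_value, hit[, p_adj]
    log2fc_cutoff: float
    p_cutoff: float

    @property
    def hits(self) -> pd.Index:
        return self.table.index[self.table["hit"]]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(t.pvalue)
    return 1.0 if np.isnan(p) else p


def call_hits(
    matrix: AbundanceMatrix,
    labeled_group: str = "labeled",
    background_group: str = "background",
    log2fc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    equal_var: bool = False,
    adjust: str | None = None,
) -> HitTable:
    """Call labeled hits by log2 fold change over background + t-test.

    ``log2fc_cutoff=1`` is the stringent preset (>2-fold over background);
    ``log2fc_cutoff=0`` the permissive one for rare-label experiments.
    Welch's unequal-variance t-test by default (``equal_var=True`` for the
    pooled flavor). ``adjust='bh'`` adds Benjamini–Hochberg adjusted p
    values and gates the hit flag on them.
    """
    if not matrix.log2_scale:
        raise ValueError("call_hits expects log2-scale (filtered, imputed) data")
    lab_cols = matrix.sample_names(group=labeled_group)
    bg_cols = matrix.sample_names(group=background_group)
    if len(lab_cols) < 2 or len(bg_cols) < 2:
        raise ValueError("both groups need >= 2 samples")
    lab = matrix.data[lab_cols].to_numpy(dtype=float)
    bg = matrix.data[bg_cols].to_numpy(dtype=float)
    if np.isnan(lab).any() or np.isnan(bg).any():
        raise ValueError("missing values remain; filter and impute first")

    log2fc = lab.mean(axis=1) - bg.mean(axis=1)
    pvals = np.array(
        [_welch_or_pooled(lab[i], bg[i], equal_var) for i in range(lab.shape[0])]
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals}, index=matrix.data.index
    )
    p_gate = pvals
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(pvals, method="fdr_bh")[1]
        p_gate = table["p_adj"].to_numpy()
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["hit"] = (log2fc > log2fc_cutoff) & (p_gate < p_cutoff)
    return HitTable(table, log2fc_cutoff, p_cutoff)
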