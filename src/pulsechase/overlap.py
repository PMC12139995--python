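"""Protein-set overlap statistics against a labeled-proteome background.

Partitions two or three protein lists into Venn regions, tests each
pairwise overlap for enrichment over chance with an exact hypergeometric
upper tail (``P(X >= observed)`` for ``X ~ Hypergeom(N, |A|, |B|)``), and
summarizes multi-aberration burden (how many proteins of a focal list fall
in at least one aberration list). The default background universe is the
3787 maximally detectable labeled neuronal proteins; always pass the
background appropriate to your experiment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_N = 3787


@dataclass
class OverlapResult:
    """Venn partition plus per-pair hypergeometric enrichment."""

    background_n: int
    set_sizes: dict[str, int]
    partition: dict[frozenset, int]  # exclusive Venn region → count
    pairwise: dict[tuple, dict]  # (name_a, name_b) → p/enrichment/expected/observed
    triple: dict | None = None

    def region(self, *names: str) -> int:
        return self.partition.get(frozenset(names), 0)

    def observed_overlap(self, a: str, b: str) -> int:
        """Total pairwise intersection: every region containing both sets."""
        return sum(
            count for key, count in self.partition.items() if a in key and b in key
        )


def venn_partition(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive region counts for 2 or 3 deduplicated id collections."""
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_partition supports 2 or 3 sets")
    partition: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            ) if len(combo) < len(names) else set()
            partition[frozenset(combo)] = len(inside - outside)
    return partition


def hypergeom_enrichment(
    size_a: int,
    size_b: int,
    observed: int,
    background_n: int | None = None,
) -> tuple[float, float, float]:
    """Upper-tail hypergeometric overlap test of two sets.

    Returns ``(p, enrichment, expected)`` where ``p = P(X >= observed)``
    for ``X ~ Hypergeom(N, size_a, size_b)``, ``expected =
    size_a·size_b/N`` and ``enrichment = observed/expected``.
    """
    n = DEFAULT_BACKGROUND_N if background_n is None else background_n
    if background_n is None:
        logger.info("hypergeom_enrichment: using default background N=%d", n)
    if size_a > n or size_b > n:
        raise ValueError("set size exceeds background")
    if observed > min(size_a, size_b):
        raise ValueError("overlap exceeds the smaller set")
    expected = size_a * size_b / n
    p = float(stats.hypergeom.sf(observed - 1, n, size_a, size_b))
    enrichment = observed / expected if expected > 0 else np.nan
    return p, enrichment, expected


def analyze_overlap(
    sets: dict[str, set], background_n: int | None = None
) -> OverlapResult:
    """Full overlap analysis: partition + pairwise (and 3-way) enrichment.

    Pairwise overlaps are totals (any triple region included). The 3-way
    expected count uses the independence approximation |A||B||C|/N².
    """
    n = DEFAULT_BACKGROUND_N if background_n is None else background_n
    partition = venn_partition(sets)
    sizes = {name: len(s) for name, s in sets.items()}
    result = OverlapResult(n, sizes, partition, {})
    for a, b in itertools.combinations(sets, 2):
        obs = result.observed_overlap(a, b)
        p, enr, exp = hypergeom_enrichment(sizes[a], sizes[b], obs, n)
        result.pairwise[(a, b)] = {
            "observed": obs,
            "expected": exp,
            "enrichment": enr,
            "p": p,
        }
    if len(sets) == 3:
        names = list(sets)
        obs3 = partition[frozenset(names)]
        exp3 = sizes[names[0]] * sizes[names[1]] * sizes[names[2]] / n**2
        result.triple = {
            "observed": obs3,
            "expected": exp3,
            "enrichment": obs3 / exp3 if exp3 > 0 else np.nan,
            "note": "expected count assumes full independence (|A||B||C|/N^2)",
        }
    return result


@dataclass
class BurdenSummary:
    """How many focal proteins carry at least one aberration."""

    focal_size: int
    count: int
    fraction_pct: float


def burden_summary(focal_set: set, aberration_sets: list[set]) -> BurdenSummary:
    """Fraction of a focal list found in the union of aberration lists."""
    if not focal_set:
        raise ValueError("focal set is empty")
    union: set = set().union(*aberration_sets) if aberration_sets else set()
    count = len(focal_set & union)
    pct = round(100.0 * count / len(focal_set), 2)
    return BurdenSummary(len(focal_set), count, pct)


def fold_change_to_percent(log2fc: float) -> float:
    """Convert a log2 fold change to percent change: ``100·(2^fc − 1)``."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    return 100.0 * (2.0**log2fc - 1.0)


def read_protein_list(path) -> set:
    """One id per line; a GMT-like row (name, description, ids...) also works."""
    ids: set = set()
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) == 1 and "\t" in lines[0]:
        parts = lines[0].split("\t")
        ids.update(parts[2:] if len(parts) > 2 else parts)
    else:
        for ln in lines:
            ids.add(ln.split("\t")[0])
    return ids
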