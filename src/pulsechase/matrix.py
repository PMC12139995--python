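"""Protein abundance matrices with per-sample metadata.

The central container is :class:`AbundanceMatrix`: a proteins × samples
table of non-negative reporter intensities (NaN = missing) plus a sample
sheet annotating each column with its experimental role (labeled vs
wildtype background), replicate, chase timepoint, age group and brain
region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("labeled", "background")
AGES = ("young", "middle", "aged", "n/a")

#: sample-sheet columns, in canonical order
META_COLUMNS = ("sample", "group", "replicate", "timepoint_days", "age", "region")


@dataclass
class AbundanceMatrix:
    """Proteins × samples abundance table with sample annotations.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein id; columns are sample names;
        values are non-negative abundances or NaN for missing.
    samples
        DataFrame indexed by sample name with columns ``group``
        (``labeled``/``background``), ``replicate``, ``timepoint_days``
        (float or NaN), ``age`` and ``region``.
    log2_scale
        Whether ``data`` holds log2-transformed values.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dupes[:5]}")
        missing = [s for s in self.data.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        bad = set(self.samples["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")
        if not self.log2_scale:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("abundances must be non-negative on the raw scale")

    # -- convenience selectors -------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    def sample_names(self, **criteria) -> list[str]:
        """Sample names matching all given metadata ``column=value`` pairs."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return [s for s in self.data.columns if mask.get(s, False)]

    def subset(self, samples: list[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.data[samples].copy(), self.samples.loc[samples].copy(), self.log2_scale
        )

    def timepoints(self) -> list[float]:
        """Sorted distinct chase timepoints of the labeled samples (days)."""
        tps = self.samples.loc[
            self.samples["group"] == "labeled", "timepoint_days"
        ].dropna()
        return sorted(set(float(t) for t in tps))

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, data_path, samples_path) -> None:
        out = self.data.copy()
        out.index.name = "protein_id"
        out.to_csv(data_path, sep="\t")
        meta = self.samples.reset_index()
        meta.columns = ["sample"] + list(meta.columns[1:])
        meta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, data_path, samples_path, log2_scale: bool = False) -> "AbundanceMatrix":
        data = pd.read_csv(data_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t").set_index("sample")
        return cls(data, meta, log2_scale=log2_scale)


def make_sample_sheet(rows: list[dict]) -> pd.DataFrame:
    """Build a sample sheet from dicts; fills optional fields with defaults."""
    df = pd.DataFrame(rows)
    for col, default in (
        ("replicate", 1),
        ("timepoint_days", np.nan),
        ("age", "n/a"),
        ("region", "n/a"),
    ):
        if col not in df.columns:
            df[col] = default
    return df.set_index("sample")[list(META_COLUMNS[1:])]
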