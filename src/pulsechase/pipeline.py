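"""End-to-end orchestration: simulate → enrich → turnover → cluster → overlap.

A :class:`PipelineConfig` mirrors every stage flag, round-trips through
YAML/JSON losslessly and rejects unknown keys. All randomness flows from
one root seed, split deterministically per stage, so identical config +
seed gives byte-identical numeric outputs. Every report carries a
provenance block (package version, UTC timestamp, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix import AbundanceMatrix
from .simulate import SimConfig, simulate_plex
from .preprocess import filter_valid_values, log2_transform, impute_missing, call_hits
from .kinetics import (
    build_trajectories,
    passing,
    exclusion_counts,
    fit_trajectory,
    fits_to_frame,
    trajectories_to_frame,
    half_life_fold_changes,
)
from .clustering import (
    cluster_young,
    project_onto_reference,
    delta_integrals,
)
from .overlap import analyze_overlap, burden_summary, read_protein_list

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    seed: int = 0
    # simulate stage (set simulate=False to read input TSVs instead)
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    abundance_tsv: str | None = None
    samples_tsv: str | None = None
    # enrich stage
    min_valid: str | float = 0.51
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    log2fc_cutoff: float = 1.0
    p_cutoff: float = 0.05
    # turnover stage
    tp1_log2fc_gate: float = 1.5
    max_rise: float = 5.0
    pulse_days: float = 7.0
    tp_offset: float = 0.0
    compare_ages: bool = True
    # cluster stage
    c_min: int = 2
    c_max: int = 8
    fuzzifier: float = 2.0
    elbow_frac: float = 0.25
    # overlap stage (optional list files)
    protein_lists: dict = field(default_factory=dict)  # name → path
    background_n: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seeds(root_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2^31 derived from one root."""
    rng = np.random.default_rng(root_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def provenance(config: PipelineConfig) -> dict:
    return {
        "package": "pulsechase",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every configured stage; returns a report dict (also written as JSON).

    Stages never mutate their on-disk inputs; each writes its own TSV/JSON
    outputs under ``outdir``. Any stage failure raises :class:`StageError`
    naming the stage, leaving earlier outputs in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {"provenance": provenance(config), "config": config.to_dict()}
    config.to_yaml(outdir / "config.yaml")

    # -- simulate / load ----------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = SimConfig(**{**config.sim, "seed": seeds[0]})
            young, truth_y = simulate_plex(sim_cfg, "young")
            young.to_tsv(outdir / "abundance_young.tsv", outdir / "samples_young.tsv")
            truth_y.to_csv(outdir / "ground_truth_young.tsv", sep="\t")
            aged = truth_a = None
            if config.compare_ages and sim_cfg.aged_halflife_fold != 1.0:
                aged, truth_a = simulate_plex(sim_cfg, "aged")
                aged.to_tsv(outdir / "abundance_aged.tsv", outdir / "samples_aged.tsv")
                truth_a.to_csv(outdir / "ground_truth_aged.tsv", sep="\t")
            report["simulate"] = {"config": sim_cfg.to_dict()}
        else:
            if not (config.abundance_tsv and config.samples_tsv):
                raise ValueError("simulate=False requires abundance_tsv and samples_tsv")
            young = AbundanceMatrix.from_tsv(config.abundance_tsv, config.samples_tsv)
            aged = None
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    # -- enrich -------------------------------------------------------------
    stage = "enrich"
    try:
        filtered = filter_valid_values(young, config.min_valid)
        logged = log2_transform(filtered)
        imputed = impute_missing(
            logged, config.impute_width, config.impute_downshift, seed=seeds[1]
        )
        hits = call_hits(
            imputed,
            log2fc_cutoff=config.log2fc_cutoff,
            p_cutoff=config.p_cutoff,
        )
        hits.to_tsv(outdir / "hits.tsv")
        report["enrich"] = {
            "n_input": int(young.n_proteins),
            "n_after_filter": int(filtered.n_proteins),
            "n_hits": int(len(hits.hits)),
        }
    except Exception as e:
        raise StageError(stage, e) from e

    # -- turnover -----------------------------------------------------------
    stage = "turnover"
    try:
        trajs_y = build_trajectories(
            young, tp1_log2fc_gate=config.tp1_log2fc_gate, max_rise=config.max_rise
        )
        keep_y = passing(trajs_y)
        trajectories_to_frame(trajs_y).to_csv(
            outdir / "trajectories_young.tsv", sep="\t", index=False
        )
        fits_y = [
            fit_trajectory(t, config.pulse_days, config.tp_offset, seed=seeds[2])
            for t in keep_y
        ]
        fits_to_frame(fits_y).to_csv(outdir / "fits_young.tsv", sep="\t")
        report["turnover"] = {
            "n_input": len(trajs_y),
            "n_passed": len(keep_y),
            "excluded_by_reason": exclusion_counts(trajs_y),
        }
        fits_a = None
        trajs_a_keep = None
        if aged is not None:
            trajs_a = build_trajectories(
                aged, tp1_log2fc_gate=config.tp1_log2fc_gate, max_rise=config.max_rise
            )
            trajs_a_keep = passing(trajs_a)
            fits_a = [
                fit_trajectory(t, config.pulse_days, config.tp_offset, seed=seeds[2])
                for t in trajs_a_keep
            ]
            fits_to_frame(fits_a).to_csv(outdir / "fits_aged.tsv", sep="\t")
            fc_table, fc_summary = half_life_fold_changes(fits_y, fits_a)
            fc_table.to_csv(outdir / "halflife_fold_changes.tsv", sep="\t")
            report["turnover"]["age_comparison"] = fc_summary
    except Exception as e:
        raise StageError(stage, e) from e

    # -- cluster ------------------------------------------------------------
    stage = "cluster"
    try:
        if len(keep_y) >= max(config.c_min, 2):
            model = cluster_young(
                keep_y,
                c_candidates=range(config.c_min, config.c_max + 1),
                m=config.fuzzifier,
                seed=seeds[3],
                elbow_frac=config.elbow_frac,
            )
            model.memberships.to_csv(outdir / "memberships.tsv", sep="\t")
            pd.DataFrame(model.centroids, columns=[f"t{t:g}" for t in model.times]).to_csv(
                outdir / "centroids.tsv", sep="\t", index_label="cluster"
            )
            model.hard_labels.to_csv(outdir / "labels.tsv", sep="\t")
            report["cluster"] = {
                "c_chosen": model.n_clusters,
                "elbow": model.elbow.to_dict(orient="records"),
            }
            if trajs_a_keep:
                labels_a = project_onto_reference(model, trajs_a_keep)
                score = delta_integrals(keep_y, trajs_a_keep, labels_a)
                score.per_protein.to_csv(outdir / "delta_integrals.tsv", sep="\t")
                report["cluster"]["delta_integrals"] = {
                    "per_cluster": score.per_cluster.to_dict(orient="records"),
                    "anova_p": score.anova_p,
                }
        else:
            report["cluster"] = {"skipped": "too few passing trajectories"}
    except Exception as e:
        raise StageError(stage, e) from e

    # -- overlap ------------------------------------------------------------
    stage = "overlap"
    try:
        if config.protein_lists:
            sets = {n: read_protein_list(p) for n, p in config.protein_lists.items()}
            res = analyze_overlap(sets, config.background_n)
            names = list(sets)
            burden = None
            if len(names) >= 2:
                b = burden_summary(sets[names[0]], [sets[n] for n in names[1:]])
                burden = dataclasses.asdict(b)
            report["overlap"] = {
                "background_n": res.background_n,
                "set_sizes": res.set_sizes,
                "partition": {"+".join(sorted(k)): v for k, v in res.partition.items()},
                "pairwise": {f"{a}|{b}": v for (a, b), v in res.pairwise.items()},
                "triple": res.triple,
                "burden_first_vs_rest": burden,
            }
    except Exception as e:
        raise StageError(stage, e) from e

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
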