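"""End-to-end orchestration: manifest -> clone tables -> diversity -> dynamics
-> similarity -> hematopoietic scores -> indices.

The pipeline is a pure function of its input files and configuration: rerun
with the same inputs it writes byte-identical tabular outputs (the run log
carries no timestamps for the same reason).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from tcrdyn.clonotype import build_clone_table, clone_table_frame, expanded_cell_fraction
from tcrdyn.contig_io import ChainPolicy, assemble_clonotypes, read_contig_table
from tcrdyn.diversity import diversity_profile
from tcrdyn.dynamics import (
    classify_dynamics_exact_test,
    classify_dynamics_foldchange,
    match_clones,
    summarize_patient,
)
from tcrdyn.hemascore import (
    load_reference,
    predictive_index,
    recovery_score,
    score_panel,
    therapeutic_index,
)
from tcrdyn.similarity import cross_set_similarity

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    manifest: str
    output_dir: str
    blood_counts: str | None = None
    reference: str | None = None
    key_level: str = "nt"
    require_trb: bool = False
    expanded_min: int = 3
    highly_min: int = 10
    min_cells: int = 20
    up: float = 2.0
    down: float = 0.5
    alpha: float = 0.05
    lfc: float = 1.0
    classifier: str = "foldchange"  # or "exact"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.classifier not in ("foldchange", "exact"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not (self.down <= 1.0 <= self.up):
            raise ValueError("fold thresholds must bracket 1.0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    output_dir: Path
    diversity: pd.DataFrame
    summaries: pd.DataFrame
    indices: dict
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_sample(cfg: RunConfig, path: Path, sample_id: str):
    contigs = read_contig_table(path)
    cells = assemble_clonotypes(
        contigs,
        key_level=cfg.key_level,
        chain_policy=ChainPolicy(require_trb=cfg.require_trb),
    )
    return build_clone_table(cells, sample_id=sample_id, key_level=cfg.key_level)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full analysis described by ``cfg``.

    Emits, under ``cfg.output_dir``: per-clone tables (``clone_tables.tsv``),
    per-sample diversity (``diversity.tsv``), per-clone dynamics
    (``dynamics.tsv``), per-patient summaries (``patient_summaries.tsv``),
    per-patient new-vs-pre-existing similarity (``similarity.tsv``),
    blood-count scores (``hemascore.tsv``) and correlation indices
    (``indices.json``) when blood counts are supplied, plus the effective
    config and a run log. Failing patients are isolated and reported in
    ``RunResult.failures`` rather than aborting the run.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tcrdyn")
    root.addHandler(handler)
    root.setLevel(cfg.log_level)
    try:
        return _run(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, outdir: Path) -> RunResult:
    manifest = pd.read_csv(cfg.manifest, sep="\t")
    manifest_dir = Path(cfg.manifest).parent
    if "cohort" not in manifest.columns:
        manifest["cohort"] = "patient"
    log.info("manifest: %d samples, %d patients",
             len(manifest), manifest.patient_id.nunique())

    # paired-sample sanity: a post sample needs a pre sample
    by_patient = manifest.groupby("patient_id").timepoint.apply(set)
    orphans = sorted(p for p, tps in by_patient.items() if tps == {"post"})
    if orphans:
        raise ValueError(f"post sample(s) without a paired pre sample: {orphans}")

    failures: list[str] = []
    tables: dict[tuple[str, str], object] = {}
    diversity_rows, clone_frames = [], []
    for row in manifest.itertuples():
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_dir / path
        sample_id = f"{row.patient_id}_{row.timepoint}"
        try:
            table = _load_sample(cfg, path, sample_id)
        except Exception as exc:  # isolate the failing sample
            log.error("sample %s failed: %s", sample_id, exc)
            failures.append(f"{sample_id}: {exc}")
            continue
        tables[(row.patient_id, row.timepoint)] = table
        prof = diversity_profile(table)
        diversity_rows.append(
            {
                "sample_id": sample_id,
                "patient_id": row.patient_id,
                "timepoint": row.timepoint,
                "cohort": row.cohort,
                "total_cells": table.total_cells,
                "n_clones": prof.n_clones,
                "shannon_bits": prof.shannon_bits,
                "gini": prof.gini,
                "expanded_cell_fraction": expanded_cell_fraction(
                    table, cfg.expanded_min
                ),
            }
        )
        clone_frames.append(clone_table_frame(table, cfg.expanded_min, cfg.highly_min))

    diversity = pd.DataFrame(diversity_rows)
    dynamics_rows, summary_rows, similarity_rows = [], [], []
    summaries = []
    for patient_id in manifest.patient_id.unique():
        pre = tables.get((patient_id, "pre"))
        post = tables.get((patient_id, "post"))
        if pre is None or post is None:
            if pre is not None and "post" not in by_patient.get(patient_id, set()):
                log.info("patient %s has a single timepoint; dynamics skipped",
                         patient_id)
            continue
        try:
            dyn = match_clones(pre, post, patient_id=patient_id)
            for d in dyn:
                if cfg.classifier == "exact":
                    classify_dynamics_exact_test(
                        d, pre.total_cells, post.total_cells,
                        alpha=cfg.alpha, lfc=cfg.lfc, min_cells=cfg.min_cells)
                else:
                    classify_dynamics_foldchange(
                        d, min_cells=cfg.min_cells, up=cfg.up, down=cfg.down)
            summary = summarize_patient(dyn, expanded_min=cfg.expanded_min)
            summaries.append(summary)
            summary_rows.append(asdict(summary))
            for d in dyn:
                dynamics_rows.append(
                    {
                        "patient_id": d.patient_id,
                        "clonotype_key": d.clonotype_key,
                        "pre_count": d.pre_count,
                        "post_count": d.post_count,
                        "pre_freq": d.pre_freq,
                        "post_freq": d.post_freq,
                        "fold_change": "" if d.fold_change is None else d.fold_change,
                        "origin": d.origin,
                        "dynamics_class": d.dynamics_class,
                    }
                )
            new_seqs = sorted({d.cdr3b_aa for d in dyn
                               if d.origin == "new" and d.cdr3b_aa})
            pre_seqs = sorted({d.cdr3b_aa for d in dyn
                               if d.origin == "pre_existing" and d.cdr3b_aa})
            if new_seqs and pre_seqs:
                sim = cross_set_similarity(
                    new_seqs, pre_seqs, labels=("new", "pre_existing"))
                similarity_rows.append(
                    {
                        "patient_id": patient_id,
                        "set_a": sim.set_a_label,
                        "set_b": sim.set_b_label,
                        "n_new_clones": len(new_seqs),
                        "n_pre_existing_clones": len(pre_seqs),
                        "mean_max_similarity": sim.mean_max_similarity,
                    }
                )
        except Exception as exc:
            log.error("patient %s failed: %s", patient_id, exc)
            failures.append(f"{patient_id}: {exc}")

    summaries_df = pd.DataFrame(summary_rows)

    indices: dict = {}
    hemascore_rows = []
    if cfg.blood_counts and cfg.reference:
        reference = load_reference(cfg.reference)
        blood = pd.read_csv(cfg.blood_counts, sep="\t")
        panels: dict[tuple[str, str], object] = {}
        for row in blood.itertuples():
            panel = score_panel(
                row.patient_id, row.timepoint,
                {"anc": row.anc, "plt": row.plt, "arc": row.arc}, reference)
            panels[(row.patient_id, row.timepoint)] = panel
            hemascore_rows.append(
                {"patient_id": row.patient_id, "timepoint": row.timepoint,
                 **{a: panel.values[a] for a in panel.values},
                 **{f"{a}_score": panel.scores[a] for a in panel.scores},
                 "hematopoietic_score": panel.hematopoietic_score})
        recoveries = {
            p: recovery_score(panels[(p, "pre")], panels[(p, "post")]).value
            for p, tp in panels
            if tp == "pre" and (p, "post") in panels
        }
        post_scores = {
            p: panels[(p, "post")].hematopoietic_score
            for p, tp in panels if tp == "post"
        }
        new_burden = {s.patient_id: s.new_clone_size for s in summaries}
        baseline_expanded = {
            r["patient_id"]: r["expanded_cell_fraction"]
            for r in diversity_rows
            if r["timepoint"] == "pre" and r["cohort"] == "patient"
        }
        try:
            ti = therapeutic_index(new_burden, recoveries)
            indices["therapeutic_index_new_clone_size"] = asdict(ti)
        except ValueError as exc:
            log.warning("Ti not computed: %s", exc)
        try:
            pi = predictive_index(baseline_expanded, post_scores)
            indices["predictive_index_baseline_expanded_fraction"] = asdict(pi)
        except ValueError as exc:
            log.warning("Pi not computed: %s", exc)

    # write the bundle
    fmt = "%.10g"
    if clone_frames:
        pd.concat(clone_frames, ignore_index=True).to_csv(
            outdir / "clone_tables.tsv", sep="\t", index=False, float_format=fmt)
    diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False, float_format=fmt)
    pd.DataFrame(dynamics_rows).to_csv(
        outdir / "dynamics.tsv", sep="\t", index=False, float_format=fmt)
    summaries_df.to_csv(
        outdir / "patient_summaries.tsv", sep="\t", index=False, float_format=fmt)
    pd.DataFrame(similarity_rows).to_csv(
        outdir / "similarity.tsv", sep="\t", index=False, float_format=fmt)
    if hemascore_rows:
        pd.DataFrame(hemascore_rows).to_csv(
            outdir / "hemascore.tsv", sep="\t", index=False, float_format=fmt)
    (outdir / "indices.json").write_text(json.dumps(indices, indent=2, sort_keys=True))
    cfg.to_yaml(outdir / "run_config.yaml")
    if failures:
        log.error("%d sample/patient failures", len(failures))

    return RunResult(
        output_dir=outdir,
        diversity=diversity,
        summaries=summaries_df,
        indices=indices,
        failures=failures,
    )
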