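"""Configuration-driven orchestration: simulate -> extract -> cluster ->
select -> report.

A run is described by one declarative mapping (YAML on disk or a dict):
either a simulation block or a manifest of per-cycle FASTQ files, plus
extraction, clustering and selection parameters.  ``run_pipeline`` executes
the stages in order, writes every stage output under the run directory and
returns a JSON-serializable report; identical (config, seed) pairs produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .families import (cluster_families, families_to_frame, identity_matrix,
                       pairwise_identity, select_family_candidates)
from .reads import (CycleLibrary, ExtractionConfig, FrequencyMatrix,
                    build_cycle_library, complexity, frequencies, parse_fastq,
                    read_manifest)
from .selection import (MergedCandidate, SelectionThresholds,
                        candidates_to_frame, enrichment_report,
                        merge_strategies, toggle_candidates)
from .simulate import CycleSpec, SimConfig, SimTruth, run_protocol, write_fastq
from .tree import nj_tree, pick_representatives, tree_to_newick

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline",
           "evaluate_recovery"]

log = logging.getLogger("aptaselex")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is part of the message."""


@dataclass
class RunConfig:
    """Normalized pipeline configuration (exactly one input source)."""

    outdir: Path
    sim: SimConfig | None = None
    manifest: Path | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    cluster_min_freq: float = 1e-6
    cluster_identity: float = 0.80
    cluster_max_sequences: int = 5000
    merge_identity: float = 0.90
    n_representatives: int = 15
    compare_before: str | None = None
    compare_after: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    keep_fastq: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.manifest is None):
            raise ValueError("exactly one of sim / manifest must be given")


def _build_sim_config(block: dict, seed: int, errors: list[str]) -> SimConfig | None:
    cycles = []
    for c in block.pop("cycles", []):
        try:
            cycles.append(CycleSpec(**c))
        except (TypeError, ValueError) as exc:
            errors.append(f"sim.cycles: {exc}")
            return None
    if not cycles:
        from .simulate import _toggle_cycles
        cycles = list(_toggle_cycles())
    block.setdefault("seed", seed)
    if "var_len_range" in block:
        block["var_len_range"] = tuple(block["var_len_range"])
    try:
        return SimConfig(cycles=tuple(cycles), **block)
    except (TypeError, ValueError) as exc:
        errors.append(f"sim: {exc}")
        return None


def validate_config(source, seed: int | None = None,
                    outdir=None) -> tuple[RunConfig | None, list[str]]:
    """Normalize a YAML path or mapping into a :class:`RunConfig`.

    Returns ``(config, errors)``; on any error the config is ``None`` and
    every problem is named."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(source).parent
    else:
        raw = dict(source or {})
        base = Path(".")
    errors: list[str] = []
    known = {"sim", "manifest", "extraction", "thresholds", "clustering",
             "merge_identity", "n_representatives", "compare", "outdir",
             "seed", "log_level", "keep_fastq"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")

    if ("sim" in raw) == ("manifest" in raw):
        errors.append("exactly one of 'sim' or 'manifest' is required")
        return None, errors

    run_seed = seed if seed is not None else int(raw.get("seed", 0))
    sim = manifest = None
    if "sim" in raw:
        sim = _build_sim_config(dict(raw["sim"] or {}), run_seed, errors)
    else:
        manifest = Path(raw["manifest"])
        if not manifest.is_absolute():
            manifest = base / manifest
        if not manifest.exists():
            errors.append(f"manifest not found: {manifest}")

    try:
        extraction = ExtractionConfig(**{
            k: tuple(v) if k == "len_range" else v
            for k, v in (raw.get("extraction") or {}).items()})
    except (TypeError, ValueError) as exc:
        errors.append(f"extraction: {exc}")
        extraction = ExtractionConfig()
    try:
        thresholds = SelectionThresholds(**(raw.get("thresholds") or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"thresholds: {exc}")
        thresholds = SelectionThresholds()

    clustering = raw.get("clustering") or {}
    compare = raw.get("compare") or {}
    out = Path(outdir) if outdir is not None else Path(raw.get("outdir", "aptaselex_run"))
    if errors:
        return None, errors
    cfg = RunConfig(
        outdir=out,
        sim=sim,
        manifest=manifest,
        extraction=extraction,
        thresholds=thresholds,
        cluster_min_freq=float(clustering.get("min_freq", 1e-6)),
        cluster_identity=float(clustering.get("identity_threshold", 0.80)),
        cluster_max_sequences=int(clustering.get("max_sequences", 5000)),
        merge_identity=float(raw.get("merge_identity", 0.90)),
        n_representatives=int(raw.get("n_representatives", 15)),
        compare_before=compare.get("before"),
        compare_after=compare.get("after"),
        seed=run_seed,
        log_level=str(raw.get("log_level", "INFO")),
        keep_fastq=bool(raw.get("keep_fastq", True)),
    )
    return cfg, []


def _infer_compare(cycle_meta: pd.DataFrame) -> tuple[str, str]:
    """Default before/after cycles: the last cycle before the positive
    selector class changes for the final time, and the final cycle."""
    ids = list(cycle_meta["cycle_id"])
    after = ids[-1]
    before = ids[0]
    if "positive_class" in cycle_meta.columns:
        final_cls = cycle_meta["positive_class"].iloc[-1]
        for i in range(len(ids) - 1, -1, -1):
            if cycle_meta["positive_class"].iloc[i] != final_cls:
                before = ids[i]
                break
    elif len(ids) > 1:
        before = ids[-2]
    return before, after


def _stage(report: dict, name: str):
    report["stages"].append(name)
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": [],
                    "failed_stage": None}
    truth: SimTruth | None = None
    try:
        # --- input: simulate or load ------------------------------------
        if config.sim is not None:
            _stage(report, "simulate")
            sim_libs, truth = run_protocol(config.sim)
            fastq_dir = out / "fastq"
            fastq_dir.mkdir(exist_ok=True)
            rows = []
            for lib, spec in zip(sim_libs, config.sim.cycles):
                path = fastq_dir / f"{lib.cycle_id}.fastq.gz"
                write_fastq(lib, config.extraction.flank5,
                            config.extraction.flank3, path)
                rows.append((lib.cycle_id, f"fastq/{lib.cycle_id}.fastq.gz",
                             spec.positive_class, spec.negative_class))
            cycle_meta = pd.DataFrame(rows, columns=[
                "cycle_id", "path", "positive_class", "negative_class"])
            cycle_meta_abs = cycle_meta.assign(
                path=[str(out / p) for p in cycle_meta["path"]])
            cycle_meta.to_csv(out / "manifest.tsv", sep="\t", index=False)
        else:
            _stage(report, "load_manifest")
            cycle_meta_abs = cycle_meta = read_manifest(config.manifest)

        # --- extract ------------------------------------------------------
        _stage(report, "extract")
        libs: list[CycleLibrary] = []
        for _, row in cycle_meta_abs.iterrows():
            libs.append(build_cycle_library(parse_fastq(row["path"]),
                                            config.extraction,
                                            cycle_id=row["cycle_id"]))
        summary = pd.DataFrame({
            "cycle_id": [l.cycle_id for l in libs],
            "total_reads": [l.total_reads for l in libs],
            "extracted_reads": [l.extracted_reads for l in libs],
            "unique_sequences": [l.unique_count for l in libs],
            "complexity_pct": [complexity(l) for l in libs],
        })
        summary.to_csv(out / "cycle_summary.tsv", sep="\t", index=False)
        report["cycles"] = summary.to_dict(orient="records")

        _stage(report, "frequencies")
        matrix = frequencies(libs, epsilon=config.thresholds.background)
        counts = matrix.counts.copy()
        counts.index.name = "sequence"
        counts.to_csv(out / "counts.tsv", sep="\t")

        before = config.compare_before
        after = config.compare_after
        if before is None or after is None:
            inf_b, inf_a = _infer_compare(cycle_meta)
            before = before or inf_b
            after = after or inf_a
        report["compare"] = {"before": before, "after": after}

        # --- cluster ------------------------------------------------------
        _stage(report, "cluster")
        fams = cluster_families(matrix, after,
                                min_freq=config.cluster_min_freq,
                                identity_threshold=config.cluster_identity,
                                max_sequences=config.cluster_max_sequences)
        families_to_frame(fams).to_csv(out / "families.tsv", sep="\t",
                                       index=False)
        cluster_cands = select_family_candidates(
            fams, phi_threshold=config.thresholds.high_freq)
        report["n_families"] = len(fams)
        report["n_cluster_candidates"] = len(cluster_cands)

        # --- select -------------------------------------------------------
        _stage(report, "select")
        toggle_cands = toggle_candidates(matrix, before, after,
                                         config.thresholds)
        report["n_toggle_candidates"] = len(toggle_cands)
        report["rule_counts"] = {
            r: sum(1 for c in toggle_cands if c.rule_id == r)
            for r in ("R1", "R2", "R3")}
        report["enrichment"] = enrichment_report(matrix, before, after,
                                                 config.thresholds)

        _stage(report, "merge")
        merged = merge_strategies(cluster_cands, toggle_cands,
                                  identity_threshold=config.merge_identity)
        frame = candidates_to_frame(merged)
        frame.to_csv(out / "candidates.tsv", sep="\t", index=False)
        report["n_merged_candidates"] = len(merged)
        report["n_convergent"] = int(sum(m.convergent for m in merged))
        report["candidates"] = frame.to_dict(orient="records")

        # --- tree + representatives ----------------------------------------
        _stage(report, "tree")
        seqs = [m.sequence for m in merged]
        if len(seqs) >= 3:
            dist = 1.0 - identity_matrix(seqs)
            np.fill_diagonal(dist, 0.0)
            tr = nj_tree(seqs, dist)
            (out / "candidates.nwk").write_text(tree_to_newick(tr) + "\n")
            freq_lookup = {m.sequence: m.f_after for m in merged}
            reps = pick_representatives(tr, min(config.n_representatives,
                                                len(seqs)), freq_lookup)
        else:
            reps = sorted(seqs)
        report["representatives"] = reps

        report["thresholds"] = dataclasses.asdict(config.thresholds)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        stage = report["stages"][-1] if report["stages"] else "setup"
        report["failed_stage"] = stage
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    if truth is not None:
        report["_truth"] = truth  # in-memory only, never serialized
    return report


def evaluate_recovery(merged: list[MergedCandidate], truth: SimTruth,
                      identity_threshold: float = 0.90) -> dict:
    """Score a merged candidate list against simulator ground truth.

    A planted cross-reactive family counts as recovered when some candidate
    is its seed or is >= ``identity_threshold`` identity to it; it counts
    as convergently recovered when such a candidate carries the convergent
    flag.  Background fraction is the share of candidates not planted in
    any family.
    """
    seeds = truth.cross_reactive_seeds()
    fam = truth.family_id
    recovered = convergent = 0
    for seed in seeds:
        hit = conv = False
        for m in merged:
            if m.sequence == seed or pairwise_identity(m.sequence, seed) >= identity_threshold:
                hit = True
                conv = conv or m.convergent
        recovered += hit
        convergent += conv
    n_bg = sum(1 for m in merged
               if m.sequence not in fam.index or fam[m.sequence] < 0)
    return {
        "n_cross_seeds": len(seeds),
        "recovered": recovered,
        "recovered_convergent": convergent,
        "recovery_rate": recovered / len(seeds) if seeds else float("nan"),
        "convergent_rate": convergent / len(seeds) if seeds else float("nan"),
        "n_candidates": len(merged),
        "background_fraction": n_bg / len(merged) if merged else 0.0,
    }
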