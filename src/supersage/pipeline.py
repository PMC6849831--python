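"""End-to-end orchestration: simulate -> extract -> dge -> map -> report.

A single hierarchical config (YAML-friendly mapping) drives a full run.
Every stage writes its outputs into the run directory and records them in
``manifest.json`` with SHA-256 checksums, so a rerun with the same config
and seed can be verified byte-for-byte.  Any stage failure aborts with the
stage name and the underlying cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import dge as dge_mod
from . import extraction, mapping, reporting, simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "dge", "map", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    fastq: dict[str, str] = field(default_factory=dict)   # label -> path
    reference: str | None = None
    annotations: str | None = None
    index_map: dict[str, str] = field(default_factory=dict)  # index -> label
    adapter2_prefix: str = "CTGCTGCGTA"
    thresholds: dge_mod.ClassificationThresholds = field(
        default_factory=dge_mod.ClassificationThresholds)
    nf: float | None = None
    top_n: int = 40

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any], outdir: str | Path) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        sim = None
        if raw.get("simulation") is not None:
            sim_raw = dict(raw["simulation"])
            sim_raw.setdefault("seed", seed)
            sim = simulate.config_from_mapping(sim_raw)
        thresholds = dge_mod.ClassificationThresholds(
            **raw.get("thresholds", {}))
        thresholds.validate()
        cfg = cls(
            outdir=Path(outdir),
            seed=seed,
            simulation=sim,
            fastq=dict(raw.get("fastq", {})),
            reference=raw.get("reference"),
            annotations=raw.get("annotations"),
            index_map=dict(raw.get("indexes", {})),
            adapter2_prefix=raw.get("adapter2_prefix",
                                    sim.adapter2_prefix if sim else "CTGCTGCGTA"),
            thresholds=thresholds,
            nf=raw.get("nf"),
            top_n=int(raw.get("top_n", 40)),
        )
        if sim is not None and not cfg.index_map:
            cfg.index_map = {sim.index_lib1: "lib1", sim.index_lib2: "lib2"}
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        out = outdir if outdir is not None else raw.get("outdir", path.parent / "run")
        return cls.from_mapping(raw, out)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all applicable stages; returns the manifest (also written to
    ``manifest.json`` in the run directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def record(stage: str, **paths: Path) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in paths.items()}

    # --- simulate -----------------------------------------------------
    fastq = dict(config.fastq)
    reference = config.reference
    truth = None
    if config.simulation is not None:
        try:
            sim = config.simulation
            transcripts = simulate.generate_transcriptome(sim)
            fasta = simulate.write_transcriptome(transcripts, outdir / "transcriptome.fasta")
            truth = simulate.assign_expression(transcripts, sim)
            truth_path = simulate.write_ground_truth(truth, outdir / "ground_truth.tsv")
            result = simulate.simulate_reads(
                transcripts, truth, sim, outdir / "lib1.fastq", outdir / "lib2.fastq")
            record("simulate", transcriptome=fasta, ground_truth=truth_path,
                   fastq_lib1=result.fastq_lib1, fastq_lib2=result.fastq_lib2)
            fastq = {"lib1": str(result.fastq_lib1), "lib2": str(result.fastq_lib2)}
            if reference is None:
                reference = str(fasta)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError("simulate", exc) from exc

    # --- extract ------------------------------------------------------
    try:
        if not fastq:
            raise FileNotFoundError("no FASTQ inputs (provide 'fastq' or 'simulation')")
        if not config.index_map:
            raise ValueError("no index map configured")
        table, stats = extraction.count_tags(
            fastq.values(), config.index_map, config.adapter2_prefix)
        table, n_removed = extraction.remove_singletons(table)
        stats.singletons_removed = n_removed
        counts_path = extraction.write_tag_counts(table, outdir / "tag_counts.tsv")
        stats_path = outdir / "extraction_stats.tsv"
        stats.to_frame().to_csv(stats_path, sep="\t", index=False)
        log.info("extract: %d reads, %d unique tags, %d singletons removed",
                 stats.reads_total, stats.unique_tags, n_removed)
        record("extract", tag_counts=counts_path, extraction_stats=stats_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("extract", exc) from exc

    # --- dge ----------------------------------------------------------
    try:
        records, summary = dge_mod.run_dge(table, config.thresholds, nf=config.nf)
        dge_path = dge_mod.write_dge_results(records, outdir / "dge_results.tsv")
        summary_path = outdir / "dge_summary.json"
        with open(summary_path, "w") as fh:
            json.dump({"n_total": summary.n_total, "n_oe": summary.n_oe,
                       "n_ue": summary.n_ue, "percent_de": summary.percent_de},
                      fh, sort_keys=True, indent=2)
        record("dge", dge_results=dge_path, dge_summary=summary_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("dge", exc) from exc

    # --- map ----------------------------------------------------------
    try:
        if reference is None:
            raise FileNotFoundError("no reference FASTA configured")
        if not Path(reference).exists():
            raise FileNotFoundError(f"reference FASTA not found: {reference}")
        index = mapping.build_index(reference)
        de_tags = [r.tag for r in records if r.label != "NS"]
        hits = mapping.map_tags(de_tags, index)
        hits_path = mapping.write_tag_hits(hits, outdir / "tag_hits.tsv")
        record("map", tag_hits=hits_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("map", exc) from exc

    # --- report -------------------------------------------------------
    try:
        annotations = None
        if config.annotations:
            annotations = reporting.load_annotations(config.annotations)
        top_oe = reporting.top_table(records, annotations, config.top_n, "OE")
        top_ue = reporting.top_table(records, annotations, config.top_n, "UE")
        top_oe_path = outdir / "top_oe.tsv"
        top_ue_path = outdir / "top_ue.tsv"
        top_oe.to_csv(top_oe_path, sep="\t", index=False)
        top_ue.to_csv(top_ue_path, sep="\t", index=False)
        hist = dge_mod.fc_histogram(
            records, {"OE": [2.5, 8.0, float("inf")], "UE": [0.0, 0.1, 0.4]})
        hist_path = outdir / "fc_histogram.tsv"
        hist.to_csv(hist_path, sep="\t", index=False)
        n_mapped_de = len({h.tag for h in hits})
        summary_txt = reporting.summary_text(
            summary, stats, extra={"DE tags mapped to reference": n_mapped_de})
        summary_txt_path = outdir / "report_summary.txt"
        summary_txt_path.write_text(summary_txt)
        record("report", top_oe=top_oe_path, top_ue=top_ue_path,
               fc_histogram=hist_path, summary=summary_txt_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest
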