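"""End-to-end orchestration: simulate/load -> filter -> AI test -> annotate ->
enrich, with a machine-readable run manifest.

The run is deterministic: identical config and inputs reproduce byte-identical
outputs (timestamps live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import sys
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, ai, filters, io, nmd, simulate, stats
from .config import validate_config

log = logging.getLogger("aimseq")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _report_row(rep: filters.FilterReport) -> dict:
    return {"stage": rep.stage_name, "records_in": rep.records_in,
            "records_out": rep.records_out, "n_removed": len(rep.removed_ids)}


def run_pipeline(config_path, outdir) -> Path:
    """Run the full analysis into ``outdir``; returns the output directory.

    Any stage failure aborts with a stage-named error and removes partial
    outputs.
    """
    cfg = validate_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(cfg, config_path, outdir)
    except Exception:
        for p in outdir.glob("*"):
            if p.is_file():
                p.unlink()
        raise


def _run(cfg: dict, config_path, outdir: Path) -> Path:
    started = datetime.now(timezone.utc).isoformat()
    manifest: dict = {"tool": "aimseq", "version": __version__,
                      "config": {k: v for k, v in sorted(cfg.items())},
                      "seed": cfg["seed"], "stages": [], "inputs": {}}

    # -- stage: inputs (simulate or load) ---------------------------------
    stage = "simulate" if cfg["mutations"] is None else "load"
    try:
        if cfg["mutations"] is None:
            sim = simulate.SimulationConfig(
                n_samples=cfg["n_samples"], n_genes=cfg["n_genes"],
                category_weights=simulate.preset_weights(cfg["preset"]),
                nmd_retention=cfg["retention"], splice_retention_boost=cfg["boost"],
                dna_depth=cfg["dna_depth"], rna_depth=cfg["rna_depth"],
                depth_dispersion=cfg["depth_dispersion"],
                neutral_cn_fraction=cfg["neutral_cn_fraction"],
                hypermutator_fraction=cfg["hypermutator_fraction"],
                mean_mutations_per_sample=cfg["mean_mutations_per_sample"],
                nmd_boundary_inclusive=cfg["nmd_boundary_inclusive"],
                seed=cfg["seed"],
            )
            transcripts = simulate.simulate_transcripts(sim)
            records, segments, truths = simulate.simulate_cohort(sim, transcripts)
            simulate.write_cohort(outdir / "inputs", sim, transcripts)
            for name in ("mutations", "transcripts", "segments", "truth"):
                manifest["inputs"][name] = _sha256(outdir / "inputs" / {
                    "mutations": "mutations.tsv", "transcripts": "transcripts.gtf",
                    "segments": "segments.seg", "truth": "truth.tsv"}[name])
        else:
            if cfg["transcripts"] is None:
                raise PipelineError("annotate", "config gives mutations but no transcripts file")
            records = io.read_mutation_table(cfg["mutations"])
            transcripts = io.read_transcript_models(
                cfg["transcripts"], format=cfg["transcript_format"])
            segments = io.read_segments(cfg["segments"]) if cfg["segments"] else []
            truths = []
            for key in ("mutations", "transcripts", "segments"):
                if cfg[key]:
                    manifest["inputs"][key] = _sha256(Path(cfg[key]))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append({"name": stage, "n_records": len(records)})

    # -- stage: qc filters -------------------------------------------------
    try:
        reports = []
        records, rep = filters.filter_by_depth(
            records, cfg["min_dna_depth"], cfg["min_rna_depth"])
        reports.append(rep)
        records, rep = filters.drop_hypermutated(
            records, cfg["hypermutation_rate"], cfg["exome_size_mb"])
        reports.append(rep)
        records, rep = filters.drop_multimutant_genes(records)
        reports.append(rep)
        funnel = pd.DataFrame([_report_row(r) for r in reports])
        funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
        for r in reports:
            log.info("filter %s: %d -> %d", r.stage_name, r.records_in, r.records_out)
            manifest["stages"].append({"name": f"filter:{r.stage_name}",
                                       **_report_row(r)})
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    if not records:
        raise PipelineError("filter", "no records survive the QC funnel")

    # -- stage: AI test ----------------------------------------------------
    try:
        params = ai.BFModelParams(cfg["alpha"], cfg["beta"], cfg["bf_threshold"])
        results = ai.evaluate_records(records, params)
        grid = ai.threshold_grid(records, cfg["grid_dna"], cfg["grid_rna"], params)
        grid.to_csv(outdir / "depth_grid.tsv", sep="\t", index=False,
                    float_format="%.6g")
    except Exception as exc:
        raise PipelineError("test", str(exc)) from exc
    manifest["stages"].append({"name": "test", "n_results": len(results)})

    # -- stage: annotate ---------------------------------------------------
    try:
        annotations, splice_rows = [], []
        for rec in records:
            tr = transcripts.get(rec.gene)
            if tr is None:
                continue
            if rec.category in io.TRUNCATING:
                try:
                    annotations.append(nmd.annotate_ptc(
                        rec, tr, boundary_inclusive=cfg["nmd_boundary_inclusive"],
                        allow_retranslation=cfg["allow_retranslation"]))
                except nmd.AnnotationError as exc:
                    log.warning("PTC annotation skipped: %s", exc)
            elif rec.category == "splice_site":
                try:
                    call = nmd.classify_splice_site(rec, tr)
                    splice_rows.append({
                        "sample_id": rec.sample_id, "chrom": rec.chrom,
                        "pos": rec.pos, "side": call.side, "offset": call.offset,
                        "canonical_ref": call.canonical_ref})
                except nmd.AnnotationError as exc:
                    log.warning("splice classification skipped: %s", exc)
        ann_df = nmd.annotations_to_frame(annotations)
        ann_df.to_csv(outdir / "ptc_annotations.tsv", sep="\t", index=False)
        pd.DataFrame(splice_rows, columns=["sample_id", "chrom", "pos", "side",
                                           "offset", "canonical_ref"]).to_csv(
            outdir / "splice_calls.tsv", sep="\t", index=False)
        io.write_results(results, outdir / "ai_results.tsv",
                         annotations=ann_df, allow_empty=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc
    manifest["stages"].append({"name": "annotate", "n_ptc": len(annotations),
                               "n_splice": len(splice_rows)})

    # -- stage: enrich -----------------------------------------------------
    try:
        nmd_class = {a.record_key: a.nmd_class for a in annotations}
        summary = ai.category_summary(results, ("category",))
        summary.to_csv(outdir / "category_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        nmd_summary = ai.category_summary(
            [r for r in results if r.record.key in nmd_class],
            ("category", "nmd_class"), extra_fields={"nmd_class": nmd_class})
        nmd_summary.to_csv(outdir / "nmd_summary.tsv", sep="\t", index=False,
                           float_format="%.6g")
        # copy-neutral restriction applies to the missense analysis only
        missense = [r for r in records if r.category == "missense"]
        cn_missense, cn_rep = filters.filter_copy_neutral(
            missense, segments, cfg["cn_low"], cfg["cn_high"])
        manifest["stages"].append({"name": "filter:copy_neutral_missense",
                                   **_report_row(cn_rep)})
        cn_results = ai.evaluate_records(cn_missense, params)
        enrich = stats.gene_ai_enrichment(
            cn_results, focal_class=cfg["focal_class"], min_events=cfg["min_events"])
        enrich.to_csv(outdir / "gene_enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")
        stats.export_ranked_list(enrich, outdir / "gene_enrichment.rnk")
        spectra = pd.DataFrame([
            {"ai_class": r.ai_class,
             "spectrum": stats.spectrum_class(r.record.ref_allele, r.record.alt_allele),
             "ts_tv": stats.ts_tv(r.record.ref_allele, r.record.alt_allele)}
            for r in cn_results
        ], columns=["ai_class", "spectrum", "ts_tv"])
        spectra.groupby(["ai_class", "spectrum"]).size().rename("n").reset_index() \
            .to_csv(outdir / "spectra.tsv", sep="\t", index=False)
        spectra.groupby(["ai_class", "ts_tv"]).size().rename("n").reset_index() \
            .to_csv(outdir / "ts_tv.tsv", sep="\t", index=False)
        # cumulative sig-neg-AFD ratio vs distance to the last junction
        trunc = [(r, nmd_class.get(r.record.key)) for r in results
                 if r.record.key in nmd_class]
        ann_by_key = {a.record_key: a for a in annotations}
        penult = [(ann_by_key[r.record.key].dist_last_junction,
                   r.ai_class == "sig_neg_afd")
                  for r, _ in trunc
                  if ann_by_key[r.record.key].region.startswith("penultimate")]
        if penult:
            values = [max(0, v) for v, _ in penult]
            flags = [f for _, f in penult]
            curve = stats.cumulative_ratio_curve(values, flags, 10,
                                                 max(values) + 10)
            curve.to_frame().to_csv(outdir / "junction_distance_curve.tsv",
                                    sep="\t", index=False, float_format="%.6g")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc
    manifest["stages"].append({"name": "enrich", "n_genes": len(enrich)})

    manifest["started"] = started
    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
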