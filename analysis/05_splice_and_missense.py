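#!/usr/bin/env python
"""Splice-site and missense AI analyses.

Splice sites: classify each mutation as donor (5' GT) or acceptor (3' AG) and
compare sig-pos-AFD ratios by side — intron retention of the mutant allele
shows up as mutant over-expression. Missense: restrict to copy-number-neutral
mutations (|log2 ratio| < 0.15), tabulate mutation spectra and Ts/Tv by AI
class, run the per-gene Fisher enrichment for sig-pos-AFD and export the
GSEA-preranked gene list.
"""

from pathlib import Path

import pandas as pd

from aimseq import ai, filters, io, nmd, stats

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = io.read_mutation_table(ROOT / "mutations_filtered.tsv")
    models = io.read_transcript_models(ROOT / "cohort" / "transcripts.gtf")
    segments = io.read_segments(ROOT / "cohort" / "segments.seg")

    # -- splice sites -----------------------------------------------------
    splice = [r for r in records if r.category == "splice_site"]
    calls, rows = {}, []
    for rec in splice:
        try:
            call = nmd.classify_splice_site(rec, models[rec.gene])
        except nmd.AnnotationError:
            continue
        calls[rec.key] = call
        rows.append({"sample_id": rec.sample_id, "chrom": rec.chrom,
                     "pos": rec.pos, "side": call.side, "offset": call.offset})
    pd.DataFrame(rows).to_csv(ROOT / "splice_calls.tsv", sep="\t", index=False)
    splice_res = ai.evaluate_records([r for r in splice if r.key in calls])
    side_summary = ai.category_summary(
        splice_res, ("side",),
        extra_fields={"side": {k: c.side for k, c in calls.items()}})
    side_summary.to_csv(ROOT / "splice_side_summary.tsv", sep="\t", index=False,
                        float_format="%.6g")
    print("sig-pos-AFD ratio by splice side:")
    print(side_summary[["side", "n", "sig_pos_ratio"]].to_string(index=False))

    # -- missense, copy-neutral restriction --------------------------------
    missense = [r for r in records if r.category == "missense"]
    neutral, rep = filters.filter_copy_neutral(missense, segments)
    print(f"\ncopy-neutral missense: kept {rep.records_out}/{rep.records_in}")
    res = ai.evaluate_records(neutral)

    spectra = pd.DataFrame([
        {"ai_class": r.ai_class,
         "spectrum": stats.spectrum_class(r.record.ref_allele, r.record.alt_allele),
         "ts_tv": stats.ts_tv(r.record.ref_allele, r.record.alt_allele)}
        for r in res])
    spec_counts = spectra.groupby(["ai_class", "spectrum"]).size().unstack(fill_value=0)
    spec_counts.to_csv(ROOT / "spectra.tsv", sep="\t")
    tstv_counts = spectra.groupby(["ai_class", "ts_tv"]).size().unstack(fill_value=0)
    tstv_counts.to_csv(ROOT / "ts_tv.tsv", sep="\t")
    if spec_counts.shape[0] >= 2:
        stat, p = stats.chisq_independence(spec_counts.to_numpy())
        print(f"spectra x AI class chi-square: stat={stat:.2f}, p={p:.3g}")

    enrich = stats.gene_ai_enrichment(res, focal_class="sig_pos_afd", min_events=1)
    enrich.to_csv(ROOT / "gene_enrichment.tsv", sep="\t", index=False,
                  float_format="%.6g")
    stats.export_ranked_list(enrich, ROOT / "gene_enrichment.rnk")
    shown = enrich[enrich["neg_log10_p"] > 2.5]
    print(f"genes above the -log10 p > 2.5 display threshold: {len(shown)}")


if __name__ == "__main__":
    main()
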