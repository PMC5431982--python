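"""Shared fixtures.

``funnel_cohort`` builds the 200-row QC fixture deterministically, with every
violation planted by hand so each filter's expected removals are known exactly:

* 10 rows failing the 10/10 depth rule (5 with 9 DNA reads, 5 with 9 RNA reads)
* 5 rows at exactly 10/10 reads (boundary, must be kept)
* one sample (``SHYP``) with 15 mutations, above 10 mutations/Mb on a 1 Mb target
* one within-sample multi-mutant gene (2 rows) plus a gene mutated once in each
  of two samples (must be kept)
* 15 rows violating the copy-neutral rule: 5 in a segment at exactly +0.15
  (strict boundary), 5 in a lost segment (-0.5), 5 with no covering segment
"""

from __future__ import annotations

import pytest

from aimseq.io import CopySegment, MutationRecord


def _rec(sample, gene, pos, dna=(15, 15), rna=(15, 15), category="missense",
         chrom="chr1", ref="C", alt="T"):
    return MutationRecord(
        sample_id=sample, gene=gene, chrom=chrom, pos=pos,
        ref_allele=ref, alt_allele=alt, category=category,
        dna_ref=dna[0], dna_alt=dna[1], rna_ref=rna[0], rna_alt=rna[1],
    )


@pytest.fixture(scope="session")
def funnel_cohort():
    records: list[MutationRecord] = []
    expected: dict[str, set] = {}

    # depth violations: DNA depth 9 (x5) and RNA depth 9 (x5)
    low_dna = [_rec("SDEP", f"D{i:02d}", 100 + i, dna=(4, 5), rna=(25, 25))
               for i in range(5)]
    low_rna = [_rec("SDEP", f"D{i:02d}", 105 + i, dna=(25, 25), rna=(4, 5))
               for i in range(5, 10)]
    records += low_dna + low_rna
    expected["depth"] = {r.key for r in low_dna + low_rna}

    # exact 10/10 boundary rows: kept by the depth filter
    boundary = [_rec("SBND", f"B{i:02d}", 200 + i, dna=(5, 5), rna=(5, 5))
                for i in range(5)]
    records += boundary

    # hypermutated sample: 15 mutations on a 1 Mb target, threshold 10/Mb
    hyper = [_rec("SHYP", f"H{i:02d}", 300 + i) for i in range(15)]
    records += hyper
    expected["hypermutation"] = {r.key for r in hyper}

    # multi-mutant gene within one sample; same gene once in another sample kept
    multi = [_rec("SMUL", "GMULTI", 400), _rec("SMUL", "GMULTI", 401)]
    records += multi + [_rec("SMUL", "GSOLO", 402), _rec("SMUL2", "GMULTI", 403)]
    expected["multimutant_gene"] = {r.key for r in multi}

    # copy-number cases: neutral kept; +0.15 boundary, loss, uncovered removed.
    # Spread across four samples so no sample crosses the hypermutation rate.
    cn_keep = [_rec("SCN1", f"C{i:02d}", 500 + i) for i in range(5)]
    cn_bound = [_rec("SCN2", f"C{i:02d}", 10500 + i) for i in range(5, 10)]
    cn_loss = [_rec("SCN3", f"C{i:02d}", 20500 + i) for i in range(10, 15)]
    cn_uncov = [_rec("SCN4", f"C{i:02d}", 35000 + i) for i in range(15, 20)]
    records += cn_keep + cn_bound + cn_loss + cn_uncov
    expected["copy_neutral"] = {r.key for r in cn_bound + cn_loss + cn_uncov}

    # filler: 146 unique-gene rows spread over samples below every threshold
    n_filler = 200 - len(records)
    filler = [_rec(f"SF{i // 10:02d}", f"F{i:03d}", 600 + i) for i in range(n_filler)]
    records += filler
    assert len(records) == 200

    segments = []
    for s in ("SCN1", "SCN2", "SCN3", "SCN4"):
        segments += [
            CopySegment(s, "chr1", 1, 10000, 0.0),
            CopySegment(s, "chr1", 10001, 20000, 0.15),
            CopySegment(s, "chr1", 20001, 30000, -0.5),
        ]
    cn_samples = {"SCN1", "SCN2", "SCN3", "SCN4"}
    neutral_samples = {r.sample_id for r in records if r.sample_id not in cn_samples}
    segments += [CopySegment(s, "chr1", 1, 100_000, 0.01)
                 for s in sorted(neutral_samples)]

    return {"records": records, "segments": segments, "expected": expected,
            "exome_size_mb": 1.0}
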