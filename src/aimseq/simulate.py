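"""Synthetic cohorts with known ground-truth allelic-imbalance effects.

The generator emulates the structure of a tumor WES + RNA-seq mutation
cohort: a category mixture matching the published per-tumor-type proportions,
binomial DNA/RNA allele counts at negative-binomially distributed depths,
NMD-driven depletion of the mutant RNA fraction for NMD-sensitive truncating
mutations, intron-retention-driven enrichment for splice-site mutations,
mostly copy-neutral segment profiles, and a configurable fraction of
hypermutated outlier samples.

The NMD effect is modeled as a per-transcript survival factor: if mutant
transcripts survive decay at rate ``r``, the observable mutant fraction
becomes ``r p / (r p + (1 - p))`` for a DNA-level mutant fraction ``p``.
Splice-site intron retention uses the same mapping with a factor above one.
The simulator derives each truncating mutation's true NMD sensitivity from
the transcript geometry by an independent brute-force walk over the
concatenated exons, so annotation code can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    CopySegment, MutationRecord, TranscriptModel,
    write_mutation_table, write_segments, write_transcript_gtf,
)

#: Per-tumor-type mutation-category proportions (percent, as published for the
#: five TCGA cohorts); each column is renormalized to sum to 1 before use.
CATEGORY_PRESETS: dict[str, dict[str, float]] = {
    "BRCA": {"nonsense": 5.2, "missense": 65.4, "splice_site": 0.3,
             "silent": 19.9, "frameshift": 3.7, "inframe": 0.9},
    "HNSC": {"nonsense": 5.3, "missense": 63.4, "splice_site": 0.4,
             "silent": 24.9, "frameshift": 2.3, "inframe": 0.8},
    "KIRC": {"nonsense": 3.3, "missense": 46.9, "splice_site": 0.2,
             "silent": 18.0, "frameshift": 13.4, "inframe": 2.4},
    "LUAD": {"nonsense": 5.2, "missense": 65.0, "splice_site": 0.4,
             "silent": 23.4, "frameshift": 2.2, "inframe": 0.8},
    "STAD": {"nonsense": 3.8, "missense": 61.9, "splice_site": 0.3,
             "silent": 23.9, "frameshift": 3.9, "inframe": 1.2},
}

NUCLEOTIDES = "ACGT"


def preset_weights(name: str = "BRCA") -> dict[str, float]:
    raw = CATEGORY_PRESETS[name]
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass
class SimulationConfig:
    """Cohort-level knobs; defaults are the study conditions the cohort emulates."""

    n_samples: int = 50
    n_genes: int = 200
    category_weights: dict[str, float] = field(default_factory=lambda: preset_weights("BRCA"))
    dna_fraction_prior: tuple[float, float] = (8.0, 12.0)  # Beta shapes, mean 0.4
    fixed_dna_fraction: Optional[float] = None  # point condition overriding the prior
    nmd_retention: float = 0.25
    splice_retention_boost: float = 4.0
    dna_depth: float = 80.0
    rna_depth: float = 80.0
    depth_dispersion: Optional[float] = 8.0  # None = exact depths at the means
    neutral_cn_fraction: float = 0.8
    hypermutator_fraction: float = 0.02
    mean_mutations_per_sample: float = 60.0
    hypermutator_multiplier: float = 15.0
    nmd_boundary_inclusive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_weights must sum to 1 (got {total})")
        if not (0.0 < self.nmd_retention <= 1.0):
            raise ValueError("nmd_retention must lie in (0, 1]")
        if self.splice_retention_boost < 1.0:
            raise ValueError("splice_retention_boost must be >= 1")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("depths must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-record simulation bookkeeping: the true allele fractions and effect."""

    record_key: tuple
    true_dna_fraction: float
    true_rna_fraction: float
    effect: str  # none | nmd | intron_retention | other_up | other_down
    nmd_sensitive_truth: Optional[bool] = None


def rna_fraction_under_nmd(p_dna: float, retention: float) -> float:
    """Mutant RNA fraction after mutant transcripts survive decay at rate ``retention``.

    retention = 1 leaves the fraction unchanged; retention -> 0 removes the
    mutant allele from the transcript pool.
    """
    if not (0.0 <= p_dna <= 1.0):
        raise ValueError("p_dna must lie in [0, 1]")
    if not (0.0 < retention):
        raise ValueError("retention must be positive")
    num = retention * p_dna
    denom = num + (1.0 - p_dna)
    if denom == 0.0:  # p_dna == 1
        return 1.0
    return num / denom


def _nmd_sensitive_bruteforce(
    transcript: TranscriptModel, ptc_cds_pos: int, boundary_inclusive: bool = True
) -> bool:
    """True NMD sensitivity by walking the concatenated spliced sequence.

    Deliberately independent of the annotation module: assigns each spliced
    nucleotide an exon index by brute force, then counts nucleotides from the
    PTC to the start of the last exon.
    """
    exon_of_nt: list[int] = []
    for idx, (s, e) in enumerate(transcript.exons, start=1):
        exon_of_nt.extend([idx] * (e - s + 1))
    tpos = transcript.cds_transcript_start + ptc_cds_pos - 1
    n_exons = len(transcript.exons)
    if exon_of_nt[tpos - 1] == n_exons:
        return False
    # nucleotides strictly between the PTC base and the first base of the last exon
    first_last_exon_nt = exon_of_nt.index(n_exons) + 1
    dist = first_last_exon_nt - tpos - 1
    return dist >= 50 if boundary_inclusive else dist > 50


def _t2g(exons: list[tuple[int, int]], strand: str, tpos: int) -> int:
    """Spliced position -> genomic, for exon lists in transcription order."""
    offset = 0
    for s, e in exons:
        length = e - s + 1
        if tpos <= offset + length:
            within = tpos - offset - 1
            return (s + within) if strand == "+" else (e - within)
        offset += length
    raise ValueError(f"transcript position {tpos} out of range")


def simulate_transcripts(config: SimulationConfig) -> dict[str, TranscriptModel]:
    """Random gene models: 2-12 exons of 60-400 nt, CDS covering >= 60% of the
    spliced length, random strand; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    models: dict[str, TranscriptModel] = {}
    chrom_cursor = {f"chr{i}": 1_000 for i in range(1, 6)}
    for i in range(config.n_genes):
        gene = f"G{i + 1:05d}"
        chrom = f"chr{(i % 5) + 1}"
        n_exons = int(rng.integers(2, 13))
        lengths = rng.integers(60, 401, size=n_exons)
        introns = rng.integers(200, 2001, size=n_exons - 1)
        start = chrom_cursor[chrom]
        exons_fwd = []
        pos = start
        for j, L in enumerate(lengths):
            exons_fwd.append((pos, pos + int(L) - 1))
            pos += int(L)
            if j < n_exons - 1:
                pos += int(introns[j])
        chrom_cursor[chrom] = pos + int(rng.integers(5_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = exons_fwd if strand == "+" else exons_fwd[::-1]
        spliced = int(sum(lengths))
        frac = rng.uniform(0.6, 0.9)
        cds_len = max(9, 3 * (int(spliced * frac) // 3))
        utr5 = int(rng.integers(0, spliced - cds_len + 1))
        models[gene] = TranscriptModel(
            transcript_id=f"{gene}.t1", gene=gene, chrom=chrom, strand=strand,
            exons=exons,
            cds_start=_t2g(exons, strand, utr5 + 1),
            cds_end=_t2g(exons, strand, utr5 + cds_len),
        )
    return models
    return models


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = NUCLEOTIDES[rng.integers(0, 4)]
    alt = NUCLEOTIDES[rng.integers(0, 4)]
    while alt == ref:
        alt = NUCLEOTIDES[rng.integers(0, 4)]
    return ref, alt


def _place_splice_site(
    transcript: TranscriptModel, rng: np.random.Generator
) -> tuple[int, str, str]:
    """Genomic position and ref/alt at a random canonical +-2 splice position."""
    n = len(transcript.exons)
    intron_idx = int(rng.integers(0, n - 1))  # intron after exon intron_idx (0-based)
    donor = rng.random() < 0.5
    plus = transcript.strand == "+"
    if donor:
        offset = int(rng.integers(1, 3))  # +1 or +2
        s, e = transcript.exons[intron_idx]
        pos = e + offset if plus else s - offset
        ref = "G" if offset == 1 else "T"
    else:
        offset = -int(rng.integers(1, 3))  # -1 or -2
        s, e = transcript.exons[intron_idx + 1]
        pos = s + offset if plus else e - offset
        ref = "G" if offset == -1 else "A"
    alt = NUCLEOTIDES[rng.integers(0, 4)]
    while alt == ref:
        alt = NUCLEOTIDES[rng.integers(0, 4)]
    return pos, ref, alt


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: Optional[float]) -> int:
    """Negative-binomial depth around ``mean`` (uneven capture/expression);
    dispersion None means exact depth at the mean."""
    if dispersion is None:
        return max(1, int(round(mean)))
    p = dispersion / (dispersion + mean)
    return max(1, int(rng.negative_binomial(dispersion, p)))


def simulate_cohort(
    config: SimulationConfig,
    transcripts: Optional[dict[str, TranscriptModel]] = None,
) -> tuple[list[MutationRecord], list[CopySegment], list[GroundTruth]]:
    """Draw a full cohort of mutations, copy segments and ground truths.

    A single seeded random stream drives every draw in a fixed order, so the
    output is reproducible bit-for-bit per seed.
    """
    if transcripts is None:
        transcripts = simulate_transcripts(config)
    genes = sorted(transcripts)
    rng = np.random.default_rng(config.seed + 1)
    cats = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats])
    a0, b0 = config.dna_fraction_prior

    n_hyper = int(round(config.hypermutator_fraction * config.n_samples))
    hyper_samples = set(rng.choice(config.n_samples, size=n_hyper, replace=False).tolist())

    records: list[MutationRecord] = []
    truths: list[GroundTruth] = []
    segments: list[CopySegment] = []

    for s_idx in range(config.n_samples):
        sample = f"S{s_idx + 1:04d}"
        mean_n = config.mean_mutations_per_sample
        if s_idx in hyper_samples:
            mean_n *= config.hypermutator_multiplier
        n_mut = max(1, int(rng.poisson(mean_n)))
        gene_draw = rng.integers(0, len(genes), size=n_mut)
        cat_draw = rng.choice(len(cats), size=n_mut, p=weights)
        for g_i, c_i in zip(gene_draw, cat_draw):
            gene = genes[int(g_i)]
            tr = transcripts[gene]
            category = cats[int(c_i)]
            if config.fixed_dna_fraction is not None:
                p_dna = float(config.fixed_dna_fraction)
            else:
                p_dna = float(rng.beta(a0, b0))
            ptc_cds: Optional[int] = None
            effect = "none"
            nmd_truth: Optional[bool] = None
            if category == "splice_site":
                pos, ref, alt = _place_splice_site(tr, rng)
                effect = "intron_retention" if config.splice_retention_boost > 1 else "none"
                p_rna = rna_fraction_under_nmd(p_dna, config.splice_retention_boost) \
                    if effect != "none" else p_dna
            else:
                cds_len = tr.cds_length
                if category == "nonsense":
                    cds_pos = int(rng.integers(1, max(2, cds_len - 3)))
                    ref, alt = _random_snv_alleles(rng)
                    ptc_codon_start = cds_pos - (cds_pos - 1) % 3
                    nmd_truth = _nmd_sensitive_bruteforce(
                        tr, ptc_codon_start, config.nmd_boundary_inclusive)
                elif category == "frameshift":
                    cds_pos = int(rng.integers(1, max(2, cds_len - 60)))
                    if rng.random() < 0.5:
                        ref, alt = "AC", "A"
                    else:
                        ref, alt = "A", "AG"
                    jump = 3 * int(rng.integers(2, 40))
                    raw = min(cds_pos + jump, cds_len - 2)
                    ptc_cds = raw - (raw - 1) % 3
                    nmd_truth = _nmd_sensitive_bruteforce(
                        tr, ptc_cds, config.nmd_boundary_inclusive)
                elif category == "inframe":
                    cds_pos = int(rng.integers(1, max(2, cds_len - 6)))
                    ref, alt = "AGCT", "A"
                else:  # missense / silent
                    cds_pos = int(rng.integers(1, cds_len + 1))
                    ref, alt = _random_snv_alleles(rng)
                pos = tr.transcript_to_genomic(tr.cds_transcript_start + cds_pos - 1)
                if nmd_truth and config.nmd_retention < 1.0:
                    effect = "nmd"
                    p_rna = rna_fraction_under_nmd(p_dna, config.nmd_retention)
                else:
                    p_rna = p_dna
            dna_n = _nb_depth(rng, config.dna_depth, config.depth_dispersion)
            rna_n = _nb_depth(rng, config.rna_depth, config.depth_dispersion)
            dna_alt_n = int(rng.binomial(dna_n, p_dna))
            rna_alt_n = int(rng.binomial(rna_n, p_rna))
            rec = MutationRecord(
                sample_id=sample, gene=gene, chrom=tr.chrom, pos=int(pos),
                ref_allele=ref, alt_allele=alt, category=category,
                dna_ref=dna_n - dna_alt_n, dna_alt=dna_alt_n,
                rna_ref=rna_n - rna_alt_n, rna_alt=rna_alt_n,
                ptc_cds_pos=ptc_cds,
            )
            records.append(rec)
            truths.append(GroundTruth(
                record_key=rec.key, true_dna_fraction=p_dna,
                true_rna_fraction=p_rna if effect != "none" else p_dna,
                effect=effect, nmd_sensitive_truth=nmd_truth,
            ))
        segments.extend(_simulate_segments(sample, transcripts, config, rng))
    return records, segments, truths


def _simulate_segments(
    sample: str,
    transcripts: dict[str, TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[CopySegment]:
    """Tile each chromosome's gene span with segments, mostly copy-neutral."""
    spans: dict[str, tuple[int, int]] = {}
    for tr in transcripts.values():
        lo = min(s for s, _ in tr.exons) - 500
        hi = max(e for _, e in tr.exons) + 500
        cur = spans.get(tr.chrom)
        spans[tr.chrom] = (lo, hi) if cur is None else (min(cur[0], lo), max(cur[1], hi))
    segments = []
    for chrom in sorted(spans):
        lo, hi = spans[chrom]
        n_seg = int(rng.integers(3, 7))
        cuts = np.sort(rng.integers(lo + 1, hi, size=n_seg - 1))
        edges = [lo, *cuts.tolist(), hi]
        for a, b in zip(edges[:-1], edges[1:]):
            if rng.random() < config.neutral_cn_fraction:
                lr = float(rng.uniform(-0.12, 0.12))
            else:
                lr = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.8))
            segments.append(CopySegment(sample, chrom, int(a), int(b), round(lr, 4)))
    return segments


def truths_to_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        sample_id, chrom, pos, ref, alt = t.record_key
        rows.append({
            "sample_id": sample_id, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "true_dna_fraction": t.true_dna_fraction,
            "true_rna_fraction": t.true_rna_fraction,
            "effect": t.effect, "nmd_sensitive_truth": t.nmd_sensitive_truth,
        })
    return pd.DataFrame(rows)


def write_cohort(
    outdir: str | Path,
    config: SimulationConfig,
    transcripts: Optional[dict[str, TranscriptModel]] = None,
) -> dict[str, Path]:
    """Simulate and write mutations.tsv, transcripts.gtf, segments.seg, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if transcripts is None:
        transcripts = simulate_transcripts(config)
    records, segments, truths = simulate_cohort(config, transcripts)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "transcripts": outdir / "transcripts.gtf",
        "segments": outdir / "segments.seg",
        "truth": outdir / "truth.tsv",
    }
    write_mutation_table(records, paths["mutations"])
    write_transcript_gtf(transcripts.values(), paths["transcripts"])
    write_segments(segments, paths["segments"])
    truths_to_frame(truths).to_csv(paths["truth"], sep="\t", index=False)
    return paths
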