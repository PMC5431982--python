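"""Domain types and readers/writers for the external file formats.

The mutation table is a tab-separated file modeled on a somatic MAF with two
extra pairs of columns carrying per-mutation allele read counts from
whole-exome (DNA) and transcriptome (RNA) sequencing. Transcript models come
from GTF (``exon`` + ``CDS`` features) or BED12; copy-number segments from SEG.

Internal coordinates are 1-based inclusive genomic positions and 1-based
CDS/transcript nucleotide positions; BED's 0-based half-open intervals are
converted at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger("aimseq")

#: The six mutation classes analysed: four SNV classes and two indel classes.
CATEGORIES = ("nonsense", "missense", "splice_site", "silent", "frameshift", "inframe")

#: Classes that introduce a premature termination codon and can trigger NMD.
TRUNCATING = ("nonsense", "frameshift")

AI_CLASSES = ("sig_pos_afd", "sig_neg_afd", "no_sig")

_MUTATION_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "category",
    "dna_ref", "dna_alt", "rna_ref", "rna_alt",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row or value violates the input contract."""


class ModelError(ValueError):
    """A transcript model is internally inconsistent."""


def normalize_category(raw: str) -> str:
    """Map free-form category spellings (e.g. MAF's ``Splice_Site``) onto the enum."""
    key = str(raw).strip().lower()
    aliases = {
        "nonsense_mutation": "nonsense",
        "missense_mutation": "missense",
        "splice_site": "splice_site",
        "splicesite": "splice_site",
        "silent": "silent",
        "synonymous": "silent",
        "frame_shift": "frameshift",
        "frameshift_indel": "frameshift",
        "in_frame": "inframe",
        "inframe_indel": "inframe",
    }
    key = aliases.get(key, key)
    if key not in CATEGORIES:
        raise ValidationError(f"unknown mutation category: {raw!r}")
    return key


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation with DNA- and RNA-level allele read counts."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    category: str
    dna_ref: int
    dna_alt: int
    rna_ref: int
    rna_alt: int
    ptc_cds_pos: Optional[int] = None
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name in ("dna_ref", "dna_alt", "rna_ref", "rna_alt"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative read count {name}={getattr(self, name)}")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown mutation category: {self.category!r}")
        is_snv = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        if is_snv and self.ref_allele == self.alt_allele:
            raise ValidationError(f"SNV ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def dna_depth(self) -> int:
        return self.dna_ref + self.dna_alt

    @property
    def rna_depth(self) -> int:
        return self.rna_ref + self.rna_alt


@dataclass(frozen=True)
class CopySegment:
    """A copy-number segment (SEG row): genomic interval with a log2 copy ratio."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log_ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start > end ({self.start} > {self.end}) on {self.chrom}"
            )


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS model; all PTC and splice-site geometry lives on it.

    ``exons`` are 1-based inclusive genomic intervals ordered in *transcription*
    order (for minus-strand models exon 1 is the highest-coordinate interval).
    ``cds_start``/``cds_end`` are the genomic positions of the first base of the
    start codon and the last base of the stop codon (strand-aware, so
    ``cds_start > cds_end`` on the minus strand).
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: zero exons")
        for s, e in self.exons:
            if s > e:
                raise ModelError(f"{self.transcript_id}: exon start > end ({s} > {e})")
        genomic_sorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ModelError(f"{self.transcript_id}: overlapping exons")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.exons) != expected:
            raise ModelError(f"{self.transcript_id}: exons not in transcription order")
        for pos, label in ((self.cds_start, "cds_start"), (self.cds_end, "cds_end")):
            if self.genomic_to_transcript(pos) is None:
                raise ModelError(f"{self.transcript_id}: {label} {pos} outside exons")
        if self.cds_transcript_end < self.cds_transcript_start:
            raise ModelError(f"{self.transcript_id}: CDS end upstream of CDS start")
        if self.cds_sequence is not None and len(self.cds_sequence) % 3 != 0:
            raise ModelError(f"{self.transcript_id}: CDS length not divisible by 3")

    # -- spliced-coordinate machinery -------------------------------------

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def junctions(self) -> list[int]:
        """Transcript coordinate of the last base of each exon except the last.

        Junction *k* sits between spliced positions ``junctions[k]`` and
        ``junctions[k] + 1``.
        """
        out, total = [], 0
        for length in self.exon_lengths[:-1]:
            total += length
            out.append(total)
        return out

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """1-based spliced-transcript coordinate of a genomic position, or None in introns."""
        span_lo = min(s for s, _ in self.exons)
        span_hi = max(e for _, e in self.exons)
        if pos < span_lo or pos > span_hi:
            raise ValueError(f"position {pos} outside transcript span [{span_lo},{span_hi}]")
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                within = (pos - s) if self.strand == "+" else (e - pos)
                return offset + within + 1
            offset += e - s + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if tpos < 1 or tpos > self.spliced_length:
            raise ValueError(f"transcript position {tpos} out of range")
        offset = 0
        for s, e in self.exons:
            length = e - s + 1
            if tpos <= offset + length:
                within = tpos - offset - 1
                return (s + within) if self.strand == "+" else (e - within)
            offset += length
        raise AssertionError("unreachable")

    def exon_index_of_transcript_pos(self, tpos: int) -> int:
        """1-based transcription-order index of the exon containing a spliced position."""
        offset = 0
        for i, length in enumerate(self.exon_lengths, start=1):
            if tpos <= offset + length:
                return i
            offset += length
        raise ValueError(f"transcript position {tpos} out of range")

    @property
    def cds_transcript_start(self) -> int:
        t = self.genomic_to_transcript(self.cds_start)
        assert t is not None
        return t

    @property
    def cds_transcript_end(self) -> int:
        t = self.genomic_to_transcript(self.cds_end)
        assert t is not None
        return t

    @property
    def cds_length(self) -> int:
        return self.cds_transcript_end - self.cds_transcript_start + 1


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id, "gene": r.gene, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref_allele, "alt": r.alt_allele, "category": r.category,
            "dna_ref": r.dna_ref, "dna_alt": r.dna_alt,
            "rna_ref": r.rna_ref, "rna_alt": r.rna_alt,
            "ptc_cds_pos": r.ptc_cds_pos,
        }
        row.update(dict(r.extra))
        rows.append(row)
    return pd.DataFrame(rows)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read the mutation TSV into :class:`MutationRecord` objects.

    Unknown extra columns are preserved on ``record.extra`` and written back
    untouched by :func:`write_mutation_table`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table {path} missing column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in _MUTATION_COLUMNS + ["ptc_cds_pos"]]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            counts = {}
            for c in ("pos", "dna_ref", "dna_alt", "rna_ref", "rna_alt"):
                counts[c] = int(str(d[c]).replace("−", "-"))
            ptc = d.get("ptc_cds_pos", "")
            ptc_val = int(ptc) if str(ptc).strip() not in ("", "NA", "nan", ".") else None
            rec = MutationRecord(
                sample_id=d["sample_id"], gene=d["gene"], chrom=d["chrom"],
                pos=counts["pos"], ref_allele=d["ref"], alt_allele=d["alt"],
                category=normalize_category(d["category"]),
                dna_ref=counts["dna_ref"], dna_alt=counts["dna_alt"],
                rna_ref=counts["rna_ref"], rna_alt=counts["rna_alt"],
                ptc_cds_pos=ptc_val,
                extra=tuple((c, d[c]) for c in extra_cols),
            )
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
        records.append(rec)
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    if df.empty:
        df = pd.DataFrame(columns=_MUTATION_COLUMNS + ["ptc_cds_pos"])
    df["ptc_cds_pos"] = df["ptc_cds_pos"].astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_segments(path: str | Path) -> list[CopySegment]:
    """Read a SEG file (sample, chrom, start, end, [num_marks], seg_mean)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    cols = list(df.columns)
    mean_col = cols[-1]
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        vals = list(row)
        try:
            seg = CopySegment(
                sample_id=str(vals[0]), chrom=str(vals[1]),
                start=int(vals[2]), end=int(vals[3]),
                log_ratio=float(getattr(row, mean_col, vals[-1])),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
        segments.append(seg)
    return segments


def write_segments(segments: Iterable[CopySegment], path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
         "end": s.end, "seg_mean": s.log_ratio}
        for s in segments
    ]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "seg_mean"]).to_csv(
        path, sep="\t", index=False
    )


# -- transcript models -----------------------------------------------------

def _models_from_parts(parts: dict) -> dict[str, TranscriptModel]:
    """Assemble per-gene models, keeping the longest-CDS transcript per gene."""
    by_gene: dict[str, TranscriptModel] = {}
    for tid, p in parts.items():
        exons = sorted(p["exons"])
        if p["strand"] == "-":
            exons = exons[::-1]
        cds_lo, cds_hi = p["cds_lo"], p["cds_hi"]
        cds_start, cds_end = (cds_lo, cds_hi) if p["strand"] == "+" else (cds_hi, cds_lo)
        model = TranscriptModel(
            transcript_id=tid, gene=p["gene"], chrom=p["chrom"], strand=p["strand"],
            exons=exons, cds_start=cds_start, cds_end=cds_end,
            cds_sequence=p.get("cds_sequence"),
        )
        prev = by_gene.get(model.gene)
        if prev is None or model.cds_length > prev.cds_length:
            if prev is not None:
                log.info(
                    "gene %s: keeping transcript %s (CDS %d nt) over %s (CDS %d nt)",
                    model.gene, model.transcript_id, model.cds_length,
                    prev.transcript_id, prev.cds_length,
                )
            by_gene[model.gene] = model
    return by_gene


def _read_gtf(path: str | Path) -> dict[str, TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    parts: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gene = feat.attributes.get("gene_id", [tid])[0]
        p = parts.setdefault(
            tid, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
                  "exons": [], "cds_lo": None, "cds_hi": None},
        )
        if feat.featuretype == "exon":
            p["exons"].append((feat.start, feat.end))
        else:
            p["cds_lo"] = feat.start if p["cds_lo"] is None else min(p["cds_lo"], feat.start)
            p["cds_hi"] = feat.end if p["cds_hi"] is None else max(p["cds_hi"], feat.end)
    for tid, p in parts.items():
        if not p["exons"]:
            raise ModelError(f"{tid}: zero exons")
        if p["cds_lo"] is None:
            raise ModelError(f"{tid}: no CDS features")
    return _models_from_parts(parts)


def _read_bed12(path: str | Path) -> dict[str, TranscriptModel]:
    names = ["chrom", "chromStart", "chromEnd", "name", "score", "strand",
             "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str, comment="#")
    parts: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        chrom_start = int(row.chromStart)
        n = int(row.blockCount)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != n or len(starts) != n or n == 0:
            raise ModelError(f"{row.name}: malformed BED12 blocks")
        # 0-based half-open blocks -> 1-based inclusive exons
        exons = [
            (chrom_start + st + 1, chrom_start + st + sz)
            for st, sz in zip(starts, sizes)
        ]
        tid = str(row.name)
        gene = tid.split("|")[0]
        parts[tid] = {
            "gene": gene, "chrom": str(row.chrom), "strand": str(row.strand),
            "exons": exons,
            "cds_lo": int(row.thickStart) + 1, "cds_hi": int(row.thickEnd),
        }
    return _models_from_parts(parts)


def read_transcript_models(path: str | Path, format: str = "gtf") -> dict[str, TranscriptModel]:
    """Read transcript models from GTF or BED12, keyed by gene.

    When a gene carries several transcripts, the one with the longest CDS is
    kept (and the choice logged).
    """
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unsupported transcript format: {format!r}")


def write_transcript_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models as a minimal GTF (exon + CDS features)."""
    lines = []
    for m in sorted(models, key=lambda m: (m.chrom, min(s for s, _ in m.exons))):
        attrs = f'gene_id "{m.gene}"; transcript_id "{m.transcript_id}";'
        cds_lo, cds_hi = sorted((m.cds_start, m.cds_end))
        for s, e in sorted(m.exons):
            lines.append(
                f"{m.chrom}\taimseq\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}"
            )
            lo, hi = max(s, cds_lo), min(e, cds_hi)
            if lo <= hi:
                lines.append(
                    f"{m.chrom}\taimseq\tCDS\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_transcript_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    lines = []
    for m in sorted(models, key=lambda m: (m.chrom, min(s for s, _ in m.exons))):
        exons = sorted(m.exons)
        chrom_start = exons[0][0] - 1
        chrom_end = exons[-1][1]
        sizes = ",".join(str(e - s + 1) for s, e in exons)
        starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons)
        cds_lo, cds_hi = sorted((m.cds_start, m.cds_end))
        lines.append("\t".join(map(str, [
            m.chrom, chrom_start, chrom_end, m.transcript_id, 0, m.strand,
            cds_lo - 1, cds_hi, "0", len(exons), sizes, starts,
        ])))
    Path(path).write_text("\n".join(lines) + "\n")


# -- AI results ------------------------------------------------------------

@dataclass(frozen=True)
class AIResult:
    """Per-mutation allelic-imbalance call: VAF pair, AFD, log10 Bayes factor, class."""

    record: MutationRecord
    dna_vaf: float
    rna_vaf: float
    afd: float
    log10_bf: float
    ai_class: str

    def __post_init__(self) -> None:
        if self.ai_class not in AI_CLASSES:
            raise ValidationError(f"unknown AI class {self.ai_class!r}")
        if not -1.0 - 1e-9 <= self.afd <= 1.0 + 1e-9:
            raise ValidationError(f"AFD out of [-1,1]: {self.afd}")


def _fmt6(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "nan"
    return f"{x:.6g}"


RESULT_COLUMNS = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "category",
                  "dna_vaf", "rna_vaf", "afd", "log10_bf", "ai_class"]


def write_results(
    results: list[AIResult],
    path: str | Path,
    annotations: Optional[pd.DataFrame] = None,
    allow_empty: bool = False,
) -> None:
    """Write AI results (and optional per-record annotation columns) as TSV.

    Floats are rendered with 6 significant digits. Duplicate (sample, chrom,
    pos) rows are written verbatim with a logged warning.
    """
    if not results and not allow_empty:
        raise ValidationError("empty result list (pass allow_empty=True to write a header)")
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.record.sample_id, "gene": r.record.gene,
            "chrom": r.record.chrom, "pos": r.record.pos,
            "ref": r.record.ref_allele, "alt": r.record.alt_allele,
            "category": r.record.category,
            "dna_vaf": _fmt6(r.dna_vaf), "rna_vaf": _fmt6(r.rna_vaf),
            "afd": _fmt6(r.afd), "log10_bf": _fmt6(r.log10_bf),
            "ai_class": r.ai_class,
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df) and df.duplicated(subset=["sample_id", "chrom", "pos"]).any():
        log.warning("duplicate (sample, chrom, pos) rows in results written verbatim")
    if annotations is not None and len(df):
        df = df.merge(annotations, how="left",
                      on=[c for c in ("sample_id", "chrom", "pos") if c in annotations.columns])
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back as a DataFrame (floats parsed)."""
    return pd.read_csv(path, sep="\t")
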