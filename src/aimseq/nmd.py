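"""Transcript-coordinate geometry for NMD classification and splice-site calls.

A premature termination codon (PTC) triggers nonsense-mediated decay when the
ribosome terminates upstream of a retained exon-junction complex. Under the
50-nt rule a PTC is NMD-sensitive when it lies at least 50 nt upstream of the
3'-most exon-exon junction of the mature transcript; PTCs in the last exon
escape. All distances here are measured in spliced (mRNA) coordinates, since
the EJC model concerns the mature transcript, and the PTC position used for
distances is the first base of the stop codon.

The exactly-50-nt boundary is classified sensitive by default (inclusive
``>= 50``); the convention is configurable because published statements of the
rule differ on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import MutationRecord, TranscriptModel, TRUNCATING

STOP_CODONS = {"TAA", "TAG", "TGA"}

REGIONS = ("last_exon", "penultimate_ge50", "penultimate_lt50", "other")


class AnnotationError(ValueError):
    """A mutation cannot be placed on its transcript model."""


@dataclass(frozen=True)
class PTCAnnotation:
    """Positional features of a premature termination codon on one transcript."""

    record_key: tuple
    transcript_id: str
    ptc_cds_pos: int
    exon_index: int
    dist_last_junction: int
    dist_start_codon: int
    dist_downstream_junction: Optional[int]
    region: str
    nmd_class: str


@dataclass(frozen=True)
class SpliceSiteCall:
    """A canonical splice-site mutation: donor GT / acceptor AG, intronic offset."""

    record_key: tuple
    side: str  # donor_5prime | acceptor_3prime
    offset: int  # +1/+2 donor, -2/-1 acceptor (transcript orientation)
    canonical_ref: str


def map_genomic_to_cds(transcript: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """1-based CDS nucleotide of a genomic position; None for introns and UTRs.

    Raises ValueError when the position falls outside the transcript span.
    """
    tpos = transcript.genomic_to_transcript(genomic_pos)
    if tpos is None:
        return None
    cds = tpos - transcript.cds_transcript_start + 1
    if cds < 1 or cds > transcript.cds_length:
        return None
    return cds


def _ptc_features(
    transcript: TranscriptModel, ptc_cds_pos: int, boundary_inclusive: bool
) -> dict:
    """Distance features for a PTC given as a 1-based CDS coordinate."""
    if ptc_cds_pos < 1 or ptc_cds_pos > transcript.cds_length:
        raise AnnotationError(
            f"PTC CDS position {ptc_cds_pos} outside CDS (length {transcript.cds_length})"
        )
    tpos = transcript.cds_transcript_start + ptc_cds_pos - 1
    junctions = transcript.junctions
    n_exons = len(transcript.exons)
    exon_index = transcript.exon_index_of_transcript_pos(tpos)
    # junction k sits between the last base of exon k (transcript coord J_k)
    # and the first base of exon k+1; dist = J_k - tpos, so a PTC downstream
    # of the junction (in the last exon) is strictly negative.
    dist_last = (junctions[-1] - tpos) if junctions else -tpos
    if exon_index == n_exons:
        region = "last_exon"
        dist_down = None
    else:
        dist_down = junctions[exon_index - 1] - tpos
        if exon_index == n_exons - 1:
            ge50 = dist_last >= 50 if boundary_inclusive else dist_last > 50
            region = "penultimate_ge50" if ge50 else "penultimate_lt50"
        else:
            region = "other"
    if region == "last_exon":
        nmd_class = "insensitive"
    elif boundary_inclusive:
        nmd_class = "sensitive" if dist_last >= 50 else "insensitive"
    else:
        nmd_class = "sensitive" if dist_last > 50 else "insensitive"
    return {
        "ptc_cds_pos": ptc_cds_pos,
        "exon_index": exon_index,
        "dist_last_junction": dist_last,
        "dist_start_codon": ptc_cds_pos - 1,
        "dist_downstream_junction": dist_down,
        "region": region,
        "nmd_class": nmd_class,
    }


def _frameshift_ptc_by_retranslation(
    transcript: TranscriptModel, record: MutationRecord
) -> int:
    """Naive PTC search: shift the CDS reading frame at the indel and translate
    to the first stop codon. Requires ``cds_sequence`` on the model."""
    seq = transcript.cds_sequence
    if seq is None:
        raise AnnotationError(
            f"{record.gene}: frameshift without ptc_cds_pos and no cds_sequence to re-translate"
        )
    cds = map_genomic_to_cds(transcript, record.pos)
    if cds is None:
        raise AnnotationError(f"{record.gene}: frameshift position maps outside the CDS")
    shift = len(record.alt_allele) - len(record.ref_allele)
    if shift % 3 == 0:
        raise AnnotationError(f"{record.gene}: indel length change is in-frame")
    if shift > 0:
        mutated = seq[:cds] + "N" * shift + seq[cds:]
    else:
        mutated = seq[:cds] + seq[cds - shift:]
    frame0 = (cds - 1) - (cds - 1) % 3
    for i in range(frame0, len(mutated) - 2, 3):
        if mutated[i:i + 3].upper() in STOP_CODONS:
            ptc = min(i + 1, transcript.cds_length)
            return ptc
    raise AnnotationError(f"{record.gene}: no stop codon found after frameshift")


def annotate_ptc(
    record: MutationRecord,
    transcript: TranscriptModel,
    boundary_inclusive: bool = True,
    allow_retranslation: bool = False,
) -> PTCAnnotation:
    """Annotate a truncating mutation with PTC geometry and its NMD class.

    Nonsense SNVs: the PTC is the codon containing the mutated base (the codon
    start is used for all distances). Frameshifts: an explicit ``ptc_cds_pos``
    on the record is required, unless ``allow_retranslation`` and the model
    carries a CDS sequence.
    """
    if record.category not in TRUNCATING:
        raise AnnotationError(f"category {record.category!r} carries no PTC")
    if record.category == "nonsense":
        cds = map_genomic_to_cds(transcript, record.pos)
        if cds is None:
            raise AnnotationError(
                f"{record.gene}: nonsense SNV at {record.chrom}:{record.pos} "
                "maps outside the CDS"
            )
        ptc_cds = cds - (cds - 1) % 3
    elif record.ptc_cds_pos is not None:
        ptc_cds = record.ptc_cds_pos
    elif allow_retranslation:
        ptc_cds = _frameshift_ptc_by_retranslation(transcript, record)
    else:
        raise AnnotationError(
            f"{record.gene}: frameshift record has no ptc_cds_pos "
            "(enable retranslation or supply the annotation)"
        )
    feats = _ptc_features(transcript, ptc_cds, boundary_inclusive)
    return PTCAnnotation(
        record_key=record.key, transcript_id=transcript.transcript_id, **feats
    )


def classify_splice_site(
    record: MutationRecord, transcript: TranscriptModel
) -> SpliceSiteCall:
    """Classify a splice-site mutation as donor (5', GT) or acceptor (3', AG).

    Only the canonical +-2 intronic dinucleotide positions are accepted; the
    offset is expressed in transcript orientation (+1/+2 = first/second
    intronic nt after an exon end, -2/-1 = last two intronic nt before an exon
    start).
    """
    if record.category != "splice_site":
        raise AnnotationError(f"category {record.category!r} is not splice_site")
    pos = record.pos
    plus = transcript.strand == "+"
    donor_canon = {1: "G", 2: "T"}
    accept_canon = {-2: "A", -1: "G"}
    n = len(transcript.exons)
    for i, (s, e) in enumerate(transcript.exons):
        # donor side: intron following exon i (not after the last exon)
        if i < n - 1:
            delta = (pos - e) if plus else (s - pos)
            if delta in (1, 2):
                return SpliceSiteCall(record.key, "donor_5prime", delta, donor_canon[delta])
        # acceptor side: intron preceding exon i (not before the first exon)
        if i > 0:
            delta = (pos - s) if plus else (e - pos)
            if delta in (-1, -2):
                return SpliceSiteCall(record.key, "acceptor_3prime", delta, accept_canon[delta])
    raise AnnotationError(
        f"{record.gene}: position {record.chrom}:{pos} is not within 2 nt of an "
        "intron boundary"
    )


def first_exon_features(annotations: Sequence[PTCAnnotation]) -> pd.DataFrame:
    """Table of (record key, in_first_exon, dist_start_codon) for PTC annotations."""
    rows = [
        {"record_key": a.record_key, "in_first_exon": a.exon_index == 1,
         "dist_start_codon": a.dist_start_codon}
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=["record_key", "in_first_exon", "dist_start_codon"])


def annotations_to_frame(annotations: Sequence[PTCAnnotation]) -> pd.DataFrame:
    """Flatten PTC annotations into a joinable table (sample_id, chrom, pos keys)."""
    rows = []
    for a in annotations:
        sample_id, chrom, pos, _, _ = a.record_key
        rows.append({
            "sample_id": sample_id, "chrom": chrom, "pos": pos,
            "transcript_id": a.transcript_id, "ptc_cds_pos": a.ptc_cds_pos,
            "exon_index": a.exon_index, "dist_last_junction": a.dist_last_junction,
            "dist_start_codon": a.dist_start_codon,
            "dist_downstream_junction": a.dist_downstream_junction,
            "region": a.region, "nmd_class": a.nmd_class,
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "transcript_id", "ptc_cds_pos", "exon_index",
        "dist_last_junction", "dist_start_codon", "dist_downstream_junction",
        "region", "nmd_class",
    ])
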