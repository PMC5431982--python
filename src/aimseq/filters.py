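"""Preprocessing funnel: depth filter, hypermutated-sample exclusion,
multi-mutant-gene discard, and the copy-number-neutral restriction.

Each filter returns the kept records plus a :class:`FilterReport` so the whole
funnel is auditable (records_in = records_out + removed).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io import CopySegment, MutationRecord


@dataclass
class FilterReport:
    stage_name: str
    records_in: int
    records_out: int
    removed_ids: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.records_out != self.records_in - len(self.removed_ids):
            raise ValueError(
                f"{self.stage_name}: records_out {self.records_out} != "
                f"records_in {self.records_in} - removed {len(self.removed_ids)}"
            )


def _report(stage: str, records: Sequence[MutationRecord],
            kept: Sequence[MutationRecord]) -> FilterReport:
    kept_keys = Counter(r.key for r in kept)
    removed = []
    for r in records:
        if kept_keys[r.key] > 0:
            kept_keys[r.key] -= 1
        else:
            removed.append(r.key)
    return FilterReport(stage, len(records), len(kept), removed)


def filter_by_depth(
    records: Sequence[MutationRecord], min_dna: int = 10, min_rna: int = 10
) -> tuple[list[MutationRecord], FilterReport]:
    """Keep mutations supported by at least ``min_dna`` DNA and ``min_rna`` RNA reads.

    Boundaries are inclusive ("no less than" the threshold).
    """
    if min_dna < 0 or min_rna < 0:
        raise ValueError("depth thresholds must be non-negative")
    kept = [r for r in records if r.dna_depth >= min_dna and r.rna_depth >= min_rna]
    return kept, _report("depth", records, kept)


def flag_hypermutated(
    records: Sequence[MutationRecord],
    rate_threshold: float = 10.0,
    exome_size_mb: float = 38.0,
) -> set[str]:
    """Samples whose mutation burden strictly exceeds ``rate_threshold`` per Mb."""
    if exome_size_mb <= 0:
        raise ValueError("exome_size_mb must be positive")
    counts = Counter(r.sample_id for r in records)
    return {s for s, n in counts.items() if n / exome_size_mb > rate_threshold}


def drop_hypermutated(
    records: Sequence[MutationRecord],
    rate_threshold: float = 10.0,
    exome_size_mb: float = 38.0,
) -> tuple[list[MutationRecord], FilterReport]:
    flagged = flag_hypermutated(records, rate_threshold, exome_size_mb)
    kept = [r for r in records if r.sample_id not in flagged]
    return kept, _report("hypermutation", records, kept)


def drop_multimutant_genes(
    records: Sequence[MutationRecord],
) -> tuple[list[MutationRecord], FilterReport]:
    """Discard mutations in genes carrying >= 2 mutations *within the same sample*.

    A gene mutated once in each of two samples is retained in both.
    """
    counts = Counter((r.sample_id, r.gene) for r in records)
    kept = [r for r in records if counts[(r.sample_id, r.gene)] == 1]
    return kept, _report("multimutant_gene", records, kept)


def filter_copy_neutral(
    records: Sequence[MutationRecord],
    segments: Iterable[CopySegment],
    low: float = -0.15,
    high: float = 0.15,
) -> tuple[list[MutationRecord], FilterReport]:
    """Keep mutations inside a same-sample segment with ``low < log_ratio < high``.

    Both inequalities are strict; mutations covered by no segment are removed
    (treated as non-neutral).
    """
    if low >= high:
        raise ValueError("low must be < high")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for seg in segments:
        tree = trees.setdefault((seg.sample_id, seg.chrom), IntervalTree())
        tree.addi(seg.start, seg.end + 1, seg.log_ratio)  # half-open internal
    kept = []
    for r in records:
        tree = trees.get((r.sample_id, r.chrom))
        if tree is None:
            continue
        hits = tree[r.pos]
        if hits and all(low < iv.data < high for iv in hits):
            kept.append(r)
    return kept, _report("copy_neutral", records, kept)
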