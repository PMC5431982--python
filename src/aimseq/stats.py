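"""Downstream statistics: paired VAF test, exact 2x2 tests, mutation spectra,
Ts/Tv, cumulative ratio curves, per-gene AI enrichment and ranked-list export.

The 2x2 exact test is an in-package log-space hypergeometric enumeration with
a vectorized batch API (``fisher_exact_grid``), using the same two-sided
convention as R/scipy (sum of all tables with point probability at most
(1 + 1e-7) times the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import AIResult, ValidationError

_REL_TOL = 1.0 + 1e-7  # two-sided point-probability tolerance, as in R's fisher.test


class DegenerateInputError(ValueError):
    """The input carries no information for the requested statistic."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): row 1 = focal group sig / non-sig, row 2 = background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DegenerateInputError("all-zero 2x2 table")


def paired_vaf_test(results: Sequence[AIResult], direction: str = "rna_less"):
    """One-tailed paired t-test of RNA-VAF against DNA-VAF.

    ``rna_less`` tests whether RNA-VAFs are significantly lower than DNA-VAFs
    (the NMD direction); ``rna_greater`` the opposite tail. Returns (t, p).
    """
    if direction not in ("rna_less", "rna_greater"):
        raise ValidationError(f"unknown direction {direction!r}")
    rna = np.array([r.rna_vaf for r in results], dtype=float)
    dna = np.array([r.dna_vaf for r in results], dtype=float)
    if len(rna) < 2:
        raise DegenerateInputError("paired t-test needs at least 2 pairs")
    if np.allclose(rna - dna, (rna - dna)[0]):
        raise DegenerateInputError("zero variance of paired differences")
    alt = "less" if direction == "rna_less" else "greater"
    t, p = sps.ttest_rel(rna, dna, alternative=alt)
    return float(t), float(p)


def _log_hypergeom_pmf(a, r1, c1, n):
    """log P(X = a) for X ~ Hypergeom(population n, successes c1, draws r1)."""
    a = np.asarray(a, dtype=float)
    return (
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - a + 1) - gammaln(n - r1 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def _support(r1: int, c1: int, n: int) -> np.ndarray:
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return np.arange(lo, hi + 1)


def fisher_exact_2x2(table: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``greater`` tests enrichment of cell ``a``; ``two_sided`` sums all tables
    with the same margins whose probability does not exceed the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, a + b + c + d
    support = _support(r1, c1, n)
    pmf = np.exp(_log_hypergeom_pmf(support, r1, c1, n))
    obs = pmf[support == a][0]
    if alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "two_sided":
        p = pmf[pmf <= obs * _REL_TOL].sum()
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def fisher_exact_grid(tables: np.ndarray, alternative: str = "two_sided") -> np.ndarray:
    """Vectorized exact test for an (N, 4) array of 2x2 tables (a, b, c, d rows).

    Groups tables by their margins so the hypergeometric pmf over each support
    is computed once; intended for exhaustive grids.
    """
    tables = np.asarray(tables, dtype=np.int64)
    a, b, c, d = tables.T
    r1, c1, n = a + b, a + c, a + b + c + d
    out = np.empty(len(tables), dtype=float)
    keys = np.stack([r1, c1, n], axis=1)
    order = np.lexsort(keys.T)
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(
        np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)) + 1
    for grp in np.split(order, boundaries):
        gr1, gc1, gn = keys[grp[0]]
        support = _support(int(gr1), int(gc1), int(gn))
        pmf = np.exp(_log_hypergeom_pmf(support, gr1, gc1, gn))
        ga = a[grp]
        idx = ga - support[0]
        if alternative == "greater":
            tail = np.cumsum(pmf[::-1])[::-1]
            out[grp] = tail[idx]
        elif alternative == "two_sided":
            obs = pmf[idx]
            out[grp] = (pmf[None, :] * (pmf[None, :] <= obs[:, None] * _REL_TOL)).sum(axis=1)
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
    return np.minimum(out, 1.0)


_PYRIMIDINE_CONTEXT = {
    ("C", "A"): "C:G>A:T", ("G", "T"): "C:G>A:T",
    ("C", "G"): "C:G>G:C", ("G", "C"): "C:G>G:C",
    ("C", "T"): "C:G>T:A", ("G", "A"): "C:G>T:A",
    ("T", "A"): "T:A>A:T", ("A", "T"): "T:A>A:T",
    ("T", "C"): "T:A>C:G", ("A", "G"): "T:A>C:G",
    ("T", "G"): "T:A>G:C", ("A", "C"): "T:A>G:C",
}

SPECTRUM_CLASSES = ("C:G>A:T", "C:G>G:C", "C:G>T:A", "T:A>A:T", "T:A>C:G", "T:A>G:C")


def spectrum_class(ref: str, alt: str) -> str:
    """Collapse the 12 SNV substitutions onto the six strand-symmetric classes."""
    key = (str(ref).upper(), str(alt).upper())
    if key not in _PYRIMIDINE_CONTEXT:
        raise ValidationError(f"invalid substitution {ref}>{alt}")
    return _PYRIMIDINE_CONTEXT[key]


def ts_tv(ref: str, alt: str) -> str:
    """Transition (A<->G, C<->T) vs transversion."""
    r, a = str(ref).upper(), str(alt).upper()
    if r == a or r not in "ACGT" or a not in "ACGT":
        raise ValidationError(f"invalid SNV {ref}>{alt}")
    return "transition" if {r, a} in ({"A", "G"}, {"C", "T"}) else "transversion"


def chisq_independence(counts: pd.DataFrame | np.ndarray):
    """Pearson chi-square test of independence on a class x group count table."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("need a table with at least 2 rows and 2 columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero marginal in contingency table")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


@dataclass
class RatioCurve:
    """Cumulative event-ratio curve: bin k covers all values < k * bin_width."""

    bin_upper_edges: list[float]
    n_total: list[int]
    n_event: list[int]

    @property
    def ratios(self) -> list[float]:
        return [e / t if t > 0 else float("nan")
                for e, t in zip(self.n_event, self.n_total)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_upper_edge": self.bin_upper_edges,
            "n_total": self.n_total, "n_event": self.n_event,
            "ratio": self.ratios,
        })


def cumulative_ratio_curve(
    values: Sequence[float], event_flags: Sequence[bool],
    bin_width: float, max_value: float,
) -> RatioCurve:
    """Event fraction among mutations with covariate below each cumulative edge.

    Bins are left-closed at 0 and right-open: edge ``e`` counts values in
    ``[0, e)``. Empty bins report total 0 and a NaN ratio.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if len(values) != len(flags):
        raise ValidationError("values and event_flags must have equal length")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    edges, totals, events = [], [], []
    edge = bin_width
    while edge <= max_value + 1e-12:
        mask = values < edge
        edges.append(edge)
        totals.append(int(mask.sum()))
        events.append(int(flags[mask].sum()))
        edge += bin_width
    return RatioCurve(edges, totals, events)


def gene_ai_enrichment(
    results: Sequence[AIResult], focal_class: str = "sig_pos_afd",
    min_events: int = 1,
) -> pd.DataFrame:
    """Per-gene one-sided Fisher test for enrichment of a focal AI class.

    Each gene is tested against the background of all other genes in the same
    result set: table ((gene focal, gene other), (background focal, background
    other)), alternative 'greater'. A Benjamini-Hochberg column is reported
    alongside the raw p-values but not used for filtering.
    """
    df = pd.DataFrame({
        "gene": [r.record.gene for r in results],
        "focal": [r.ai_class == focal_class for r in results],
    })
    return gene_enrichment_frame(df, min_events=min_events)


def gene_enrichment_frame(df: pd.DataFrame, min_events: int = 1) -> pd.DataFrame:
    """Same test on a prepared frame with ``gene`` and boolean ``focal`` columns."""
    if df.empty:
        return pd.DataFrame(columns=["gene", "n_mutations", "n_focal", "p_fisher",
                                     "neg_log10_p", "q_bh"])
    total = len(df)
    total_focal = int(df["focal"].sum())
    g = df.groupby("gene", sort=True).agg(n_mutations=("focal", "size"),
                                          n_focal=("focal", "sum")).reset_index()
    rows = []
    for r in g.itertuples(index=False):
        table = ContingencyTable2x2(
            a=int(r.n_focal), b=int(r.n_mutations - r.n_focal),
            c=total_focal - int(r.n_focal),
            d=(total - int(r.n_mutations)) - (total_focal - int(r.n_focal)),
        )
        p = fisher_exact_2x2(table, alternative="greater")
        rows.append({"gene": r.gene, "n_mutations": int(r.n_mutations),
                     "n_focal": int(r.n_focal), "p_fisher": p,
                     "neg_log10_p": float(-np.log10(max(p, 1e-300)))})
    out = pd.DataFrame(rows)
    out["q_bh"] = multipletests(out["p_fisher"], method="fdr_bh")[1]
    out = out[out["n_focal"] >= min_events].reset_index(drop=True)
    return out


def export_ranked_list(enrichment: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write a GSEA-preranked style .rnk file: gene, -log10 Fisher p.

    Sorted by descending score; ties broken alphabetically by gene.
    """
    ranked = enrichment[["gene", "neg_log10_p"]].copy()
    ranked = ranked.sort_values(
        ["neg_log10_p", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    ranked.to_csv(path, sep="\t", index=False, header=False,
                  float_format="%.6g")
    return ranked
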