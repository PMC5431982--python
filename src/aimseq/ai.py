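"""Allelic-imbalance calling: VAF, AFD, and the two-binomial Bayes-factor test.

For a mutation with DNA counts (k_D alt of n_D reads) and RNA counts (k_R alt
of n_R reads) the test compares

* H1 — independent mutant-allele proportions p_D, p_R, each with a
  Beta(alpha, beta) prior, against
* H0 — one shared proportion p with the same Beta(alpha, beta) prior.

Both marginal likelihoods are conjugate Beta-Binomial integrals, so

    BF10 = B(a+k_D, b+n_D-k_D) B(a+k_R, b+n_R-k_R)
           -------------------------------------------- ,
           B(a, b) B(a+k_D+k_R, b+n_D+n_R-k_D-k_R)

with B the Beta function; the binomial coefficients cancel between numerator
and denominator. Everything is computed in log space via log-Gamma and
reported as log10(BF10). A mutation is called significantly imbalanced when
BF10 > 10 (log10 BF > 1), the conventional "strong evidence" cutoff; the sign
of the allelic fraction difference AFD = RNA-VAF - DNA-VAF labels the call
sig_pos_afd or sig_neg_afd.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln

from .io import AIResult, CATEGORIES, MutationRecord, ValidationError

LOG10 = np.log(10.0)


@dataclass(frozen=True)
class BFModelParams:
    """Beta prior shapes and the Bayes-factor significance cutoff."""

    alpha: float = 1.0
    beta: float = 1.0
    bf_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.bf_threshold <= 0:
            raise ValidationError("alpha, beta and bf_threshold must all be positive")


DEFAULT_PARAMS = BFModelParams()


def compute_vaf(alt_count: int, ref_count: int) -> float:
    """Fraction of reads supporting the mutant allele: alt / (alt + ref)."""
    if alt_count < 0 or ref_count < 0:
        raise ValidationError("negative read count")
    total = alt_count + ref_count
    if total == 0:
        raise ValidationError("VAF undefined at zero total depth; depth-filter first")
    return alt_count / total


def compute_afd(dna_vaf: float, rna_vaf: float) -> float:
    """Allelic fraction difference RNA-VAF minus DNA-VAF, in [-1, 1]."""
    if not (0.0 <= dna_vaf <= 1.0 and 0.0 <= rna_vaf <= 1.0):
        raise ValidationError("VAFs must lie in [0, 1]")
    return rna_vaf - dna_vaf


def log10_bayes_factor(
    dna_alt, dna_total, rna_alt, rna_total, params: BFModelParams = DEFAULT_PARAMS
):
    """log10 Bayes factor of independent vs shared allele proportions.

    Accepts scalars or equal-shaped integer arrays (vectorized).
    """
    kd = np.asarray(dna_alt)
    nd = np.asarray(dna_total)
    kr = np.asarray(rna_alt)
    nr = np.asarray(rna_total)
    if np.any(kd < 0) or np.any(kr < 0) or np.any(kd > nd) or np.any(kr > nr):
        raise ValidationError("require 0 <= alt <= total for both DNA and RNA counts")
    if np.any(nd <= 0) or np.any(nr <= 0):
        raise ValidationError("totals must be positive")
    a, b = params.alpha, params.beta
    log_m1 = (
        betaln(a + kd, b + nd - kd) + betaln(a + kr, b + nr - kr) - 2 * betaln(a, b)
    )
    log_m0 = betaln(a + kd + kr, b + nd + nr - kd - kr) - betaln(a, b)
    out = (log_m1 - log_m0) / LOG10
    return float(out) if out.ndim == 0 else out


def classify_ai(
    dna_vaf: float, rna_vaf: float, log10_bf: float,
    params: BFModelParams = DEFAULT_PARAMS,
) -> str:
    """Label a mutation sig_pos_afd / sig_neg_afd / no_sig.

    Significance requires BF strictly above the threshold; a zero AFD is never
    significant regardless of the BF.
    """
    afd = compute_afd(dna_vaf, rna_vaf)
    if log10_bf > np.log10(params.bf_threshold):
        if afd > 0:
            return "sig_pos_afd"
        if afd < 0:
            return "sig_neg_afd"
    return "no_sig"


def evaluate_records(
    records: Sequence[MutationRecord], params: BFModelParams = DEFAULT_PARAMS
) -> list[AIResult]:
    """Run the AI test on every record (records must be depth-filtered: totals > 0)."""
    results = []
    for r in records:
        dna_vaf = compute_vaf(r.dna_alt, r.dna_ref)
        rna_vaf = compute_vaf(r.rna_alt, r.rna_ref)
        bf = log10_bayes_factor(r.dna_alt, r.dna_depth, r.rna_alt, r.rna_depth, params)
        results.append(AIResult(
            record=r, dna_vaf=dna_vaf, rna_vaf=rna_vaf,
            afd=compute_afd(dna_vaf, rna_vaf), log10_bf=bf,
            ai_class=classify_ai(dna_vaf, rna_vaf, bf, params),
        ))
    return results


_FIELD_GETTERS = {
    "category": lambda r: r.record.category,
    "sample_id": lambda r: r.record.sample_id,
    "gene": lambda r: r.record.gene,
    "chrom": lambda r: r.record.chrom,
    "ai_class": lambda r: r.ai_class,
}


def category_summary(
    results: Sequence[AIResult], group_keys: Sequence[str] = ("category",),
    extra_fields: dict | None = None,
) -> pd.DataFrame:
    """Per-group counts and sig-pos / sig-neg ratios.

    The sig-neg-AFD ratio of a group is the number of sig_neg_afd mutations
    divided by the total number of mutations in the group (likewise sig-pos).
    ``extra_fields`` maps a key name to a dict record-key -> value, for
    grouping by externally computed labels (e.g. NMD class).
    """
    rows = []
    for res in results:
        row = {}
        for k in group_keys:
            if k in _FIELD_GETTERS:
                row[k] = _FIELD_GETTERS[k](res)
            elif extra_fields and k in extra_fields:
                row[k] = extra_fields[k].get(res.record.key)
            else:
                raise ValidationError(f"unknown group key {k!r}")
        row["ai_class"] = res.ai_class
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=list(group_keys) + ["n", "n_sig_pos", "n_sig_neg",
                                        "sig_pos_ratio", "sig_neg_ratio"])
    g = df.groupby(list(group_keys), dropna=False, sort=True)
    out = g.agg(
        n=("ai_class", "size"),
        n_sig_pos=("ai_class", lambda s: int((s == "sig_pos_afd").sum())),
        n_sig_neg=("ai_class", lambda s: int((s == "sig_neg_afd").sum())),
    ).reset_index()
    out = out[out["n"] > 0]
    out["sig_pos_ratio"] = out["n_sig_pos"] / out["n"]
    out["sig_neg_ratio"] = out["n_sig_neg"] / out["n"]
    return out


def threshold_grid(
    records: Sequence[MutationRecord],
    dna_cutoffs: Sequence[int],
    rna_cutoffs: Sequence[int],
    params: BFModelParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Class proportions per mutation category over a grid of minimum-depth cutoffs.

    For each (min_dna, min_rna) pair the depth filter is re-applied and the
    sig-pos / sig-neg / no-sig proportions recomputed per category; the three
    proportions sum to 1 in every cell with data.
    """
    if not len(dna_cutoffs) or not len(rna_cutoffs):
        raise ValidationError("cutoff lists must be non-empty")
    # BF depends only on counts, so evaluate once and re-filter results.
    evaluable = [r for r in records if r.dna_depth > 0 and r.rna_depth > 0]
    results = evaluate_records(evaluable, params)
    rows = []
    for min_dna in dna_cutoffs:
        for min_rna in rna_cutoffs:
            sub = [res for res in results
                   if res.record.dna_depth >= min_dna and res.record.rna_depth >= min_rna]
            by_cat: dict[str, list[AIResult]] = {}
            for res in sub:
                by_cat.setdefault(res.record.category, []).append(res)
            for cat in CATEGORIES:
                group = by_cat.get(cat, [])
                n = len(group)
                if n == 0:
                    continue
                n_pos = sum(res.ai_class == "sig_pos_afd" for res in group)
                n_neg = sum(res.ai_class == "sig_neg_afd" for res in group)
                rows.append({
                    "min_dna": min_dna, "min_rna": min_rna, "category": cat, "n": n,
                    "sig_pos_ratio": n_pos / n, "sig_neg_ratio": n_neg / n,
                    "no_sig_ratio": (n - n_pos - n_neg) / n,
                })
    return pd.DataFrame(rows, columns=["min_dna", "min_rna", "category", "n",
                                       "sig_pos_ratio", "sig_neg_ratio", "no_sig_ratio"])
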