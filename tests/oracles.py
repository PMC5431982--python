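"""Independent oracles used across the test suite.

Everything here deliberately avoids the code paths it checks: the Bayes-factor
oracle integrates the marginal likelihoods numerically, the geometry oracle
walks the concatenated spliced sequence nucleotide by nucleotide, and the
Fisher oracle enumerates hypergeometric tables via scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import beta as beta_dist, hypergeom

from aimseq.io import TranscriptModel

# -- Bayes factor ----------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_X = 0.5 * (_GL_NODES + 1.0)  # map [-1,1] -> [0,1]
_W = 0.5 * _GL_WEIGHTS


def binomial_marginal_quadrature(k: int, n: int, alpha: float = 1.0, beta: float = 1.0):
    """∫ C(n,k) p^k (1-p)^(n-k) Beta(p; a, b) dp by 64-node Gauss-Legendre.

    Exact (to machine precision) for integer priors with k + n <= 127 since the
    integrand is then a polynomial. The binomial coefficient is included so the
    value is a genuine marginal likelihood; coefficients cancel in the BF.
    """
    from math import comb

    dens = beta_dist.pdf(_X, alpha, beta)
    vals = _X ** k * (1.0 - _X) ** (n - k) * dens
    return comb(n, k) * float(np.sum(_W * vals))


def log10_bf_quadrature(kd, nd, kr, nr, alpha=1.0, beta=1.0) -> float:
    m1 = (binomial_marginal_quadrature(kd, nd, alpha, beta)
          * binomial_marginal_quadrature(kr, nr, alpha, beta))
    from math import comb

    dens = beta_dist.pdf(_X, alpha, beta)
    vals = _X ** (kd + kr) * (1.0 - _X) ** ((nd - kd) + (nr - kr)) * dens
    m0 = comb(nd, kd) * comb(nr, kr) * float(np.sum(_W * vals))
    return float(np.log10(m1 / m0))


def log10_bf_scipy_quad(kd, nd, kr, nr, alpha=1.0, beta=1.0) -> float:
    """Adaptive-quadrature variant for non-polynomial (non-integer-prior) cases."""

    def marg(ks, ns):
        f = lambda p: p ** ks * (1 - p) ** (ns - ks) * beta_dist.pdf(p, alpha, beta)
        val, _ = integrate.quad(f, 0.0, 1.0)
        return val

    m1 = marg(kd, nd) * marg(kr, nr)
    m0 = marg(kd + kr, nd + nr)
    return float(np.log10(m1 / m0))


def log10_bf_grid_oracle(max_total: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """All count tuples with 1 <= totals <= max_total and the quadrature log10 BF.

    Returns (counts array of shape (N, 4) with columns kd, nd, kr, nr, log10 BF).
    Uses a table of uniform-prior integrals I[i, j] = ∫ p^i (1-p)^j dp computed
    by Gauss-Legendre; BF = I[kd, nd-kd] I[kr, nr-nr+...] / (I_sum * B(1,1)).
    """
    m = 2 * max_total + 1
    I = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            I[i, j] = float(np.sum(_W * _X ** i * (1.0 - _X) ** j))
    tuples = []
    for nd in range(1, max_total + 1):
        for kd in range(nd + 1):
            tuples.append((kd, nd))
    pairs = np.array(tuples)
    kd = np.repeat(pairs[:, 0], len(pairs))
    nd = np.repeat(pairs[:, 1], len(pairs))
    kr = np.tile(pairs[:, 0], len(pairs))
    nr = np.tile(pairs[:, 1], len(pairs))
    m1 = I[kd, nd - kd] * I[kr, nr - kr]
    m0 = I[kd + kr, (nd - kd) + (nr - kr)]
    counts = np.stack([kd, nd, kr, nr], axis=1)
    return counts, np.log10(m1 / m0)


# -- transcript geometry ---------------------------------------------------

def walk_ptc_features(model: TranscriptModel, ptc_cds_pos: int) -> dict:
    """Brute-force PTC geometry: enumerate spliced nucleotides one by one."""
    nts: list[tuple[int, int]] = []  # (genomic position, 1-based exon index)
    for idx, (s, e) in enumerate(model.exons, start=1):
        span = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        nts.extend((g, idx) for g in span)
    cds_start_i = next(i for i, (g, _) in enumerate(nts) if g == model.cds_start)
    t_i = cds_start_i + ptc_cds_pos - 1
    exon_index = nts[t_i][1]
    n_exons = len(model.exons)
    if n_exons > 1:
        last_junction_i = max(i for i, (_, x) in enumerate(nts) if x == n_exons - 1)
        dist_last = last_junction_i - t_i
    else:
        dist_last = -(t_i + 1)
    if exon_index == n_exons:
        dist_down = None
    else:
        dist_down = max(i for i, (_, x) in enumerate(nts) if x == exon_index) - t_i
    return {
        "exon_index": exon_index,
        "dist_last_junction": dist_last,
        "dist_start_codon": ptc_cds_pos - 1,
        "dist_downstream_junction": dist_down,
    }


def random_transcript(rng: np.random.Generator, min_exons: int = 2,
                      max_exons: int = 12) -> TranscriptModel:
    """A random valid transcript model built without the simulator."""
    n_exons = int(rng.integers(min_exons, max_exons + 1))
    lengths = rng.integers(60, 401, size=n_exons)
    introns = rng.integers(50, 501, size=max(0, n_exons - 1))
    start = int(rng.integers(1_000, 50_000))
    fwd = []
    pos = start
    for i, L in enumerate(lengths):
        fwd.append((pos, pos + int(L) - 1))
        pos += int(L) + (int(introns[i]) if i < n_exons - 1 else 0)
    strand = "+" if rng.random() < 0.5 else "-"
    exons = fwd if strand == "+" else fwd[::-1]
    spliced = int(lengths.sum())
    cds_len = max(9, 3 * (int(spliced * rng.uniform(0.5, 0.9)) // 3))
    utr5 = int(rng.integers(0, spliced - cds_len + 1))

    def t2g(tpos):
        off = 0
        for s, e in exons:
            L = e - s + 1
            if tpos <= off + L:
                w = tpos - off - 1
                return s + w if strand == "+" else e - w
            off += L
        raise AssertionError

    return TranscriptModel(
        transcript_id="T", gene="G", chrom="chr1", strand=strand, exons=exons,
        cds_start=t2g(utr5 + 1), cds_end=t2g(utr5 + cds_len),
    )


def reflect_transcript(model: TranscriptModel, pivot: int) -> TranscriptModel:
    """Mirror a transcript through a genomic pivot and flip its strand."""
    exons = [(pivot - e, pivot - s) for s, e in model.exons]
    return TranscriptModel(
        transcript_id=model.transcript_id, gene=model.gene, chrom=model.chrom,
        strand="-" if model.strand == "+" else "+", exons=exons,
        cds_start=pivot - model.cds_start, cds_end=pivot - model.cds_end,
    )


# -- Fisher ----------------------------------------------------------------

def fisher_enumeration_oracle(tables: np.ndarray, alternative: str = "two_sided"):
    """Exact p by explicit enumeration over scipy.stats.hypergeom pmfs."""
    out = np.empty(len(tables))
    for i, (a, b, c, d) in enumerate(np.asarray(tables, dtype=int)):
        r1, c1, n = a + b, a + c, a + b + c + d
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, n, c1, r1)
        obs = pmf[support == a][0]
        if alternative == "greater":
            out[i] = pmf[support >= a].sum()
        else:
            out[i] = pmf[pmf <= obs * (1 + 1e-7)].sum()
    return np.minimum(out, 1.0)


def fisher_enumeration_grid(tables: np.ndarray, alternative: str = "two_sided"):
    """Exhaustive-enumeration oracle for large table grids.

    Same convention as :func:`fisher_enumeration_oracle` but grouped by table
    margins so the scipy hypergeometric pmf is evaluated once per margin set.
    """
    tables = np.asarray(tables, dtype=np.int64)
    a, b, c, d = tables.T
    r1, c1, n = a + b, a + c, a + b + c + d
    out = np.empty(len(tables))
    order = np.lexsort((c1, r1, n))
    sorted_keys = np.stack([n[order], r1[order], c1[order]], axis=1)
    boundaries = np.flatnonzero(np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)) + 1
    for grp in np.split(order, boundaries):
        gn, gr1, gc1 = int(n[grp[0]]), int(r1[grp[0]]), int(c1[grp[0]])
        lo, hi = max(0, gr1 + gc1 - gn), min(gr1, gc1)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, gn, gc1, gr1)
        idx = a[grp] - lo
        if alternative == "greater":
            tail = np.cumsum(pmf[::-1])[::-1]
            out[grp] = tail[idx]
        else:
            obs = pmf[idx]
            out[grp] = (pmf[None, :] * (pmf[None, :] <= obs[:, None] * (1 + 1e-7))).sum(axis=1)
    return np.minimum(out, 1.0)


def all_tables_up_to(total: int) -> np.ndarray:
    """Every (a, b, c, d) with 0 < a+b+c+d <= total."""
    tables = []
    for n in range(1, total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    tables.append((a, b, c, n - a - b - c))
    return np.array(tables, dtype=np.int64)
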