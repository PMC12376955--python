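"""Independent brute-force reference implementations used only by tests.

Everything here is transcribed directly from first principles (pairwise
comparisons, exhaustive enumeration, published formulas retyped) and shares
no code with the package, so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def _alleles_at_site(column: np.ndarray) -> list[int]:
    """Expand diploid genotype codes into a flat allele list, skipping missing."""
    out: list[int] = []
    for g in column:
        if g == MISSING:
            continue
        if g == 0:
            out += [0, 0]
        elif g == 1:
            out += [0, 1]
        else:
            out += [1, 1]
    return out


def pi_site(column: np.ndarray) -> float:
    """Mean pairwise difference at one site by explicit pair enumeration."""
    alleles = _alleles_at_site(column)
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = sum(
        1 for i, j in itertools.combinations(range(n), 2)
        if alleles[i] != alleles[j]
    )
    return diff / (n * (n - 1) / 2)


def pi_total(geno: np.ndarray) -> float:
    return float(sum(pi_site(geno[:, j]) for j in range(geno.shape[1])))


def harmonic(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def harmonic2(k: int) -> float:
    return sum(1.0 / i**2 for i in range(1, k + 1))


def watterson(s: int, n: int) -> float:
    return 0.0 if s == 0 else s / harmonic(n - 1)


def segregating(geno: np.ndarray) -> int:
    count = 0
    for j in range(geno.shape[1]):
        alleles = _alleles_at_site(geno[:, j])
        if len(set(alleles)) > 1:
            count += 1
    return count


def tajimas_d(geno: np.ndarray) -> float | None:
    """Tajima's D from scratch: pi by pair counting, constants re-derived.

    Assumes a fully-called matrix (one sample size n applies).
    """
    n = 2 * geno.shape[0]
    s = segregating(geno)
    if s == 0:
        return None
    pi = pi_total(geno)
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def singleton_count(geno: np.ndarray) -> int:
    """Sites where the minor allele occurs in exactly one sequence."""
    count = 0
    for j in range(geno.shape[1]):
        alleles = _alleles_at_site(geno[:, j])
        ones = sum(alleles)
        if min(ones, len(alleles) - ones) == 1:
            count += 1
    return count


def fu_li_dstar_fstar(geno: np.ndarray) -> tuple[float, float] | None:
    """Fu & Li's starred statistics, constants retyped from the literature."""
    n = 2 * geno.shape[0]
    s = segregating(geno)
    if s == 0:
        return None
    eta_s = singleton_count(geno)
    pi = pi_total(geno)
    a = harmonic(n - 1)
    b = harmonic2(n - 1)
    a1 = a + 1.0 / n
    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
        1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n
    )
    vD = ((n / (n - 1)) ** 2 * b + a**2 * dn
          - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (a**2 + b)
    uD = (n / (n - 1)) * (a - n / (n - 1)) - vD
    dstar = ((n / (n - 1)) * s - a * eta_s) / math.sqrt(uD * s + vD * s**2)
    vF = ((2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
          + 2 * (n - 1) * a / n**2 - 8 * b / n) / (a**2 + b)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a1)
          / (3 * n * (n - 1))) / a - vF
    fstar = (pi - ((n - 1) / n) * eta_s) / math.sqrt(uF * s + vF * s**2)
    return dstar, fstar


def wc_fst_site(col_a: np.ndarray, col_b: np.ndarray) -> tuple[float, float, float] | None:
    """Weir & Cockerham (1984) a, b, c at one site, retyped independently."""
    stats = []
    for col in (col_a, col_b):
        called = [g for g in col if g != MISSING]
        n_i = len(called)
        if n_i < 2:
            return None
        p_i = sum(called) / (2 * n_i)
        h_i = sum(1 for g in called if g == 1) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def project_site_enumeration(n: int, i: int, m: int) -> np.ndarray:
    """Average derived-count histogram over all C(n, m) subsamples.

    Enumerates every subset of an explicit allele list with ``i`` derived
    copies; the mean histogram is the exact hypergeometric projection.
    """
    alleles = [1] * i + [0] * (n - i)
    hist = np.zeros(m + 1)
    total = 0
    for combo in itertools.combinations(range(n), m):
        hist[sum(alleles[j] for j in combo)] += 1
        total += 1
    return hist / total


def topo_range_window(values: np.ndarray, nodata: float, window: int) -> np.ndarray:
    """Per-cell windowed range by explicit double loop (truncated edges)."""
    h = window // 2
    nrows, ncols = values.shape
    out = np.full(values.shape, nodata)
    for r in range(nrows):
        for c in range(ncols):
            lo, hi = None, None
            for rr in range(max(0, r - h), min(nrows, r + h + 1)):
                for cc in range(max(0, c - h), min(ncols, c + h + 1)):
                    v = values[rr, cc]
                    if v == nodata:
                        continue
                    lo = v if lo is None else min(lo, v)
                    hi = v if hi is None else max(hi, v)
            if lo is not None:
                out[r, c] = 10.0 * math.log10(hi - lo + 1.0)
    return out
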