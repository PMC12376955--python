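"""Diversity, differentiation, and neutrality statistics.

Per-locus statistics (segregating sites S, nucleotide diversity pi,
Watterson's theta) are averaged across RAD loci for genome-wide values, the
way short-locus reduced-representation data are usually summarized.  The
neutrality statistics (Tajima's D, Fu & Li's D* and F*) are computed on the
concatenated per-population matrix; their significance comes from coalescent
simulation nulls (see :mod:`popdemog.neutrality`), not from analytic
approximations.

Tajima (1989) constants::

    a1 = sum_{i<n} 1/i        a2 = sum_{i<n} 1/i^2
    b1 = (n+1)/(3(n-1))       b2 = 2(n^2+n+3)/(9n(n-1))
    c1 = b1 - 1/a1            c2 = b2 - (n+2)/(a1 n) + a2/a1^2
    e1 = c1/a1                e2 = c2/(a1^2 + a2)
    D  = (pi - S/a1) / sqrt(e1 S + e2 S (S-1))

Fu & Li's starred (no-outgroup) statistics use the singleton count eta_s
(sites whose minor allele occurs exactly once) with the corrected variance
constants adopted by mainstream implementations.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .coalsim import harmonic
from .genotype_io import MISSING, PopulationMap, VariantMatrix

__all__ = [
    "LOCUS_LENGTH_BP",
    "SummaryStatistics",
    "per_locus_table",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajimas_d_from_classes",
    "fu_li_dstar_fstar",
    "fu_li_from_classes",
    "wc_fst",
    "site_allele_counts",
    "summarize_population",
]

#: post-trim ddRAD read length; fixed by the library design, used as the
#: per-locus denominator for per-base-pair diversity
LOCUS_LENGTH_BP = 39


@dataclasses.dataclass
class SummaryStatistics:
    """Per-locus table plus genome-wide averages and neutrality statistics.

    ``neutrality`` values are ``None`` (undefined) when S = 0.
    """

    per_locus: pd.DataFrame
    genome: dict
    neutrality: dict


def site_allele_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per site: (alternate-allele count, observed allele count) ignoring missing."""
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    n_obs = 2 * called.sum(axis=0)
    return alt, n_obs


def _pi_per_site(g: np.ndarray) -> np.ndarray:
    """Mean pairwise difference contribution per site: 2 j (n-j) / (n (n-1))."""
    alt, n_obs = site_allele_counts(g)
    out = np.zeros(g.shape[1])
    ok = n_obs >= 2
    j = alt[ok].astype(float)
    n = n_obs[ok].astype(float)
    out[ok] = 2.0 * j * (n - j) / (n * (n - 1.0))
    return out


def per_locus_table(m: VariantMatrix) -> pd.DataFrame:
    """Per-locus S, pi (sum over the locus's sites), and Watterson's theta.

    Watterson's theta uses the mean number of observed alleles across the
    locus's polymorphic sites (missing data make n vary by site).
    """
    pi_site = _pi_per_site(m.genotypes)
    alt, n_obs = site_allele_counts(m.genotypes)
    seg = (alt > 0) & (alt < n_obs)
    rows = []
    by_locus: dict[str, list[int]] = {}
    for j, lid in enumerate(m.locus_ids):
        by_locus.setdefault(lid, []).append(j)
    for lid, sites in by_locus.items():
        sites = np.array(sites)
        s_count = int(seg[sites].sum())
        pi_sum = float(pi_site[sites].sum())
        ns = n_obs[sites][seg[sites]]
        if s_count > 0:
            n_eff = float(ns.mean())
            theta_w = s_count / harmonic(int(round(n_eff)) - 1)
        else:
            theta_w = 0.0
        rows.append({"locus": lid, "S": s_count, "pi": pi_sum, "theta_w": theta_w})
    return pd.DataFrame(rows).set_index("locus")


def nucleotide_diversity(m: VariantMatrix, mode: str = "per_locus") -> dict:
    """Genome-wide nucleotide diversity averaged over loci.

    ``per_locus`` averages the per-locus sums of site contributions (each
    divided by the fixed locus length for a per-bp value); ``per_site``
    averages the per-variant-site means instead.  Both are reported by
    :func:`summarize_population`.
    """
    table = per_locus_table(m)
    if mode not in ("per_locus", "per_site"):
        raise ValueError("mode must be 'per_locus' or 'per_site'")
    if mode == "per_locus":
        value = float(table["pi"].mean())
    else:
        pi_site = _pi_per_site(m.genotypes)
        alt, n_obs = site_allele_counts(m.genotypes)
        seg = (alt > 0) & (alt < n_obs)
        value = float(pi_site[seg].mean()) if seg.any() else 0.0
    return {"mode": mode, "pi": value, "pi_per_bp": value / LOCUS_LENGTH_BP}


def watterson_theta(s: int, n: int) -> float:
    """Watterson's estimator S / a_{n-1} for n sampled alleles."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if s == 0:
        return 0.0
    return s / harmonic(n - 1)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d(pi_total: float, s: int, n: int) -> float | None:
    """Tajima's D from total mean pairwise differences, S, and sample size.

    Returns ``None`` (undefined) when S = 0.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if s == 0:
        return None
    a1 = harmonic(n - 1)
    e1, e2 = _tajima_constants(n)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def tajimas_d_from_classes(counts: np.ndarray, n: int) -> np.ndarray:
    """Vectorized Tajima's D from unfolded class counts (reps x (n-1))."""
    counts = np.atleast_2d(counts)
    i = np.arange(1, n)
    pi = counts @ (2.0 * i * (n - i) / (n * (n - 1.0)))
    s = counts.sum(axis=1).astype(float)
    a1 = harmonic(n - 1)
    e1, e2 = _tajima_constants(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
    return np.where(s > 0, d, np.nan)


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(u_D*, v_D*, u_F*, v_F*) corrected variance constants."""
    a = harmonic(n - 1)
    b = harmonic(n - 1, power=2)
    a1 = a + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n
    )
    v_dstar = ((n / (n - 1.0)) ** 2 * b + a * a * dn
               - 2 * (n * a * (a + 1)) / (n - 1.0) ** 2) / (a * a + b)
    u_dstar = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v_dstar
    v_fstar = (
        (2 * n**3 + 110.0 * n**2 - 255.0 * n + 153) / (9.0 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8.0 * b / n
    ) / (a * a + b)
    u_fstar = (
        (4 * n**2 + 19.0 * n + 3 - 12 * (n + 1) * a1) / (3.0 * n * (n - 1))
    ) / a - v_fstar
    return u_dstar, v_dstar, u_fstar, v_fstar


def fu_li_from_classes(counts: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fu & Li D*, F* from unfolded class counts (reps x (n-1)).

    Singletons eta_s are sites whose minor allele occurs exactly once, i.e.
    unfolded classes 1 and n-1 (intraspecific, no outgroup).
    """
    counts = np.atleast_2d(counts)
    s = counts.sum(axis=1).astype(float)
    eta_s = counts[:, 0].astype(float)
    if n >= 3:
        eta_s = eta_s + counts[:, -1]
    i = np.arange(1, n)
    pi = counts @ (2.0 * i * (n - i) / (n * (n - 1.0)))
    a = harmonic(n - 1)
    ud, vd, uf, vf = _fu_li_constants(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        dstar = ((n / (n - 1.0)) * s - a * eta_s) / np.sqrt(ud * s + vd * s * s)
        fstar = (pi - ((n - 1.0) / n) * eta_s) / np.sqrt(uf * s + vf * s * s)
    dstar = np.where(s > 0, dstar, np.nan)
    fstar = np.where(s > 0, fstar, np.nan)
    return dstar, fstar


def _complete_site_classes(m: VariantMatrix) -> tuple[np.ndarray, int]:
    """Unfolded class counts over fully-called polymorphic sites.

    Restricts to sites with no missing genotype so one sample size applies;
    returns (class count vector of length n-1, n alleles).
    """
    g = m.genotypes
    n = 2 * m.n_samples
    full = (g != MISSING).all(axis=0)
    alt = g[:, full].sum(axis=0)
    seg = (alt > 0) & (alt < n)
    counts = np.bincount(alt[seg], minlength=n)[1:n]
    return counts.astype(np.int64), n


def fu_li_dstar_fstar(m: VariantMatrix) -> tuple[float | None, float | None]:
    """Fu & Li's D* and F* on the concatenated matrix (complete sites only)."""
    counts, n = _complete_site_classes(m)
    if n < 4:
        raise ValueError("need at least 4 alleles")
    if counts.sum() == 0:
        return None, None
    d, f = fu_li_from_classes(counts, n)
    return float(d[0]), float(f[0])


def summarize_population(m: VariantMatrix) -> SummaryStatistics:
    """Full per-population summary: per-locus table, averages, neutrality.

    Neutrality statistics use the concatenated matrix restricted to
    fully-called sites (a single sample size n = 2 x samples applies); the
    per-locus table and averages use all sites via observed allele counts.
    """
    table = per_locus_table(m)
    genome = {
        "n_loci": int(len(table)),
        "S_mean": float(table["S"].mean()),
        "pi_locus_mean": float(table["pi"].mean()),
        "pi_per_bp": float(table["pi"].mean()) / LOCUS_LENGTH_BP,
        "pi_per_variant_site": nucleotide_diversity(m, "per_site")["pi"],
        "theta_w_mean": float(table["theta_w"].mean()),
    }
    counts, n = _complete_site_classes(m)
    s = int(counts.sum())
    if s > 0 and n >= 4:
        i = np.arange(1, n)
        pi_total = float(counts @ (2.0 * i * (n - i) / (n * (n - 1.0))))
        d = tajimas_d(pi_total, s, n)
        dstar, fstar = (float(x[0]) for x in fu_li_from_classes(counts, n))
    else:
        d = dstar = fstar = None
    neutrality = {
        "n_alleles": n,
        "S": s,
        "tajima_d": d,
        "fu_li_dstar": dstar,
        "fu_li_fstar": fstar,
    }
    return SummaryStatistics(per_locus=table, genome=genome, neutrality=neutrality)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------


def _wc_components(
    geno_a: np.ndarray, geno_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site variance components (a, b, c) for two populations.

    Diploid estimator with r = 2 populations: from per-population sample
    sizes n_i, allele frequencies p_i, and observed heterozygote frequencies
    h_i.  Returns (a, b, c, valid) arrays over sites; ``valid`` requires at
    least two called individuals per population.
    """
    comps = []
    ns, ps, hs = [], [], []
    for g in (geno_a, geno_b):
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)  # diploid individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, g, 0).sum(axis=0) / (2.0 * n_i)
            h_i = (g == 1).sum(axis=0) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    valid = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    n_sum = n1 + n2
    nbar = n_sum / r
    nc = (n_sum - (n1**2 + n2**2) / n_sum) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / n_sum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / n_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    return a, b, c, valid


def wc_fst(
    m: VariantMatrix, pm: PopulationMap, pop_a: str, pop_b: str
) -> tuple[np.ndarray, float, float]:
    """Weir & Cockerham (1984) theta-hat between two populations.

    Returns ``(per_site, mean_of_ratios, ratio_of_sums)``.  ``per_site`` has
    NaN at sites that are monomorphic across both populations or lack two
    called individuals in either; those sites are excluded from both
    averages.  Negative estimates are reported as computed.
    """
    idx_a = [m.sample_ids.index(s) for s in pm.samples_in(pop_a) if s in m.sample_ids]
    idx_b = [m.sample_ids.index(s) for s in pm.samples_in(pop_b) if s in m.sample_ids]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need >= 2 individuals per population")
    ga = m.genotypes[idx_a]
    gb = m.genotypes[idx_b]
    a, b, c, valid = _wc_components(ga, gb)
    both = np.concatenate([ga, gb])
    alt, n_obs = site_allele_counts(both)
    poly = (alt > 0) & (alt < n_obs)
    use = valid & poly
    denom = a + b + c
    per_site = np.full(m.n_sites, np.nan)
    ok = use & (denom != 0)
    per_site[ok] = a[ok] / denom[ok]
    mean_of_ratios = float(np.nanmean(per_site)) if ok.any() else float("nan")
    ratio_of_sums = (
        float(a[use].sum() / denom[use].sum()) if use.any() else float("nan")
    )
    return per_site, mean_of_ratios, ratio_of_sums


def pairwise_fst_matrix(m: VariantMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Symmetric matrix of mean-of-ratios theta-hat over population pairs."""
    pops = pm.populations
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, pa in enumerate(pops):
        out.loc[pa, pa] = 0.0
        for pb in pops[i + 1:]:
            try:
                _, mor, _ = wc_fst(m, pm, pa, pb)
            except ValueError:
                continue
            out.loc[pa, pb] = out.loc[pb, pa] = mor
    return out
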