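"""Folded 1D/2D site-frequency spectra with hypergeometric projection.

Each site is projected independently from its observed allele count down to
the target number of alleles (the dadi per-site convention), which lets
sites with missing genotypes contribute as long as they retain at least the
target count.  The projection of one site with derived count ``i`` out of
``n`` observed alleles spreads its mass over target classes ``k`` with the
hypergeometric weights ``C(i,k) C(n-i, m-k) / C(n,m)``.

Folding uses minor-allele orientation: entry ``i`` and ``n-i`` are added,
the upper half is masked, and (for even ``n``) the middle class is halved
after the addition so its mass is counted once.  The 2D fold applies the
same rule on total derived count with the anti-diagonal halved.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from .genotype_io import MISSING, VariantMatrix

__all__ = [
    "Spectrum",
    "sfs_from_matrix",
    "project",
    "fold",
    "choose_projection",
    "segregating_sites",
    "ProjectionNotRunnable",
]


class ProjectionNotRunnable(ValueError):
    """No candidate projection reaches the minimum allele count."""


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def projection_weights(n: int, i: int, m: int) -> np.ndarray:
    """Hypergeometric mass over target classes 0..m for derived count i of n."""
    k = np.arange(m + 1)
    with np.errstate(invalid="ignore"):
        logw = _log_comb(i, k) + _log_comb(n - i, m - k) - _log_comb(n, m)
    w = np.exp(logw)
    w[(k > i) | (m - k > n - i)] = 0.0
    return w


@dataclasses.dataclass
class Spectrum:
    """1D or 2D site-frequency spectrum with fold/mask metadata.

    ``counts`` has shape ``(n1+1,)`` or ``(n1+1, n2+1)`` where the sample
    sizes are in alleles.  ``mask`` marks entries excluded from sums (at
    minimum the fixed corners once masked for inference); folded spectra
    carry zero mass in the masked upper half.
    """

    counts: np.ndarray
    sample_sizes: tuple[int, ...]
    folded: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expect = tuple(n + 1 for n in self.sample_sizes)
        if self.counts.shape != expect:
            raise ValueError(f"counts shape {self.counts.shape} != {expect}")
        if (self.counts < -1e-9).any():
            raise ValueError("negative spectrum entries")
        if self.mask is None:
            self.mask = np.zeros_like(self.counts, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape mismatch")

    @property
    def dims(self) -> int:
        return self.counts.ndim

    def copy(self) -> "Spectrum":
        return Spectrum(self.counts.copy(), self.sample_sizes, self.folded,
                        self.mask.copy())

    def mask_corners(self) -> "Spectrum":
        """Mask the fixed (monomorphic) corner entries."""
        out = self.copy()
        if out.dims == 1:
            out.mask[0] = out.mask[-1] = True
        else:
            out.mask[0, 0] = out.mask[-1, -1] = True
        return out

    def total(self) -> float:
        """Sum of unmasked entries."""
        return float(self.counts[~self.mask].sum())

    # -- dadi flat text format ------------------------------------------------
    def to_file(self, path: str) -> None:
        """Write in dadi's flat SFS format (shape line, counts, mask)."""
        with open(path, "w") as fh:
            shape = " ".join(str(n + 1) for n in self.sample_sizes)
            fold = "folded" if self.folded else "unfolded"
            fh.write(f"{shape} {fold}\n")
            fh.write(" ".join(repr(float(v)) for v in self.counts.ravel()) + "\n")
            fh.write(" ".join("1" if b else "0" for b in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path: str) -> "Spectrum":
        with open(path) as fh:
            header = fh.readline().split()
            *shape, fold = header
            shape = tuple(int(s) for s in shape)
            counts = np.array([float(v) for v in fh.readline().split()]).reshape(shape)
            mask = np.array([v == "1" for v in fh.readline().split()]).reshape(shape)
        return cls(counts, tuple(s - 1 for s in shape), fold == "folded", mask)


def sfs_from_matrix(
    m: VariantMatrix,
    pops: list[list[str]],
    project_to: tuple[int, ...],
    fold_spectrum: bool = True,
) -> Spectrum:
    """Build a (projected, optionally folded) spectrum from genotype data.

    ``pops`` holds one or two lists of sample identifiers; ``project_to``
    gives the target alleles per population.  Each site is projected
    independently from its observed allele counts; sites observing fewer
    alleles than the target in any population are dropped.
    """
    if len(pops) not in (1, 2) or len(project_to) != len(pops):
        raise ValueError("pops must hold 1 or 2 sample lists matching project_to")
    idx = []
    for plist in pops:
        if not plist:
            raise ValueError("a population has zero samples")
        idx.append(np.array([m.sample_ids.index(s) for s in plist]))
    for mm, plist in zip(project_to, pops):
        if not (2 <= mm <= 2 * len(plist)):
            raise ValueError("project_to must be in [2, 2 * n_samples]")

    if len(pops) == 1:
        n_t = project_to[0]
        counts = np.zeros(n_t + 1)
        g = m.genotypes[idx[0]]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        n_obs = 2 * called.sum(axis=0)
        for j in range(m.n_sites):
            if n_obs[j] < n_t:
                continue
            counts += projection_weights(int(n_obs[j]), int(alt[j]), n_t)
        spec = Spectrum(counts, (n_t,))
    else:
        n1, n2 = project_to
        counts = np.zeros((n1 + 1, n2 + 1))
        g1, g2 = m.genotypes[idx[0]], m.genotypes[idx[1]]
        c1, c2 = g1 != MISSING, g2 != MISSING
        alt1 = np.where(c1, g1, 0).sum(axis=0)
        alt2 = np.where(c2, g2, 0).sum(axis=0)
        o1 = 2 * c1.sum(axis=0)
        o2 = 2 * c2.sum(axis=0)
        for j in range(m.n_sites):
            if o1[j] < n1 or o2[j] < n2:
                continue
            w1 = projection_weights(int(o1[j]), int(alt1[j]), n1)
            w2 = projection_weights(int(o2[j]), int(alt2[j]), n2)
            counts += np.outer(w1, w2)
        spec = Spectrum(counts, (n1, n2))
    if fold_spectrum:
        spec = fold(spec)
    return spec.mask_corners()


def project(s: Spectrum, m_alleles: tuple[int, ...]) -> Spectrum:
    """Hypergeometric down-projection of a spectrum (per dimension).

    Total mass (including corners) is preserved; masked entries of the input
    do not contribute.  Requires an unfolded spectrum (project before
    folding; the operations commute).
    """
    if s.folded:
        raise ValueError("project unfolded spectra (fold afterwards)")
    if len(m_alleles) != s.dims:
        raise ValueError("m_alleles dimensionality mismatch")
    for mt, n in zip(m_alleles, s.sample_sizes):
        if mt > n:
            raise ValueError(f"cannot project {n} alleles up to {mt}")
    counts = np.where(s.mask, 0.0, s.counts)
    for axis, (mt, n) in enumerate(zip(m_alleles, s.sample_sizes)):
        w = np.zeros((n + 1, mt + 1))
        for i in range(n + 1):
            w[i] = projection_weights(n, i, mt)
        counts = np.tensordot(counts, w, axes=([axis], [0]))
        counts = np.moveaxis(counts, -1, axis)
    return Spectrum(counts, tuple(m_alleles), folded=False)


def fold(s: Spectrum) -> Spectrum:
    """Fold to minor-allele orientation (mask upper half, halve the middle)."""
    if s.folded:
        raise ValueError("spectrum is already folded")
    counts = np.where(s.mask, 0.0, s.counts)
    rev = counts[tuple(slice(None, None, -1) for _ in range(s.dims))]
    total_n = sum(s.sample_sizes)
    if s.dims == 1:
        d = np.arange(counts.shape[0], dtype=float)
    else:
        d = (np.arange(counts.shape[0], dtype=float)[:, None]
             + np.arange(counts.shape[1], dtype=float)[None, :])
    folded = counts + rev
    folded[2 * d == total_n] *= 0.5
    upper = 2 * d > total_n
    folded[upper] = 0.0
    mask_rev = s.mask[tuple(slice(None, None, -1) for _ in range(s.dims))]
    mask = (s.mask & mask_rev) | upper
    return Spectrum(folded, s.sample_sizes, folded=True, mask=mask)


def segregating_sites(s: Spectrum) -> float:
    """Sum of unmasked, non-corner (polymorphic-class) entries."""
    corner = np.zeros_like(s.mask)
    if s.dims == 1:
        corner[0] = corner[-1] = True
    else:
        corner[0, 0] = corner[-1, -1] = True
    use = ~(s.mask | corner)
    return float(s.counts[use].sum())


def choose_projection(
    m: VariantMatrix,
    pops: list[list[str]],
    min_alleles: int = 10,
) -> tuple[tuple[int, ...], float]:
    """Scan candidate down-projections, maximizing segregating sites.

    Candidates range from ``min_alleles`` up to the maximum observed allele
    count per population (jointly over the grid in 2D); ties break toward the
    larger projection.  Raises :class:`ProjectionNotRunnable` when no
    candidate with at least ``min_alleles`` alleles per population retains
    any segregating site (the population cannot be analysed).
    """
    maxima = []
    for plist in pops:
        if not plist:
            raise ValueError("a population has zero samples")
        idx = np.array([m.sample_ids.index(s) for s in plist])
        called = m.genotypes[idx] != MISSING
        n_obs = 2 * called.sum(axis=0)
        maxima.append(int(n_obs.max()) if m.n_sites else 0)
    if any(mx < min_alleles for mx in maxima):
        raise ProjectionNotRunnable(
            f"max observable alleles {tuple(maxima)} below minimum {min_alleles}"
        )
    best: tuple[float, tuple[int, ...]] | None = None
    if len(pops) == 1:
        candidates = [(k,) for k in range(min_alleles, maxima[0] + 1)]
    else:
        candidates = [
            (k1, k2)
            for k1 in range(min_alleles, maxima[0] + 1)
            for k2 in range(min_alleles, maxima[1] + 1)
        ]
    for cand in candidates:
        spec = sfs_from_matrix(m, pops, cand, fold_spectrum=True)
        seg = segregating_sites(spec)
        key = (seg, sum(cand), cand)
        if best is None or key >= best:
            best = key
    seg, _, cand = best
    if seg <= 0:
        raise ProjectionNotRunnable("no candidate projection retains segregating sites")
    return cand, seg
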