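"""Coalescent simulator with piecewise-constant demography and infinite sites.

Scaling conventions (pinned here; every formula in the package refers back to
this block):

* **Time** is measured in units of ``4 * N_ref`` generations.
* **Population sizes** are relative: a population of size ``nu`` has
  ``nu * N_ref`` diploids, so a pair of lineages inside it coalesces at rate
  ``2 / nu`` and ``k`` lineages at rate ``k * (k - 1) / nu``.  Under this
  scaling ``E[TMRCA]`` for a sample of two in a constant population is 0.5
  (i.e., ``2 * N_ref`` generations) and the expected total branch length for a
  sample of ``n`` is the harmonic number ``a_{n-1}``.
* **Mutation**: ``theta = 4 * N_ref * mu`` per locus; mutations fall on the
  genealogy as a Poisson process with intensity ``theta`` per unit branch
  length, giving the standard ``E[S] = theta * a_{n-1}`` and unfolded spectrum
  ``E[xi_i] = theta / i``.
* **Migration**: the rate parameter ``m`` is expressed in units of
  ``2 * N_ref`` migrants per generation, so each lineage migrates backwards at
  rate ``2 * m`` per unit time.

Histories are piecewise constant.  Epochs are listed most-recent-first as
``(start_time, nu)``; for two-population models the first population's epoch
list also covers the ancestral population beyond the split time.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .genotype_io import MISSING, PopulationMap, VariantMatrix

__all__ = [
    "DemographyConfig",
    "Genealogy",
    "SimulationResult",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "expected_sfs_mc",
    "SFSEngine1D",
    "batch_class_lengths",
    "sample_site_classes",
    "harmonic",
    "to_ms_text",
]


def harmonic(k: int, power: int = 1) -> float:
    """``a_k = sum_{i=1..k} 1/i**power`` (Watterson's a_n, b_n constants)."""
    return sum(1.0 / i**power for i in range(1, k + 1))


@dataclasses.dataclass
class DemographyConfig:
    """One- or two-population piecewise-constant history.

    ``epochs[p]`` is the ordered ``(start_time, nu)`` list for population
    ``p`` (most recent first, first start must be 0).  ``migration`` is a
    list of ``(start_time, m12, m21)`` epochs where ``m12`` is the backward
    rate at which lineages currently in population 1 trace their ancestry to
    population 2; migration applies only before ``split_time``.  ``theta`` is
    per locus.
    """

    npops: int = 1
    epochs: tuple = ((0.0, 1.0),)
    split_time: float | None = None
    migration: tuple = ()
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.npops not in (1, 2):
            raise ValueError("npops must be 1 or 2")
        eps = self.epochs
        if self.npops == 1 and eps and not isinstance(eps[0][0], (tuple, list)):
            eps = (eps,)  # single flat epoch list for 1 population
        # canonicalize: merge consecutive epochs with identical size so that
        # redundant boundaries cannot perturb the arithmetic (parameter
        # settings implying the same rate trajectory give identical draws)
        canon = []
        for pop in eps:
            merged: list[tuple[float, float]] = []
            for start, nu in pop:
                if merged and merged[-1][1] == nu:
                    continue
                merged.append((float(start), float(nu)))
            canon.append(tuple(merged))
        self.epochs = tuple(canon)
        for pop in self.epochs:
            times = [t for t, _ in pop]
            if times[0] != 0.0:
                raise ValueError("first epoch must start at time 0")
            if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
                raise ValueError("epoch start times must be strictly increasing")
            if any(nu <= 0 for _, nu in pop):
                raise ValueError("nu must be > 0")
        if self.npops == 1:
            if self.split_time is not None or self.migration:
                raise ValueError("single-population configs have no split/migration")
        else:
            if self.split_time is None or self.split_time <= 0:
                raise ValueError("two-population configs need split_time > 0")
            if len(self.epochs) != 2:
                raise ValueError("two-population configs need two epoch lists")
            mig: list[tuple[float, float, float]] = []
            for start, m12, m21 in self.migration:
                if m12 < 0 or m21 < 0:
                    raise ValueError("migration rates must be >= 0")
                if mig and mig[-1][1:] == (m12, m21):
                    continue
                mig.append((float(start), float(m12), float(m21)))
            if mig == [(0.0, 0.0, 0.0)]:
                mig = []
            self.migration = tuple(mig)

    @staticmethod
    def constant(theta: float = 1.0) -> "DemographyConfig":
        return DemographyConfig(npops=1, epochs=((0.0, 1.0),), theta=theta)


def _epoch_value(epochs, t: float) -> float:
    v = epochs[0][1]
    for start, nu in epochs:
        if t >= start:
            v = nu
        else:
            break
    return v


def _mig_value(migration, t: float) -> tuple[float, float]:
    if not migration:
        return 0.0, 0.0
    m12 = m21 = 0.0
    for start, a, b in migration:
        if t >= start:
            m12, m21 = a, b
        else:
            break
    return m12, m21


def _next_change(cfg: DemographyConfig, t: float, merged: bool) -> float:
    """Earliest rate change-point strictly after t (inf if none)."""
    nxt = math.inf
    for start, _ in cfg.epochs[0]:
        if start > t:
            nxt = min(nxt, start)
            break
    if cfg.npops == 2 and not merged:
        for start, _ in cfg.epochs[1]:
            if start > t:
                nxt = min(nxt, start)
                break
        for start, _, _ in cfg.migration:
            if start > t:
                nxt = min(nxt, start)
                break
        if cfg.split_time > t:
            nxt = min(nxt, cfg.split_time)
    return nxt


@dataclasses.dataclass
class Genealogy:
    """Coalescent tree summarized as branches with leaf subtension.

    Each branch is ``(leaf_bitmask, n_leaves_pop1, n_leaves_pop2, length)``;
    the root is excluded, so every branch subtends a proper subset of leaves.
    """

    n_per_pop: tuple[int, ...]
    branches: list[tuple[int, int, int, float]]
    tmrca: float

    @property
    def total_length(self) -> float:
        return sum(b[3] for b in self.branches)

    def class_lengths(self) -> np.ndarray:
        """Branch length per frequency class.

        1 population: shape ``(n - 1,)`` for classes 1..n-1.
        2 populations: shape ``(n1 + 1, n2 + 1)`` indexed by (i, j) leaf
        counts (corners remain zero: no branch subtends all or no leaves).
        """
        if len(self.n_per_pop) == 1:
            n = self.n_per_pop[0]
            out = np.zeros(n - 1)
            for _, c1, _, length in self.branches:
                out[c1 - 1] += length
            return out
        n1, n2 = self.n_per_pop
        out = np.zeros((n1 + 1, n2 + 1))
        for _, c1, c2, length in self.branches:
            out[c1, c2] += length
        return out


def simulate_genealogy(
    cfg: DemographyConfig, n: int | tuple[int, ...], seed=None
) -> Genealogy:
    """Simulate one Kingman genealogy under the configured history.

    ``n`` is the number of sampled haploid lineages per population.  Waiting
    times use a single Exp(1) quantum per event integrated through all rate
    change-points (epoch boundaries, migration switches, the split), so
    parameter settings that imply identical rate trajectories yield identical
    genealogies under common random numbers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per_pop = (n,) if isinstance(n, int) else tuple(n)
    if cfg.npops != len(n_per_pop):
        raise ValueError("sample-size tuple does not match npops")
    if sum(n_per_pop) < 2:
        raise ValueError("need at least 2 lineages in total")

    # lineage state: bitmask over global leaf index, per-pop subtended counts,
    # current population, accrued branch length
    masks: list[int] = []
    c1s: list[int] = []
    c2s: list[int] = []
    pops: list[int] = []
    lengths: list[float] = []
    leaf = 0
    for p, np_ in enumerate(n_per_pop):
        for _ in range(np_):
            masks.append(1 << leaf)
            c1s.append(1 if p == 0 else 0)
            c2s.append(1 if p == 1 else 0)
            pops.append(p)
            lengths.append(0.0)
            leaf += 1

    branches: list[tuple[int, int, int, float]] = []
    t = 0.0
    last_t = 0.0
    merged = cfg.npops == 1
    split = cfg.split_time if cfg.npops == 2 else math.inf

    def rates(tt: float):
        k0 = sum(1 for p in pops if p == 0)
        k1 = len(pops) - k0
        nu0 = _epoch_value(cfg.epochs[0], tt)
        coal0 = k0 * (k0 - 1) / nu0
        if merged or cfg.npops == 1:
            return coal0, 0.0, 0.0, 0.0
        nu1 = _epoch_value(cfg.epochs[1], tt)
        m12, m21 = _mig_value(cfg.migration, tt)
        return coal0, k1 * (k1 - 1) / nu1, 2.0 * m12 * k0, 2.0 * m21 * k1

    while len(masks) > 1:
        quantum = rng.exponential()
        while True:
            r = rates(t)
            total = sum(r)
            nxt = _next_change(cfg, t, merged)
            if total > 0 and (nxt == math.inf or total * (nxt - t) >= quantum):
                t += quantum / total
                break
            if nxt == math.inf:
                raise RuntimeError("zero total rate with no upcoming change-point")
            quantum -= total * (nxt - t)
            t = nxt
            if not merged and t >= split:
                for i in range(len(pops)):
                    pops[i] = 0
                merged = True
        dt = t - last_t
        for i in range(len(lengths)):
            lengths[i] += dt
        last_t = t

        r = rates(t)
        u = rng.uniform(0.0, sum(r))
        if u < r[0] or u < r[0] + r[1]:
            pop = 0 if u < r[0] else 1
            idx = [i for i, p in enumerate(pops) if p == pop]
            k = len(idx)
            a = int(rng.integers(k))
            b = int(rng.integers(k - 1))
            if b >= a:
                b += 1
            ia, ib = idx[a], idx[b]
            branches.append((masks[ia], c1s[ia], c2s[ia], lengths[ia]))
            branches.append((masks[ib], c1s[ib], c2s[ib], lengths[ib]))
            masks[ia] |= masks[ib]
            c1s[ia] += c1s[ib]
            c2s[ia] += c2s[ib]
            lengths[ia] = 0.0
            for lst in (masks, c1s, c2s, pops, lengths):
                lst.pop(ib)
        else:
            pop = 0 if u < r[0] + r[1] + r[2] else 1
            idx = [i for i, p in enumerate(pops) if p == pop]
            i = idx[int(rng.integers(len(idx)))]
            pops[i] = 1 - pop

    return Genealogy(n_per_pop=n_per_pop, branches=branches, tmrca=t)


def drop_mutations(
    g: Genealogy,
    theta: float | None = None,
    fixed_s: int | None = None,
    seed=None,
) -> np.ndarray:
    """Place infinite-sites mutations on a genealogy.

    Returns a haplotype matrix of shape ``(n_leaves, S)`` over {0, 1}, one
    column per mutation.  ``S ~ Poisson(theta * total_length)`` (lengths in
    4N units; see the module conventions) or exactly ``fixed_s`` when
    conditioning on the number of segregating sites.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if (theta is None) == (fixed_s is None):
        raise ValueError("give exactly one of theta or fixed_s")
    total = g.total_length
    s = int(rng.poisson(theta * total)) if fixed_s is None else int(fixed_s)
    n_leaves = sum(g.n_per_pop)
    if s == 0:
        return np.empty((n_leaves, 0), dtype=np.int8)
    lens = np.array([b[3] for b in g.branches])
    which = rng.choice(len(lens), size=s, p=lens / lens.sum())
    haps = np.zeros((n_leaves, s), dtype=np.int8)
    for col, bi in enumerate(which):
        mask = g.branches[bi][0]
        for leaf in range(n_leaves):
            if mask >> leaf & 1:
                haps[leaf, col] = 1
    return haps


@dataclasses.dataclass
class SimulationResult:
    """Simulated dataset plus its generating truth record."""

    matrix: VariantMatrix
    popmap: PopulationMap
    haplotypes: list[np.ndarray]  # per-locus (n_haplotypes, S_locus)
    truth: dict


def simulate_dataset(
    cfg: DemographyConfig,
    n_samples: int | tuple[int, ...],
    n_loci: int,
    seed: int,
    missing_rate: float = 0.0,
    n_admixed: int = 0,
    admixed_q: float = 0.30,
    pop_labels: tuple[str, ...] | None = None,
) -> SimulationResult:
    """Simulate a RAD-like diploid dataset of independent loci.

    ``n_samples`` counts diploid individuals per population; each locus is an
    independent genealogy over ``2 * n_samples`` haplotypes with
    ``theta = cfg.theta`` mutations.  Haplotypes are paired into diploids at
    random (no selfing), giving Hardy-Weinberg genotypes.  Missing genotypes
    are injected i.i.d. at ``missing_rate``; ``n_admixed`` individuals (spread
    across populations) receive an off-population ancestry of ``admixed_q`` in
    the generated Q matrix, the rest are pure.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    dip = (n_samples,) if isinstance(n_samples, int) else tuple(n_samples)
    if len(dip) != cfg.npops:
        raise ValueError("n_samples tuple does not match npops")
    hap_per_pop = tuple(2 * d for d in dip)
    labels = pop_labels or tuple(f"pop{p + 1}" for p in range(cfg.npops))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_loci + 1)
    aux_rng = np.random.default_rng(children[-1])

    sample_ids: list[str] = []
    sample_pops: list[str] = []
    for p, d in enumerate(dip):
        for i in range(d):
            sample_ids.append(f"{labels[p]}_s{i}")
            sample_pops.append(labels[p])

    locus_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    cols: list[np.ndarray] = []
    haplotypes: list[np.ndarray] = []
    for ell in range(n_loci):
        rng = np.random.default_rng(children[ell])
        g = simulate_genealogy(cfg, hap_per_pop if cfg.npops == 2 else hap_per_pop[0],
                               seed=rng)
        haps = drop_mutations(g, theta=cfg.theta, seed=rng)
        # random within-population pairing of haplotypes into diploids
        order: list[int] = []
        off = 0
        for hp in hap_per_pop:
            order.extend(off + rng.permutation(hp))
            off += hp
        haps = haps[np.array(order, dtype=int)]
        haplotypes.append(haps)
        geno = (haps[0::2] + haps[1::2]).astype(np.int8)
        name = f"locus_{ell}"
        for s_idx in range(geno.shape[1]):
            locus_ids.append(name)
            positions.append((name, s_idx + 1))
            cols.append(geno[:, s_idx])
    geno_all = (
        np.stack(cols, axis=1) if cols else np.empty((len(sample_ids), 0), np.int8)
    )
    if missing_rate > 0 and geno_all.size:
        drop = aux_rng.random(geno_all.shape) < missing_rate
        geno_all = np.where(drop, np.int8(MISSING), geno_all)
    matrix = VariantMatrix(sample_ids, locus_ids, positions, geno_all)

    import pandas as pd

    q = np.zeros((len(sample_ids), len(labels)))
    admix_targets = set(range(0, len(sample_ids), max(1, len(sample_ids) // max(n_admixed, 1)))) if n_admixed else set()
    admix_targets = set(sorted(admix_targets)[:n_admixed])
    for i, pop in enumerate(sample_pops):
        pi = labels.index(pop)
        if i in admix_targets and len(labels) > 1:
            q[i, pi] = 1.0 - admixed_q
            other = (pi + 1) % len(labels)
            q[i, other] = admixed_q
        else:
            q[i, pi] = 1.0
    q_df = pd.DataFrame(q, index=sample_ids, columns=list(labels))
    popmap = PopulationMap(dict(zip(sample_ids, sample_pops)), q_df)

    truth = {
        "config": dataclasses.asdict(cfg),
        "seed": seed,
        "n_samples": dip,
        "n_loci": n_loci,
        "missing_rate": missing_rate,
        "n_admixed": n_admixed,
    }
    return SimulationResult(matrix, popmap, haplotypes, truth)


# ---------------------------------------------------------------------------
# Expected spectra by Monte Carlo with common random numbers
# ---------------------------------------------------------------------------


def _advance_times(
    t: np.ndarray, quantum: np.ndarray, kk1: float, starts: np.ndarray, nus: np.ndarray
) -> np.ndarray:
    """Waiting time to consume Exp(1) quanta at rate kk1/nu(t), vectorized.

    ``starts``/``nus`` describe the piecewise-constant size (last epoch
    extends to infinity).  Returns the elapsed time per replicate.
    """
    rem = quantum.astype(float).copy()
    cur = t.astype(float).copy()
    n_ep = len(starts)
    for e in range(n_ep):
        hi = starts[e + 1] if e + 1 < n_ep else math.inf
        lo = np.maximum(cur, starts[e])
        width = np.maximum(hi - lo, 0.0)
        rate = kk1 / nus[e]
        need = rem / rate
        exhausted = need <= width  # quantum ends inside this epoch
        step = np.where(exhausted, need, width)
        active = (rem > 0) & (width > 0)
        cur = np.where(active, lo + step, cur)
        # zero exactly on exhaustion: a floating-point residual would
        # otherwise advance time across the next epoch boundary for free
        rem = np.where(active, np.where(exhausted, 0.0, rem - step * rate), rem)
    return cur - t


class SFSEngine1D:
    """Deterministic Monte-Carlo expected-SFS engine for one population.

    For a single population the ranked tree shape is independent of the size
    history, so topologies and Exp(1) waiting-time quanta are drawn once per
    ``(n, reps, seed_base)`` (replicate ``r`` always uses ``seed_base + r``)
    and any piecewise-constant history maps to class branch lengths by pure
    time rescaling.  The objective surface seen by the optimizer is therefore
    an exact function of the parameters (common random numbers), and
    histories implying identical rate trajectories (e.g., a two-epoch model
    with ``nu = 1``) give bit-identical spectra.
    """

    def __init__(self, n: int, reps: int, seed_base: int):
        if n < 2:
            raise ValueError("n must be >= 2")
        self.n = n
        self.reps = reps
        self.seed_base = seed_base
        levels = n - 1
        quanta = np.empty((reps, levels))
        counts = np.zeros((reps, levels, levels), dtype=np.float32)
        sub = np.empty(n, dtype=np.int64)
        for r in range(reps):
            rng = np.random.default_rng(seed_base + r)
            quanta[r] = rng.exponential(size=levels)
            sub[:] = 1
            for lvl, k in enumerate(range(n, 1, -1)):
                row = counts[r, lvl]
                for i in range(k):
                    row[sub[i] - 1] += 1.0
                a = int(rng.integers(k))
                b = int(rng.integers(k - 1))
                if b >= a:
                    b += 1
                sub[a] += sub[b]
                sub[b] = sub[k - 1]
        self._quanta = quanta
        self._counts = counts
        self._counts_flat = counts.reshape(reps * levels, levels)
        self._kk1 = np.array([k * (k - 1) for k in range(n, 1, -1)], dtype=float)
        # cumulative intensity targets sum_{j<=k} E_j / (j (j-1)) are
        # parameter-independent; precompute once
        self._G = np.cumsum(quanta / self._kk1, axis=1).astype(np.float32)

    def expected_sfs(self, epochs) -> np.ndarray:
        """Unfolded expected spectrum per unit theta (classes 1..n-1)."""
        merged: list[tuple[float, float]] = []
        for start, nu in epochs:
            if merged and merged[-1][1] == nu:
                continue
            merged.append((float(start), float(nu)))
        starts = np.array([s for s, _ in merged])
        nus = np.array([nu for _, nu in merged])
        # Closed-form time rescaling: with Lam(t) = int_0^t ds / nu(s), the
        # coalescence times satisfy Lam(t_k) = sum_{j<=k} E_j / (j (j-1)), so
        # each level time is the piecewise-linear inverse of Lam evaluated at
        # the cumulative quanta — fully vectorized over replicates and levels.
        G = self._G
        if len(starts) == 1:
            t = G * np.float32(nus[0])
        else:
            lam = np.concatenate(([0.0], np.cumsum(np.diff(starts) / nus[:-1])))
            t = (G * np.float32(nus[0])).astype(np.float32)
            for e in range(1, len(starts)):
                past = G >= np.float32(lam[e])
                t = np.where(
                    past,
                    np.float32(starts[e]) + (G - np.float32(lam[e])) * np.float32(nus[e]),
                    t,
                )
        dt = np.empty_like(t)
        dt[:, 0] = t[:, 0]
        np.subtract(t[:, 1:], t[:, :-1], out=dt[:, 1:])
        # float32 contraction against the topology tensor; Monte-Carlo error
        # dwarfs the single-precision rounding
        out = dt.reshape(-1) @ self._counts_flat
        return out.astype(float) / self.reps


_ENGINE_CACHE: dict[tuple[int, int, int], SFSEngine1D] = {}


def get_engine_1d(n: int, reps: int, seed_base: int) -> SFSEngine1D:
    key = (n, reps, seed_base)
    if key not in _ENGINE_CACHE:
        _ENGINE_CACHE[key] = SFSEngine1D(n, reps, seed_base)
    return _ENGINE_CACHE[key]


def expected_sfs_mc(
    cfg: DemographyConfig,
    n_alleles: int | tuple[int, ...],
    reps: int,
    seed_base: int,
) -> np.ndarray:
    """Monte-Carlo expected SFS per unit theta under common random numbers.

    Replicate ``r`` always uses seed ``seed_base + r`` regardless of the
    parameter values, so repeated calls with the same configuration are
    bit-identical and the spectrum varies smoothly with parameters.  Output
    times theta = expected counts for one locus set.  1 population: unfolded
    classes 1..n-1; 2 populations: array of shape ``(n1+1, n2+1)``.
    """
    if cfg.npops == 1:
        n = n_alleles if isinstance(n_alleles, int) else n_alleles[0]
        return get_engine_1d(n, reps, seed_base).expected_sfs(cfg.epochs[0])
    n1, n2 = n_alleles
    acc = np.zeros((n1 + 1, n2 + 1))
    for r in range(reps):
        g = simulate_genealogy(cfg, (n1, n2), seed=np.random.default_rng(seed_base + r))
        acc += g.class_lengths()
    return acc / reps


# ---------------------------------------------------------------------------
# Vectorized constant-size batch engine (neutrality nulls)
# ---------------------------------------------------------------------------


def batch_class_lengths(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Constant-size Kingman class branch lengths for many replicates at once.

    Returns shape ``(reps, n-1)``: branch length subtending i leaves (class
    i-1) per replicate, in 4N units.  Same model as
    :func:`simulate_genealogy` with a constant history, vectorized across
    replicates for the simulation nulls.
    """
    sub = np.ones((reps, n), dtype=np.int64)
    out = np.zeros((reps, n - 1))
    rows = np.arange(reps)
    for k in range(n, 1, -1):
        t = rng.exponential(1.0 / (k * (k - 1)), size=reps)
        np.add.at(out, (rows[:, None], sub[:, :k] - 1), t[:, None])
        a = rng.integers(0, k, size=reps)
        b = rng.integers(0, k - 1, size=reps)
        b = np.where(b >= a, b + 1, b)
        sub[rows, a] += sub[rows, b]
        sub[rows, b] = sub[rows, k - 1]
    return out


def sample_site_classes(
    class_lengths: np.ndarray,
    rng: np.random.Generator,
    fixed_s: int | None = None,
    theta: float | None = None,
) -> np.ndarray:
    """Draw per-class segregating-site counts for each replicate.

    Fixed-S mode places exactly ``fixed_s`` mutations multinomially with
    probabilities proportional to class branch lengths (a binomial cascade,
    vectorized over replicates); theta mode draws independent Poisson counts
    with mean ``theta * length``.
    """
    if (fixed_s is None) == (theta is None):
        raise ValueError("give exactly one of fixed_s or theta")
    reps, classes = class_lengths.shape
    if theta is not None:
        return rng.poisson(theta * class_lengths)
    totals = class_lengths.sum(axis=1)
    remaining = np.full(reps, fixed_s, dtype=np.int64)
    rem_mass = totals.copy()
    counts = np.zeros((reps, classes), dtype=np.int64)
    for c in range(classes - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rem_mass > 0, class_lengths[:, c] / rem_mass, 0.0)
        p = np.clip(p, 0.0, 1.0)
        counts[:, c] = rng.binomial(remaining, p)
        remaining -= counts[:, c]
        rem_mass -= class_lengths[:, c]
    counts[:, -1] = remaining
    return counts


def to_ms_text(result: SimulationResult) -> str:
    """Render simulated haplotypes in ms-style text (one block per locus)."""
    blocks = []
    for haps in result.haplotypes:
        s = haps.shape[1]
        block = ["//", f"segsites: {s}"]
        if s:
            pos = " ".join(f"{(i + 1) / (s + 1):.5f}" for i in range(s))
            block.append(f"positions: {pos}")
            block.extend("".join(str(int(v)) for v in row) for row in haps)
        blocks.append("\n".join(block))
    return "\n".join(["popdemog-sim"] + blocks) + "\n"
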