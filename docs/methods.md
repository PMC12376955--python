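# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `popdemog`.  It is the reference for what the package
computes and why; nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scaling conventions

All coalescent quantities use one convention, pinned in
`popdemog/coalsim.py`:

* time in units of **4 N_ref generations**;
* population sizes **ν relative to N_ref** (pair coalescence rate 2/ν, so
  E[TMRCA] of a sample of two in a constant population is 0.5, i.e. 2 N_ref
  generations, and the expected total branch length for n lineages is the
  harmonic number a_{n−1});
* mutation **θ = 4 N_ref µ per locus**, dropped as a Poisson process with
  intensity θ per unit branch length, giving E[S] = θ·a_{n−1} and the
  neutral unfolded spectrum E[ξ_i] = θ/i;
* migration **m in units of 2 N_ref migrants per generation** (backward
  per-lineage migration rate 2m per time unit).  For asymmetric rates,
  m12 is the backward rate at which lineages currently in population 1
  trace their ancestry to population 2.

Epoch lists are most-recent-first `(start_time, ν)` pairs; in
two-population configurations the first population's list extends past the
split time and describes the ancestral population (fixed at ν = 1 in all
menu models, which anchors the θ scale).

## Data model and filters

Genotypes are diploid, unphased, biallelic counts of the alternate allele
(0/1/2, −1 missing), grouped into RAD loci parsed from the VCF ID column
(`locus:column` or `locus_column`; CHROM as fallback).  The filter order is
fixed: sites called in fewer than 70% of individuals are removed first,
then individuals missing more than 50% of the remaining loci.  A locus
counts as missing for a sample only when all of its sites are uncalled,
matching the allele-dropout mechanism by which RAD loci disappear
wholesale; with one SNP per locus this coincides with site-level
missingness.  The admixture filter removes samples whose summed Q-matrix
ancestry outside their assigned population strictly exceeds 0.25 — ties at
the threshold are retained, reading "greater than 25%" literally.
Population subsetting never drops columns; sites monomorphic within the
subset are flagged so spectra and statistics can account for them
explicitly.

## Summary statistics

Per site, π = 2j(n−j)/(n(n−1)) with j the alternate-allele count among the
n observed alleles, summed within each locus; genome-wide values average
over loci.  Because the study design fixes the locus length (39 bp reads
after trimming), the per-base-pair π divides the per-locus mean by 39; the
per-variant-site mean is reported alongside, since which denominator a
given published value used is often ambiguous.

Tajima's D uses the 1989 constants; Fu & Li's D* and F* are the
intraspecific (no-outgroup) starred forms with the corrected variance
constants used by the mainstream C/R implementations, with η_s the number
of sites whose minor allele occurs exactly once.  The neutrality statistics
are computed on the concatenated per-population matrix restricted to
fully-called sites, so a single sample size applies; the per-locus tables
use all sites through observed allele counts.  Correctness rests on two
independent oracles: brute-force reimplementations (pairwise Hamming
counting, retyped constants) agree to 1e−10 on hundreds of random matrices,
and neutral-simulation means are ≈ 0.  (The exact neutral mean of these
statistics is slightly negative — about −0.08 for D at n = 20 — a known
property of the estimators, not an implementation artifact.)

Weir & Cockerham's (1984) θ̂ is computed per site from the variance
components a, b, c for two populations; both the mean of per-site ratios
(the common per-locus averaging) and the ratio of sums are reported, and
negative estimates are kept as computed.  Sites monomorphic across both
populations, or with fewer than two called individuals in either, are
excluded from the averages.

## Spectra and projection

Spectra are built per site: each site is projected independently from its
observed allele count n to the target m by the hypergeometric rule
C(i,k)C(n−i,m−k)/C(n,m), so sites with missing genotypes contribute
whenever they retain at least m alleles; sites observing fewer are
dropped.  The projection search scans every target from the minimum (10
alleles by default — populations that cannot reach it are reported "not
runnable") to the maximum observed, jointly over the grid in 2D, and keeps
the target maximizing segregating sites in the folded spectrum, breaking
ties toward the larger target.  Folding uses minor-allele orientation:
entry i and n−i are summed, the upper half is masked, and middle classes
(2(i+j) = n_total) are halved after summation so their mass is counted
once.  Corners are always masked for inference: without invariant-site
totals the monomorphic classes carry no information.  Projection is exact —
it matches explicit enumeration of all C(n,m) subsamples — linear, and
composes (projecting in two steps equals one step), which the tests assert.

## Expected spectra: Monte Carlo with common random numbers

Expected spectra per unit θ are branch-length expectations computed by
coalescent Monte Carlo rather than by a diffusion PDE solver: the targets
are identical (E[ξ_i] = θ × expected branch length subtending i leaves),
and common random numbers (replicate r always uses seed_base + r) make the
likelihood surface a deterministic function of the parameters, which is
what a simplex optimizer needs.

For one population, the ranked tree topology is independent of the size
history, so the engine pre-draws topologies and Exp(1) waiting-time quanta
once per (n, reps, seed) and maps any piecewise-constant history to class
branch lengths through the inverse of the cumulative coalescent intensity
Λ(t) = ∫dt/ν(t) — a closed-form, fully vectorized transformation.  Two
consequences are tested exactly: the same engine call is bit-identical, and
histories implying the same rate trajectory (a two-epoch model with ν = 1;
secondary contact with m = 0 versus clean isolation) give bit-identical
spectra, because epoch lists are canonicalized before any arithmetic.  The
two-population engine is a per-replicate event-loop simulator that
integrates one Exp(1) quantum per event through all rate change-points
(epoch boundaries, migration switches, the split), preserving the same CRN
property.  The engine agrees with msprime (used in tests as an independent
oracle only) on constant, expansion, and bottleneck histories.

Default engine replicates are 50,000 (1D) and 10,000 (2D).  The test suite
and acceptance experiments use 2,000–10,000 replicates, which keeps a full
three-round 1D fit near twenty seconds while leaving Monte-Carlo error well
below the data's sampling noise at the simulated θ.

## Likelihood, optimization, model ranking

The fit criterion is the Poisson composite likelihood: data entry d with
model entry m (per unit θ) contributes d·ln(θ̂m) − θ̂m − lnΓ(d+1), with
θ̂ = Σd/Σm profiled analytically over the jointly unmasked entries.  Model
entries are floored at 1e−12 so finite-replicate zeros cannot generate
infinite penalties.  The θ̂ relation is exact and tested: scaling the data
by c scales θ̂ by c.

Optimization runs in log-parameter space (parameters are positive and
perturbed multiplicatively): round 1 starts 50 replicates from three-fold
perturbations (each parameter × 2^U(−3,3)) of the model defaults, round 2
starts 50 from two-fold perturbations of the round-1 best, round 3 starts
100 from one-fold perturbations of the round-2 best; every replicate is a
Nelder–Mead run capped at 20 simplex iterations, with out-of-bounds
proposals penalized.  The iteration cap is read as simplex iterations per
replicate; it is logged per replicate so users can raise it.  Only the
single best replicate is carried between rounds (a top-k variant would be a
small extension; the single-best reading is the default).  Default bounds
are ν ∈ [0.01, 100], T ∈ [0.001, 10], m ∈ [0.001, 20], with the lower
migration bound kept strictly positive because the search runs in log
space; m = 0 remains available to model builders directly (it is how the
nesting identities are tested).

The parameter-free standard neutral model skips optimization: θ̂ and log L
are evaluated directly and AIC = −2 log L.  Models are ranked by
AIC = 2k − 2 log L with ΔAIC to the best; fits are tagged with a hash of
the data spectrum so fits of different data cannot be ranked together.

2D model menu: divergence without migration, with symmetric or asymmetric
migration, ancient migration (gene flow only for the first T1 after the
split), secondary contact (gene flow only in the most recent T2), and
size-change variants of the isolation and symmetric-migration models.
This follows the standard published two-population model families; the
pipeline exposes the list as configuration rather than hard-coding a
subset.

## Neutrality test

The null for an observed statistic is R = 1000 constant-size coalescent
simulations matched to the data, by default conditioned on the observed
number of segregating sites (fixed-S), which removes dependence on θ
estimation error; a θ-matched mode (θ set to Watterson's estimate, S
Poisson) is available and recorded in the output.  Ranks count ties as
as-extreme (conservative); both tails are reported and the headline flag
uses the tail matching the observed deviation, with thresholds
⌊0.05R⌋ / ⌊0.10R⌋ — 50 and 100 of 1000.  No two-tailed correction is
applied; the rule is per-tail by construction.

Calibration is verified at scale: applying the full matched-null test to
500 datasets simulated under the null rejects in the lower tail at a rate
statistically consistent with 5% (and likewise in the upper tail).  One
structural caveat: the null simulates a single genealogy carrying all S
sites, while an observed genome-wide statistic averages over many
independent loci and therefore has smaller variance than the null.  For
multi-locus data the test is conservative — real but moderate departures
(D around −1.3 at n = 20) often rank near but not past the 5% threshold,
as the examples show.

## Synthetic data generator

`simulate_dataset` emulates the structure of a RAD-seq SNP matrix:
independent loci (one genealogy each, no within-locus recombination),
infinite-sites mutations at θ per locus, haplotypes paired at random into
diploids (Hardy–Weinberg, no selfing), i.i.d. missing genotypes at a
configurable rate, and an optional Q matrix in which a chosen number of
individuals carry 30% off-population ancestry (just past the 25% removal
threshold).  Defaults in tests follow the regimes the method targets:
tens of diploids, hundreds of loci, θ near 1 per locus, missingness 5–25%.

What it deliberately does not emulate: genotyping error and allele-dropout
bias (missingness is independent of genotype), linked selection,
within-locus linkage beyond complete linkage, finite-sites recurrent
mutation, and non-equilibrium spatial structure.  Passing tests therefore
demonstrate correctness of the estimators and inference machinery under
the generating model, not robustness to those real-data artifacts.

## Terrain metric

Per cell, the elevation range (max − min) over a centered odd window
(default 9 × 9), transformed as 10·log10(range + 1).  The log base and the
+1 offset are a package choice (flat terrain maps exactly to 0 and the
scale reads like decibels); they are recorded here and in the output
metadata.  Edges use the truncated window — implemented via edge-replicated
max/min filters, which is exactly the truncated-window rule for order
statistics — and nodata cells are excluded, propagating only when a window
contains no valid cell.  The implementation matches a brute-force double
loop exactly and is monotone in window size.

## Determinism

Every stage takes an explicit seed; the pipeline derives per-stage seeds
from one master seed via `SeedSequence` and logs them in the report.  Two
runs with the same configuration produce identical numeric outputs, which
the test suite asserts end to end.

## Known limitations

* Composite-likelihood AIC ignores linkage between sites; the one-SNP-per-
  locus thinning is the standard mitigation and is applied before fitting.
* No uncertainty quantification on fitted parameters (no bootstrap /
  Godambe adjustment) — model ranking is by raw AIC, as in the workflow
  this package implements.
* The 2D engine is event-loop Python; at the default 10,000 replicates a
  full 2D fit is expensive (hours-scale), so exploratory 2D work should
  lower the replicate count, at the cost of a noisier expectation.
* No recombination within loci, no selection, no three-population models.
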