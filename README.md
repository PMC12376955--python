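# popdemog

SFS-based demographic inference for RAD-seq population data.

`popdemog` is a reusable, tested implementation of a standard
reduced-representation population-genomics workflow, built for studies that
ask how populations — for example rainforest-restricted amphibians sampled
across a fragmented landscape — expanded, contracted, or exchanged migrants
through past climate cycles.  It takes a VCF of biallelic SNPs grouped into
RAD loci plus a sample-to-population map and produces:

1. **Filtering** — site presence (≥ 70% of individuals by default),
   per-sample missingness (> 50% of loci removed), one random SNP per RAD
   locus against linkage, and removal of admixed individuals (> 25%
   off-population ancestry in a STRUCTURE-style Q matrix).
2. **Summary statistics** — per-locus segregating sites *S*, nucleotide
   diversity π, Watterson's θ_W (averaged genome-wide), Weir–Cockerham
   F_ST, and the neutrality statistics Tajima's *D* and Fu & Li's *D*\*,
   *F*\* on the concatenated per-population matrix.
3. **Simulation-based neutrality tests** — the observed statistic is ranked
   against 1000 constant-size coalescent simulations matched to the
   observed *S*; landing among the 50 (100) most extreme values in a tail
   flags *p* < 0.05 (*p* < 0.1).
4. **SFS demographic modelling** — folded site-frequency spectra with
   per-site hypergeometric projection (the projection maximizing the number
   of segregating sites is chosen, minimum 10 alleles), expected spectra
   from a coalescent Monte-Carlo engine with common random numbers, Poisson
   composite likelihood with analytically profiled θ, a three-round
   perturbed multi-start Nelder–Mead protocol (50 / 50 / 100 replicates at
   3- / 2- / 1-fold perturbation, 20 simplex iterations each), and AIC
   model ranking over 1D (neutral, two-epoch, three-epoch) and 2D
   (divergence ± gene flow, ancient migration, secondary contact, ± size
   change) model menus.
5. **Synthetic data** — a coalescent simulator (piecewise-constant sizes,
   two-population splits, time-varying migration, infinite-sites mutations,
   diploid genotypes, missingness, Q matrices) so every stage can be tested
   against known truth without any real data.
6. **Terrain** — the topographic-variance raster metric
   `10 · log10(max − min + 1)` in a 9 × 9 moving window, for relating
   demographic signals to landscape complexity.

## The model in brief

Time is measured in units of 4 *N*_ref generations, sizes ν relative to
*N*_ref, θ = 4 *N*_ref µ per locus, and migration *m* in units of 2 *N*_ref
migrants per generation (see `popdemog.coalsim` for the full conventions).
SFS entry *d_i* of the data is treated as Poisson with mean θ · *m_i*(p)
where *m_i* is the model spectrum per unit θ; θ is profiled analytically
(θ̂ = Σd / Σm) and models are ranked by AIC = 2k − 2 log L.  Expected
spectra are computed by coalescent Monte Carlo with common random numbers,
which makes the likelihood surface a deterministic, smooth function of the
parameters; for one population the engine factorizes tree topology from
time rescaling, so a fit evaluation costs a few milliseconds.

## Worked example

`examples/05_fit_demography.py` simulates 1000 RAD loci under a five-fold
expansion (ν = 5 at T = 0.5, total θ = 500, n = 20 alleles) and fits the
neutral and two-epoch models:

```
data: 4032 segregating sites, n = 20 alleles
two_epoch: nu = 5.37 (truth 5.0), T = 0.61 (truth 0.5), theta = 456
    model  k  log_likelihood        aic  delta_aic  best
two_epoch  2      -43.969385  91.938770   0.000000  True
      snm  0     -467.060293 934.120586 842.181817 False
```

The fitted ν is within 8% of the truth and the two-epoch model beats the
neutral model by ΔAIC ≈ 842 — a decisive preference for the expansion
history that generated the data.  The other scripts in `examples/` walk
through simulation, summary statistics, the neutrality test, the
projection search, the terrain metric, and the full pipeline; each prints
the numbers it computes and what they mean.

A thin CLI mirrors the stages (`popdemog simulate | sumstats | neutrality |
sfs | fit | terrain | run-all`); `run-all` executes a YAML-configured
pipeline and writes per-stage TSV/JSON plus a run report with an
expansion/contraction call per population.

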