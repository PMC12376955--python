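"""Simulate a RAD-seq-like dataset under a known demographic history.

A ten-fold population expansion 0.1 coalescent time units ago (backwards:
the population shrinks to nu = 0.1 of its present size), 10 diploids, 200
independent loci with theta = 0.8 per locus, 5% missing genotypes.  The
truth record ties every number downstream back to the generating model.
"""

from popdemog import DemographyConfig, simulate_dataset, write_vcf
from popdemog.genotype_io import write_population_map

cfg = DemographyConfig(npops=1, epochs=((0.0, 1.0), (0.1, 0.1)), theta=0.8)
result = simulate_dataset(cfg, n_samples=10, n_loci=200, seed=42,
                          missing_rate=0.05)

m = result.matrix
print(f"samples: {m.n_samples}, loci: {len(m.loci)}, SNPs: {m.n_sites}")
print(f"missing genotype fraction: {(m.genotypes == -1).mean():.3f}")
print(f"truth: {result.truth['config']['epochs']}")

write_vcf(m, "expansion.vcf")
write_population_map(result.popmap, "expansion.popmap.tsv")
print("wrote expansion.vcf + expansion.popmap.tsv")
# The epoch list reads most-recent-first: size 1.0 now, size 0.1 before
# t = 0.1 — i.e., a strong recent expansion, which should leave an excess
# of rare variants (negative Tajima's D) in the next example.
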