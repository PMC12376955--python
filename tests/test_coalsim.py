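import numpy as np
import pytest

from popdemog import coalsim
from popdemog.coalsim import (
    DemographyConfig,
    SFSEngine1D,
    batch_class_lengths,
    drop_mutations,
    expected_sfs_mc,
    harmonic,
    sample_site_classes,
    simulate_dataset,
    simulate_genealogy,
)
from popdemog.genotype_io import MISSING, filter_missingness
from popdemog.sumstats import tajimas_d_from_classes


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self):
        # E[TMRCA] for n=2 is 2*N_ref generations: 1.0 in 2N units,
        # 0.5 in the module's 4N units
        cfg = DemographyConfig.constant()
        rng = np.random.default_rng(0)
        t = np.array([simulate_genealogy(cfg, 2, seed=rng).tmrca
                      for _ in range(20_000)])
        se = t.std() / np.sqrt(len(t))
        assert abs(2 * t.mean() - 1.0) < 3 * 2 * se

    def test_total_branch_length_expectation(self):
        # E[L] = 2 * a_9 in 2N units = a_9 in 4N units for n=10
        cfg = DemographyConfig.constant()
        rng = np.random.default_rng(1)
        tot = np.array([simulate_genealogy(cfg, 10, seed=rng).total_length
                        for _ in range(20_000)])
        se = tot.std() / np.sqrt(len(tot))
        assert abs(tot.mean() - harmonic(9)) < 3 * se

    def test_deep_split_without_migration_shares_no_polymorphism(self):
        cfg = DemographyConfig(
            npops=2, epochs=(((0.0, 1.0),), ((0.0, 1.0),)), split_time=50.0
        )
        rng = np.random.default_rng(2)
        for _ in range(40):
            g = simulate_genealogy(cfg, (6, 6), seed=rng)
            haps = drop_mutations(g, theta=2.0, seed=rng)
            a, b = haps[:6], haps[6:]
            for j in range(haps.shape[1]):
                # every variant arising more recently than the (ancient)
                # split segregates in only one population
                poly_a = 0 < a[:, j].sum() < 6
                poly_b = 0 < b[:, j].sum() < 6
                assert not (poly_a and poly_b)

    def test_migration_restores_shared_polymorphism(self):
        cfg = DemographyConfig(
            npops=2, epochs=(((0.0, 1.0),), ((0.0, 1.0),)), split_time=50.0,
            migration=((0.0, 5.0, 5.0),),
        )
        rng = np.random.default_rng(3)
        shared = 0
        for _ in range(40):
            g = simulate_genealogy(cfg, (6, 6), seed=rng)
            haps = drop_mutations(g, theta=2.0, seed=rng)
            a, b = haps[:6], haps[6:]
            for j in range(haps.shape[1]):
                if 0 < a[:, j].sum() < 6 and 0 < b[:, j].sum() < 6:
                    shared += 1
        assert shared > 0


class TestMutations:
    def test_fixed_s_conditioning(self):
        cfg = DemographyConfig.constant()
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = simulate_genealogy(cfg, 8, seed=rng)
            haps = drop_mutations(g, fixed_s=40, seed=rng)
            assert haps.shape == (8, 40)
            # infinite sites: every mutation is polymorphic
            sums = haps.sum(axis=0)
            assert np.all((sums > 0) & (sums < 8))

    def test_segregating_sites_expectation(self):
        # E[S] = theta * a_{n-1} = 5 * a_9 ~ 14.14
        cfg = DemographyConfig.constant(theta=5.0)
        rng = np.random.default_rng(5)
        s = np.array([
            drop_mutations(simulate_genealogy(cfg, 10, seed=rng),
                           theta=5.0, seed=rng).shape[1]
            for _ in range(20_000)
        ])
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - 5 * harmonic(9)) < 3 * se

    def test_unfolded_spectrum_expectation(self):
        # E[xi_i] = theta / i, via the vectorized batch engine
        rng = np.random.default_rng(6)
        lengths = batch_class_lengths(10, 20_000, rng)
        counts = sample_site_classes(lengths, rng, theta=5.0)
        mean = counts.mean(axis=0)
        se = counts.std(axis=0) / np.sqrt(counts.shape[0])
        expected = 5.0 / np.arange(1, 10)
        assert np.all(np.abs(mean - expected) < 3 * se)


class TestSimulateDataset:
    def test_no_missingness_filter_is_identity(self):
        cfg = DemographyConfig.constant(theta=1.0)
        res = simulate_dataset(cfg, n_samples=6, n_loci=50, seed=7,
                               missing_rate=0.0)
        assert filter_missingness(res.matrix, 0.7, 0.5) == res.matrix

    def test_expansion_contraction_tajima_direction(self):
        rng_seed = 8
        means = {}
        for name, nu_anc in (("expansion", 0.1), ("contraction", 10.0)):
            cfg = DemographyConfig(
                npops=1, epochs=((0.0, 1.0), (0.1, nu_anc)), theta=0.6
            )
            vals = []
            for rep in range(30):
                res = simulate_dataset(cfg, n_samples=10, n_loci=80,
                                       seed=rng_seed + rep)
                g = res.matrix.genotypes
                alt = g.sum(axis=0)
                counts = np.bincount(alt[(alt > 0) & (alt < 20)], minlength=20)[1:20]
                vals.append(tajimas_d_from_classes(counts, 20)[0])
            means[name] = np.nanmean(vals)
        assert means["expansion"] < 0 < means["contraction"]

    def test_reproducible_from_truth_record(self):
        cfg = DemographyConfig(npops=1, epochs=((0.0, 2.0), (0.4, 1.0)),
                               theta=1.5)
        a = simulate_dataset(cfg, 5, 30, seed=11, missing_rate=0.1)
        b = simulate_dataset(cfg, 5, 30, seed=11, missing_rate=0.1)
        assert a.matrix == b.matrix
        assert a.truth == b.truth

    def test_admixture_q_matrix_generated(self):
        cfg = DemographyConfig(
            npops=2, epochs=(((0.0, 1.0),), ((0.0, 1.0),)), split_time=0.5,
            theta=1.0,
        )
        res = simulate_dataset(cfg, (4, 4), 20, seed=12, n_admixed=2)
        q = res.popmap.q_matrix
        off = 1.0 - np.array([q.loc[s, res.popmap.assignments[s]]
                              for s in q.index])
        assert (off > 0.25).sum() == 2

    def test_ms_text_output_shape(self):
        cfg = DemographyConfig.constant(theta=1.0)
        res = simulate_dataset(cfg, 3, 5, seed=13)
        text = coalsim.to_ms_text(res)
        assert text.count("segsites:") == 5


class TestExpectedSfs:
    def test_constant_size_closed_form(self):
        xi = expected_sfs_mc(DemographyConfig.constant(), 10, reps=30_000,
                             seed_base=100)
        expected = 1.0 / np.arange(1, 10)
        assert np.max(np.abs(xi - expected) / expected) < 0.03

    def test_crn_determinism_and_parameter_identity(self):
        cfg2 = DemographyConfig(npops=1, epochs=((0.0, 1.0), (0.3, 1.0)))
        a = expected_sfs_mc(cfg2, 12, reps=2000, seed_base=5)
        b = expected_sfs_mc(DemographyConfig.constant(), 12, reps=2000,
                            seed_base=5)
        np.testing.assert_array_equal(a, b)
        c = expected_sfs_mc(cfg2, 12, reps=2000, seed_base=5)
        np.testing.assert_array_equal(a, c)

    def test_engine_matches_general_simulator(self):
        # the factorized 1D engine and the event-loop simulator implement the
        # same process: compare Monte-Carlo means for a bottleneck history
        epochs = ((0.0, 0.2), (0.3, 2.0), (1.0, 1.0))
        eng = SFSEngine1D(8, 40_000, 200)
        xi_eng = eng.expected_sfs(epochs)
        cfg = DemographyConfig(npops=1, epochs=epochs)
        acc = np.zeros(7)
        reps = 20_000
        rng = np.random.default_rng(3000)
        for r in range(reps):
            acc += simulate_genealogy(cfg, 8, seed=rng).class_lengths()
        xi_gen = acc / reps
        assert np.max(np.abs(xi_eng - xi_gen) / xi_gen) < 0.1

    def test_split_fst_increases_with_divergence_time(self):
        # deeper splits accumulate more between-population branch length
        fst_proxy = []
        for t_split in (0.05, 0.4, 2.0):
            cfg = DemographyConfig(
                npops=2, epochs=(((0.0, 1.0),), ((0.0, 1.0),)),
                split_time=t_split,
            )
            sfs = expected_sfs_mc(cfg, (6, 6), reps=400, seed_base=50)
            # private fixed classes grow with divergence
            private = sfs[6, 0] + sfs[0, 6]
            fst_proxy.append(private / sfs.sum())
        assert fst_proxy[0] < fst_proxy[1] < fst_proxy[2]

    def test_exchangeability_of_batch_engine(self):
        # class-length distribution must not depend on leaf labels: compare
        # two seeds' means (same distribution) rather than labelings
        rng = np.random.default_rng(14)
        a = batch_class_lengths(8, 8000, rng).mean(axis=0)
        b = batch_class_lengths(8, 8000, np.random.default_rng(15)).mean(axis=0)
        assert np.max(np.abs(a - b) / b) < 0.15
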