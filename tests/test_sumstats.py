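import numpy as np
import pytest

import oracles
from conftest import make_matrix, random_matrix
from popdemog import coalsim
from popdemog.genotype_io import MISSING, PopulationMap
from popdemog.sumstats import (
    fu_li_dstar_fstar,
    fu_li_from_classes,
    nucleotide_diversity,
    per_locus_table,
    summarize_population,
    tajimas_d,
    tajimas_d_from_classes,
    watterson_theta,
    wc_fst,
)


class TestPi:
    def test_single_pair_differing_at_three_sites(self):
        # one diploid made of two haplotypes differing at 3 of a locus's sites
        m = make_matrix([[1, 1, 1, 0]], locus_ids=["L"] * 4)
        table = per_locus_table(m)
        assert table.loc["L", "pi"] == pytest.approx(3.0)

    def test_monomorphic_locus_zero(self):
        m = make_matrix([[0, 0], [0, 0]], locus_ids=["L", "L"])
        assert per_locus_table(m).loc["L", "pi"] == 0.0

    def test_matches_pair_counting_oracle_with_missing_data(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            m = random_matrix(rng, int(rng.integers(2, 8)),
                              int(rng.integers(2, 20)), missing_rate=0.2)
            assert per_locus_table(m)["pi"].sum() == pytest.approx(
                oracles.pi_total(m.genotypes), abs=1e-10
            )

    def test_neutral_simulation_mean_equals_theta(self):
        # E[pi] = theta per locus under neutrality
        cfg = coalsim.DemographyConfig.constant(theta=5.0)
        res = coalsim.simulate_dataset(cfg, n_samples=8, n_loci=1200, seed=99)
        table = per_locus_table(res.matrix)
        se = table["pi"].std() / np.sqrt(len(table))
        assert abs(table["pi"].mean() - 5.0) < 3 * se


class TestWatterson:
    @pytest.mark.parametrize(
        "s,n,expected",
        [(7, 2, 7.0), (10, 5, 4.8), (0, 9, 0.0)],
    )
    def test_values(self, s, n, expected):
        assert watterson_theta(s, n) == pytest.approx(expected)


class TestTajimasD:
    def test_zero_when_pi_equals_s_over_a1(self):
        n, s = 10, 12
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_d(s / a1, s, n) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_for_no_segregating_sites(self):
        assert tajimas_d(0.0, 0, 10) is None

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            m = random_matrix(rng, int(rng.integers(2, 9)),
                              int(rng.integers(2, 30)))
            expected = oracles.tajimas_d(m.genotypes)
            got = summarize_population(m).neutrality["tajima_d"]
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-10)

    def test_neutral_simulation_mean_near_zero(self):
        n, reps = 20, 4000
        rng = np.random.default_rng(23)
        lengths = coalsim.batch_class_lengths(n, reps, rng)
        counts = coalsim.sample_site_classes(lengths, rng, theta=5.0)
        d = tajimas_d_from_classes(counts, n)
        assert abs(np.nanmean(d)) < 0.1

    def test_invariant_to_sample_relabeling_and_allele_swap(self):
        rng = np.random.default_rng(24)
        m = random_matrix(rng, 6, 20)
        d0 = summarize_population(m).neutrality["tajima_d"]
        perm = rng.permutation(6)
        d1 = summarize_population(m.take_samples(perm)).neutrality["tajima_d"]
        flipped = make_matrix(2 - m.genotypes, list(m.locus_ids))
        d2 = summarize_population(flipped).neutrality["tajima_d"]
        assert d0 == pytest.approx(d1, abs=1e-12)
        assert d0 == pytest.approx(d2, abs=1e-12)


class TestFuLi:
    def test_dstar_numerator_without_singletons(self):
        # doubleton-only data: eta_s = 0 so the D* numerator is n/(n-1) * S > 0
        g = np.zeros((4, 5), dtype=np.int8)
        g[0, :] = 2  # derived count 2 of 8 at every site
        m = make_matrix(g)
        dstar, _ = fu_li_dstar_fstar(m)
        assert dstar > 0

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(25)
        for _ in range(50):
            m = random_matrix(rng, int(rng.integers(2, 9)),
                              int(rng.integers(2, 30)))
            expected = oracles.fu_li_dstar_fstar(m.genotypes)
            got = fu_li_dstar_fstar(m)
            if expected is None:
                assert got == (None, None)
            else:
                assert got[0] == pytest.approx(expected[0], abs=1e-10)
                assert got[1] == pytest.approx(expected[1], abs=1e-10)

    def test_neutral_simulation_means_near_zero(self):
        n, reps = 20, 4000
        rng = np.random.default_rng(26)
        lengths = coalsim.batch_class_lengths(n, reps, rng)
        counts = coalsim.sample_site_classes(lengths, rng, theta=5.0)
        dstar, fstar = fu_li_from_classes(counts, n)
        assert abs(np.nanmean(dstar)) < 0.1
        assert abs(np.nanmean(fstar)) < 0.12

    def test_expansion_skews_dstar_negative(self):
        cfg = coalsim.DemographyConfig(npops=1, epochs=((0.0, 1.0), (0.1, 0.05)))
        rng = np.random.default_rng(27)
        vals = []
        for _ in range(200):
            g = coalsim.simulate_genealogy(cfg, 20, seed=rng)
            counts = rng.poisson(5.0 * g.class_lengths())
            vals.append(fu_li_from_classes(counts, 20)[0][0])
        assert np.nanmean(vals) < -0.5


class TestWcFst:
    def _map(self, na, nb):
        ids = [f"s{i}" for i in range(na + nb)]
        return PopulationMap({s: ("A" if i < na else "B")
                              for i, s in enumerate(ids)})

    def test_identical_populations_nonpositive(self):
        # same frequencies and heterozygosity in both populations
        g = np.array([[1, 1], [0, 1], [1, 1], [0, 1]], dtype=np.int8)
        m = make_matrix(g)
        per_site, mor, ros = wc_fst(m, self._map(2, 2), "A", "B")
        assert np.all(per_site[np.isfinite(per_site)] <= 0)

    def test_fixed_difference_approaches_one(self):
        na = nb = 50
        g = np.concatenate(
            [np.zeros((na, 3), dtype=np.int8), np.full((nb, 3), 2, np.int8)]
        )
        m = make_matrix(g)
        _, mor, ros = wc_fst(m, self._map(na, nb), "A", "B")
        assert mor > 0.98 and ros > 0.98

    def test_matches_component_transcription(self):
        rng = np.random.default_rng(28)
        for _ in range(40):
            m = random_matrix(rng, 8, int(rng.integers(2, 30)),
                              missing_rate=0.1)
            pm = self._map(4, 4)
            per_site, mor, ros = wc_fst(m, pm, "A", "B")
            for j in range(m.n_sites):
                comp = oracles.wc_fst_site(m.genotypes[:4, j], m.genotypes[4:, j])
                if comp is None or not np.isfinite(per_site[j]):
                    continue
                a, b, c = comp
                if a + b + c != 0:
                    assert per_site[j] == pytest.approx(
                        a / (a + b + c), abs=1e-10
                    )

    def test_per_site_values_bounded(self):
        rng = np.random.default_rng(29)
        m = random_matrix(rng, 10, 50)
        per_site, _, _ = wc_fst(m, self._map(5, 5), "A", "B")
        finite = per_site[np.isfinite(per_site)]
        assert np.all(finite <= 1.0 + 1e-12) and np.all(finite >= -1.0 - 1e-12)


class TestSummaries:
    def test_theta_w_unbiased_under_neutrality(self):
        cfg = coalsim.DemographyConfig.constant(theta=3.0)
        res = coalsim.simulate_dataset(cfg, n_samples=10, n_loci=800, seed=31)
        table = per_locus_table(res.matrix)
        se = table["theta_w"].std() / np.sqrt(len(table))
        assert abs(table["theta_w"].mean() - 3.0) < 3 * se

    def test_both_pi_denominators_reported(self, small_matrix):
        per_locus = nucleotide_diversity(small_matrix, "per_locus")
        per_site = nucleotide_diversity(small_matrix, "per_site")
        assert per_locus["pi_per_bp"] == pytest.approx(per_locus["pi"] / 39)
        assert per_site["pi"] > 0
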