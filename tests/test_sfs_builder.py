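import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_matrix
from popdemog import coalsim
from popdemog.genotype_io import MISSING
from popdemog.sfs_builder import (
    ProjectionNotRunnable,
    Spectrum,
    choose_projection,
    fold,
    project,
    projection_weights,
    segregating_sites,
    sfs_from_matrix,
)


class TestProjection:
    def test_worked_hypergeometric_value(self):
        # [., 3, 2, 1, .] at n=4 projected to m=2:
        # entry 1 = 3*(1/2) + 2*(2/3) + 1*(1/2) = 10/3
        s = Spectrum([0, 3, 2, 1, 0], (4,))
        p = project(s, (2,))
        assert p.counts[1] == pytest.approx(10 / 3, abs=1e-12)

    def test_projection_to_full_size_is_identity(self):
        s = Spectrum([0.0, 3, 2, 1, 5], (4,))
        p = project(s, (4,))
        np.testing.assert_allclose(p.counts, s.counts, atol=1e-12)

    def test_total_mass_preserved(self):
        rng = np.random.default_rng(1)
        s = Spectrum(rng.random(9), (8,))
        for m in (2, 4, 7):
            assert project(s, (m,)).counts.sum() == pytest.approx(
                s.counts.sum(), rel=1e-12
            )

    def test_matches_exhaustive_subsample_enumeration(self):
        # exact agreement with averaging over all C(n, m) subsamples, n <= 8
        for n in range(3, 9):
            for i in range(n + 1):
                for m in range(2, n + 1):
                    expected = oracles.project_site_enumeration(n, i, m)
                    np.testing.assert_allclose(
                        projection_weights(n, i, m), expected, atol=1e-12
                    )

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_projection_composes(self, seed):
        # project(project(s, m1), m2) == project(s, m2): composition of
        # hypergeometric subsampling
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 12))
        s = Spectrum(rng.random(n + 1) * 10, (n,))
        m1 = int(rng.integers(4, n))
        m2 = int(rng.integers(2, m1))
        via = project(project(s, (m1,)), (m2,))
        direct = project(s, (m2,))
        np.testing.assert_allclose(via.counts, direct.counts, atol=1e-9)

    def test_projection_above_n_errors(self):
        with pytest.raises(ValueError):
            project(Spectrum([1.0, 1, 1], (2,)), (4,))


class TestFold:
    def test_fold_example_and_conservation(self):
        s = Spectrum([0, 3, 2, 1, 0], (4,))
        f = fold(s)
        assert f.counts[1] == 4 and f.counts[2] == 2
        assert f.mask[3] and f.mask[4]
        assert segregating_sites(f) == pytest.approx(segregating_sites(s))

    def test_symmetric_spectrum_doubles_lower_half(self):
        s = Spectrum([0, 2, 5, 7, 5, 2, 0], (6,))
        f = fold(s)
        np.testing.assert_allclose(f.counts[1:4], [4, 10, 7])

    def test_fold_twice_errors(self):
        f = fold(Spectrum([0, 1, 1, 0], (3,)))
        with pytest.raises(ValueError):
            fold(f)

    def test_fold_commutes_with_projection(self):
        rng = np.random.default_rng(3)
        s = Spectrum(rng.random(11), (10,))
        a = fold(project(s, (6,)))
        # folding first then projecting is not defined on the folded object,
        # so compare against folding the projection of the unfolded spectrum
        # computed through the 2-step path with different intermediate size
        b = fold(project(project(s, (8,)), (6,)))
        np.testing.assert_allclose(a.counts, b.counts, atol=1e-9)

    def test_2d_fold_masks_upper_triangle_and_halves_diagonal(self):
        rng = np.random.default_rng(4)
        s = Spectrum(rng.random((5, 5)), (4, 4))
        f = fold(s)
        total = 4 + 4
        for i in range(5):
            for j in range(5):
                if 2 * (i + j) > total:
                    assert f.mask[i, j]
                elif 2 * (i + j) == total:
                    assert f.counts[i, j] == pytest.approx(
                        0.5 * (s.counts[i, j] + s.counts[4 - i, 4 - j])
                    )
        assert f.counts[~f.mask].sum() == pytest.approx(s.counts.sum(), rel=1e-12)


class TestSfsFromMatrix:
    def test_direct_count_two_hets(self):
        m = make_matrix([[1], [1]])
        spec = sfs_from_matrix(m, [["s0", "s1"]], (4,), fold_spectrum=False)
        assert spec.counts[2] == pytest.approx(1.0)
        assert spec.counts.sum() == pytest.approx(1.0)

    def test_site_with_missing_dropped_when_target_exceeds_observed(self):
        m = make_matrix([[1], [MISSING]])
        spec = sfs_from_matrix(m, [["s0", "s1"]], (4,), fold_spectrum=False)
        assert spec.counts.sum() == 0.0

    def test_neutral_simulation_mean_proportional_to_one_over_i(self):
        cfg = coalsim.DemographyConfig.constant(theta=2.0)
        rng = np.random.default_rng(8)
        n = 10
        acc = np.zeros(n + 1)
        reps = 600
        for _ in range(reps):
            g = coalsim.simulate_genealogy(cfg, n, seed=rng)
            acc[1:n] += rng.poisson(2.0 * g.class_lengths())
        xi = acc[1:n] / reps
        expected = 2.0 / np.arange(1, n)
        se = np.sqrt(xi / reps) + 1e-9
        assert np.all(np.abs(xi - expected) < 5 * np.maximum(se, 0.05))


class TestChooseProjection:
    def test_no_missing_data_optimum_is_full_size(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        m = make_matrix(g, locus_ids=[f"L{j}" for j in range(40)])
        proj, seg = choose_projection(m, [m.sample_ids], min_alleles=10)
        assert proj == (20,)

    def test_matches_exhaustive_candidate_scan(self):
        rng = np.random.default_rng(10)
        g = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        g[rng.random(g.shape) < 0.3] = MISSING
        m = make_matrix(g, locus_ids=[f"L{j}" for j in range(30)])
        pops = [m.sample_ids]
        proj, seg = choose_projection(m, pops, min_alleles=4)
        best = max(
            (
                segregating_sites(sfs_from_matrix(m, pops, (k,))),
                k,
            )
            for k in range(4, 17)
        )
        assert seg == pytest.approx(best[0])
        assert proj == (best[1],)

    def test_too_few_samples_not_runnable(self):
        g = np.ones((4, 5), dtype=np.int8)  # 8 alleles max < 10
        m = make_matrix(g)
        with pytest.raises(ProjectionNotRunnable):
            choose_projection(m, [m.sample_ids], min_alleles=10)


class TestSegregatingSites:
    def test_sum_and_monomorphic(self):
        f = fold(Spectrum([0, 3, 1, 0, 0], (4,))).mask_corners()
        assert segregating_sites(f) == pytest.approx(4.0)
        empty = Spectrum([7.0, 0, 0, 0, 9.0], (4,)).mask_corners()
        assert segregating_sites(empty) == 0.0

    def test_equals_polymorphic_site_count_without_projection(self):
        rng = np.random.default_rng(12)
        g = rng.integers(0, 3, size=(6, 25)).astype(np.int8)
        m = make_matrix(g)
        spec = sfs_from_matrix(m, [m.sample_ids], (12,), fold_spectrum=True)
        alt = g.sum(axis=0)
        poly = int(((alt > 0) & (alt < 12)).sum())
        assert segregating_sites(spec) == pytest.approx(poly)


class TestSerialization:
    def test_dadi_flat_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        spec = fold(Spectrum(rng.random((5, 7)), (4, 6))).mask_corners()
        path = tmp_path / "spec.fs"
        spec.to_file(str(path))
        back = Spectrum.from_file(str(path))
        np.testing.assert_array_equal(back.counts, spec.counts)
        np.testing.assert_array_equal(back.mask, spec.mask)
        assert back.folded and back.sample_sizes == (4, 6)
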