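"""Normalization stack, pseudo-bulking, tiling and chromosome split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scgraphdec.preprocess import (
    DenoiseParams,
    LibNormParams,
    TileSpec,
    eigen_denoise,
    library_size_normalize,
    minmax_normalize,
    pseudobulk_expression,
    soft_threshold,
    split_chromosomes,
    tile_region,
)
from scgraphdec.types import ContactMap, NormState, TrackSet

from conftest import random_symmetric_map


class TestLibraryNormalization:
    def test_single_entry_closed_form(self):
        out = library_size_normalize(np.array([1.0]), LibNormParams(pseudocount=1e-8))
        assert out[0] == pytest.approx(np.log(25_000 + 1e-8), abs=1e-9)

    def test_uniform_map_with_alpha_equal_total(self):
        out = library_size_normalize(np.ones((2, 2)), LibNormParams(alpha=4.0, pseudocount=1e-8))
        np.testing.assert_allclose(out, np.log(1 + 1e-8), atol=1e-12)

    def test_zero_entry_maps_to_log_pseudocount(self):
        for eps in (1e-8, 1.0):
            out = library_size_normalize(np.array([0.0, 2.0]), LibNormParams(pseudocount=eps))
            assert out[0] == pytest.approx(np.log(eps))
            assert np.all(np.isfinite(out))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="empty library"):
            library_size_normalize(np.zeros((3, 3)))

    def test_scale_invariance(self, rng):
        # the operation's purpose: pseudo-bulks with different cell counts
        # (scalar multiples) give identical profiles
        t = rng.integers(1, 50, size=(10, 10)).astype(float)
        a = library_size_normalize(t)
        b = library_size_normalize(7.3 * t)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_matches_naive_loop(self, rng):
        t = rng.random((50, 50)) * 5
        params = LibNormParams()
        expected = np.empty_like(t)
        total = t.sum()
        for i in range(50):
            for j in range(50):
                expected[i, j] = np.log(t[i, j] / total * params.alpha + params.pseudocount)
        np.testing.assert_allclose(library_size_normalize(t, params), expected, atol=1e-12)


class TestEigenDenoise:
    def test_diagonal_closed_form(self):
        cmap = ContactMap("c", 50_000, np.diag([2.0, 0.1]), NormState.LIBNORM)
        out = eigen_denoise(cmap, DenoiseParams(0.5))
        np.testing.assert_allclose(out.matrix, np.diag([1.5, 0.0]), atol=1e-12)

    def test_negative_eigenvalue_shrunk_toward_zero(self):
        assert soft_threshold(np.array([-0.8]), 0.5)[0] == pytest.approx(-0.3)
        assert soft_threshold(np.array([0.3]), 0.5)[0] == 0.0

    def test_threshold_zero_is_identity(self, random_map):
        out = eigen_denoise(
            ContactMap("t", 50_000, random_map.matrix, NormState.LIBNORM), DenoiseParams(0.0)
        )
        np.testing.assert_allclose(out.matrix, random_map.matrix, atol=1e-8)

    def test_never_increases_frobenius_norm(self, rng):
        for _ in range(5):
            m = random_symmetric_map(rng, n=15)
            out = eigen_denoise(m, DenoiseParams(0.5))
            assert np.linalg.norm(out.matrix) <= np.linalg.norm(m.matrix) + 1e-9

    def test_repeated_denoise_equals_cumulative_shrinkage_on_diagonal(self):
        d = np.diag([3.0, 1.2, 0.4])
        cmap = ContactMap("c", 50_000, d, NormState.LIBNORM)
        twice = eigen_denoise(eigen_denoise(cmap, DenoiseParams(0.5)), DenoiseParams(0.5))
        cumulative = np.diag(soft_threshold(np.diag(d), 1.0))
        np.testing.assert_allclose(twice.matrix, cumulative, atol=1e-10)

    def test_asymmetric_rejected(self):
        m = np.array([[1.0, 2.0], [0.0, 1.0]])
        cmap = ContactMap.__new__(ContactMap)
        cmap.chrom, cmap.resolution, cmap.matrix, cmap.norm_state = "c", 50_000, m, NormState.LIBNORM
        with pytest.raises(ValueError, match="symmetric"):
            eigen_denoise(cmap)

    def test_matches_naive_implementation(self, rng):
        m = random_symmetric_map(rng, n=50).matrix
        cmap = ContactMap("t", 50_000, m, NormState.LIBNORM)
        out = eigen_denoise(cmap, DenoiseParams(0.5))
        vals, vecs = np.linalg.eigh(m)
        shrunk = np.sign(vals) * np.maximum(np.abs(vals) - 0.5, 0)
        naive = vecs @ np.diag(shrunk) @ vecs.T
        np.testing.assert_allclose(out.matrix, naive, atol=1e-8)


class TestMinMax:
    def test_basic(self):
        np.testing.assert_allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(minmax_normalize(np.array([5.0, 5.0])), [0, 0])

    def test_idempotent_on_canonical_range(self):
        np.testing.assert_array_equal(minmax_normalize(np.array([0.0, 1.0])), [0, 1])

    def test_bounds_for_nonconstant_input(self, rng):
        for _ in range(5):
            x = rng.normal(size=20)
            out = minmax_normalize(x)
            assert out.min() == 0.0 and out.max() == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([]))

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            st.integers(2, 40),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_output_always_in_unit_interval(self, x):
        out = minmax_normalize(x)
        assert out.min() >= 0.0 and out.max() <= 1.0
        if np.unique(x).size > 1:
            assert out.min() == 0.0 and out.max() == 1.0


class TestSoftThresholdProperties:
    @settings(deadline=None, derandomize=True)
    @given(
        arrays(np.float64, st.integers(1, 30), elements=st.floats(-100, 100, allow_nan=False)),
        st.floats(0.0, 10.0),
    )
    def test_shrinks_magnitude_and_preserves_sign(self, lam, t):
        out = soft_threshold(lam, t)
        assert np.all(np.abs(out) <= np.abs(lam) + 1e-12)
        nz = out != 0
        assert np.all(np.sign(out[nz]) == np.sign(lam[nz]))
        assert np.all(np.abs(lam[np.abs(lam) <= t]) >= np.abs(out[np.abs(lam) <= t]))
        assert np.all(out[np.abs(lam) < t] == 0.0)


class TestPseudobulk:
    @pytest.fixture
    def annotations(self):
        return pd.DataFrame(
            {
                "chrom": ["c1", "c1", "c1", "c2"],
                "start": [150_000, 150_000, 100_000, 0],
                "end": [200_000, 200_000, 200_000, 50_000],
                "strand": ["+", "+", "+", "+"],
            },
            index=["gA", "gB", "gC", "gOther"],
        )

    def test_single_gene_single_bin(self, annotations):
        counts = pd.DataFrame({"gA": [4, 6]})
        plus, minus = pseudobulk_expression(counts, annotations, "c1", 50_000, 5)
        assert plus[3] == 10.0
        assert np.all(minus == 0)

    def test_two_genes_same_bin_averaged(self, annotations):
        counts = pd.DataFrame({"gA": [4], "gB": [8]})
        plus, _ = pseudobulk_expression(counts, annotations, "c1", 50_000, 5)
        assert plus[3] == pytest.approx(6.0)

    def test_gene_spanning_bins_contributes_to_each(self, annotations):
        counts = pd.DataFrame({"gC": [6]})
        plus, _ = pseudobulk_expression(counts, annotations, "c1", 50_000, 5)
        # gC spans bins 2 and 3; its total joins each bin's averaging pool
        assert plus[2] == pytest.approx(6.0)
        assert plus[3] == pytest.approx(6.0)

    def test_empty_pseudobulk_rejected(self, annotations):
        counts = pd.DataFrame({"gA": pd.Series([], dtype=float)})
        with pytest.raises(ValueError, match="empty pseudo-bulk"):
            pseudobulk_expression(counts, annotations, "c1", 50_000, 5)

    def test_unknown_gene_skipped_with_warning(self, annotations):
        counts = pd.DataFrame({"gA": [1], "gMystery": [5]})
        with pytest.warns(UserWarning, match="gMystery"):
            plus, _ = pseudobulk_expression(counts, annotations, "c1", 50_000, 5)
        assert plus[3] == 1.0


class TestTiling:
    def make_pair(self, n):
        rng = np.random.default_rng(0)
        cmap = random_symmetric_map(rng, n=n)
        tracks = TrackSet("t", 50_000, rng.random((5, n)))
        return cmap, tracks

    @pytest.mark.parametrize(
        "n_bins,window,stride,expected_starts",
        [(160, 128, 16, [0, 16, 32]), (128, 128, 16, [0]), (127, 128, 16, [])],
    )
    def test_tile_starts(self, n_bins, window, stride, expected_starts):
        cmap, tracks = self.make_pair(n_bins)
        spec = TileSpec(window_bins=window, stride_bins=stride)
        if expected_starts:
            tiles = list(tile_region(cmap, tracks, spec))
        else:
            with pytest.warns(UserWarning, match="shorter than one"):
                tiles = list(tile_region(cmap, tracks, spec))
        assert [t[0] for t in tiles] == expected_starts
        for s, tile, block in tiles:
            np.testing.assert_array_equal(tile, cmap.matrix[s : s + window, s : s + window])
            assert block.shape == (window, 5)

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            TileSpec(window_bins=128, stride_bins=0)


class TestSplitChromosomes:
    def test_mouse_autosomes(self):
        chroms = [f"chr{i}" for i in range(1, 20)]
        train, test = split_chromosomes(chroms)
        assert sorted(test) == ["chr11", "chr7"]
        assert len(train) == 17

    def test_sex_and_mito_excluded(self):
        train, test = split_chromosomes(["chr1", "chrX", "chrY", "chrMT", "chr7"])
        assert "chrX" not in train + test
        assert "chrY" not in train + test
        assert "chrMT" not in train + test

    def test_configured_override(self):
        train, test = split_chromosomes(["s1", "s2"], test_chroms={"s2"})
        assert train == ["s1"] and test == ["s2"]
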