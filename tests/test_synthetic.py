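"""Synthetic co-assay generator: distributional contracts and determinism."""

import json

import numpy as np
import pytest

from scgraphdec import data_io
from scgraphdec.metrics import call_tad_boundaries
from scgraphdec.synthetic import (
    TAD,
    SyntheticSpec,
    active_tad_indicator,
    make_dataset,
    make_ground_truth,
    make_tracks,
    resolve_layout,
    sample_bulk,
    sample_sc_target,
    shared_boundary_bins,
)


def small_spec(**kw):
    defaults = dict(n_bins=64, n_cell_types=2, mixture_weights=(0.6, 0.4), seed=5)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


class TestGroundTruth:
    def test_pure_decay_entry_ratio(self):
        spec = small_spec(
            shared_tads=(), specific_tads=((), ()), decay_exponent=1.0
        )
        maps = make_ground_truth(spec)
        m = maps[0].matrix
        # (1+1)^-1 / (1+3)^-1 = 2 at offsets 1 vs 3
        assert m[0, 1] / m[0, 3] == pytest.approx(2.0)

    def test_probability_mass_function(self):
        for c, m in enumerate(make_ground_truth(small_spec())):
            assert m.matrix.sum() == pytest.approx(1.0)
            assert m.matrix.min() >= 0
            np.testing.assert_allclose(m.matrix, m.matrix.T)

    def test_tad_block_enrichment(self):
        tad = TAD(0, 8, 2.0)
        spec = small_spec(shared_tads=(tad,), specific_tads=((), ()))
        m = make_ground_truth(spec)[0].matrix
        plain = make_ground_truth(
            small_spec(shared_tads=(), specific_tads=((), ()))
        )[0].matrix
        # after renormalization the in-block / out-of-block enrichment ratio
        # relative to the pure-decay baseline is exactly the TAD intensity
        in_ratio = np.median(m[:8, :8] / plain[:8, :8])
        out_ratio = np.median(m[8:, 8:] / plain[8:, 8:])
        assert in_ratio / out_ratio == pytest.approx(2.0, rel=1e-9)

    def test_identical_layouts_give_identical_maps(self):
        tads = (TAD(4, 16, 2.0),)
        spec = small_spec(shared_tads=tads, specific_tads=((), ()))
        a, b = make_ground_truth(spec)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_contradictory_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            make_ground_truth(
                small_spec(shared_tads=(TAD(0, 10, 2.0), TAD(5, 15, 3.0)), specific_tads=((), ()))
            )

    def test_nested_subtads_allowed(self):
        spec = small_spec(shared_tads=(TAD(0, 20, 1.5), TAD(4, 10, 2.0)), specific_tads=((), ()))
        m = make_ground_truth(spec)[0].matrix
        assert np.all(np.isfinite(m))


class TestBulkSampling:
    def test_degenerate_weights_sample_single_type(self):
        spec = small_spec(mixture_weights=(1.0, 0.0), read_depth_bulk=2e4)
        truths = make_ground_truth(spec)
        rng = np.random.default_rng(0)
        bulk = sample_bulk(truths, spec, rng=rng)
        direct = sample_sc_target(truths[0], spec, rng=np.random.default_rng(0))
        # same probability vector and stream: identical draws up to depth
        assert bulk.matrix.sum() == pytest.approx(spec.read_depth_bulk)

    def test_multinomial_expectation(self):
        spec = small_spec(
            n_bins=16,
            read_depth_bulk=5000,
            shared_tads=(TAD(0, 8, 2.0),),
            specific_tads=((TAD(8, 12, 2.5),), (TAD(12, 16, 2.5),)),
        )
        truths = make_ground_truth(spec)
        w = np.asarray(spec.mixture_weights)
        mix = sum(wc * t.matrix for wc, t in zip(w, truths))
        draws = [
            sample_bulk(truths, spec, rng=np.random.default_rng(i)).matrix for i in range(200)
        ]
        mean = np.mean(draws, axis=0)
        expected = spec.read_depth_bulk * mix
        # symmetrized multinomial: per-entry SE ~ sqrt(depth * p * (p_ij + p_ji)) / ... use 3 SE
        se = np.sqrt(spec.read_depth_bulk * mix / 2.0 / 200) + 1e-9
        assert np.all(np.abs(mean - expected) < 3 * se + 0.05 * expected + 1e-6)

    def test_high_depth_converges_to_mixture(self):
        spec = small_spec(read_depth_bulk=1e6)
        truths = make_ground_truth(spec)
        w = np.asarray(spec.mixture_weights)
        mix = sum(wc * t.matrix for wc, t in zip(w, truths))
        bulk = sample_bulk(truths, spec).matrix
        assert np.abs(bulk / bulk.sum() - mix).sum() < 0.05

    def test_total_reads_conserved_exactly(self):
        spec = small_spec(read_depth_sc=12_345)
        truths = make_ground_truth(spec)
        target = sample_sc_target(truths[0], spec)
        assert target.matrix.sum() == pytest.approx(12_345, abs=1e-9)

    def test_zero_depth_empty_map(self):
        spec = small_spec(read_depth_sc=0)
        truths = make_ground_truth(spec)
        assert sample_sc_target(truths[0], spec).matrix.sum() == 0

    def test_sparsity_monotone_in_depth(self):
        spec = small_spec()
        truths = make_ground_truth(spec)
        zero_fracs = []
        for depth in (100, 1000, 10_000, 100_000):
            s = small_spec(read_depth_sc=depth)
            m = sample_sc_target(truths[0], s).matrix
            zero_fracs.append((m == 0).mean())
        assert all(a >= b for a, b in zip(zero_fracs, zero_fracs[1:]))


class TestTracks:
    def test_clean_expression_is_scaled_indicator(self):
        spec = small_spec(expr_coupling=1.0, noise_sd=0.0)
        tracks = make_tracks(spec, 0)
        expr = tracks.channels[0] + tracks.channels[1]
        ind = active_tad_indicator(spec, 0)
        np.testing.assert_allclose(expr, ind * spec.expr_scale)

    def test_uncoupled_expression_independent_of_structure(self):
        spec = SyntheticSpec(n_bins=512, n_cell_types=2, mixture_weights=(0.5, 0.5),
                             expr_coupling=0.0, seed=3)
        tracks = make_tracks(spec, 0)
        expr = tracks.channels[0] + tracks.channels[1]
        ind = active_tad_indicator(spec, 0)
        assert abs(np.corrcoef(expr, ind)[0, 1]) < 0.1

    def test_clean_ctcf_peaks_at_shared_boundaries(self):
        spec = small_spec(noise_sd=0.0)
        tracks = make_tracks(spec, 0)
        peaks = np.nonzero(tracks.channels[2])[0]
        np.testing.assert_array_equal(peaks, shared_boundary_bins(spec))

    def test_cpg_correlates_with_ctcf(self):
        spec = small_spec(n_bins=256, noise_sd=0.05)
        tracks = make_tracks(spec, 0)
        corr = np.corrcoef(tracks.channels[4], 0.5 * (tracks.channels[2] + tracks.channels[3]))[0, 1]
        assert corr >= 0.7

    def test_tracks_differ_between_cell_types(self):
        spec = small_spec()
        a = make_tracks(spec, 0).channels[:2].sum(axis=0)
        b = make_tracks(spec, 1).channels[:2].sum(axis=0)
        assert not np.allclose(a, b)


class TestLayouts:
    def test_default_layout_counts(self):
        spec = SyntheticSpec(seed=9)
        shared, specific = resolve_layout(spec)
        assert len(shared) == spec.n_shared_tads
        assert len(specific) == spec.n_cell_types
        assert all(len(s) == spec.n_specific_tads for s in specific)

    def test_layout_deterministic_from_seed(self):
        a = resolve_layout(SyntheticSpec(seed=9))
        b = resolve_layout(SyntheticSpec(seed=9))
        assert a == b

    def test_bulk_boundaries_detect_specific_tads(self):
        # the deconvolution premise: cell-type TADs with mixture weight
        # >= 0.3 leave detectable boundary signatures in deep bulk
        spec = SyntheticSpec(seed=2, read_depth_bulk=5e6)
        shared, specific = resolve_layout(spec)
        truths = make_ground_truth(spec)
        bulk = sample_bulk(truths, spec)
        called = call_tad_boundaries(bulk, window=6, min_prominence=0.1).boundaries
        for c, weight in enumerate(spec.mixture_weights):
            if weight < 0.3:
                continue
            for tad in specific[c]:
                for edge in (tad.start, tad.end):
                    # the caller cannot see beyond window bins of either end
                    if edge < 6 or edge >= spec.n_bins - 6:
                        continue
                    assert np.min(np.abs(called - edge)) <= 2, (c, tad)


class TestDataset:
    def test_reproducible_manifest_and_files(self, tmp_path):
        spec = small_spec()
        m1 = make_dataset(spec, str(tmp_path / "a"))
        m2 = make_dataset(spec, str(tmp_path / "b"))
        assert m1["spec_hash"] == m2["spec_hash"]
        f1 = (tmp_path / "a" / m1["files"]["bulk"]).read_text()
        f2 = (tmp_path / "b" / m2["files"]["bulk"]).read_text()
        assert f1 == f2

    def test_artifact_counts_and_round_trip(self, tmp_path):
        spec = small_spec(n_bins=128, n_cell_types=3, mixture_weights=(0.5, 0.3, 0.2))
        manifest = make_dataset(spec, str(tmp_path))
        files = manifest["files"]
        assert len(files["cell_types"]) == 3
        bulk = data_io.load_contact_map(
            str(tmp_path / files["bulk"]), spec.chrom, spec.resolution, n_bins=spec.n_bins
        )
        assert bulk.n_bins == spec.n_bins
        for entry in files["cell_types"]:
            tm = data_io.load_contact_map(
                str(tmp_path / entry["target"]), spec.chrom, spec.resolution, n_bins=spec.n_bins
            )
            np.testing.assert_allclose(tm.matrix, tm.matrix.T)
            ts = data_io.load_tracks(
                [str(tmp_path / p) for p in entry["tracks"]],
                spec.chrom,
                spec.resolution,
                spec.n_bins,
            )
            assert ts.n_bins == spec.n_bins

    def test_manifest_is_valid_json_with_layout(self, tmp_path):
        make_dataset(small_spec(), str(tmp_path))
        manifest = json.loads((tmp_path / "manifest_s1.json").read_text())
        assert manifest["spec"]["shared_tads"]


class TestSpecValidation:
    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            SyntheticSpec(n_cell_types=2, mixture_weights=(0.7, 0.7))

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_cell_types=3, mixture_weights=(0.5, 0.5))
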