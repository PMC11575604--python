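"""Tests for the synthetic-data generator and its persistence."""

import numpy as np
import pytest

from echoshift import (
    AcquisitionParams,
    DatasetManifest,
    ParameterRanges,
    SpectraDataset,
    SpinSignalSpec,
    generate_dataset,
    generate_sample,
    make_label,
    normalize_input,
    sample_spin_systems,
    simulate_echo_series,
)


class TestSampleSpinSystems:
    def test_fixed_seed_reproducible(self):
        ranges = ParameterRanges()
        a, ab_a = sample_spin_systems(ranges, 123)
        b, ab_b = sample_spin_systems(ranges, 123)
        assert a == b and ab_a == ab_b

    def test_draws_respect_configured_ranges(self):
        ranges = ParameterRanges(j_hz=(3.0, 9.0), t2_s=(0.1, 0.4))
        js, t2s, counts = [], [], []
        for seed in range(400):
            specs, _ = sample_spin_systems(ranges, seed)
            counts.append(len(specs))
            for s in specs:
                t2s.append(s.t2_s)
                js.extend(j for j, _ in s.couplings)
        assert min(js) >= 3.0 and max(js) <= 9.0
        assert min(t2s) >= 0.1 and max(t2s) <= 0.4
        assert min(counts) >= ranges.n_signals[0]
        # solvent singlet may add one signal on top of the drawn count
        assert max(counts) <= ranges.n_signals[1] + 1

    def test_degenerate_ranges_give_identical_specs(self):
        ranges = ParameterRanges(
            amplitude=(0.5, 0.5), t2_s=(0.2, 0.2), n_signals=(3, 3),
            n_couplings=(1, 1), j_hz=(7.0, 7.0), pow_range=(2, 2),
            solvent_fraction=0.0,
        )
        specs, _ = sample_spin_systems(ranges, 9)
        assert len(specs) == 3
        assert all(s.amplitude == 0.5 and s.t2_s == 0.2 for s in specs)
        assert all(s.couplings == ((7.0, 2),) for s in specs)

    def test_frequencies_within_central_fraction(self):
        ranges = ParameterRanges(freq_fraction=0.5)
        for seed in range(50):
            specs, _ = sample_spin_systems(ranges, seed, sw_hz=4096.0)
            for s in specs:
                assert abs(s.freq_hz) <= 0.25 * 4096.0

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ParameterRanges(j_hz=(10.0, 5.0))


class TestMakeLabel:
    def test_no_signals_gives_zero_vector(self, acq_small):
        label = make_label([], acq_small)
        assert label.sum() == 0 and len(label) == acq_small.np_points

    def test_center_signal_lands_at_midpoint(self, acq):
        label = make_label([SpinSignalSpec(1.0, 0.0, 0.3)], acq)
        assert label[2048] == 1 and label.sum() == 1

    def test_label_index_matches_grid_rounding(self, acq):
        # 1 Hz per point: f = 100.4 Hz rounds to bin 2148
        label = make_label([SpinSignalSpec(1.0, 100.4, 0.3)], acq)
        assert label[2148] == 1

    def test_colliding_signals_merge_to_single_one(self, acq):
        specs = [SpinSignalSpec(1.0, 100.0, 0.3), SpinSignalSpec(1.0, 100.3, 0.3)]
        label = make_label(specs, acq)
        assert label.sum() == 1

    def test_out_of_band_frequency_rejected(self, acq):
        with pytest.raises(ValueError):
            make_label([SpinSignalSpec(1.0, 3000.0, 0.3)], acq)


class TestNormalizeInput:
    def test_first_row_max_is_one(self, acq_small):
        series = simulate_echo_series([SpinSignalSpec(2.7, 100.0, 0.3)], acq_small)
        stack, scale = normalize_input(series)
        assert np.abs(stack[0]).max() == pytest.approx(1.0)

    def test_scale_invariance(self, acq_small):
        s1 = simulate_echo_series([SpinSignalSpec(1.0, 100.0, 0.3)], acq_small)
        s7 = simulate_echo_series([SpinSignalSpec(7.0, 100.0, 0.3)], acq_small)
        a, _ = normalize_input(s1)
        b, _ = normalize_input(s7)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_round_trip_with_scale(self, acq_small):
        series = simulate_echo_series([SpinSignalSpec(3.0, -200.0, 0.2)], acq_small)
        stack, scale = normalize_input(series)
        np.testing.assert_allclose(stack * scale, series.real_stack(), rtol=1e-6)

    def test_zero_series_rejected(self, acq_small):
        with pytest.raises(ValueError):
            normalize_input(simulate_echo_series([], acq_small))


class TestGenerateSample:
    def test_label_positions_sit_on_simulated_signals(self, acq_small, easy_ranges):
        for seed in range(5):
            rec = generate_sample(easy_ranges, acq_small, seed)
            truth_bins = {int(acq_small.hz_to_index(f)) for f in rec.metadata["freq_hz"]}
            label_bins = set(np.flatnonzero(rec.label))
            assert label_bins == truth_bins

    def test_label_sum_accounts_for_collisions(self, acq_small):
        ranges = ParameterRanges()
        for seed in range(10):
            rec = generate_sample(ranges, acq_small, seed)
            assert rec.label.sum() == rec.metadata["n_signals"] - rec.metadata["n_collisions"]

    def test_determinism(self, acq_small, easy_ranges):
        a = generate_sample(easy_ranges, acq_small, 4)
        b = generate_sample(easy_ranges, acq_small, 4)
        np.testing.assert_array_equal(a.input_stack, b.input_stack)
        np.testing.assert_array_equal(a.label, b.label)
        assert a.metadata == b.metadata

    def test_wsn_targeting_controls_noise(self, acq_small):
        quiet = ParameterRanges(n_signals=(2, 2), wsn=(150.0, 150.0),
                                solvent_fraction=0.0, phase_fraction=0.0)
        loud = ParameterRanges(n_signals=(2, 2), wsn=(3.0, 3.0),
                               solvent_fraction=0.0, phase_fraction=0.0)
        rec_q = generate_sample(quiet, acq_small, 11)
        rec_l = generate_sample(loud, acq_small, 11)
        assert rec_l.metadata["noise_sd"] > rec_q.metadata["noise_sd"] * 10


class TestDatasetFile:
    def test_round_trip_and_regeneration(self, tmp_path, easy_ranges, acq_small):
        manifest = DatasetManifest(n_samples=6, seed=5, ranges=easy_ranges, acq=acq_small)
        path = tmp_path / "ds.h5"
        ds = generate_dataset(manifest, path)
        loaded = SpectraDataset.from_hdf5(path)
        np.testing.assert_array_equal(ds.inputs, loaded.inputs)
        regenerated = SpectraDataset.from_manifest(loaded.manifest)
        np.testing.assert_array_equal(loaded.inputs, regenerated.inputs)
        np.testing.assert_array_equal(loaded.labels, regenerated.labels)

    def test_empty_dataset_is_valid(self, tmp_path, acq_small):
        manifest = DatasetManifest(n_samples=0, seed=0, acq=acq_small)
        ds = generate_dataset(manifest, tmp_path / "empty.h5")
        assert len(ds) == 0
        assert SpectraDataset.from_hdf5(tmp_path / "empty.h5").manifest.n_samples == 0

    def test_identical_seeds_give_identical_files(self, tmp_path, easy_ranges, acq_small):
        manifest = DatasetManifest(n_samples=4, seed=77, ranges=easy_ranges, acq=acq_small)
        a = generate_dataset(manifest, tmp_path / "a.h5")
        b = generate_dataset(manifest, tmp_path / "b.h5")
        np.testing.assert_array_equal(a.inputs, b.inputs)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.metadata == b.metadata

    def test_splits_are_disjoint_and_cover(self, easy_ranges, acq_small):
        manifest = DatasetManifest(
            n_samples=10, seed=1, split_fractions=(0.6, 0.2, 0.2),
            ranges=easy_ranges, acq=acq_small,
        )
        ds = SpectraDataset.from_manifest(manifest)
        parts = [ds.split(name) for name in ("train", "val", "test")]
        assert [len(p) for p in parts] == [6, 2, 2]
        stacked = np.concatenate([p.inputs for p in parts])
        np.testing.assert_array_equal(stacked, ds.inputs)


def test_parameter_marginals_are_uniform():
    """Drawn J values should follow the configured uniform marginal (KS test)."""
    from scipy import stats

    ranges = ParameterRanges(n_couplings=(1, 1), j_hz=(2.0, 18.0))
    js = []
    for seed in range(300):
        specs, _ = sample_spin_systems(ranges, seed)
        js.extend(j for s in specs for j, _ in s.couplings)
    js = (np.asarray(js) - 2.0) / 16.0
    assert stats.kstest(js, "uniform").pvalue > 0.01
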