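"""Closed-form and property tests for the spin-echo simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from echoshift import (
    ABSystemSpec,
    AcquisitionParams,
    ComplexFid,
    SpinSignalSpec,
    add_noise,
    apply_phase_distortion,
    compute_wsn,
    fid_to_spectrum,
    simulate_ab_fid,
    simulate_ab_series,
    simulate_echo_series,
    simulate_fid,
)
from echoshift.physics import Spectrum


def conventional_fid(spec, acq):
    """Independent single-pulse oracle: one shared time grid t = k/SW."""
    t = np.arange(acq.np_points) / acq.sw_hz
    s = spec.amplitude * np.exp(2j * np.pi * spec.freq_hz * t) * np.exp(-t / spec.t2_s)
    for j, p in spec.couplings:
        s = s * np.cos(np.pi * j * t) ** p
    return s


class TestSimulateFid:
    def test_unit_amplitude_no_decay_gives_ones(self, acq):
        spec = SpinSignalSpec(1.0, 0.0, 1e9)
        fid = simulate_fid(spec, acq, 0.0)
        np.testing.assert_allclose(fid.samples, np.ones(acq.np_points), rtol=1e-6)

    def test_doublet_null_at_half_period_is_exact_zero(self, acq):
        # 2τ = 1/(2J): cos(π·J·2τ) = 0, so the first FID point vanishes
        spec = SpinSignalSpec(1.0, 100.0, 0.5, ((10.0, 1),))
        fid = simulate_fid(spec, acq, 1.0 / (2 * 10.0))
        assert fid.samples[0] == 0

    def test_echo_time_zero_equals_conventional_single_pulse(self, acq):
        spec = SpinSignalSpec(0.8, -313.0, 0.21, ((7.3, 2), (12.1, 1)))
        fid = simulate_fid(spec, acq, 0.0)
        np.testing.assert_allclose(
            fid.samples, conventional_fid(spec, acq), rtol=1e-11, atol=1e-14
        )

    def test_shift_refocused_but_j_evolves_over_echo_delay(self, acq):
        # at the echo (k=0) the shift phase is zero; J and T2 are not reset
        spec = SpinSignalSpec(1.0, 500.0, 0.3, ((8.0, 1),))
        tau2 = 0.04
        fid = simulate_fid(spec, acq, tau2)
        expected0 = np.exp(-tau2 / 0.3) * np.cos(np.pi * 8.0 * tau2)
        assert fid.samples[0] == pytest.approx(expected0, rel=1e-12)
        assert fid.samples[0].imag == 0.0

    def test_invalid_parameters_rejected(self, acq):
        with pytest.raises(ValueError):
            SpinSignalSpec(1.0, 0.0, -0.5)
        with pytest.raises(ValueError):
            SpinSignalSpec(0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            SpinSignalSpec(1.0, 0.0, 0.5, ((-3.0, 1),))
        with pytest.raises(ValueError):
            simulate_fid(SpinSignalSpec(1.0, 0.0, 0.5), acq, -0.01)


class TestFidToSpectrum:
    def test_zero_fid_gives_zero_spectrum(self, acq):
        sp = fid_to_spectrum(ComplexFid(np.zeros(acq.np_points)), acq)
        assert not sp.values.any()

    def test_singlet_argmax_at_nearest_grid_point(self, acq):
        spec = SpinSignalSpec(1.0, 100.0, 0.5)
        sp = fid_to_spectrum(simulate_fid(spec, acq, 0.0), acq)
        k = int(np.argmax(np.abs(sp.values)))
        assert sp.freq_axis_hz[k] == pytest.approx(100.0, abs=acq.sw_hz / acq.np_points)

    def test_linearity(self, acq, rng):
        x = rng.normal(size=acq.np_points) + 1j * rng.normal(size=acq.np_points)
        y = rng.normal(size=acq.np_points) + 1j * rng.normal(size=acq.np_points)
        lhs = fid_to_spectrum(ComplexFid(2.5 * x - 1.5j * y), acq).values
        rhs = (2.5 * fid_to_spectrum(ComplexFid(x), acq).values
               - 1.5j * fid_to_spectrum(ComplexFid(y), acq).values)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_length_mismatch_rejected(self, acq):
        with pytest.raises(ValueError):
            fid_to_spectrum(ComplexFid(np.zeros(100)), acq)


class TestEchoSeries:
    def test_singlet_peak_stays_positive_and_decays_with_t2(self, acq):
        t2 = 0.4
        spec = SpinSignalSpec(1.0, 200.0, t2)
        series = simulate_echo_series([spec], acq)
        k = int(acq.hz_to_index(200.0))
        heights = [s.values.real[k] for s in series.spectra]
        assert all(h > 0 for h in heights)
        for a, b in zip(acq.echo_times_s, acq.echo_times_s[1:]):
            i, j = acq.echo_times_s.index(a), acq.echo_times_s.index(b)
            ratio = heights[j] / heights[i]
            assert ratio == pytest.approx(np.exp(-(b - a) / t2), rel=0.01)

    def test_doublet_components_follow_j_modulation_sign(self):
        # the doublet components at f ± J/2 carry the echo phase e^{±iπJ·2τ}:
        # absorptive-positive at 2τ=0, dispersive (null on center) at
        # 2τ = 1/(2J), inverted at 2τ = 1/J
        j = 10.0
        acq = AcquisitionParams(echo_times_s=(0.0, 0.05, 0.1))
        spec = SpinSignalSpec(1.0, 300.0, 0.5, ((j, 1),))
        series = simulate_echo_series([spec], acq)
        k_lo = int(acq.hz_to_index(300.0 - j / 2))
        k_hi = int(acq.hz_to_index(300.0 + j / 2))
        h = [(s.values.real[k_lo], s.values.real[k_hi]) for s in series.spectra]
        assert h[0][0] > 0 and h[0][1] > 0
        assert abs(h[1][0]) < 0.05 * h[0][0] and abs(h[1][1]) < 0.05 * h[0][1]
        assert h[2][0] < 0 and h[2][1] < 0

    def test_multi_signal_series_is_sum_of_singles(self, acq_small):
        s1 = SpinSignalSpec(1.0, -100.0, 0.3, ((7.0, 1),))
        s2 = SpinSignalSpec(0.5, 200.0, 0.2)
        both = simulate_echo_series([s1, s2], acq_small)
        only1 = simulate_echo_series([s1], acq_small)
        only2 = simulate_echo_series([s2], acq_small)
        for b, a, c in zip(both.spectra, only1.spectra, only2.spectra):
            np.testing.assert_allclose(b.values, a.values + c.values, rtol=1e-12)

    def test_empty_spec_list_gives_zero_series(self, acq_small):
        series = simulate_echo_series([], acq_small)
        assert not any(s.values.any() for s in series.spectra)


class TestNoise:
    def test_zero_sd_is_identity(self, acq_small):
        series = simulate_echo_series([SpinSignalSpec(1.0, 0.0, 0.3)], acq_small)
        out = add_noise(series, 0.0, 1)
        for a, b in zip(series.spectra, out.spectra):
            np.testing.assert_array_equal(a.values, b.values)

    def test_fixed_seed_reproducible(self, acq_small):
        series = simulate_echo_series([], acq_small)
        a = add_noise(series, 2.0, 99)
        b = add_noise(series, 2.0, 99)
        for x, y in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(x.values, y.values)

    def test_sample_sd_matches_request(self, acq):
        series = simulate_echo_series([], acq)
        out = add_noise(series, 3.0, 7)
        sd = out.spectra[0].values.real.std()
        assert sd == pytest.approx(3.0, rel=0.05)

    def test_negative_sd_rejected(self, acq_small):
        with pytest.raises(ValueError):
            add_noise(simulate_echo_series([], acq_small), -1.0, 0)


class TestPhaseDistortion:
    def test_zero_rotation_is_identity(self, acq_small):
        series = simulate_echo_series([SpinSignalSpec(1.0, 10.0, 0.3)], acq_small)
        out = apply_phase_distortion(series, 0.0)
        for a, b in zip(series.spectra, out.spectra):
            np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_rotations_compose_mod_2pi(self, acq_small):
        series = simulate_echo_series([SpinSignalSpec(1.0, 10.0, 0.3)], acq_small)
        out = apply_phase_distortion(apply_phase_distortion(series, np.pi), np.pi)
        for a, b in zip(series.spectra, out.spectra):
            np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-9)

    def test_quarter_turn_makes_dispersive_lineshape(self, acq):
        spec = SpinSignalSpec(1.0, 0.0, 0.5)
        series = simulate_echo_series([spec], acq)
        out = apply_phase_distortion(series, np.pi / 2)
        real = out.spectra[0].values.real
        k = int(acq.hz_to_index(0.0))
        # dispersive: antisymmetric about the line center, near-zero on it
        assert abs(real[k]) < 0.05 * np.abs(real).max()
        assert np.sign(real[k - 3]) != np.sign(real[k + 3])


class TestABSystem:
    def test_j_zero_gives_two_equal_lines_at_delta(self, acq):
        ab = ABSystemSpec(center_hz=0.0, delta_hz=200.0, j_hz=0.0)
        sp = fid_to_spectrum(simulate_ab_fid(ab, acq, 0.0), acq)
        k_lo = int(acq.hz_to_index(-100.0))
        k_hi = int(acq.hz_to_index(100.0))
        assert sp.values.real[k_lo] == pytest.approx(sp.values.real[k_hi], rel=1e-9)
        assert ab.alpha == 0.0

    def test_delta_equals_j_line_weights(self):
        # Δν = J: D = √2·J, α = 1/√2, weights 1 ± 1/√2
        ab = ABSystemSpec(center_hz=0.0, delta_hz=10.0, j_hz=10.0)
        assert ab.alpha == pytest.approx(1 / np.sqrt(2))
        assert ab.d_hz == pytest.approx(np.sqrt(2) * 10.0)

    def test_degenerate_limit_outer_lines_vanish(self, acq):
        # sharp lines (T2 = 2 s) so Lorentzian tails do not mask the weights
        ab = ABSystemSpec(center_hz=0.0, delta_hz=1e-6, j_hz=12.0, t2_s=2.0)
        assert ab.alpha == pytest.approx(1.0, abs=1e-9)
        sp = fid_to_spectrum(simulate_ab_fid(ab, acq, 0.0), acq)
        # inner pair collapses onto the center at ±(D−J)/2 → 0; the outer
        # pair at ±(D+J)/2 = ±J carries weight 1 − J/D → 0
        inner = np.abs(sp.values.real[int(acq.hz_to_index(0.0))])
        outer = np.abs(sp.values.real[int(acq.hz_to_index(-12.0))])
        assert outer < 1e-3 * inner

    def test_degenerate_system_rejected(self, acq):
        with pytest.raises(ValueError):
            simulate_ab_fid(ABSystemSpec(0.0, 0.0, 0.0), acq, 0.0)

    @staticmethod
    def _ab_residual(acq, j, ratio, t2=0.3):
        """Max |AB − weak-coupling pair| over peak height at 2τ = 0.

        The reference doublet pair sits at the apparent shifts ± D/2 (D → Δν
        in the weak limit), the standard AB → AX convergence statement; the
        remaining difference is the roofing weight asymmetry of order
        α = J/D plus Lorentzian-tail cross terms.
        """
        delta = ratio * j
        ab = ABSystemSpec(0.0, delta, j, t2_s=t2)
        d = ab.d_hz
        weak = [
            SpinSignalSpec(1.0, -d / 2, t2, ((j, 1),)),
            SpinSignalSpec(1.0, +d / 2, t2, ((j, 1),)),
        ]
        a = fid_to_spectrum(simulate_ab_fid(ab, acq, 0.0), acq).values.real
        fid = (simulate_fid(weak[0], acq, 0.0).samples
               + simulate_fid(weak[1], acq, 0.0).samples)
        b = fid_to_spectrum(ComplexFid(fid), acq).values.real
        peak = max(np.abs(a).max(), np.abs(b).max())
        return np.abs(a - b).max() / peak

    def test_weak_coupling_convergence_to_doublet_pair(self, acq):
        # Δν/J = 100: residual below 1% of peak height, and shrinking
        # further as the shift difference grows
        r100 = self._ab_residual(acq, j=7.0, ratio=100)
        r_far = self._ab_residual(acq, j=2.0, ratio=500)
        assert r100 < 0.01
        assert r_far < r100 / 2


class TestWsn:
    def test_definition_arithmetic(self):
        values = np.zeros(100, dtype=complex)
        values[10] = 8.0  # weakest signal height 8
        values[30] = 20.0
        noise = np.zeros(100)
        noise[60:100] = [2.0, -2.0] * 20  # sd = 2
        sp = Spectrum(values + noise, np.arange(100, dtype=float))
        wsn = compute_wsn(sp, [(5, 15), (25, 35)], (60, 100))
        assert wsn == pytest.approx(8.0 / 2.0)

    def test_scale_invariance(self, acq_small, rng):
        series = add_noise(
            simulate_echo_series([SpinSignalSpec(1.0, 100.0, 0.3)], acq_small), 1.0, 3
        )
        sp = series.spectra[0]
        k = int(acq_small.hz_to_index(100.0))
        args = ([(k - 10, k + 10)], (50, 400))
        a = compute_wsn(sp, *args)
        b = compute_wsn(Spectrum(7.0 * sp.values, sp.freq_axis_hz), *args)
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_brute_force_recomputation(self, acq_small):
        series = add_noise(
            simulate_echo_series([SpinSignalSpec(1.0, 100.0, 0.3)], acq_small), 2.0, 11
        )
        sp = series.spectra[0]
        k = int(acq_small.hz_to_index(100.0))
        regions, noise = [(k - 10, k + 10)], (50, 400)
        expected = min(sp.values.real[a:b].max() for a, b in regions)
        expected /= np.std(sp.values.real[noise[0]:noise[1]])
        assert compute_wsn(sp, regions, noise) == pytest.approx(expected, rel=1e-12)

    def test_overlapping_regions_rejected(self, acq_small):
        sp = simulate_echo_series([SpinSignalSpec(1.0, 0.0, 0.3)], acq_small).spectra[0]
        with pytest.raises(ValueError):
            compute_wsn(sp, [(100, 200)], (150, 300))


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_noise_determinism_property(seed):
    acq = AcquisitionParams(np_points=128, sw_hz=128.0, echo_times_s=(0.0, 0.02))
    series = simulate_echo_series([], acq)
    a = add_noise(series, 1.0, seed)
    b = add_noise(series, 1.0, seed)
    for x, y in zip(a.spectra, b.spectra):
        np.testing.assert_array_equal(x.values, y.values)


class TestSeriesIO:
    def test_hdf5_round_trip(self, acq_small, tmp_path):
        from echoshift import load_series_hdf5, save_series_hdf5

        series = add_noise(
            simulate_echo_series([SpinSignalSpec(1.0, 50.0, 0.3, ((7.0, 1),))],
                                 acq_small), 1.0, 5)
        path = tmp_path / "series.h5"
        save_series_hdf5(series, path)
        loaded = load_series_hdf5(path)
        assert loaded.acq == acq_small
        for a, b in zip(series.spectra, loaded.spectra):
            np.testing.assert_array_equal(a.values, b.values)

    def test_csv_round_trip(self, acq_small, tmp_path):
        from echoshift.physics import spectrum_from_csv, spectrum_to_csv

        sp = simulate_echo_series([SpinSignalSpec(1.0, 50.0, 0.3)],
                                  acq_small).spectra[0]
        path = tmp_path / "spec.csv"
        spectrum_to_csv(sp, path)
        loaded = spectrum_from_csv(path, sp.freq_axis_hz)
        np.testing.assert_allclose(loaded.values, sp.values, rtol=1e-6, atol=1e-9)
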