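"""Analytic simulation of J-modulated spin-echo ¹H NMR spectra.

In a spin echo (90°–τ–180°–τ–acquire) the chemical shift is refocused at the
echo and then evolves only during acquisition, while transverse relaxation
and scalar (J) coupling evolve for the whole delay-plus-acquisition period.
For a weakly coupled resonance the complex signal is

    s(k) = A · exp(i·2π·f·t1_k) · exp(−t2_k / T2) · Π_m cos(π·J_m·t2_k)^pow_m

with t1_k = k/SW (shift evolution, restarted at the echo) and
t2_k = 2τ + k/SW (relaxation and J evolution, running since excitation).
Varying the echo time 2τ therefore leaves singlets in phase but rotates the
phases of multiplet components — the feature a downstream detector exploits.

Strong coupling of two spins (an AB system) is modelled analytically through
its four-line pattern with roofing weights; artifacts beyond the two-spin
analytic treatment are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SpinSignalSpec",
    "ABSystemSpec",
    "ComplexFid",
    "Spectrum",
    "EchoSeries",
    "simulate_fid",
    "fid_to_spectrum",
    "simulate_echo_series",
    "add_noise",
    "apply_phase_distortion",
    "simulate_ab_fid",
    "simulate_ab_series",
    "compute_wsn",
    "default_echo_times",
    "save_series_hdf5",
    "load_series_hdf5",
    "spectrum_to_csv",
    "spectrum_from_csv",
]

DEFAULT_NP_POINTS = 4096
DEFAULT_SW_HZ = 4096.0
DEFAULT_SPECTROMETER_MHZ = 500.0
DEFAULT_CARRIER_PPM = 4.7


def default_echo_times(n: int = 8, step_s: float = 0.02) -> tuple[float, ...]:
    """Echo times 2τ = 0, step, 2·step, …  (8 × 0.02 s by default).

    A 0.02 s increment sweeps cos(π·J·2τ) through about a full cycle for a
    typical J ≈ 7 Hz over the 8-spectrum series.
    """
    return tuple(step_s * k for k in range(n))


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings shared by every spectrum of an echo series.

    np_points : complex samples per FID (spectra have the same length)
    sw_hz : spectral width in Hz; dwell time is 1/sw_hz
    spectrometer_mhz : proton Larmor frequency, for Hz → ppm conversion
    echo_times_s : ordered echo times 2τ in seconds, first one 0
    carrier_ppm : chemical shift at the centre of the spectrum
    """

    np_points: int = DEFAULT_NP_POINTS
    sw_hz: float = DEFAULT_SW_HZ
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ
    echo_times_s: tuple[float, ...] = field(default_factory=default_echo_times)
    carrier_ppm: float = DEFAULT_CARRIER_PPM

    def __post_init__(self) -> None:
        if self.np_points <= 0:
            raise ValueError("np_points must be positive")
        if not self.sw_hz > 0:
            raise ValueError("sw_hz must be positive")
        if self.spectrometer_mhz <= 0:
            raise ValueError("spectrometer_mhz must be positive")
        et = tuple(float(t) for t in self.echo_times_s)
        if len(et) == 0:
            raise ValueError("echo_times_s must be non-empty")
        if et[0] != 0.0:
            raise ValueError("first echo time must be 0 s")
        if any(b <= a for a, b in zip(et, et[1:])):
            raise ValueError("echo_times_s must be strictly increasing")
        object.__setattr__(self, "echo_times_s", et)

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_s)

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sw_hz

    @property
    def freq_axis_hz(self) -> np.ndarray:
        """Frequency grid −sw/2 … +sw/2 (exclusive), step sw/np; 0 Hz at np/2."""
        n = self.np_points
        return (np.arange(n) - n // 2) * (self.sw_hz / n)

    def index_to_hz(self, index) -> np.ndarray:
        return (np.asarray(index) - self.np_points // 2) * (self.sw_hz / self.np_points)

    def hz_to_index(self, freq_hz) -> np.ndarray:
        """Nearest grid bin for an offset in Hz (used for labels and peak refs)."""
        idx = np.rint(np.asarray(freq_hz) / (self.sw_hz / self.np_points)) + self.np_points // 2
        return idx.astype(int)

    def hz_to_ppm(self, freq_hz) -> np.ndarray:
        return self.carrier_ppm + np.asarray(freq_hz) / self.spectrometer_mhz


@dataclass(frozen=True)
class SpinSignalSpec:
    """One weakly coupled resonance.

    couplings is a list of (J_hz, pow) pairs, one per distinct group of
    coupled protons; pow counts the equivalent spins in the group.  An empty
    list is a singlet.
    """

    amplitude: float
    freq_hz: float
    t2_s: float
    couplings: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.t2_s <= 0:
            raise ValueError("t2_s must be positive")
        cps = tuple((float(j), int(p)) for j, p in self.couplings)
        for j, p in cps:
            if j < 0:
                raise ValueError("J must be non-negative")
            if p < 1:
                raise ValueError("pow must be a positive integer")
        object.__setattr__(self, "couplings", cps)

    @property
    def linewidth_hz(self) -> float:
        return 1.0 / (np.pi * self.t2_s)


@dataclass(frozen=True)
class ABSystemSpec:
    """Two-spin strong-coupling (AB) system.

    delta_hz is the chemical-shift difference Δν of the two spins, j_hz the
    coupling.  The roofing factor is α = J/√(Δν² + J²): 0 in the weak limit,
    1 when the shifts are degenerate.
    """

    center_hz: float
    delta_hz: float
    j_hz: float
    amplitude: float = 1.0
    t2_s: float = 0.3

    def __post_init__(self) -> None:
        if self.delta_hz < 0 or self.j_hz < 0:
            raise ValueError("delta_hz and j_hz must be non-negative")
        if self.amplitude <= 0 or self.t2_s <= 0:
            raise ValueError("amplitude and t2_s must be positive")

    @property
    def d_hz(self) -> float:
        return float(np.hypot(self.delta_hz, self.j_hz))

    @property
    def alpha(self) -> float:
        d = self.d_hz
        if d == 0:
            raise ValueError("degenerate AB system: delta_hz = j_hz = 0")
        return self.j_hz / d

    @property
    def shift_positions_hz(self) -> tuple[float, float]:
        """The two true chemical shifts, center ± Δν/2."""
        return (self.center_hz - self.delta_hz / 2, self.center_hz + self.delta_hz / 2)


@dataclass(frozen=True)
class ComplexFid:
    """Complex time-domain signal; t_start_s is the first sample's t2."""

    samples: np.ndarray
    t_start_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=complex))


@dataclass(frozen=True)
class Spectrum:
    values: np.ndarray
    freq_axis_hz: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        f = np.asarray(self.freq_axis_hz, dtype=float)
        if v.shape != f.shape:
            raise ValueError("values and freq_axis_hz must have equal length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "freq_axis_hz", f)


@dataclass(frozen=True)
class EchoSeries:
    """One spectrum per echo time, all on the same frequency grid."""

    spectra: tuple[Spectrum, ...]
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        sp = tuple(self.spectra)
        if len(sp) != self.acq.n_echoes:
            raise ValueError("need one spectrum per echo time")
        for s in sp:
            if len(s.values) != self.acq.np_points:
                raise ValueError("spectrum length must equal np_points")
        object.__setattr__(self, "spectra", sp)

    def real_stack(self) -> np.ndarray:
        """(n_echoes, np_points) array of the real parts."""
        return np.stack([s.values.real for s in self.spectra])

    def complex_stack(self) -> np.ndarray:
        return np.stack([s.values for s in self.spectra])


# ----------------------------------------------------------------------------
# FID simulation
# ----------------------------------------------------------------------------

def _time_grids(acq: AcquisitionParams, echo_time_s: float) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(acq.np_points)
    t1 = k / acq.sw_hz
    t2 = echo_time_s + t1
    return t1, t2


def _cospi(y) -> np.ndarray:
    """cos(π·y) with exact zeros at half-integer y (echo-null condition)."""
    out = np.cos(np.pi * np.asarray(y))
    out[np.mod(y, 1.0) == 0.5] = 0.0
    return out


def _sinpi(y) -> np.ndarray:
    """sin(π·y) with exact zeros at integer y."""
    out = np.sin(np.pi * np.asarray(y))
    out[np.mod(y, 1.0) == 0.0] = 0.0
    return out


def simulate_fid(spec: SpinSignalSpec, acq: AcquisitionParams, echo_time_s: float) -> ComplexFid:
    """Spin-echo FID of one weakly coupled resonance at echo time 2τ.

    Chemical shift evolves over t1 = k/SW only (refocused at the echo);
    relaxation and J modulation evolve over t2 = 2τ + k/SW.  At 2τ = 0 the
    two grids coincide and the FID equals a conventional single-pulse FID.
    """
    if echo_time_s < 0:
        raise ValueError("echo_time_s must be non-negative")
    t1, t2 = _time_grids(acq, echo_time_s)
    s = spec.amplitude * np.exp(2j * np.pi * spec.freq_hz * t1) * np.exp(-t2 / spec.t2_s)
    for j_hz, pow_ in spec.couplings:
        s = s * _cospi(j_hz * t2) ** pow_
    return ComplexFid(samples=s, t_start_s=echo_time_s)


def simulate_ab_fid(ab: ABSystemSpec, acq: AcquisitionParams, echo_time_s: float) -> ComplexFid:
    """Spin-echo FID of a two-spin AB system.

    With D = √(Δν² + J²) the four lines sit at center ± D/2 ± J/2 with
    roofing weights 1 ∓ J/D (outer lines weak, inner strong).  The D/2 part
    behaves as a chemical shift (evolves over t1, refocused), the ±J/2 part
    as a coupling (evolves over t2), so the weak-coupling limit D → Δν
    reproduces the cos(πJ·t2) doublet pair exactly, echo phases included.
    """
    if echo_time_s < 0:
        raise ValueError("echo_time_s must be non-negative")
    d = ab.d_hz
    if d == 0:
        raise ValueError("degenerate AB system: delta_hz = j_hz = 0")
    t1, t2 = _time_grids(acq, echo_time_s)
    decay = np.exp(-t2 / ab.t2_s)
    s = np.zeros(acq.np_points, dtype=complex)
    for sign_d in (-1.0, 1.0):
        shift_part = ab.center_hz + sign_d * d / 2
        for sign_j in (-1.0, 1.0):
            weight = 1.0 - sign_d * sign_j * ab.j_hz / d
            s += (
                (ab.amplitude / 2)
                * weight
                * np.exp(2j * np.pi * shift_part * t1)
                * np.exp(1j * np.pi * sign_j * ab.j_hz * t2)
            )
    return ComplexFid(samples=s * decay, t_start_s=echo_time_s)


# ----------------------------------------------------------------------------
# Fourier transform and series assembly
# ----------------------------------------------------------------------------

def fid_to_spectrum(fid: ComplexFid, acq: AcquisitionParams) -> Spectrum:
    """Discrete Fourier transform with 0 Hz at index np/2.

    The first FID point is halved before the transform (standard practice to
    suppress the constant baseline offset of a Lorentzian).  The transform is
    linear, so multi-signal spectra are sums of single-signal spectra.
    """
    samples = np.asarray(fid.samples, dtype=complex)
    if len(samples) != acq.np_points:
        raise ValueError(
            f"FID length {len(samples)} does not match np_points {acq.np_points}"
        )
    x = samples.copy()
    x[0] *= 0.5
    values = np.fft.fftshift(np.fft.fft(x))
    return Spectrum(values=values, freq_axis_hz=acq.freq_axis_hz)


def _summed_series_fids(specs: Sequence[SpinSignalSpec],
                        acq: AcquisitionParams) -> np.ndarray:
    """(n_echoes, np) summed FIDs for all echo times at once.

    Exploits t2 = 2τ + t1: the acquisition-time factors are computed once per
    signal and each echo contributes only scalar weights, via
    cos(πJ·t2) = cos(πJ·t1)·cos(πJ·2τ) − sin(πJ·t1)·sin(πJ·2τ) and
    exp(−t2/T2) = exp(−2τ/T2)·exp(−t1/T2).  Matches the per-signal
    simulate_fid route to rounding error (asserted by the linearity tests).
    """
    t1 = np.arange(acq.np_points) / acq.sw_hz
    taus = np.asarray(acq.echo_times_s)
    out = np.zeros((len(taus), acq.np_points), dtype=complex)
    for s in specs:
        base = s.amplitude * np.exp((2j * np.pi * s.freq_hz - 1.0 / s.t2_s) * t1)
        echo_amp = np.exp(-taus / s.t2_s)
        mods = np.ones((len(taus), acq.np_points))
        for j_hz, pow_ in s.couplings:
            c1, s1 = _cospi(j_hz * t1), _sinpi(j_hz * t1)
            ce, se = _cospi(j_hz * taus), _sinpi(j_hz * taus)
            term = ce[:, None] * c1[None, :] - se[:, None] * s1[None, :]
            for _ in range(pow_):
                mods *= term
        out += (echo_amp[:, None] * mods) * base[None, :]
    return out


def simulate_echo_series(
    specs: Sequence[SpinSignalSpec],
    acq: AcquisitionParams,
    ab_systems: Sequence[ABSystemSpec] = (),
) -> EchoSeries:
    """Noise-free echo series of the summed signals (may be empty → zeros)."""
    fids = _summed_series_fids(specs, acq)
    spectra = []
    for k, tau2 in enumerate(acq.echo_times_s):
        fid = fids[k]
        for ab in ab_systems:
            fid = fid + simulate_ab_fid(ab, acq, tau2).samples
        spectra.append(fid_to_spectrum(ComplexFid(fid, tau2), acq))
    return EchoSeries(spectra=tuple(spectra), acq=acq)


def simulate_ab_series(ab: ABSystemSpec, acq: AcquisitionParams) -> EchoSeries:
    return simulate_echo_series([], acq, ab_systems=[ab])


# ----------------------------------------------------------------------------
# Noise and phase distortion
# ----------------------------------------------------------------------------

def add_noise(series: EchoSeries, noise_sd: float, rng_seed: int) -> EchoSeries:
    """Add i.i.d. complex Gaussian noise (sd per real/imag channel) per point.

    Frequency-domain white noise; equivalent to time-domain white noise up to
    the DFT scaling.  Reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return series
    rng = np.random.default_rng(rng_seed)
    spectra = []
    for s in series.spectra:
        noise = rng.normal(scale=noise_sd, size=(2, len(s.values)))
        spectra.append(Spectrum(s.values + noise[0] + 1j * noise[1], s.freq_axis_hz))
    return EchoSeries(spectra=tuple(spectra), acq=series.acq)


def apply_phase_distortion(series: EchoSeries, r: float, first_order: float = 0.0) -> EchoSeries:
    """Rotate every spectrum by exp(i·φ(ν)).

    Zero-order by default: φ = r everywhere.  With first_order ≠ 0 a linear
    term is added, φ(ν) = r + first_order · ν/(sw/2).
    """
    if not np.isfinite(r) or not np.isfinite(first_order):
        raise ValueError("phase parameters must be finite")
    spectra = []
    for s in series.spectra:
        phi = r + first_order * s.freq_axis_hz / (series.acq.sw_hz / 2)
        spectra.append(Spectrum(s.values * np.exp(1j * phi), s.freq_axis_hz))
    return EchoSeries(spectra=tuple(spectra), acq=series.acq)


# ----------------------------------------------------------------------------
# Weakest signal-to-noise ratio
# ----------------------------------------------------------------------------

def compute_wsn(
    spectrum: Spectrum,
    signal_regions: Sequence[tuple[int, int]],
    noise_region: tuple[int, int],
) -> float:
    """Weakest signal height divided by the noise standard deviation.

    Heights are maxima of the real part over each signal region; the noise sd
    is the standard deviation of the real part over a signal-free region.
    Scale-invariant by construction.
    """
    n = len(spectrum.values)
    lo, hi = noise_region
    if not (0 <= lo < hi <= n):
        raise ValueError("noise_region out of bounds or empty")
    if not signal_regions:
        raise ValueError("need at least one signal region")
    real = spectrum.values.real
    heights = []
    for a, b in signal_regions:
        if not (0 <= a < b <= n):
            raise ValueError("signal region out of bounds or empty")
        if max(a, lo) < min(b, hi):
            raise ValueError("signal region overlaps the noise region")
        heights.append(real[a:b].max())
    noise_sd = real[lo:hi].std()
    if noise_sd == 0:
        raise ValueError("noise region has zero standard deviation; wS/N undefined")
    return float(min(heights) / noise_sd)


# ----------------------------------------------------------------------------
# Series and spectrum I/O (HDF5 with paired real/imag arrays; 2-column CSV)
# ----------------------------------------------------------------------------

def save_series_hdf5(series: EchoSeries, path) -> None:
    """Write an echo series: /real and /imag (n_echoes × np) plus the
    acquisition settings as attributes."""
    import dataclasses
    import json

    import h5py

    stack = series.complex_stack()
    with h5py.File(str(path), "w") as f:
        f.create_dataset("real", data=stack.real)
        f.create_dataset("imag", data=stack.imag)
        f.attrs["acq"] = json.dumps(dataclasses.asdict(series.acq))


def load_series_hdf5(path) -> EchoSeries:
    import json

    import h5py

    with h5py.File(str(path), "r") as f:
        acq_dict = json.loads(f.attrs["acq"])
        acq_dict["echo_times_s"] = tuple(acq_dict["echo_times_s"])
        acq = AcquisitionParams(**acq_dict)
        values = f["real"][...] + 1j * f["imag"][...]
    spectra = tuple(Spectrum(v, acq.freq_axis_hz) for v in values)
    return EchoSeries(spectra=spectra, acq=acq)


def spectrum_to_csv(spectrum: Spectrum, path) -> None:
    """Two columns (real, imag), one row per frequency point."""
    np.savetxt(str(path),
               np.column_stack([spectrum.values.real, spectrum.values.imag]),
               delimiter=",", header="real,imag", comments="")


def spectrum_from_csv(path, freq_axis_hz=None) -> Spectrum:
    data = np.loadtxt(str(path), delimiter=",", skiprows=1)
    values = data[:, 0] + 1j * data[:, 1]
    if freq_axis_hz is None:
        n = len(values)
        freq_axis_hz = (np.arange(n) - n // 2) * 1.0
    return Spectrum(values, np.asarray(freq_axis_hz, dtype=float))
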