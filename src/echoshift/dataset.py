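"""Synthetic training data: randomized spin systems → echo stacks + labels.

Each sample is a full spin-echo experiment on a random mixture: 1–20
resonances with random shifts, amplitudes, relaxation times and multiplet
structure, optionally a dominant solvent-like singlet, optional zero-order
phase distortion, and complex Gaussian noise scaled to a target weakest
signal-to-noise ratio (wS/N).  The network input is the real part of the
eight echo spectra, normalized so the 2τ = 0 spectrum has unit maximum
amplitude; the target is a 0/1 vector with a single 1 at the grid bin of
each signal's chemical shift.

Generation is fully determined by a master seed: sample i uses
``np.random.SeedSequence([master_seed, i])``, so any sample — and the whole
file — can be regenerated bit-for-bit from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import h5py
import numpy as np
import yaml

from .physics import (
    ABSystemSpec,
    AcquisitionParams,
    EchoSeries,
    SpinSignalSpec,
    add_noise,
    apply_phase_distortion,
    simulate_echo_series,
)

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

__all__ = [
    "ParameterRanges",
    "DatasetManifest",
    "SampleRecord",
    "sample_spin_systems",
    "make_label",
    "normalize_input",
    "generate_sample",
    "generate_dataset",
    "SpectraDataset",
]


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges for the random spin systems.

    Frequencies are drawn uniformly over the central ``freq_fraction`` of the
    spectral width.  The target wS/N is drawn log-uniformly (weak-signal
    cases are as common as easy ones on a log scale).  A ``solvent_fraction``
    of samples gain one large singlet whose amplitude is a log-uniform
    multiple of the strongest ordinary signal.  ``ab_fraction`` controls how
    many samples contain a strongly coupled two-spin system (off by default:
    the detector is trained on weakly coupled spectra only and strong
    coupling is handled through the phase-distortion augmentation).
    """

    amplitude: tuple[float, float] = (0.05, 1.0)
    t2_s: tuple[float, float] = (0.015, 1.0)
    n_signals: tuple[int, int] = (1, 20)
    n_couplings: tuple[int, int] = (0, 3)
    j_hz: tuple[float, float] = (2.0, 18.0)
    pow_range: tuple[int, int] = (1, 3)
    freq_fraction: float = 0.9
    wsn: tuple[float, float] = (3.0, 200.0)
    phase_r: tuple[float, float] = (-1.0, 1.0)
    phase_fraction: float = 0.5
    solvent_fraction: float = 0.2
    solvent_amplitude: tuple[float, float] = (10.0, 300.0)
    ab_fraction: float = 0.0
    ab_alpha: tuple[float, float] = (0.1, 0.74)

    def __post_init__(self) -> None:
        for name in ("amplitude", "t2_s", "j_hz", "wsn", "phase_r",
                     "solvent_amplitude", "n_signals", "n_couplings",
                     "pow_range", "ab_alpha"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
        if not 0 < self.freq_fraction <= 1:
            raise ValueError("freq_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DatasetManifest:
    """Everything needed to regenerate a dataset file bit-for-bit."""

    n_samples: int
    seed: int
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    format_version: int = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def split_slices(self) -> dict[str, slice]:
        n = self.n_samples
        n_train = int(round(n * self.split_fractions[0]))
        n_val = int(round(n * self.split_fractions[1]))
        n_val = min(n_val, n - n_train)
        return {
            "train": slice(0, n_train),
            "val": slice(n_train, n_train + n_val),
            "test": slice(n_train + n_val, n),
        }

    def to_dict(self) -> dict:
        return {
            "format_version": self.format_version,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "split_fractions": list(self.split_fractions),
            "ranges": dataclasses.asdict(self.ranges),
            "acq": dataclasses.asdict(self.acq),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        ranges = d.get("ranges", {})
        for key in ("amplitude", "t2_s", "j_hz", "wsn", "phase_r",
                    "solvent_amplitude", "n_signals", "n_couplings",
                    "pow_range", "ab_alpha"):
            if key in ranges:
                ranges[key] = tuple(ranges[key])
        acq = d.get("acq", {})
        if "echo_times_s" in acq:
            acq["echo_times_s"] = tuple(acq["echo_times_s"])
        return cls(
            n_samples=d["n_samples"],
            seed=d["seed"],
            split_fractions=tuple(d.get("split_fractions", (0.8, 0.1, 0.1))),
            ranges=ParameterRanges(**ranges),
            acq=AcquisitionParams(**acq),
            format_version=d.get("format_version", FORMAT_VERSION),
        )


@dataclass
class SampleRecord:
    """One training example: normalized echo stack, 0/1 label, provenance."""

    input_stack: np.ndarray  # float32, (n_echoes, np_points)
    label: np.ndarray  # uint8, (np_points,)
    metadata: dict


# ----------------------------------------------------------------------------
# Random spin systems
# ----------------------------------------------------------------------------

def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_spin_systems(
    ranges: ParameterRanges,
    rng_seed,
    sw_hz: float = 4096.0,
    default_j_hz: float = 7.0,
) -> tuple[list[SpinSignalSpec], list[ABSystemSpec]]:
    """Draw one random mixture of resonances (and possibly one AB system).

    ``rng_seed`` may be an int, a SeedSequence or a Generator.  Frequencies
    are uniform over the central ``freq_fraction`` of the width; a solvent
    singlet, when present, multiplies the strongest drawn amplitude by a
    log-uniform factor.
    """
    rng = np.random.default_rng(rng_seed)
    f_half = ranges.freq_fraction * sw_hz / 2
    n = int(rng.integers(ranges.n_signals[0], ranges.n_signals[1] + 1))
    specs: list[SpinSignalSpec] = []
    for _ in range(n):
        n_coup = int(rng.integers(ranges.n_couplings[0], ranges.n_couplings[1] + 1))
        couplings = tuple(
            (float(rng.uniform(*ranges.j_hz)),
             int(rng.integers(ranges.pow_range[0], ranges.pow_range[1] + 1)))
            for _ in range(n_coup)
        )
        specs.append(
            SpinSignalSpec(
                amplitude=float(rng.uniform(*ranges.amplitude)),
                freq_hz=float(rng.uniform(-f_half, f_half)),
                t2_s=float(rng.uniform(*ranges.t2_s)),
                couplings=couplings,
            )
        )
    if rng.random() < ranges.solvent_fraction:
        factor = _loguniform(rng, *ranges.solvent_amplitude)
        strongest = max(s.amplitude for s in specs)
        specs.append(
            SpinSignalSpec(
                amplitude=strongest * factor,
                freq_hz=float(rng.uniform(-f_half, f_half)),
                t2_s=float(rng.uniform(*ranges.t2_s)),
                couplings=(),
            )
        )
    ab_systems: list[ABSystemSpec] = []
    if rng.random() < ranges.ab_fraction:
        alpha = float(rng.uniform(*ranges.ab_alpha))
        j_hz = float(rng.uniform(*ranges.j_hz))
        # alpha = J/D  =>  D = J/alpha, delta = sqrt(D^2 - J^2)
        delta = j_hz * np.sqrt(max(1.0 / alpha**2 - 1.0, 0.0))
        ab_systems.append(
            ABSystemSpec(
                center_hz=float(rng.uniform(-f_half, f_half)),
                delta_hz=float(delta),
                j_hz=j_hz,
                amplitude=float(rng.uniform(*ranges.amplitude)),
                t2_s=float(rng.uniform(*ranges.t2_s)),
            )
        )
    return specs, ab_systems


# ----------------------------------------------------------------------------
# Labels and input normalization
# ----------------------------------------------------------------------------

def make_label(
    specs: Sequence[SpinSignalSpec],
    acq: AcquisitionParams,
    ab_systems: Sequence[ABSystemSpec] = (),
) -> np.ndarray:
    """0/1 vector with a 1 at the grid bin of each signal's chemical shift.

    AB systems contribute their two true shifts (center ± Δν/2).  Signals
    whose shifts round to the same bin collapse to a single 1; the collision
    is logged and reflected in the returned vector's sum.
    """
    freqs = [s.freq_hz for s in specs]
    for ab in ab_systems:
        freqs.extend(ab.shift_positions_hz)
    label = np.zeros(acq.np_points, dtype=np.uint8)
    half = acq.sw_hz / 2
    for f in freqs:
        if not (-half < f < half):
            raise ValueError(f"frequency {f} Hz outside (−sw/2, sw/2)")
        idx = int(acq.hz_to_index(f))
        if label[idx]:
            logger.warning("label collision at bin %d (f = %.2f Hz)", idx, f)
        label[idx] = 1
    return label


def normalize_input(series: EchoSeries) -> tuple[np.ndarray, float]:
    """Stack real parts (echo-major) and scale by the 2τ = 0 maximum.

    Returns the (n_echoes, np_points) float array and the scale that was
    divided out, so the original real parts can be recovered.
    """
    stack = series.real_stack()
    scale = float(np.abs(stack[0]).max())
    if scale == 0:
        raise ValueError("cannot normalize an all-zero series")
    return stack / scale, scale


# ----------------------------------------------------------------------------
# Sample and dataset generation
# ----------------------------------------------------------------------------

def _signal_windows(
    specs: Sequence[SpinSignalSpec],
    ab_systems: Sequence[ABSystemSpec],
    acq: AcquisitionParams,
) -> list[tuple[int, int]]:
    """Index windows covering each signal's full multiplet extent."""
    hz_per_pt = acq.sw_hz / acq.np_points
    windows = []
    items: list[tuple[float, float]] = [
        (s.freq_hz, sum(j * p for j, p in s.couplings) / 2 + 3 * s.linewidth_hz)
        for s in specs
    ]
    for ab in ab_systems:
        items.append((ab.center_hz, (ab.d_hz + ab.j_hz) / 2 + 3 / (np.pi * ab.t2_s)))
    for f, half_hz in items:
        c = int(acq.hz_to_index(f))
        w = int(np.ceil(half_hz / hz_per_pt)) + 3
        windows.append((max(c - w, 0), min(c + w + 1, acq.np_points)))
    return windows


def _noise_sd_for_wsn(
    series: EchoSeries,
    windows: Sequence[tuple[int, int]],
    wsn_target: float,
) -> float:
    """Noise sd so the weakest signal of the noiseless 2τ=0 spectrum hits wS/N."""
    real0 = series.spectra[0].values.real
    weakest = min(real0[a:b].max() for a, b in windows)
    return max(weakest, 0.0) / wsn_target


def generate_sample(
    ranges: ParameterRanges,
    acq: AcquisitionParams,
    seed_seq: np.random.SeedSequence | int,
) -> SampleRecord:
    """Simulate one sample: spin systems → echo series → distort → noise → stack."""
    if isinstance(seed_seq, (int, np.integer)):
        seed_seq = np.random.SeedSequence([int(seed_seq)])
    rng = np.random.default_rng(seed_seq)
    specs, ab_systems = sample_spin_systems(ranges, rng, sw_hz=acq.sw_hz)
    series = simulate_echo_series(specs, acq, ab_systems=ab_systems)

    windows = _signal_windows(specs, ab_systems, acq)
    wsn_target = _loguniform(rng, *ranges.wsn)
    noise_sd = _noise_sd_for_wsn(series, windows, wsn_target)

    r = 0.0
    if rng.random() < ranges.phase_fraction:
        r = float(rng.uniform(*ranges.phase_r))
        series = apply_phase_distortion(series, r)
    noise_seed = int(rng.integers(2**31))
    series = add_noise(series, noise_sd, noise_seed)

    stack, scale = normalize_input(series)
    label = make_label(specs, acq, ab_systems)
    n_signals = len(specs) + 2 * len(ab_systems)
    metadata = {
        "freq_hz": [s.freq_hz for s in specs]
        + [f for ab in ab_systems for f in ab.shift_positions_hz],
        "freq_ppm": [float(acq.hz_to_ppm(s.freq_hz)) for s in specs]
        + [float(acq.hz_to_ppm(f)) for ab in ab_systems for f in ab.shift_positions_hz],
        "amplitude": [s.amplitude for s in specs],
        "t2_s": [s.t2_s for s in specs],
        "couplings": [list(map(list, s.couplings)) for s in specs],
        "ab_systems": [
            {"center_hz": ab.center_hz, "delta_hz": ab.delta_hz,
             "j_hz": ab.j_hz, "alpha": ab.alpha}
            for ab in ab_systems
        ],
        "wsn_target": wsn_target,
        "noise_sd": noise_sd,
        "phase_r": r,
        "scale": scale,
        "noise_seed": noise_seed,
        "n_signals": n_signals,
        "n_collisions": int(n_signals - int(label.sum())),
    }
    return SampleRecord(stack.astype(np.float32), label, metadata)


def iter_samples(manifest: DatasetManifest) -> Iterator[SampleRecord]:
    for i in range(manifest.n_samples):
        yield generate_sample(
            manifest.ranges, manifest.acq, np.random.SeedSequence([manifest.seed, i])
        )


def generate_dataset(manifest: DatasetManifest, path) -> "SpectraDataset":
    """Write the dataset to HDF5 (+ YAML manifest sidecar) and return a view.

    Layout: /inputs float32 (N, n_echoes, np), /labels uint8 (N, np),
    /metadata JSON strings.  Regeneration from the manifest is deterministic.
    """
    path = str(path)
    n = manifest.n_samples
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest.to_dict(), sort_keys=True)
        inputs = f.create_dataset(
            "inputs", (n, manifest.acq.n_echoes, manifest.acq.np_points), dtype="f4"
        )
        labels = f.create_dataset("labels", (n, manifest.acq.np_points), dtype="u1")
        meta = f.create_dataset("metadata", (n,), dtype=h5py.string_dtype())
        for i, rec in enumerate(iter_samples(manifest)):
            inputs[i] = rec.input_stack
            labels[i] = rec.label
            meta[i] = json.dumps(rec.metadata, sort_keys=True)
    with open(path + ".manifest.yaml", "w") as f:
        yaml.safe_dump(manifest.to_dict(), f, sort_keys=True)
    return SpectraDataset.from_hdf5(path)


class SpectraDataset:
    """In-memory view of a generated dataset (inputs, labels, metadata)."""

    def __init__(self, inputs: np.ndarray, labels: np.ndarray,
                 metadata: list[dict], manifest: DatasetManifest | None = None):
        if len(inputs) != len(labels) or len(inputs) != len(metadata):
            raise ValueError("inputs, labels, metadata must have equal length")
        self.inputs = inputs
        self.labels = labels
        self.metadata = metadata
        self.manifest = manifest

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest) -> "SpectraDataset":
        records = list(iter_samples(manifest))
        if records:
            inputs = np.stack([r.input_stack for r in records])
            labels = np.stack([r.label for r in records])
        else:
            inputs = np.zeros((0, manifest.acq.n_echoes, manifest.acq.np_points), np.float32)
            labels = np.zeros((0, manifest.acq.np_points), np.uint8)
        return cls(inputs, labels, [r.metadata for r in records], manifest)

    @classmethod
    def from_hdf5(cls, path) -> "SpectraDataset":
        with h5py.File(str(path), "r") as f:
            manifest = DatasetManifest.from_dict(json.loads(f.attrs["manifest"]))
            inputs = f["inputs"][...]
            labels = f["labels"][...]
            metadata = [json.loads(m) for m in f["metadata"].asstr()[...]]
        return cls(inputs, labels, metadata, manifest)

    def __len__(self) -> int:
        return len(self.inputs)

    def __getitem__(self, i: int) -> SampleRecord:
        return SampleRecord(self.inputs[i], self.labels[i], self.metadata[i])

    def split(self, name: str) -> "SpectraDataset":
        if self.manifest is None:
            raise ValueError("dataset has no manifest; cannot split")
        sl = self.manifest.split_slices()[name]
        return SpectraDataset(
            self.inputs[sl], self.labels[sl], self.metadata[sl], None
        )
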