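"""From confidences to chemical-shift stick spectra.

The trained network emits one confidence per frequency point.  Points at or
above the decision threshold (0.5 by default — the value at which the F1
score is high) are kept; contiguous supra-threshold runs are collapsed to
the run's confidence maximum (leftmost on ties) since a real detector may
smear a signal over neighbouring points.  Peaks are reported as grid index,
offset in Hz and chemical shift in ppm, and the stick spectrum is a 0/1
vector of unit-height impulses — by construction it carries position, not
intensity, information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import normalize_input
from .network import ModelState, forward
from .physics import AcquisitionParams, ComplexFid, EchoSeries

__all__ = [
    "Peak",
    "PeakList",
    "threshold_peaks",
    "indices_to_ppm",
    "zero_fill",
    "predict",
    "predict_from_stack",
]

ZERO_FILL_BLOCK = 4096


@dataclass(frozen=True)
class Peak:
    index: int
    confidence: float
    freq_hz: float | None = None
    shift_ppm: float | None = None


class PeakList:
    """Detected peaks, indices strictly increasing."""

    def __init__(self, peaks: list[Peak]):
        idx = [p.index for p in peaks]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("peak indices must be strictly increasing")
        self.peaks = list(peaks)

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def indices(self) -> np.ndarray:
        return np.array([p.index for p in self.peaks], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [p.index for p in self.peaks],
                "freq_hz": [p.freq_hz for p in self.peaks],
                "shift_ppm": [p.shift_ppm for p in self.peaks],
                "confidence": [p.confidence for p in self.peaks],
            }
        )


def threshold_peaks(conf: np.ndarray, threshold: float = 0.5) -> PeakList:
    """Collapse contiguous supra-threshold runs to their maximum.

    Each maximal run of points with confidence ≥ threshold contributes one
    peak at its maximum-confidence index (leftmost index on exact ties);
    isolated supra-threshold points are kept as-is.  Raising the threshold
    can only remove peaks, never add new ones.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    conf = np.asarray(conf, dtype=float)
    if conf.ndim != 1:
        raise ValueError("confidence vector must be one-dimensional")
    above = conf >= threshold
    peaks: list[Peak] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        k = start + int(np.argmax(conf[start:stop]))  # argmax → leftmost tie
        peaks.append(Peak(index=int(k), confidence=float(conf[k])))
    return PeakList(peaks)


def indices_to_ppm(peaks: PeakList, acq: AcquisitionParams) -> PeakList:
    """Fill in Hz offsets and ppm shifts from the grid convention.

    Index i maps to offset (i − np/2)·sw/np Hz and to chemical shift
    carrier_ppm + offset/spectrometer_mhz.  For spectra zero-filled to a
    multiple of 4096 the same grid spacing applies with np scaled
    accordingly, which is what ``acq.np_points`` must reflect.
    """
    out = []
    for p in peaks:
        hz = float(acq.index_to_hz(p.index))
        out.append(
            Peak(
                index=p.index,
                confidence=p.confidence,
                freq_hz=hz,
                shift_ppm=float(acq.hz_to_ppm(hz)),
            )
        )
    return PeakList(out)


def zero_fill(fid: ComplexFid, block: int = ZERO_FILL_BLOCK) -> ComplexFid:
    """Pad with exact zeros to the smallest multiple of ``block`` ≥ length."""
    samples = np.asarray(fid.samples)
    n = len(samples)
    if n == 0:
        raise ValueError("cannot zero-fill an empty FID")
    target = ((n + block - 1) // block) * block
    padded = np.concatenate([samples, np.zeros(target - n, dtype=samples.dtype)])
    return ComplexFid(samples=padded, t_start_s=fid.t_start_s)


def predict_from_stack(
    model: ModelState,
    stack: np.ndarray,
    acq: AcquisitionParams,
    threshold: float = 0.5,
):
    """Confidence → peaks → stick spectrum for an already-normalized stack."""
    conf = forward(model, stack, train=False)[0]
    peaks = indices_to_ppm(threshold_peaks(conf, threshold), acq)
    stick = np.zeros(conf.shape[-1], dtype=np.uint8)
    if len(peaks):
        stick[peaks.indices] = 1
    return conf, peaks, stick


def predict(
    model: ModelState,
    series: EchoSeries,
    acq: AcquisitionParams | None = None,
    threshold: float = 0.5,
):
    """Run the detector on an echo series.

    Returns (confidence vector, peak list with ppm, unit-height stick
    spectrum).  The series is normalized exactly as during training (real
    parts, scaled by the 2τ = 0 maximum).
    """
    if acq is None:
        acq = series.acq
    if acq.n_echoes != model.config.n_echoes:
        raise ValueError(
            f"series has {acq.n_echoes} echoes but the model expects "
            f"{model.config.n_echoes}"
        )
    stack, _ = normalize_input(series)
    return predict_from_stack(model, stack, acq, threshold)
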