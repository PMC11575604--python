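# echoshift

Ultra-high-resolution chemical-shift spectra from J-modulated spin-echo
¹H NMR series.

## The problem

¹H NMR spectra are crowded: scalar (J) coupling splits every resonance into
a multiplet, and in a narrow chemical-shift range multiplets overlap until
individual shifts cannot be read off.  Pure-shift experiments (PSYCHE,
Zangger–Sterk) collapse multiplets to singlets but pay heavily in
sensitivity and artifacts.

`echoshift` takes a different route.  A spin echo refocuses chemical-shift
evolution while J-coupling and relaxation keep evolving, so a series of
spin-echo spectra acquired at increasing echo times 2τ carries a distinctive
signature: singlet phases are invariant, multiplet component phases rotate
as exp(±i·π·J·2τ).  A convolutional network reads a stack of eight such
spectra and emits, for every frequency point, the confidence that a signal
center lies there.  Thresholding at 0.5 yields a "stick spectrum" — unit
impulses at the chemical shifts, with no linewidth and no multiplet
structure — at the full sensitivity of the plain spin echo.

For one weakly coupled resonance the simulated spin-echo signal is

    s(k) = A · exp(i·2π·f·t1ₖ) · exp(−t2ₖ/T2) · Π_m cos(π·J_m·t2ₖ)^pow_m,

with t1ₖ = k/SW and t2ₖ = 2τ + k/SW.  The package simulates these series
(plus analytic AB strong-coupling systems, noise, and phase distortion),
generates seeded training datasets, trains the detector with an MAE loss,
and scores detections with the precision/recall/F1 protocol
(P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)) under a ±3-point matching
tolerance.  Everything — including the convolutional network and its
backpropagation — is implemented on NumPy; see `docs/methods.md` for the
model, the network design and the numerical choices.

## Worked example

Simulate a three-signal mixture, train nothing (use the bundled desk
profile to train in ~10 minutes), and read peaks:

```python
import numpy as np
import echoshift as es
from echoshift.profiles import train_desk_model

# 1. a mixture: singlet, doublet (J=7), doublet-of-triplets
acq = es.AcquisitionParams()          # 4096 pts, 4096 Hz @ 500 MHz
specs = [
    es.SpinSignalSpec(1.0, -700.0, 0.4),
    es.SpinSignalSpec(0.7,  150.0, 0.3, ((7.0, 1),)),
    es.SpinSignalSpec(0.5,  900.0, 0.3, ((7.0, 2), (12.0, 1))),
]
series = es.add_noise(es.simulate_echo_series(specs, acq), 5.0, rng_seed=0)

# 2. train the desk-scale detector (≈10 min CPU) and predict
model, _, _ = train_desk_model(seed=1)
conf, peaks, stick = es.predict(model, series, acq)
print(peaks.to_dataframe())
```

which prints (one row per detected signal):

```
   index  freq_hz  shift_ppm  confidence
0   1347   -701.0      3.298    1.000000
1   2197    149.0      4.998    1.000000
2   2947    899.0      6.498    1.000000
3   3430   1382.0      7.464    0.621589
```

The first three sticks sit at the simulated shifts to within one grid point
(1 Hz = 0.002 ppm): the doublet and the eight-line multiplet each collapse
to a single line at their chemical shift.  The fourth row is a borderline
false detection from the added noise — its confidence (0.62) barely clears
the 0.5 threshold while genuine signals saturate at 1.0, the near-binary
confidence behaviour this detector is designed to produce (here only 0.05%
of the 4096 confidences fall between 0.1 and 0.9).  Raising the threshold
to 0.7 removes it; the desk-scale model's aggregate precision/recall
trade-off at 0.5 is measured by `scripts/acceptance.py` below.

The same pipeline is scriptable from the shell:

```bash
echoshift simulate --demo --out runs/demo
echoshift make-dataset --n 2500 --seed 1 --out runs/train.h5
echoshift train --data runs/train.h5 --out runs/model
echoshift predict --model runs/model/model.npz --input runs/train.h5 --out runs/peaks.csv
echoshift evaluate --model runs/model/model.npz --data runs/train.h5 --out runs/eval
echoshift sweep --model runs/model/model.npz --param wsn --grid 2,3,4,6,10 --out runs/sweep
```

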