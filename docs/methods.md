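# Methods

This note records the model, the synthetic-data conditions, the network and
training choices, and the numerical conventions used by `echoshift`, together
with the reasoning behind the decisions that were genuinely open.

## Spin-echo signal model

A spin echo (90°–τ–180°–τ–acquire) refocuses chemical-shift evolution at the
echo while transverse relaxation and scalar coupling evolve continuously.
For a weakly coupled resonance with amplitude A, offset f (Hz), relaxation
time T₂ (s) and couplings {(J_m, pow_m)} the acquired complex signal is

    s(k) = A · exp(i·2π·f·t1_k) · exp(−t2_k/T2) · Π_m cos(π·J_m·t2_k)^pow_m

on the two time grids t1_k = k/SW (shift, restarted at the echo) and
t2_k = 2τ + k/SW (relaxation and J, running since excitation), k = 0…np−1.
Because t2 advances at the same rate as t1 during acquisition, each coupling
splits the resonance into components at f ± J/2, ± 3J/2, … whose phases carry
the factor exp(±i·π·J·2τ): singlets are phase-invariant across the echo
series, multiplets rotate with echo time.  That phase signature — not the
lineshape — is what the detector learns.

At 2τ = 0 the two grids coincide and the simulation reduces exactly to a
conventional single-pulse FID; this identity is asserted in the tests.

**Strong coupling (AB systems).**  A two-spin AB system with shift
difference Δν and coupling J is simulated through its analytic four-line
pattern: with D = √(Δν² + J²), lines at center ± D/2 ± J/2 and roofing
weights 1 ∓ J/D (outer lines weak).  The ± D/2 part evolves over t1 like a
chemical shift; the ± J/2 part over t2 like a coupling.  The roofing factor
is reported as α = J/D ∈ [0, 1] (0 = weak coupling, 1 = degenerate shifts),
a standard, bounded, monotone parameterization of the roofing effect.  In
the weak limit the model converges to the corresponding pair of J-coupled
resonances *placed at the apparent shifts ± D/2* (the usual AB → AX
statement); the residual at Δν/J = 100 is of order α ≈ 1% of the peak
height, dominated by the roofing-weight asymmetry itself.  Artifact terms
beyond this analytic two-spin treatment (and >2-spin strong coupling) are
out of scope.

**Acquisition defaults.**  np = 4096 complex points, SW = 4096 Hz at
500 MHz (≈ 8.2 ppm of ¹H at 1 Hz/point), carrier 4.7 ppm, and eight echo
times 2τ = 0, 0.02, …, 0.14 s.  The 0.02 s increment sweeps cos(π·J·2τ)
through about one full cycle across the series for a typical J ≈ 7 Hz, so
the echo dimension samples the whole phase rotation.  All of these are
configurable.

**Noise and phase errors.**  Noise is i.i.d. complex Gaussian added in the
frequency domain (equivalent to time-domain white noise up to the DFT
scaling), with the per-sample standard deviation chosen to hit a target
weakest-signal-to-noise ratio wS/N — the height of the weakest signal on the
noiseless 2τ = 0 spectrum divided by the noise sd.  Phase distortion is a
zero-order (frequency-independent) rotation by r radians; a first-order term
is available as an option but is not part of the default conditions.

## Synthetic training data

Each sample draws a random mixture and simulates the full echo series:

| parameter | default range | notes |
| --- | --- | --- |
| signals per sample | 1 … 20 | uniform |
| amplitude A | 0.05 … 1 | uniform; 20:1 dynamic range |
| offset f | central 90% of SW | uniform |
| T₂ | 0.015 … 1 s | uniform; linewidths 0.3 … 21 Hz |
| couplings per signal | 0 … 3 | uniform |
| J | 2 … 18 Hz | uniform |
| pow (equivalent spins) | 1 … 3 | uniform |
| target wS/N | 3 … 200 | log-uniform |
| phase error r | −1 … 1 rad | applied to 50% of samples |
| solvent-like singlet | 20% of samples | amplitude ×10…300 (log-uniform) the strongest signal |
| AB system fraction | 0 | training uses weak coupling only |

The ranges sit just inside the generalization limits probed by the
robustness sweeps (J up to 24 Hz, linewidths up to 22 Hz, |r| beyond 1 rad),
so the sweeps measure genuine extrapolation.  The log-uniform wS/N draw
makes hard low-signal cases as common as easy ones on a log scale.  Training
uses weakly coupled spectra only; tolerance to strong coupling is expected
to come from the phase-distortion augmentation, which mimics the
lineshape-phase mixtures that roofing produces.

The network input is the real part of the eight spectra, stacked echo-major
and divided by the maximum |real| of the 2τ = 0 spectrum (the scale is kept
in the metadata, so the normalization is invertible).  The real part alone
carries the phase information as absorptive/dispersive lineshape mixing; a
complex two-channel representation is a config option but not the default.
The label is a 0/1 vector with a single 1 at the grid bin nearest each
signal's chemical shift; two signals rounding to the same bin merge into one
1 and the collision is logged and counted in the metadata.

Sample i of a dataset derives all of its randomness from
`SeedSequence([master_seed, i])`, so the manifest (sizes, ranges,
acquisition, seed) regenerates any dataset bit-for-bit.

**What the generator does not emulate:** static-field inhomogeneity and
shimming errors, baseline distortion, solvent tails and radiation damping,
temperature drift, >2-spin strong-coupling artifacts, and vendor-specific
digital filters.  Passing tests therefore demonstrate the method under the
stated analytic conditions, not on arbitrary experimental spectra;
pre-phased, baseline-corrected real data is the intended real-world input.

## Network

Input (1 × W × H): W frequency points × H = 8 echo spectra, one channel.
Three stages, all convolutions along the frequency axis with kernel 3:

1. **Per-echo feature extraction** — a stem convolution to `stem_channels`,
   then residual blocks (two convolutions + batch norm each, identity skip)
   with dilations cycling through `res_dilations`.  Dilation widens the
   receptive field to cover a full multiplet (tens of Hz) at kernel-3 cost.
2. **Echo down-sampling** — strided convolutions (stride 2 on the echo
   axis) fuse H → H/2 → … → 1 while channels grow geometrically to C,
   correlating the phase behaviour of each resonance across echo times.
3. **Step-wise channel merging** — convolutions reduce C step by step
   (default 64 → 16 → 4), each step followed by batch normalization and a
   softmax over the frequency axis rescaled by W (a flat channel maps to 1,
   localized features sharpen), which sparsifies the representation.  The
   final merge to one channel is the confidence head itself: a biased
   convolution over the last channel stack followed by a per-point sigmoid.

Three numerical choices matter and were found necessary for stable
optimization at small scale:

- **Batch norm before each merge softmax.**  Without it the merge
  convolutions feed O(100) logits into the softmax, which collapses to a
  near-one-hot winner-take-all and stops gradient flow.
- **Multi-channel head.**  Merging to a single channel *before* the sigmoid
  head leaves one scalar pathway; if that feature starts out anti-correlated
  with the labels, its weight is driven to zero and no gradient reaches the
  feature stack (a dead equilibrium observed in practice).  Letting the last
  merge step be the head preserves several pathways.
- **Negative head-bias initialization** (−4, i.e. initial confidence
  ≈ 0.02).  Labels are overwhelmingly 0; starting sparse skips a long
  baseline-collapse phase.  This is the standard prior initialization for
  dense detection heads.

One expected property did not survive desk-scale measurement: step-wise
merging with a softmax per step is described as outperforming single-step
merging, but with the multi-channel head above, a single-step variant
reached a *higher* validation F1 at a 600-sample/8-epoch budget (0.865 vs
0.786, identical seeds).  The multi-channel head evidently supplies much of
the benefit that the step-wise cascade provides in the original design, and
the comparison is scale-dependent; the package keeps the step-wise
architecture as described, and no test asserts either direction of the
comparison.

The network is fully convolutional along the frequency axis: a model trained
at one width runs unchanged at any other, which is how zero-filled real
spectra (multiples of 4096 points) and width-reduced training crops are
handled.  The softmax rescaling by W keeps the flat-feature level at 1
independent of width.

## Training

Loss: mean absolute error between the confidence vector and the 0/1 label,
as a plain mean over all points (the default).  An optional positive
weighting (`pos_weight`) multiplies the label-1 terms; it is off by default
but **enabled in the desk-scale profiles used by the tests and the
acceptance script**, annealed geometrically from 100 down to 25 over the
run — strong early pull for the sparse positives, then enough negative
pressure to suppress satellite responses.  With ~10 ones among 4096 points,
the all-zero output is within 0.005 of the plain-MAE optimum, and at small
sample/step budgets plain MAE reliably converges to that collapse; the
weighting is what makes desk-scale training (minutes of CPU) feasible.  The
reported MAE figures are always the plain, unweighted mean.

Optimizer: Adam (lr 10⁻³ by default, β = 0.9/0.999), batch 16, with ×0.5
decay on validation plateau; the desk profiles use a higher initial lr
(5 × 10⁻³) with per-epoch exponential decay, which matters because the
sign-based L1 gradient makes Adam dither at a fixed step size near a
solution.  For the same reason the desk profiles enable Polyak-style tail
averaging (`average_tail`): the weights are averaged over the final 20% of
epochs, cancelling the end-of-run dither that otherwise freezes arbitrary
marginal confidences near 0.5 (observed as split or satellite peaks); with
averaging enabled the averaged weights are returned instead of the
best-validation snapshot.  By default (no averaging) validation selects the
checkpoint by pooled F1 at threshold 0.5 (ties by MAE).  Training runs on
random fixed-width crops (default 1024 points) of the full-width samples
purely for speed; signal density per point is unchanged, so the
width-dependent softmax statistics match between crop training and
full-width inference.

Determinism: all shuffling and crop draws derive from the config seed, and
the NumPy arithmetic is deterministic, so runs are bit-reproducible on the
same platform; checkpoints store parameters, batch-norm statistics and a
config hash that is verified on load.

## Inference

Confidences ≥ 0.5 (the decision threshold; the value at which F1 is high)
are kept; contiguous supra-threshold runs collapse to the run's confidence
maximum, leftmost on ties, because a convolutional detector may smear one
signal over adjacent bins.  Note that raising the threshold can split a run
with an interior dip into two peaks, so the peak *count* is not monotone in
the threshold; what is monotone is the set of supra-threshold points, and
every surviving peak lies inside a lower-threshold run.  Peaks are reported
as (index, Hz, ppm, confidence); the stick spectrum is unit-height by
construction — the method extracts positions, not intensities.  ppm
referencing uses the user-supplied carrier; there is no automatic TMS/DSS
referencing.  Real data enters as eight pre-phased spectra zero-filled to a
multiple of 4096 points; vendor FID formats are out of scope.

## Evaluation protocol

Predictions match truths by greedy nearest-first one-to-one assignment
within ±3 grid points (≈ 0.006 ppm at the default grid; the tolerance is an
implementation choice, configurable).  TP/FP/FN are pooled over the whole
test set before computing precision, recall and F1 (micro-averaging, which
is what single aggregate numbers over a 10 000-sample protocol imply);
degenerate 0/0 ratios are reported as NaN with an `undefined` flag.  F1 is
the harmonic mean 2PR/(P+R).

Robustness sweeps stress one parameter at a time on purpose-built fixtures
(three singlets with one weak for wS/N; a single doublet for J; a single
singlet with T2 = 1/(π·LW) for linewidth; an AB pair for α; a two-singlet
height ratio for solvent; a three-multiplet mixture for phase error r), with
everything else fixed at wS/N = 50 and T2 = 0.3 s.  Success on one seed
means every true signal matched and no false positive anywhere; the
critical value is the boundary of the widest easy-side grid run with
success fraction ≥ 0.95.  For AB fixtures the ground truth is the pair of
true chemical shifts (center ± Δν/2); up to α ≈ 0.74 the apparent-shift
displacement (D − Δν)/2 stays within the ±3-point tolerance, so the choice
does not affect the sweep's reading.

## Desk-scale profiles

The full-scale conditions (40 000 training samples, 10 000-sample
evaluation) are available through the configs, but the test suite and the
acceptance script run scaled-down profiles chosen to keep a complete
retraining-plus-evaluation cycle in CPU minutes:

- *desk training*: 2 500 training / 200 validation samples at the default
  generator conditions, network stem 12 / C 32 / 3 residual blocks
  (dilations 1, 4, 16) / merge 32 → 8 → 1, crops of 512 points, batch 16,
  14 epochs, pos_weight annealed 100 → 25, lr 5×10⁻³ with exponential decay
  and tail averaging over the final 20% of epochs.
- *evaluation*: 1 000 fresh in-distribution samples at full width.
- *sweeps*: 20 seeds per grid value (the smallest count that can resolve
  the 95% stability criterion).
- *overfit oracle*: 8 handcrafted fixed mixtures on a 512-point grid
  (singlets and pow-2 triplets, J = 6–14 Hz, amplitudes 0.4–1, two samples
  phase-distorted, wS/N 100) — a deterministic memorization target for
  verifying the optimization loop end to end.  Triplets carry their
  strongest line at the labeled center, so the bin-exact recovery the
  oracle demands is geometrically well-posed; gap-centered multiplets
  (doublets), whose centers desk-scale training localizes only to within
  the ±3-point tolerance, are exercised by the detection protocol instead.

Desk-scale detection quality is necessarily below the full-scale numbers;
the acceptance tests assert a floor (pooled F1) and factor-of-two bands on
the sweep critical values rather than the full-scale figures.

## Known limitations

- The NumPy implementation trains on CPU only; the architecture is sized
  for that budget and is smaller than what the full protocol would use.
- Strong-coupling handling is analytic two-spin only, and the detector's
  α tolerance is bounded by what phase-distortion augmentation can emulate.
- No amplitude or integral estimation: sticks are positions only.
- Label bins quantize shifts to the acquisition grid (1 Hz ≈ 0.002 ppm by
  default); sub-bin shift estimation is not attempted.
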