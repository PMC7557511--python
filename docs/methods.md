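# Methods

## Signal model of the synthetic generator

The decoder consumes exactly two properties of a facial-action EMG
recording: the spatial distribution of amplitude across the four scalp
channels (F7, F8, FC5, FC6) and the distribution of power across three
frequency bands (64–128, 128–256, 256–500 Hz).  The generator therefore
models an action window as **band-shaped Gaussian noise**: white noise is
shaped in the spectral domain (brick-wall masks per band, so realized
band-power fractions match the profile exactly up to envelope leakage),
scaled per channel to `gain x action_rms`, ramped with 100 ms
raised-cosine on/off ramps to avoid filter transients dominating epochs,
and added to a white baseline floor present throughout the trial.

Class profiles (parameter `asymmetry` a ≥ 1, `band_contrast` c ∈ [0, ⅔]):

| action | F7 | F8 | FC5 | FC6 | band fractions |
|---|---|---|---|---|---|
| raising brow | a | a | 1 | 1 | (⅓+c/2, ⅓, ⅓−c/2) |
| furrowing brow | 1 | 1 | a | a | (⅓−c/2, ⅓, ⅓+c/2) |
| left smirking | a | 1 | a | 1 | (¼, ½, ¼) |
| right smirking | 1 | a | 1 | a | (¼, ½, ¼) |

The smirks are left/right mirror images (lateralised lower-face
musculature); the brow actions are left/right symmetric but contrast the
frontal against the posterior electrode pair, which keeps all four
profiles pairwise distinct whenever a > 1.  `asymmetry` is thus a single
spatial-contrast dial: left/right for the smirks, front/back for the brow
actions.  The two brow actions additionally differ spectrally: c/2 of the
power is shifted between the outer bands in opposite directions, so their
band-fraction vectors differ by 2c in L1.

Defaults (chosen once as a realistic operating point for voluntary facial
sEMG): a = 2.0, c = 0.3, action RMS 4.0 over a unit noise floor (≈12 dB
SNR), trial-to-trial log-normal amplitude jitter with CV 0.15 (effort
varies between repetitions), and a 50 Hz mains sinusoid of amplitude 2.0
with random phase per channel.  `draw_subject` redraws these from
documented ranges (a ∈ [1.6, 2.6], c ∈ [0.2, 0.4], RMS ∈ [3, 6], mains
∈ [1, 3]) to emulate inter-subject variability.

**What the generator does not model:** volume conduction and electrode
physics, non-stationarity within the 1.5 s window, EEG/ocular/motion
artifacts, co-activation between facial muscles, fatigue drift across
sessions, and electrode-impedance variation.  Consequently the default
synthetic classes are *fully separable*: cross-validated accuracy
saturates at 100 %, whereas real facial EMG lands in the mid-90s.
Passing tests therefore demonstrate that the pipeline recovers the class
structure the signal model encodes — not that any particular accuracy
would be reached on real recordings.  The shuffled-label control (≈25 %
for four classes) verifies the evaluation cannot manufacture accuracy
from structureless labels.

## Protocol structure

Offline: 10 sessions, each containing 6 trials of each of the 4 actions
in a seeded random interleave (24 trials/session), 3.5 s trials (1 s
preparation, 1.5 s action, 1 s break) at 1000 Hz — 60 trials per action,
240 in total.  The session is read as "six trials *per action*", the only
reading consistent with 60 trials per action over ten sessions.  Only the
four feature channels are generated; the recording montage's unused
electrodes carry no information the decoder would consume.

## Preprocessing

Zero-phase (forward–backward) filtering is used offline so group delay
does not shift epochs: Butterworth band-pass of order 4 (a common sEMG
choice; the order is configurable) and a second-order IIR notch at 50 Hz
with Q = 30.  The nominal 50–500 Hz pass-band is implemented as
50–499 Hz: a band edge at the Nyquist frequency of a 1000 Hz recording is
degenerate for an IIR design.  The online simulator filters causally
(single-pass) since a real-time loop cannot look ahead; on the default
synthetic data this costs no accuracy (online sessions score 100 %), but
the phase distortion is the one systematic difference between the offline
and online paths.  No baseline correction or artifact rejection is
applied.

## Features

FFT band energy per channel and band: `P = Σ y_i²` over the DFT bins with
frequency in `[low, high)` — half-open so the shared edges at 128 and
256 Hz are counted once.  The nominal top band "256–512 Hz" cannot exist
at a 500 Hz Nyquist; it is implemented as 256–500 Hz.  No taper is
applied and energies use raw (unnormalized) DFT coefficients; the
normalization convention is immaterial because features are z-scored
(per feature, statistics fit on training folds only) before
classification — raw band energies span orders of magnitude and sigmoid
networks need bounded inputs.

The wavelet comparison uses a 3-level Daubechies-5 Mallat pyramid with
periodized boundaries and takes the energies of the three detail subbands
per channel, ordered low-to-high frequency (D3 ≈ 62.5–125, D2 ≈ 125–250,
D1 ≈ 250–500 Hz) to mirror the FFT layout.  Which wavelet coefficients
form the comparison features is a design choice; detail-subband energies
are the closest analog of the FFT band energies.

Feature vectors are channel-major: `[F7:b1, F7:b2, F7:b3, F8:b1, …]`,
covered by a layout regression test.

## Classifier and training

12-16-2 fully connected network, log-sigmoid on hidden and output layers,
net input `s = Wx + b` (the bias sign convention is absorbed into the
learned value).  Targets are the bit pairs {0,1}²; prediction thresholds
each output at 0.5.  Weight initialization is U(−0.5, 0.5)/√fan-in,
seeded.

Levenberg–Marquardt training minimizes `E(Q) = ½ Σ ‖P_m − Y_m‖²` over the
stacked parameter vector Q (order: W1, b1, W2, b2).  Residuals are
`e = output − target`; the residual Jacobian is computed analytically by
back-propagation (the second-order term of the Hessian is dropped — the
Gauss–Newton approximation).  Each epoch solves
`(JᵀJ + μI) ΔQ = −Jᵀe` by Cholesky factorization; a step is accepted only
if it strictly decreases E, whereupon μ ← μ/10, otherwise μ ← 10μ and the
step is re-proposed.  Numerical guards: μ is floored at 1e−12 (keeping
`JᵀJ + μI` numerically positive definite when columns of J vanish on
saturated sigmoids) and capped at 1e10 (training terminates with reason
`mu_overflow`).  Stopping: `‖ΔQ‖ < ε` (default 1e−6), `E ≤ goal`, or the
epoch cap (default 1000; the cross-validation protocol uses 100, ample on
this problem — full-data training converges in ≈50 epochs).  Training is
full-batch, consistent with the batch Jacobian.

The Adam baseline trains the identical network and loss with full-batch
Adam (lr 0.01, β₁ 0.9, β₂ 0.999), giving a matched-budget first-order
comparison.

## Evaluation

Ten-fold cross-validation repeated four times = 40 folds; "repeated" is
read as four independent re-partitions.  Folds are stratified by class
(6 test trials per class per fold at defaults) so every fold tests a
balanced set.  Scaler and network are fit per fold on the training nine
tenths only; a leakage test verifies the scaler statistics exclude the
held-out fold.  Accuracies are reported in percent; the ± value is the
standard deviation over folds (the aggregation axis is stated wherever a
summary is printed).  Regression performance is the Pearson correlation
between concatenated network outputs and bit targets.  The paired *t*
test and one-way ANOVA wrap the classical statistics with explicit
degenerate-case conventions (identical pairs → t = 0, p = 1; all-constant
groups → F = 0, p = 1; zero within-group variance with distinct means →
F = ∞, p = 0).  Normality/sphericity diagnostics and post-hoc machinery
are out of scope.

## Online loop

The online protocol is cued: the user holds one action per 1.5 s decision
window and one command is issued at the window's end (no rejection class
— every window yields a command).  The prosthesis keeps its previous
gesture until a new command arrives.  Wrist rotation is modelled as
discrete saturating steps on an orientation index in [−2, +2]; hand
open/close set the hand state idempotently.  The drinking task preset is
open → close (grasp) → rotate right (tip to drink) → rotate left
(return); task completion means the driven state trajectory equals the
cue-driven one.  Decisions are causal: a test perturbs samples after a
window's end and asserts the decision is unchanged.  Zero-energy windows
are still classified but flagged low-confidence.

## Problem sizes

The test suite synthesizes the full 240-trial protocol once (shared
session fixture) and runs three full 40-fold cross-validations plus a
40-fold shuffled-label control; the whole suite completes in well under a
minute on one CPU, and `scripts/acceptance.py` in about 40 s.  The
chance-level online control uses 200 stub sessions (800 decisions).

## Known limitations

* The generator's separability ceiling makes accuracy comparisons between
  feature sets and optimizers directional only (ties at 100 % are
  common); differences reported on real data cannot be reproduced from
  synthetic data.
* EDF export is not implemented; datasets persist as delimited text with
  a JSON sidecar.
* The online simulator is cue-aligned; free-running sliding-window
  decoding and hardware latency are out of scope.
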