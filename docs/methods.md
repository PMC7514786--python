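# Methods

## Problem and model

During out-of-hospital cardiac arrest the only signal universally
available through defibrillation pads is the ECG. The clinically hard
discrimination is between pulse-generating rhythms (PR) and pulseless
electrical activity (PEA): both show organized electrical activity, but
only PR produces an effective pulse. `pulsegate` classifies 5-s
single-lead ECG segments into PR/PEA with two small neural networks and
adds a selective-prediction layer that withholds low-confidence decisions.

**Front end.** Raw segments arrive at 250 Hz. They are band-pass filtered
to the typical AED bandwidth 0.5–30 Hz and downsampled to 100 Hz, giving
the network input `s[n]` with N = 500 samples for a 5-s segment. The
filter is a 4th-order Butterworth applied forward–backward: the band is
the specification, while family, order and phase behaviour are our
choices — zero phase avoids QRS morphology distortion and 4th order is a
standard AED front-end roll-off. Resampling 250→100 Hz uses polyphase
rational resampling (up 2, down 5) with its built-in anti-aliasing
filter; its passband ripple is ~1e-4 relative, which is why "constant in,
constant out" holds only to that tolerance.

**S1 — fully convolutional.** λ blocks of valid (no-padding) 1-D
convolution (M kernels of length L, one bias per kernel, ReLU) →
max-pooling with pool size K = 2 over non-overlapping windows (trailing
odd sample discarded) → dropout at rate α. A global max pooling reduces
the M channel maps to the M-vector v_D1, classified by a single sigmoid
unit, p_PR = σ(w·v_D1 + b). Valid convolution shortens the map by L − 1
per block, so an input of 500 samples through λ=4, L=7 passes
494→247→241→120→114→57→51→25 and any input at or above the closed-form
minimum length is accepted — this is what makes the 2–5-s duration sweep
possible with one trained model.

**S2 — convolutional + bidirectional GRU.** The same conv blocks, then a
bidirectional GRU replaces the global max pooling. Each direction
iterates update gate z_n = σ(W_z x_n + U_z h_{n−1} + b_z), reset gate
r_n = σ(W_r x_n + U_r h_{n−1} + b_r), candidate
h′_n = tanh(W x_n + r_n ⊙ (U h_{n−1}) + b) — the reset gate multiplies
the already-projected recurrent term — and state
h_n = z_n ⊙ h_{n−1} + (1 − z_n) ⊙ h′_n, from h_0 = 0. The final hidden
states of the forward and the time-reversed pass are concatenated into
the 2ϑ-vector v_D2, passed through an extra dropout layer and the sigmoid
unit.

**Parameter accounting.** Two conventions are deliberate and pinned by
tests: one bias per convolution kernel (not per tap), and one bias vector
per GRU gate (no separate input/recurrent biases). They give the closed
forms

    S1: M(L+1) + (λ−1)·M(ML+1) + (M+1)
    S2: conv part + 2·3·(Mϑ + ϑ² + ϑ) + (2ϑ+1)

yielding exactly 1441 parameters for S1{λ=4, M=8, L=7} and 4777 for
S2{λ=2, M=24, L=6, ϑ=6} — the quantities `scripts/acceptance.py`
recomputes by enumerating the built models.

**Why numpy.** The networks, their exact gradients (including
backpropagation through time for the GRU), ADAM, dropout and the
max-norm projection are authored directly in numpy. At ~1.4k–4.8k
parameters a framework buys nothing, and a from-scratch implementation
keeps every forward operation testable against independent loop-based
oracles (tests compare each op to a literal nested-loop evaluation at
rtol 1e-6, and all gradients to central differences).

## Training recipe

ADAM with learning rate 0.001 and decay rates (0.9, 0.999); mini-batches
of 8; 75 epochs; data reshuffled every epoch. Each mini-batch is
augmented with fresh zero-mean Gaussian noise (SD 1e-4, in the mV-scale
units of the processed signal) and an independent per-segment amplitude
rescale drawn uniformly from ±2%. The loss is the negated weighted binary
cross-entropy −Σ η_i [y_i ln p_i + (1−y_i) ln(1−p_i)] with probabilities
clamped to [1e-7, 1−1e-7]; η gives each segment of a k-segment patient
weight 1/k so every patient counts equally. After every optimizer step,
constrained kernels are projected onto ‖w‖ ≤ γ = 3.5, applied per
convolution kernel and per recurrent unit (row-wise); the output unit is
left unconstrained. The GRU additionally uses variational recurrent
dropout at rate 0.15 (one mask per sequence on the recurrent term).
Design points that were genuinely open and are fixed here: the loss is
negated with η on both terms (a non-negated form cannot be minimized and
patient equalization is the stated intent); amplitude jitter is drawn per
segment, not per batch; the last short mini-batch is used, not dropped;
there is no early stopping or schedule beyond ADAM.

## Uncertainty and selective prediction

Monte-Carlo dropout: each prediction is repeated N = 100 times with
dropout active and fresh white noise (SD 1e-4, the training scale — the
test-time amplitude is our choice) added to the input; the mean of the N
values of p_PR is the reported likelihood, their population (1/N)
variance the uncertainty. The feedback threshold is the nearest-rank
quantile of training-set uncertainties at the target feedback fraction;
ties at the threshold are retained, and amplitude jitter is not applied
at test time. Evaluation discards decisions above the threshold and
reports patient-weighted metrics on the rest together with the realized
feedback fraction; an empty retained set is an explicit "no feedback"
result.

## Baselines

Nine hand-crafted features per processed signal: QRS rate (threshold
peak detection at 40% of the absolute maximum, minimum 240 ms
separation), median QRS width at half prominence, mean absolute first
difference, Welch-PSD energy fractions in 0.5–4 / 4–12 / 12–30 Hz,
fuzzy entropy (m = 2, r = 0.2·SD, baseline-removed templates, Gaussian
membership), RR-interval coefficient of variation, and spectral
centroid. These are standard re-implementations of the named feature
domains, not bit-exact replicas of any published feature set; flat
signals get defined fallbacks (rate 0, entropy 0). Classifiers: a
300-tree random forest (per-tree resample fraction φ, ψ features per
node, sklearn), a Gaussian-kernel SVM (soft margin C, kernel width γs
in K(v,vᵢ) = exp(−γs‖v−vᵢ‖²), sklearn SVC), and kernel logistic
regression solved by IRLS on the kernel expansion with ridge penalty λl
(tolerance 1e-8, ≤100 iterations, unpenalized intercept, hand-written).
The same classifiers accept the networks' learned representations (v_D1
from S1, v_D2 from S2).

## Hyper-parameter optimization

The objective is the 4-fold patient-wise cross-validated balanced error
rate; folds are stratified by patient class and sized within one patient
of each other. Two sequential optimizers: a hand-implemented
tree-structured Parzen estimator (10 random start-up trials, good/bad
split at the 0.25 quantile, Parzen densities with range-scaled
bandwidths, 24 candidates per iteration scored by the good/bad density
ratio) for the networks, and Gaussian-process optimization (Matérn-5/2
surrogate via sklearn, expected improvement over 512 random candidates)
for the baselines. Search spaces: S1 λ∈{1..5}, M∈{8,16,24}, L∈{5..8},
α∼U(0.05,0.5); S2 adds ϑ∈{4..8}; RF φ∼U(0.5,1), ψ∈{1..9}; SVM
C,γs∼U(0.001,10000); KLR λl∼U(0.0001,0.2), γs∼U(0.0001,15). The number
of optimization iterations defaults to 50 (configurable); TPE/GP
internals beyond the method class are our design choices.

## Evaluation

Se = mean over PR-bearing patients of the patient's correctly-classified
PR fraction; Sp analogously over PEA-bearing patients; BAC = (Se+Sp)/2,
BER = 1 − BAC, reported in percent. Averaging only over patients that
possess the class is the only consistent extension of patient-equal
weighting when a patient could hold both classes; in the intended data
every patient is single-class and the definition reduces to the plain
per-patient mean. The duration sweep truncates processed signals to
their first 2–5 s and re-evaluates models trained at 5 s; a model whose
architecture needs more samples than the truncation provides is reported
as not applicable rather than an error.

## Synthetic data generator

The generator emulates the *structure* of an OHCA segment collection,
not its physiology: patients contribute 2–6 segments each (uniform);
each patient draws rhythm parameters from class-conditional priors —
PR: rate U(70,130) bpm, RR coefficient of variation U(0.01,0.05), QRS
width U(60,100) ms, ectopy probability U(0,0.05); PEA: rate U(20,70),
CV U(0.08,0.25), width U(120,220) ms, ectopy up to 0.2; both: amplitude
U(0.5,1.5) mV, noise SD U(0.01,0.05) mV. Within a patient, segment
parameters drift multiplicatively (SD 3% for PR, 10% for PEA — PEA is
the more variable rhythm). A segment is a train of Gaussian QRS pulses
(width = 4σ) at jittered RR intervals (truncated at 0.3× the mean so RR
stays positive), occasional wider inverted ectopic beats, a 0.15–0.35 Hz
sinusoidal baseline wander at 5% of amplitude and white noise. The
priors realize the qualitative PR/PEA contrasts (faster, narrower, more
regular PR) with plausible clinical ranges; they are stand-ins, not
estimates of any clinical distribution. No P/T waves, no chest
compression artefacts, no power-line interference, single lead. Passing
the end-to-end tests therefore shows the pipeline learns and calibrates
correctly on data with the right structure and class contrasts; it does
not certify clinical performance.

## Problem sizes used by the test suite

The end-to-end tests train S1{λ=2, M=8, L=5, α=0.1} with the full
75-epoch recipe on a synthetic training set of 100 patients (50 PR /
50 PEA, ≈400 segments) and evaluate on a disjoint 40-patient test set,
repeating over ten seeds; the selective-prediction check reuses those
ten models with N = 100 Monte-Carlo repeats. These sizes keep a full
run at desk scale while leaving the class structure rich enough for the
≥0.90 balanced-accuracy floor to be a meaningful bar.

## Known limitations

- The synthetic generator's separability is optimistic relative to real
  OHCA ECG; absolute accuracies on it exceed what pad ECG supports.
- The hand-crafted features reproduce feature *domains*, not any exact
  published formulas; their absolute values are not comparable across
  implementations.
- Single-lead, artefact-free segments are assumed; compression artefact
  handling is out of scope.
- The KLR solver forms the full n×n kernel matrix; it is intended for
  feature-set sizes in the thousands, not millions.
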