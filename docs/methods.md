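# Methods

## Problem and pipeline

`sevodoa` estimates depth of anesthesia (DoA) from single-channel frontal
EEG recorded during sevoflurane anesthesia.  The pipeline is

1. **Preprocess** — mains notch, 0.8–50 Hz sixth-order Butterworth band-pass
   (both zero-phase), segmentation into 5 s windows (500 samples at 100 Hz).
2. **Features** — per window, a 46-dimensional hybrid vector: 40 half-Hz
   spectral bins over 30–50 Hz, the average band powers in 30–47 Hz and
   47–50 Hz, permutation entropy, sample entropy, wavelet entropy and the
   alpha-ratio.  Feature tracks are wavelet-denoised along time, one subject
   at a time.
3. **Labels** — the end-tidal sevoflurane concentration C_et is mapped to the
   effect-site concentration C_eff by the first-order effect-compartment
   model dC_eff/dt = k_eo (C_et − C_eff), interpolated at window centers.
4. **Model** — an SDAE-LSTM (46–92–12–18–1): two sparse denoising
   autoencoders pretrained greedily, an LSTM regressor on the encoded window
   sequence, then end-to-end fine-tuning, with squared loss against C_eff.
5. **Validation** — the prediction probability Pk between the regressed index
   and C_eff, under leave-one-subject-out (LOSO) cross-validation.

The index regresses C_eff directly, so it increases with anesthetic depth;
single-feature baselines (entropies) decrease with depth and are reported
after the standard 1 − Pk reflection.

## Feature definitions and parameters

**Sample entropy** SampEn = −ln(A(m+1,r)/A(m,r)) with Chebyshev distance,
self-matches excluded, and N−m templates at both lengths so the counts are
comparable.  Defaults m = 2, r = 0.2 (as a fraction of the window standard
deviation — the field convention; the relative r makes the statistic
invariant under affine scaling), N = 500.  A constant window returns 0.
When no template pair matches at length m+1 the statistic is undefined; we
return the conventional finite ceiling −ln(2/((N−m−1)(N−m))) with a warning
rather than infinity.

**Permutation entropy** is the normalized Shannon entropy of ordinal-pattern
frequencies, −Σ P_j ln P_j / ln(m!), with m = 4, τ = 1, N = 500.  We use the
entropy-positive sign convention (values in [0, 1]; 0 for monotone windows),
consistent with entropies decreasing under anesthesia.  Ties within a
pattern are ranked by order of occurrence (stable argsort).

**Wavelet entropy** S = −Σ p_j ln p_j over the relative wavelet energies
p_j = E_j/E_total of a discrete wavelet decomposition.  Basis and depth are
open choices; defaults are `db4` with 5 levels (6 scales for a 500-sample
window) and the natural logarithm.

**Band spectra.**  A Hann-tapered single-segment periodogram of the 500-point
window gives a native resolution of 0.2 Hz.  Half-Hz features sum the native
bins whose centers fall in [f, f+0.5), for f = 30.0, 30.5, …, 49.5 (half-open
bins below 50 Hz).  The two average features are the means of the half-Hz
bins inside [30, 47) and [47, 50), so the aggregation identity is exact by
construction.  Powers are linear (not log).

**Alpha-ratio** = log10(E_30–42.5 / E_6–12) from the same periodogram; the
logarithm base is configurable (base 10 by default; the base only rescales
the feature and is absorbed by the model's z-scoring).  A zero-energy
denominator yields NaN with a warning.

## Preprocessing choices

* Filters are applied forward-backward (`filtfilt`), so feature tracks carry
  no systematic time shift relative to the concentration labels.
* The nominal 50 Hz upper band edge equals Nyquist at fs = 100 Hz; a
  Butterworth edge at Nyquist is ill-posed, so upper edges are clamped to
  0.99 · fs/2 (49.5 Hz) with a warning.  For the same reason, the session
  pipeline skips the mains notch when the mains frequency sits at or above
  that margin (50 Hz mains at 100 Hz sampling) — the clamped band-pass edge
  removes that content.  `notch_filter` itself rejects mains ≥ Nyquist.
* Mains frequency defaults to 50 Hz (the recordings this method targets come
  from a 50 Hz grid); configurable for 60 Hz sites.
* Window stride defaults to 500 samples (non-overlapping 5 s windows);
  overlap is configurable.
* Feature smoothing: `db4`, level 3, soft universal threshold
  σ√(2 ln n) with σ from the finest-detail MAD; boundary mode `smooth`
  (linear extrapolation) so ramps pass unchanged.  Smoothing is applied per
  subject **before** any train/test handling and uses only that subject's
  own track, so it cannot leak information across CV folds.

## PK/PD

The effect-site ODE is integrated with an exponential-integrator step that
treats C_et as linear within each sample interval; this is unconditionally
stable and exact for piecewise-linear input (it reproduces the step response
c(1 − e^{−k_eo t}) to machine precision).  On uniform time bases the linear
recurrence is evaluated as an order-1 IIR filter.  C_eff(0) defaults to
C_et(0), i.e. an awake patient in steady state.  k_eo has no published
population value for this setting; the default 1.0 min⁻¹ is a plausible
effect-compartment constant and is configurable (it is also jittered ±20 %
across synthetic subjects).

The inhibitory sigmoid Emax curve (defaults E_max = 100, E_min = 0,
EC50 = 2 vol %, γ = 2) is provided for index visualisation and synthetic-data
generation; training labels are the effect-site concentrations themselves.

## Synthetic sessions

Real recordings for this task are not redistributable, so the generator
emulates the study conditions: a 20-subject cohort, each subject one
induction → maintenance → emergence session.  The default end-tidal profile
rises to 3 vol % over the first minute, steps toward 7 vol % (the standard
inhalational induction), holds, and washes out; the default session length
is 900 s.

EEG is a sum of four band-limited components (delta 0.8–4 Hz, alpha
8–12 Hz, beta 13–30 Hz, gamma 30–47 Hz), each a random sum of 12 sinusoids
normalised to unit RMS, scaled by an amplitude that is a logistic function
of C_eff (center 2 vol %, width 0.6 vol %): delta grows from 4 to 30 µV RMS
with depth while beta (8→2) and gamma (6→0.5) are suppressed; alpha persists
(10→6).  White noise of 2 µV SD is added and the signal clipped at
±200 µV.  This is the simplest mechanism that reproduces the qualitative
clinical signatures the index exploits: sample/permutation entropy and
30–50 Hz relative power all fall monotonically (in expectation) as C_eff
rises.  Cohorts jitter k_eo (±20 %), the logistic center (±20 %, an EC50
analogue) and the noise level (±25 %) per subject, with deterministic
per-subject child seeds.

What the generator does **not** emulate: burst suppression (where
permutation entropy is known to fail), EMG/ocular artifacts, electrode
noise, non-stationary awake rhythms, or real pharmacokinetics beyond the
single effect compartment.  Passing the synthetic-cohort tests therefore
shows the pipeline recovers a monotone concentration–EEG relationship under
realistic noise and inter-subject variability — not that it attains any
particular accuracy on clinical data.

## Network and training

"First three layers SDAE, last two LSTM" is read as: sigmoid encoders
46→92 and 92→12 (their linear decoders exist only during pretraining), an
LSTM with 12 inputs and 18 hidden units, and a linear unit mapping the
hidden state to the index.  The LSTM cell uses sigmoid gates and tanh for
both the candidate and the cell-state output activation; the forget-gate
bias is initialised to 1.

* **Corruption**: masking-to-zero with p = 0.3.
* **Sparsity**: KL divergence between a target mean activation of 0.05 and
  the batch-mean hidden activation, weight 0.1.
* **Optimiser**: Adam with L2 weight decay 1e-5 on weight matrices.  The
  original description names Bayesian-regularised backpropagation; decayed
  stochastic gradient descent is the standard practical counterpart and is
  what we implement (all gradients are hand-derived and verified against
  finite differences).
* **Phases**: greedy AE pretraining (50 epochs each, lr 1e-2, minibatch 64),
  LSTM training on encoded sequences (150 epochs, lr 1e-2), end-to-end
  fine-tuning (50 epochs, lr 2e-3).  Epochs, rates and batch size are
  unpublished for the original; these defaults are declared configuration,
  chosen for stable convergence at cohort scale on one CPU.
* **Sequences**: each subject's window sequence is cut into truncated-BPTT
  chunks of `seq_len` windows; chunks start from a zero state.  Because
  chunks are stateless, the truncation length must cover the temporal
  context the index needs; 32-window (160 s) chunks measurably hurt held-out
  concordance, so the default is 64 windows (320 s), which spans an
  induction or emergence transition.  Prediction always streams the whole
  session through the recurrent layer in order.
* **Scaling**: features and labels are z-scored inside `fit`; predictions
  are returned on the label scale.
* The plain-LSTM ablation (`use_sdae=False`) feeds the 46 z-scored features
  directly to the LSTM and trains for the combined epoch budget.

Degenerate inputs: non-finite features or labels are rejected; a non-finite
training loss aborts with a diagnostic; constant label vectors train against
a zero z-score target and predict the constant.

## Pk and cross-validation

Pk = (P_c + P_tx/2)/(P_c + P_d + P_tx) over all unordered pairs of windows,
where pairs tied in true depth are excluded and an index-only tie means
|Δindex| ≤ `tie_tol` (0 by default — continuous indices tie only exactly;
configurable).  Enumeration is exhaustive, not sampled, so the pair-count
ratios realise the "drawn at random with replacement" definition exactly.
Raw Pk < 0.5 is reflected to 1 − Pk with a flag.  Pk is computed per
held-out subject and then averaged (mean ± SD across subjects), matching
the per-subject experiment protocol; per-fold results are exposed so any
significance test can be run externally.

LOSO: each subject in turn is held out, the network is trained from a fresh
fold seed on the remaining subjects in a repeat-specific shuffled order,
and the held-out session is predicted in temporal order.  Folds with
degenerate (constant) labels are skipped with a warning.  The whole
procedure is deterministic given the master seed.

## Problem sizes used by the test suite

Validation runs at desk scale: 600 s sessions (120 windows; the 900 s
default profile compressed proportionally), cohorts of 20 subjects, and
five independent cohort seeds for the end-to-end recovery check; oracle
comparisons use 30–100-sample windows where exhaustive enumeration is
cheap.  These sizes are the package's own validation choices and are set in
the tests, not in the library defaults.

## Known limitations

* The synthetic forward model from concentration to EEG is a stand-in; no
  quantitative concentration→EEG mapping is published for this setting, and
  none is inferred here.
* Absolute Pk values on clinical recordings cannot be reproduced or checked
  without the original private dataset; comparisons here are internal
  (model vs. ablation vs. single-feature baselines on the same cohorts).
* Single channel, no artifact rejection, no burst-suppression handling.
* EDF files can be read (optional `mne` dependency) but not written.
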