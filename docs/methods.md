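# Methods

This note documents the models and procedures implemented in `cvepkit`,
the assumptions behind them, and the design choices made where the design
was genuinely open.

## Paradigm and signal model

A c-VEP interface drives a flickering target with a binary maximal-length
sequence (m-sequence) of length K = 63 displayed at 60 Hz; one code period
lasts 1.05 s and spans Nt = round(63 · 512 / 60) = 538 EEG samples at
512 Hz.  Six stimulus classes are the circular shifts of the base code by
0, 8, 16, 24, 32 and 40 bits.  Because a ±1-mapped m-sequence has circular
autocorrelation K at lag 0 and −1 at all other lags, shifted codes are
nearly orthogonal and the attended shift is recoverable from the evoked
response.  The reference 63-bit code is stored as a literal fixture and
validated at load (length 63, 32 ones); the LFSR generator
(`generate_msequence`) generalizes it but no attempt is made to
reverse-engineer the taps that produced the reference code, since only the
code itself matters downstream.  Shift convention: `circular_shift(x, s)`
moves content to later positions, `out[k] = x[(k − s) mod K]`; the choice
is arbitrary (only class identity matters) and fixed for reproducibility.

## Synthetic recordings

No public recordings exist for this exact paradigm configuration, so all
tests and the acceptance script run on simulated EEG that preserves the
problem structure:

- **Clean component.**  The class code waveform (zero-order hold,
  538 samples) is circularly convolved with a per-channel evoked kernel —
  a Gaussian-windowed 10 Hz cosine with 90 ms peak latency, 60 ms FWHM,
  7.5 µV on occipital channels (O1, O2, Oz, PO7, PO8) and 5 µV on parietal
  ones (Pz, P3, P4).  Circular convolution is the physically faithful
  choice because the stimulus is periodic with the epoch and class
  identity is itself a circular shift.  The kernel values are arbitrary
  but representative of early visual evoked responses; tests depend only
  on the documented invariants (SNR calibration, template correlation,
  monotonicity), not on these defaults.
- **Noise.**  White, 1/f ("pink", via spectral shaping), or an equal-power
  mixture (default).  Noise is rescaled per trial so that the
  clean-to-noise power ratio matches `snr_db` exactly in expectation;
  the empirical SNR over ≥100 trials is verified within ±1 dB.
- **Nuisance structure.**  Integer latency jitter drawn uniformly from
  [−2, +2] samples (circular delay), and one multiplicative gain per
  session drawn from N(1, 0.05²), emulating electrode-impedance drift.
- **Layout.**  5 sessions × 114 trials per subject, labels balanced
  (19 per class), fully reproducible from one seed.

Default `snr_db = 10`.  What the simulator deliberately omits: volume
conduction and spatially correlated noise, ocular/muscle artifacts,
non-stationary alpha activity, and response non-linearity.  Passing tests
therefore demonstrate correctness of the algorithms and the expected
ordering/limits of the decoders, not the accuracy levels attainable on
real recordings; simulated accuracies at +10 dB are near ceiling for all
methods, unlike real-EEG results.

## Preprocessing

Per trial and channel: least-squares linear detrending (mean removal alone
would not remove drifts), then a zero-phase 4th-order Butterworth bandpass
0.5–42.66 Hz applied forward–backward (the filter family and order are
implementation choices; filtering short epochs leaves edge transients that
the tests account for by asserting on the filter's magnitude response).

The surface Laplacian uses great-circle distances on a unit spherical head
(Vincenty arctangent form, stable at small and antipodal separations).
Weights are literal inverse distances `w_ij = 1/d_ij`, truncated beyond a
normalized radius of 1, and the filtered signal is
`S'_i = S_i − Σ_{j≠i} w_ij S_j`.  Because inverse-distance rows can sum to
more than 1 this rescales amplitudes; a `normalized` flag provides the
conventional row-sum-1 (local average reference) variant.  Whether weights
should be normalized is ambiguous in the field; the literal form is the
default and both are tested.  Electrode spherical coordinates for the 8
default sites come from standard 10–05 montage tables, frozen as a JSON
fixture.

## Classical decoders

- **Templates**: class-conditional channel means of training trials (one
  template signal per electrode per class).
- **Correlation features**: Pearson correlation of every epoch channel
  with every template channel of every class, class-major ordering,
  8·8·6 = 384 features.  Zero-variance series yield 0 (logged) rather
  than NaN.
- **CCA features**: canonical correlations between the time × channels
  epoch and each class template, computed by the QR+SVD route, sorted
  descending and padded with exact zeros to 8 slots per class (48 total).
  Rank deficiency (e.g. a redundant electrode) simply produces fewer
  nonzero correlations; the padding keeps feature length fixed.  Class
  templates (not raw code waveforms) are the CCA references; the
  alternative is injectable.
- **BLDA**: per class, Bayesian linear regression to ±1 targets whose
  prior and noise precisions are re-estimated by evidence maximization
  (tol 1e−6, ≤200 iterations; backed by scikit-learn's BayesianRidge).
  One-vs-rest scores are softmax-normalized; ties go to the lowest class
  index.

## Convolutional trunk and heads

Input (8 × 538) → per-trial channel z-scoring (input conditioning;
microvolt amplitudes would otherwise saturate the sigmoid/softmax heads)
→ temporal average-resampling to 252 samples (4 per code bit) → spatial
convolution 8×1 with 8 filters → [1×11 conv, 16 filters, ReLU, 1×2 max
pool, 20% dropout] → [1×14 conv, 32 filters, ReLU, 1×2 max pool, 30%
dropout] → flatten to 32 · 63 = 2016 features.

The resampling step is what reconciles the architecture arithmetic: two
/2 poolings starting from 252 temporal samples land on exactly one
feature bin per code bit, and the flattened length of 2016 yields the
head parameter counts 2016·63 + 63 = 127,071 (bit-reconstruction head)
and 2016·6 + 6 = 12,102 (class head).  Trunk parameters are 8,640 without
convolution biases and 8,696 with; both are reported because the bias
convention behind the nominal "8.6k" is ambiguous.  Temporal convolutions
use 'same' padding; the spatial convolution is 'valid' (collapses the
electrode axis).

Training uses Adam (lr 1e−3, additive L2 1e−4), mini-batches reshuffled
each epoch, all randomness (init, shuffling, dropout, pair sampling) from
one seed.  Defaults: 40 epochs × batch 64 for the CNNs, 30 epochs ×
batch 256 pairs for the Siamese models.  The reconstruction head trains
with MSE against the 0/1 code bits (RMSE is the monitored metric); BCE is
available behind a flag.  The engine is a purpose-built numpy
implementation with hand-derived gradients, verified against finite
differences in the test suite; it is CPU-only and deterministic given the
seed.

**Siamese configurations.**  Twin trunks share weights; each trial maps to
a 63-dimensional embedding and similarity is `sigmoid(dense(|e1 − e2|))`,
trained with binary cross-entropy on exactly balanced same/different
pairs.  Inference scores a trial against `n_ref = 10` support trials per
class (mean similarity) and takes the argmax.  The ensemble variant trains
six binary models (positives within the class, negatives pairing the class
with its complement) and additionally exposes the 0.5-thresholded binary
decision of each model.

## Distance decoding of reconstructions

Given `ŷ ∈ [0,1]^63` and bank rows `c`:

- **Euclidean**: `Σ_k (ŷ_k − c_k)²` (square root omitted; it cannot change
  the argmin).  The raw sigmoid outputs are used by default — thresholding
  at 0.5 is available but discards confidence information.
- **Mahalanobis**: `(ŷ − c)ᵀ Σ_reg⁻¹ (ŷ − c)` with
  `Σ_reg = (1−λ)Σ + λαI`, λ = 0.1, α = mean diagonal of Σ.  Σ is estimated
  from training-set reconstructions by default so the test fold never
  influences the metric; a transductive mode (estimate from the decoded
  set itself) exists behind a flag.
- **EMD**: both vectors are clipped at 0 and normalized to PMFs; the 1-D
  EMD is `mean_k |CDF_p(k) − CDF_q(k)|`.  An all-nonpositive vector is a
  degenerate PMF and an error.
- **Constrained EMD**: minimum-cost transport with `X_kj = 0` for
  `|k−j| > R`, solved by dual-simplex linear programming over the banded
  variables only; cost is normalized by total flow (1 for PMFs; kept for
  generality).  Infeasibility means no admissible local transport and
  yields +∞ (the class is maximally dissimilar), not an exception; if all
  classes are infeasible the decoder falls back to unconstrained EMD and
  logs it.  Note the LP cost equals K times the CDF-form value at
  `R ≥ K−1`; rankings are unaffected.  Default R = 8 bits — one
  class-shift granularity — since no canonical value exists; it is exposed
  as a parameter.

Ties in every argmin/argmax go to the lowest class index.

## Temporal augmentation

Shifts are circular (wrap-around), consistent with the periodic stimulus;
a truncating zero-pad mode exists behind a flag.  For magnitude α: TA adds
copies shifted by −α and +α (training set triples); TC averages score
matrices over test views shifted by {−α, 0, +α} — including the unshifted
view, read as the natural extension of the unaugmented baseline — then
applies argmax for probability-like scores or argmin for distances.
Full-period circular shifts are the identity, so shift amounts act modulo
the epoch length; the truncating mode requires |s| < Nt.

## Evaluation and statistics

Leave-one-session-out CV: each session is the test fold once; accuracy is
the percentage of correctly labeled test trials, summarized as the
unweighted mean ± SD over folds.  Pipelines are constructed fresh per fold
so no state leaks; a fingerprinting test verifies the test fold never
enters training.

The comparison battery on a subjects × methods accuracy table: Friedman
test from mid-ranks with the standard tie correction, Kendall's
W = χ² / (n(k−1)) as effect size (the identity is asserted for every
result), and post-hoc pairwise Wilcoxon signed-rank tests (zero-discard
convention; exact null for n ≤ 25, normal approximation beyond) at a
Bonferroni-adjusted alpha of 0.05 / C(k,2) — 0.0014 for nine methods.
Pairs with identical columns are flagged degenerate instead of tested.

## Problem sizes and numerical choices

The test suite and acceptance script run the full study design — 5
sessions × 114 trials at +10 dB SNR with ±2-sample jitter — for the
classical decoders and the class-head CNN (6 training epochs suffice at
this SNR), and a single held-out-session split for the reconstruction CNN
(15 epochs) and Siamese decoders; the constrained-EMD decoder is evaluated
on a 60-trial subset because each trial–class pair solves a linear
program.  Degenerate inputs are handled explicitly throughout:
zero-variance channels (zero correlation, logged), all-zero LFSR states
(error), coincident electrodes (error), degenerate PMFs (error),
infeasible transport (+∞), identical method columns (degenerate flag).

## Known limitations

- The simulator's independence across channels and absence of artifacts
  make the simulated task easier than real c-VEP decoding; accuracy
  *levels* here do not transfer to real EEG.
- The network engine implements exactly the layers this architecture
  needs; it is not a general-purpose deep-learning framework, and training
  beyond desk scale (large batch counts, many epochs) is CPU-bound.
- The constrained-EMD decoder solves one LP per trial–class pair and is
  the slowest method by a wide margin.
- Spherical-spline current-source-density estimation, artifact rejection,
  and filter-bank CCA variants are out of scope.
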