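# Methods

`defdecode` decodes continuous defensive behaviors — accelerometry jerk,
bar-press rate, and a video-derived freezing score — from multi-channel
local field potentials (LFP) recorded in the infralimbic cortex (IL) and
basolateral amygdala (BLA). The pipeline has five stages: preprocessing,
windowed neuro-marker extraction, chronology-preserving cross-validation,
gradient-boosted decision-tree (GBDT) regression, and Shapley-value
feature-importance analysis with sequential feature selection. This note
records the model assumptions, parameter choices, and numerical
conventions, and what the synthetic-data experiments do and do not
demonstrate.

## Preprocessing

Bipolar-referenced LFP channels are band-pass filtered to 1–150 Hz with a
3rd-order Butterworth filter applied forward–backward (`sosfiltfilt`), so
the effective order is 6 and the phase response is exactly zero — a
requirement for the phase-based connectivity markers. Line noise is
removed with second-order IIR notches at 60 and 120 Hz; the notch quality
factor defaults to Q = 30 (bandwidth 2 Hz at 60 Hz), a conventional value
narrow enough to leave the gamma band intact. Each channel is then
demeaned.

Band decomposition uses the same zero-phase Butterworth design on seven
canonical bands: delta 1–4, theta 4–8, alpha 8–13, beta 13–30, low-gamma
30–50, gamma 50–80, high-gamma 80–150 Hz. Instantaneous phase and
amplitude come from the analytic (Hilbert) signal computed over the whole
session and sliced per window; windows within 100 ms of a session edge
retain the filter/Hilbert edge transients rather than being trimmed, a
small known bias that keeps the per-window formulas exact.

Artifact handling is automated (visual inspection is not reproducible): a
sample is masked when its robust z-score — deviation from the channel
median in units of 1.4826·MAD — exceeds 8 on any channel, padded by
0.5 s per side; windows touching masked samples are dropped. The mask is
monotone in the threshold. Automated rejection is off by default and
enabled per run.

Per-window cross-spectral densities use DPSS multitapers with
time–bandwidth product NW = 4 (7 tapers, uniform weights, adaptive
weighting off) on the cleaned broadband signal, on a 1 Hz grid from 1 to
150 Hz. With K = 7 tapers the single-window magnitude-squared coherence
of independent noise has expectation ≈ 1/K, which the test suite checks
by Monte Carlo.

## Analysis windows

All markers and behavior targets are computed on overlapping 1 s windows
with a 0.2 s step. Window statistics use exact cumulative-sum identities
(O(1) per window); the two entropies are O(T²) template counts compiled
with numba, sharing one symmetric pass over sample pairs.

## Neuro-marker conventions

Seventeen families are extracted per window: band power (BP), relative
band power (RBP), band-power ratios between bands (BPRB) and channels
(BPRC), line length (LL), Hjorth activity/mobility/complexity, maximum,
minimum, nonlinear (Teager-like) energy (NE), skewness, approximate and
sample entropy, and the inter-regional coherence (Coh), phase–amplitude
coupling (PAC), phase-locking value (PLV), Pearson correlation (Corr) and
band Pearson correlation (BCorr). Connectivity families are computed only
across the 16 IL×BLA channel pairs.

Conventions that the formulas leave open:

* **Standard deviations** use the (T−1)-denominator sample form
  everywhere (skewness, Hjorth, the entropy tolerance).
* **Hjorth derivatives** are unscaled first differences; the sampling
  rate cancels in complexity and is absorbed by tree models for mobility.
* **Entropies** use embedding m = 2 and tolerance r = 0.2 × the window
  SD. The match comparison is `≤ r` for approximate entropy and the
  strict `< r` for sample entropy, following the respective count
  constructions; ties have probability zero for continuous signals.
  Sample-entropy templates run over the first T−2 positions for both
  lengths, with self-matches excluded.
* **Coherence** aggregates per-bin magnitude-squared coherency over the
  bins of a band as the *mean*, so identical signals score exactly 1 in
  every band regardless of bandwidth.
* **Directional families** (BPRB, BPRC, PAC) are emitted in both
  orientations by default — 42 band pairs per channel, 14 ratios and 12
  PAC combinations per channel pair — which with 8 channels yields
  8·56 + 8·10 + 16·48 = 1296 features. A `symmetric_combinations` switch
  restores the one-orientation counts (21 band pairs, 7 ratios, 6 PAC
  combinations).
* **Degenerate windows** (zero power, zero variance, no entropy
  template matches) are imputed: correlations/synchrony measures to 0,
  power ratios to 1, mobility/complexity/sample entropy to the column
  median; every imputation is counted in a per-run QC report.

Feature names are canonical strings `family|channels|bands|direction|lag`
with a deterministic ordering, so a configuration is fingerprinted by the
hash of its descriptor list.

## Behavior targets

Accelerometry jerk is |d/dt √(V_X² + V_Y² + V_Z²)|: forward differences
scaled by the native rate, plain decimation to 1 kHz, then smoothing.
Bar presses are binned into 1 ms intervals and smoothed into a continuous
rate whose integral equals the press count. The freezing score is an
externally supplied 24 frames/s series interpolated linearly to 1 kHz.
"Gaussian filter with an N-sample window" is implemented as a truncated
Gaussian kernel of length N with σ = N/6 (±3σ support) normalised to unit
sum — 200 samples for jerk, 1000 for press rate. All three series are
averaged within each analysis window.

## Partitioning

The final 20% of windows form the held-out test set. The leading 80% is
divided into 9 equal chronological blocks (any remainder goes to the
*earliest* blocks, keeping validation blocks late-session); fold k of 5
trains on blocks k..k+3 and validates on block k+4. Validation and test
data therefore always postdate the training data. Overlapping windows
that straddle a fold boundary share raw samples across train/val; the
default keeps this scheme, and a `purge_gap_windows` option drops windows
within a configurable number of steps of each boundary for leakage-free
variants.

## Decoder

The regressor is LightGBM with the L2 objective (exclusive feature
bundling on by default; plain GBDT sampling). Defaults: 500 trees,
learning rate 0.05, 31 leaves, minimum 20 samples per leaf, early
stopping on validation L2 with patience 50 when a validation set is
supplied; single-threaded deterministic mode so identical inputs give
identical models. Per-iteration training (and validation) L2 losses are
recorded.

The final test-set model is fit in two stages: a first model trains on
all pre-validation blocks and early-stops on the *last* validation block
(the latest data preceding the test set); the reported model then refits
on the whole train+val prefix with that round count. This keeps round
selection strictly chronological and prevents a 1296-feature model from
overfitting noise when the features carry no signal — the zero-coupling
control in the test suite relies on it.

Evaluation reports the coefficient of determination R² = 1 − SS_res/SS_tot
(range (−∞, 1]; *not* the squared correlation) and Pearson's r. R² is
undefined for a constant target and the code raises rather than guessing.

## Feature importance and selection

Attributions are exact tree-path Shapley values computed natively by
LightGBM (`pred_contrib`), which satisfy local accuracy (Σφ + base =
prediction; verified to 1e−6 relative in the tests). They are evaluated
on each fold's validation windows — training instances would inflate the
credit of overfit splits — and aggregated as

    imp_i = 1/(5·N·S) · Σ_s Σ_f Σ_n |φ_{n,f,s,i}|

over instances n, folds f and sessions s. With unequal per-fold instance
counts (inevitable when the 9 blocks differ by one window) the
aggregation is the mean of per-fold means, which reduces to the flat
weighting when counts are equal. Ranking ties break by canonical feature
name.

Sequential selection retrains the 5 fold models on the top-i features for
i on an evaluation grid (default 1–30, every 5th to 100, every 25th to
M), finds the peak fold-mean validation R², and stops at the smallest i
statistically indistinguishable from the peak (paired t-test, p ≥ 0.05;
an exactly tied comparison counts as p = 1 so a plateau selects its
smallest size). The stopping test exists in two forms:

* **per session** (`sequential_select`): size i's five fold R² values are
  paired against the peak size's five. With only five pairs this test
  has little power, and on a single short session it can accept very
  small subsets whose held-out performance is below the peak's.
* **per population** (`pooled_selection_size`): each session's (or
  subject's, or seed's) *mean* validation R² at size i is paired against
  its value at the peak size, across the whole population, yielding one
  global subset size. This is the form the multi-subject analyses use,
  and the recommended one whenever more than one session is available.

Group contributions are measured as ΔR² on the validation folds after
removing a feature group; band-level importance contrasts use
independent-sample t-tests against all other bands pooled, and condition
comparisons (band-power-only vs selected vs all features) use paired
Wilcoxon signed-rank tests; all multiple comparisons are
Bonferroni-corrected. Lagged variants append copies of every feature
shifted back by multiples of the window step (up to 20 s) and compare
summed importances per lag.

## Synthetic sessions

Because the target data are in-vivo recordings that cannot be bundled,
the generator produces fully synthetic sessions with known ground truth:
eight channels (four per region) of pink background noise plus seven
band-limited oscillators per channel, a 3-axis accelerometer trace,
bar-press events, and a freezing-style frame score.

A smooth behavioral latent z(t) drives all couplings. It combines three
Ornstein–Uhlenbeck components (2 s correlation time, unit variance):
z = 0.85·(z_A + z_B)/√3 + 0.527·z_corr, where z_A and z_B share half
their variance. z_A and z_B multiply the high-gamma envelopes of one
planted channel per region (exp(0.5·g·z)); z_corr sets the mixing
fraction of a shared high-gamma source between those two channels,
raising their band correlation without changing either band power. The
accelerometer magnitude is softplus(g·z + 1) times a smooth 2–10 Hz
carrier; presses are an inhomogeneous Poisson train with rate
r₀·exp(−g·z) (suppression under threat, r₀ = 0.2 s⁻¹); the frame score is
a heavily noised softplus of z, emulating the empirically poor
decodability of freezing. Every band oscillator also drifts under an
independent nuisance envelope exp(0.2·w(t)) — realistic band-power
wander that additionally ensures ratio features (two nuisance sources)
are noisier readouts than the planted band powers (one).

This structure makes each planted pathway informative *and
non-redundant*: peak decoding requires both planted band powers and the
inter-region correlation, so all three must receive Shapley credit.
Setting all gains to zero severs every link between LFP and behavior
while leaving both signal families realistic, which provides the
negative control.

What the generator does **not** emulate: volume conduction and shared
references across channels, cross-frequency phase coupling, session-to-
session plasticity, artifacts (unless injected), non-Gaussian LFP
statistics, or any nonlinearity in the behavior readouts beyond the
softplus link. Passing the recovery experiments therefore shows that the
pipeline identifies planted spectral and connectivity couplings of
realistic magnitude under realistic nuisance variability — not that real
IL–BLA recordings are decodable at any particular accuracy.

## Problem sizes

The test suite and acceptance script run at desk scale: 180 s sessions
(896 windows of 1 s at 0.2 s steps) for the ten-seed recovery
experiments, 120 s for the zero-coupling controls, 240 s for the
acceptance script's session; the compact decoder for these runs uses 150
trees at learning rate 0.1 with early-stopping patience 25, and the
selection grid is 1, 2, 4, …, 256. Longer sessions and the full
selection grid change runtimes, not conclusions, and are a configuration
flag away.

## Known limitations

* Held-out R² on short sessions has high seed-to-seed variance: the test
  tail is a single contiguous 20% of an autocorrelated session, so
  individual seeds range roughly 0.27–0.58 around the ~0.43 mean under
  default gains.
* The sequential-selection stopping rule inherits the low power of a
  5-value paired t-test; under noisy folds it can return subsets smaller
  than what test-set performance would justify. The selection trace
  (curve, fold values, p-values) is always emitted so this is auditable.
* Tree-path Shapley values split credit among information-equivalent
  features (e.g. band power vs line length on the same planted channel),
  so recovery is asserted per planted pathway, not per redundant copy.
* Phase/amplitude estimates near session edges retain filter transients;
  with 1 s windows this biases at most the first and last windows.
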