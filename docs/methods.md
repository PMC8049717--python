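# Methods

This note documents the models, estimators and design choices behind
`songphen`: a pipeline that asks whether the social context of a zebra-finch
song motif (courtship vs. non-courtship rendition of the same syllable
sequence) can be read out from expansive time-series features of the raw
acoustic waveform, and whether an operant-trained female's discrimination
behaves like the classifier's.

## Synthetic motif model

No public recordings accompany the original study, so every analysis here
runs on synthetic motifs whose context contrasts emulate the reported
ones. A motif is `syllable_count` harmonic-stack syllables separated by
silent gaps. Each syllable is

* a stack of harmonics `h = 1..H` of a fundamental `f0`, with amplitudes
  `a_h = exp(-h / decay)` — the decay constant directly controls how far
  power spreads up the harmonic ladder, hence the spectral interquartile
  range (IQR). A 15%-depth, 25 Hz micro-vibrato broadens the harmonic
  lines and a breathy broadband component with the same `exp(-f/(f0·decay))`
  spectral shape is mixed in at 15% of the syllable RMS: real syllables are
  not pure line spectra, and without these the spectral quantiles are
  step functions of the generative parameters (they jump from harmonic to
  harmonic), which makes PSD-quantile features artificially unreliable;
* a pulse-shape skew implemented as a linear-in-harmonic phase rotation
  (harmonic `h` rotated by `(h-1)·asym` radians). At `asym = 0` every cycle
  is palindromic and the waveform is time reversible; increasing `asym`
  skews the cycle monotonically. Because the rotation is phase-only it
  leaves the power spectrum exactly unchanged, keeping the spectral and
  temporal-asymmetry knobs separable;
* an attack/decay amplitude envelope whose attack fraction shrinks with the
  same `asym` parameter (fast attack, slow decay), which makes the
  amplitude *envelope* time irreversible as well.

The two-scale use of `asym` is deliberate. Small-lag irreversibility
statistics of a carrier-modulated signal are blind to the direction of slow
envelope modulation (they reduce to instantaneous moments, which are
reversal-invariant), so a syllable-level envelope skew alone would leave
the waveform statistics unchanged; the pulse-scale skew is what the lag-1..4
statistics detect, while the envelope skew is what envelope-level analyses
detect.

Context effects (defaults in parentheses):

| knob | effect | default |
|---|---|---|
| `f0_context_shift` | courtship fundamental raised by this fraction | 0.05 |
| `bandwidth_effect` | non-courtship harmonic decay weakened by this fraction (wider spectral IQR) | 0.3 |
| `asym_effect` | non-courtship pulse/envelope asymmetry increment (more time irreversible) | 0.4 |

Each bird has a fixed "syllable family" (per-slot f0 multipliers in
0.85-1.3, durations 60-100 ms, gaps 20-40 ms, timbre multipliers) drawn
from a bird-level stream, so motifs are stereotyped within and distinct
across birds; bird fundamentals march up from `f0_base_hz` in
`f0_spacing_hz` steps. Per-rendition jitter is lognormal with coefficient
of variation `rendition_jitter_cv` (default 0.3) applied at full scale to
the asymmetry, at 0.3 scale to the harmonic decay, and at one fifth scale
to f0 and timing — fundamental frequency and tempo are the most stereotyped
parameters of zebra-finch song, while rendition-to-rendition "performance"
fluctuations live mostly in timbre. These scales were fixed once so that
the default effects put the combined classifier in the high-80s/90s
accuracy regime — clearly above chance, not trivially saturated — which is
the qualitative regime of the original behavioral and classifier results.
White Gaussian noise is added at 1% of signal RMS (the study's stimuli were
selected to be clean).

Randomness: every (seed, bird, context, rendition) tuple is hashed (CRC32)
into its own `SeedSequence` stream, so regenerating with more birds or
renditions never changes existing motifs.

What the generator does **not** emulate: pitch sweeps and syllable-type
diversity (all syllables are flat harmonic stacks with only micro-vibrato),
reverberation or recording artifacts, amplitude compression, and any
correlation structure between successive renditions. Passing tests
therefore show that the pipeline recovers the *kinds* of contrast it
injects at realistic signal-to-noise, not that real courtship song is
classifiable at any particular accuracy.

## Behavioral (2AFC) session model

Per-day accuracy follows a four-parameter logistic from `p_start` (0.5) to
`p_asymptote` (0.85) with inflection day 10 and unit slope; per-trial
correctness is Bernoulli at the day's rate. Probe trials are interleaved
at 15% (10-20% in the protocol being emulated), rewarded at the partial
reinforcement rate (85%) regardless of response and never punished;
training trials are rewarded only when correct. Reaction times are
lognormal; once past the inflection, incorrect responses draw from a
slower distribution (median ~1.28 s vs ~0.82 s), reproducing the
post-learning correct/incorrect RT gap. A 2% no-response rate is included;
no-response trials carry no correctness.

## Feature bank

Each operation maps one motif to named scalar features; degenerate inputs
yield NaN invalid markers rather than exceptions so that matrix-level
filtering (below) can act. The default bank has 143 features:

* **Time irreversibility.** `co_trev(tau)` is the normalized cubed-increment
  statistic `mean(d^3)/mean(d^2)^{3/2}` with `d_n = x_{n-tau} - x_n`, at
  lags 1-3 plus the first zero crossing of the autocorrelation and the
  first minimum of the automutual information. The sign convention uses
  `(x_{n-tau} - x_n)` so that `co_trev` and `dk_trev` respond in the same
  direction. `dk_trev(tau)` embeds with columns `(x_t, x_{t+tau},
  x_{t+2tau})` over `t = 1..N-2tau` and averages `a1∘a1∘a2 − a2∘a3∘a3`, at
  lags 1-4 and embedding dimension 3. (The `(N−τ)×M` row count sometimes
  quoted for this embedding is inconsistent for M = 3; the `N−(M−1)τ`
  convention used here is the one under which the worked example and the
  palindrome/antisymmetry identities hold.)
* **Autocorrelation** at lags 1, 2, 3, 5, 14, 33 (biased normalized, FFT)
  plus the first zero-crossing lag.
* **Automutual information** from 8-bin quantile histograms (nats, clamped
  at 0) at lags 1-3, the first-minimum lag, and the slope of AMI(lag 1)
  under added Gaussian noise of increasing amplitude (seeded).
* **PSD summaries** for {Welch, full-length windowed FFT, periodogram} x
  {Hamming, rectangular}: the unit-normalized PSD is treated as a
  distribution over frequency, giving median, IQR, log IQR, centroid, peak
  and quartile frequencies (42 features). Welch uses 1024-point segments
  with 50% overlap.
* **Symbolic dynamics** on equiprobable-quantile alphabets (k = 2..5):
  length-3 word entropy and max frequency, binary above/below-mean run
  statistics, transition-matrix statistics (max/min off-diagonal, trace,
  joint entropy) and the slope of transition entropy vs alphabet size.
  Quantile symbolization is used for its amplitude-scale invariance.
* **Permutation entropy** of order-3 ordinal patterns at scales 1-5
  (non-overlapping mean coarse-graining).
* **AR modeling** by conditional least squares at orders 1-6: SBC and
  Akaike FPE per order, SBC-best order, AR(1) coefficient, a Ljung-Box-style
  residual-whiteness statistic, one-step error across 5 local segments
  (mean and spread), and multi-step prediction RMSE at horizons 1, 2, 5, 10
  (sd-normalized).
* **Stationarity**: sd across 100 random windows (10% of the series) of the
  window mean/sd/skewness/kurtosis, plus central-window vs global
  comparisons (absolute differences scaled by the global sd for mean and
  median — exact ratios are undefined for zero-mean audio — ratios for
  sd and IQR, differences for skewness and kurtosis).
* **Walker** (first-order pursuit `w_{t+1} = w_t + a(x_t − w_t)`) at
  attraction 0.1 and 0.5: mean walker-input difference, variance ratio,
  sign asymmetry.
* **Local forecasting**: mean-of-last-L prediction RMSE for L in
  {1, 2, 4, 8, 16} and the best L; symbolic surprise with 3 quantile
  symbols and memory 3, with add-one smoothing over the observed alphabet
  (applied only when more than one symbol exists, so constant series have
  zero surprise).
* **Successive-difference (HRV-style)** statistics: pNN fractions at 0.25,
  0.5 and 1 series-sd, RMSSD, sd of differences.
* **Iterated differencing**: sd (relative), lag-1 acf and normalized
  spectral median after 1-3 differencing passes; slopes of the three-point
  trajectories plus the first-iteration sd.

A separate 12-feature registry approximates the classic song-analysis
baseline (9.27 ms windows, 1.36 ms hop): mean pitch (per-frame
autocorrelation peak in 250-8000 Hz) and mean amplitude, plus mean and
variance of mean frequency, Wiener entropy, pitch goodness, frequency
modulation and amplitude modulation. These are plain spectral/
autocorrelation estimators — an explicitly approximate stand-in for the
original tool's algorithms. Frame amplitudes use Blackman-weighted RMS so
pure tones show no spurious AM from fractional cycles per frame.

Preprocessing mirrors stimulus conditioning: a 2-pole Butterworth band-pass
(250-8000 Hz) applied forward only, RMS normalization to a fixed digital
level (-20 dBFS; the original 73 dB SPL is a playback calibration with no
digital counterpart), and an optional inter-syllable silence gate with
cosine ramps.

## Feature matrix and normalization

Features are assembled motifs x features with NaN invalid markers.
Filtering drops any column that is constant, non-finite anywhere, or
contains an invalid marker — the retained set is the "consistently
extracted" set. Normalization is two-stage and strictly monotone per
column (rank-preserving):

1. per-bird robust sigmoid `v -> 1/(1 + exp(-(v - median)/(1.35·IQR)))`
   (1.35 ≈ 2·Φ⁻¹(0.75) standardizes the IQR to a Gaussian sd). Centering
   each bird at 0.5 removes bird identity so the combined classifier
   separates contexts, not individuals;
2. after concatenating birds over the shared feature set, min-max scaling
   to [0, 1] on the aggregate (idempotent; zero-range columns dropped).

## Classification

The classifier is a bagged ensemble of Gini decision trees with sqrt
feature subsetting at each split (300 trees; scikit-learn forest as the
tree machinery). The ensemble score is the fraction of trees voting
courtship; a score of exactly 0.5 predicts non-courtship, so the decision
rule is deterministic. Validation is stratified 10-fold cross-validation
(stratification avoids empty-class folds at small n), reshuffled over 10
iterations, reporting the median of per-iteration held-out accuracies
(motif-weighted; identical to fold-weighting when folds are equal).
Feature importance is mean impurity decrease, normalized to max 1, with
name tie-breaks for determinism. The top-50 evaluation restricts the
matrix to the 50 highest-importance features and reruns the CV; the
random-subset benchmark draws k features uniformly without replacement and
runs a single-shuffle 10-fold CV per draw. Confidence scores are
`|score − 0.5|`, signed positive when the prediction is correct. The
confidence-vs-subject analysis is an ordinary least-squares regression of
per-stimulus subject accuracy on confidence (a fixed-effects analogue of
the original subject-level mixed model, which is out of scope).

The random-50-vs-top-50 comparison deserves a caveat: its discriminative
power depends on the bank size. With thousands of features and a handful
informative, a random 50 is mostly noise; with this compact 143-feature
bank a random 50 typically contains a third of every informative family,
and because the injected contrasts give each latent effect several
near-noiseless readouts, random subsets can match the top-50 classifier.
The benchmark is implemented and reported faithfully; on synthetic data in
the sparse regime (many noise features, few informative) it behaves as in
the original analysis.

## Operant learning criterion

Daily percent correct is computed over responded, reward-balanced,
non-probe trials, keeping days with ≥ 20 responses. A four-parameter
logistic `L + (U − L)/(1 + exp(−s(day − d₀)))` is fit by least squares
(initialized at L = 50, U = max daily %, d₀ = mid-range, s = 1, bounded to
[0, 100] %); the performance threshold is the lower 95% confidence bound
of the upper asymptote U (t quantile on n − 4 dof from the fit
covariance). Non-convergence returns a "not learned" assessment rather
than raising.

The run-length rule finds the smallest r with `n_days · p_above^r < α`
(α = 0.05): the expected number of chance runs of length r is below α, a
bound that is conservative (never shorter than the exact run-occurrence
calculation, verified against a dynamic-programming oracle) and monotone
in both arguments. `p_above` defaults to the probability that a
*chance-level* (p = 0.5) day would clear the threshold, under a binomial
day model at the median daily response count — the natural null for a
criterion meant to make a run of supra-threshold days "appear non-random".
The observed fraction of supra-threshold days is available as an
alternative estimator; it is markedly more conservative, because a bird
performing near its own asymptote hovers around the threshold and the
required run inflates to the point where learning at the simulated study
conditions (500 trials/day, 50→85%) is detected in only ~10% of seeds,
versus ~90% for the chance-null estimator. Learning day is the first
qualifying day beginning ≥ r consecutive supra-threshold days; p_above of
exactly 1 makes no run length non-random (degenerate "unattainable").

Probe generalization tests each context's daily probe-correct proportions
against 0.5 (one-sample t test); "generalized" requires both contexts
significantly above chance, and a context with no responded probes blocks
generalization. Between-subject consistency uses Pearson correlations of
per-stimulus accuracy over all subject pairs sharing ≥ 3 stimuli.

## Problem sizes and determinism

Default analyses and the acceptance script run 8 birds x 16 training (+4
probe) renditions per context at 22.05 kHz (the 250-8000 Hz analysis band
sits well under the 11 kHz Nyquist), a 15-rendition zero-effect null, a
100-draw random-50 benchmark, and one simulated learner (30 days x 500
trials); the chance-level null control in the test suite uses 17 birds x
30 renditions (1020 motifs) so the binomial interval matches that scale.
All stochastic stages (generation, bootstrap features, tree training, CV
shuffles, benchmarks) are seeded; rerunning any stage with the same
configuration is bit-reproducible.

## Known limitations

* The syllable model is deliberately minimal; none of the within-syllable
  FM, noise syllables, or bout-level structure of real song is present.
* SAP-style features approximate the classic definitions; they are not
  numerically comparable to the original implementation's outputs.
* Effect sizes are free parameters of the generator, not estimates of real
  courtship/non-courtship contrasts (the original study quantifies
  direction, not magnitude).
* Mixed-effects inference, t-SNE visualization and cross-bird
  generalization of individual classifiers require real data or external
  statistics tooling and are out of scope.
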