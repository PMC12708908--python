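# Methods

## Problem and pipeline

Two participants converse through ten 2-minute intervals bracketed by two
quiet 2-minute baselines (12 intervals per dyad). Four autonomic channels
are recorded per participant — ECG, electrodermal activity (EDA, µS),
respiration, skin temperature — and each conversation interval carries
1–9 SAM valence and arousal ratings: a self rating per participant and
optionally a single observer rating per dyad. The pipeline estimates
those per-interval ratings from physiology in three settings: goal 1
(dyad-specific: a participant's model is trained on their own other
intervals), goal 2 (dyad-nonspecific, self ratings: trained on other
dyads), goal 3 (dyad-nonspecific, observer ratings).

## Signal preparation

Channels are band-limited with zero-phase Butterworth defaults (ECG
high-pass 0.5 Hz, EDA low-pass 1 Hz, respiration band-pass 0.05–1 Hz,
temperature low-pass 0.1 Hz); the exact coefficients are not load-bearing
and are exposed in `signal_prep.FILTER_DEFAULTS`. R-peaks and breath
peaks come from prominence-based detection with physiological refractory
periods (0.25 s ≈ 240 bpm ceiling; 1.0 s for breathing). Manual R-peak
review is replaced by an automatic plausibility flag (any inter-beat
interval outside 0.3–2 s). An SCR is a local maximum at least 0.05 µS
above the most recent local minimum ("previous valley") with the rise
completed within 5 s; amplitude is trough-to-peak. Instantaneous heart
and respiration rates are piecewise-constant 60/IBI signals resampled on
a 4 Hz grid with edge extension — the simplest scheme consistent with an
"instantaneous rate as a function of time", with the grid rate
configurable.

## Individual features (20)

HRV statistics use the standard short-recording set. Mean/min/max HR are
statistics of 60000/IBI; SDNN and all other spreads are sample (n−1)
standard deviations; pNN50's denominator is the number of successive
differences. LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) powers integrate a
Lomb–Scargle spectrum of the unevenly sampled IBI tachogram — no
resampling bias on 2-minute windows. The reported band powers are
relative (unnormalized periodogram integral); the LF/HF ratio is exact
and HF = 0 yields a missing ratio. Respiration mean/SD are computed over
the instantaneous-rate series (not breath-to-breath rates; the
alternative convention differs slightly and this choice is fixed here).
"Initial" in the delta features means the interval's first sample.
Missing values (e.g. SCR amplitude SD with fewer than two SCRs)
propagate as NaN and are median-imputed from training rows only at fit
time, keeping crossvalidation folds intact.

## Synchrony features (9 measures × 4 modalities)

Both series of a pair (EDA, temperature, instantaneous HR, instantaneous
respiration rate) are z-scored per interval and decimated to a common
4 Hz grid before any measure — distances are otherwise incomparable
across dyads; 4 Hz is ample for signals band-limited below 0.5 Hz. A
zero-variance series is only centered and flagged; correlation-type
measures go missing for it.

* **DTW**: classic unconstrained dynamic programming with
  absolute-difference local cost and symmetric steps, normalized by the
  optimal warping path's length (fewest steps among minimum-cost paths —
  the tie-break is part of the contract and matched by the exhaustive
  path-enumeration oracle in the tests).
* **Derivative DTW**: the same DTW applied to the local-slope transform
  d[i] = ((x[i]−x[i−1]) + (x[i+1]−x[i−1])/2)/2 with replicated endpoints.
* **Complexity-invariant DTW**: DTW × max(CE_a,CE_b)/min(CE_a,CE_b) with
  CE(x) = sqrt(Σ(x[i+1]−x[i])²); both flat → factor 1; exactly one flat →
  capped at 1e6.
* **Nonlinear interdependence**: delay embedding (m = 3, τ = 2 samples),
  k = 4 nearest neighbours with a Theiler window of 8 samples;
  S(A|B) = mean over points of R(A)/R(A|B) where R(A) is the mean squared
  distance to the true neighbours and R(A|B) uses the time indices of B's
  neighbours; symmetrized. 1 for identical series. Defaults are typical
  for slow autonomic series and configurable; values shift smoothly with
  m, τ, k, so comparisons should hold them fixed.
* **Coherence**: Welch magnitude-squared coherence (60 s windows, 50%
  overlap) averaged over 0.01–0.5 Hz — the band autonomic rhythms occupy
  at 2-minute windows.
* **Cross-correlation**: maximum |Pearson r| over lags within ±10 s
  (physiological response latencies); the sign is discarded.
* **Cosine distance**: 1 − cos of the angle between the two series as
  vectors.
* **Hausdorff** and **symmetric segment-path distance (SSPD)**: planar
  trajectory distances on points (λ·t, value). Such distances are
  meaningless until the axes share units, so λ rescales the time span to
  the joint range of the z-scored values; λ is configurable via the pair
  construction. SSPD averages each point's minimum distance to the other
  trajectory's segments, symmetrized.

## Feature table and designs

Conversation-interval features are baseline-normalized by subtracting the
dyad's first-baseline value (mode `mean-of-both` subtracts the average of
the two baselines). Normalization is applied uniformly — also before
dyad-specific regression, where it is a harmless constant shift — and a
flag prevents double application. Designs: goals 1–2 use the
participant's own 20 individual features + 36 synchrony features
(56 columns; the partner's individual features are never used in goal 1);
goal 3 uses both participants' individual features + synchrony
(76 columns). Optional participant characteristics add age, one-hot
gender (3 levels) and four trait scores per relevant participant.
A schema-driven loader ingests externally deposited feature/ratings
tables through a column map, so the regression stack also runs without
the signal stages.

## Feature selection and estimators

MRMR ranks greedily by relevance minus mean absolute correlation with the
already-selected set; relevance is the univariate F statistic mapped onto
the correlation scale (|r| = sqrt(F/(F+dof))) so the two terms are
commensurate. The Laplacian score uses a symmetrized k-nearest-neighbour
graph (k = 5) with heat-kernel weights (t = mean squared neighbour
distance); features are ranked ascending and constant features last.

The MLP is a single hidden layer of 10 tanh units with a linear output,
trained by Levenberg–Marquardt on the sum of squared errors (damping
0.001, ×10 / ÷10 schedule) for up to 1000 epochs. LM has no conventional
learning rate; a plain full-batch gradient-descent mode is provided where
the 0.1 learning rate applies literally. There is no validation-based
early stopping; training ends at the epoch cap or on standard optimizer
convergence (damping > 1e10, gradient ∞-norm < 1e-7, or an accepted step
improving the SSE by less than a relative `mlp_ftol`, default 1e-5 —
far below the resolution of a 1–9 rating scale). Linear regression
optionally carries lasso/ridge penalties with strengths chosen on the
validation unit from {1e-3, 1e-2, 0.1, 1, 10}; the SVR uses a Gaussian
kernel with the median-pairwise-distance width heuristic. All estimators
standardize inputs by training statistics and clip predictions to [1, 9].
The median-based estimator (MBE) predicts the median of the participant's
other nine intervals (goal 1) or of all pooled per-interval ratings of
the other dyads (goals 2–3; pooling intervals rather than per-participant
medians is the plainest reading of the protocol and the per-participant
variant is a one-line change).

## Crossvalidation and statistics

Goal 1: per participant, each conversation interval is the test once,
the cyclically next interval validates, the remaining eight train
(10 folds). Goals 2–3: each dyad is the test once with the cyclically
next dyad as validation (39:1:1 at 41 dyads; 33:1:1 at 35). Within a
fold, every candidate (selector ∈ {MRMR, Laplacian}, k ∈ 5..10,
hyper-parameter variant) of a method is fitted on training rows only;
the candidate with the lowest validation RMS is applied to the test rows
(ties break toward fewer features, then candidate order). Model seeds
derive deterministically from (master seed, goal, fold, candidate).
Per unit (participant, or dyad in goal 3) the mean-absolute and RMS
errors over its 10 test intervals are reported; RMS ≥ MA (power-mean
inequality) is asserted on every summary. Methods are compared with a
repeated-measures ANOVA followed by Holm–Šidák-adjusted pairwise tests;
paired secondary comparisons (synchrony ablation, characteristics
augmentation) use a paired t-test when Shapiro–Wilk accepts normality of
the differences at α = 0.05 and Wilcoxon otherwise. MA and RMS are
adjusted as separate families.

## Synthetic cohort generator

The generator is a stand-in with the statistical structure the analysis
assumes, not a physiological model. Per dyad and component (valence,
arousal), an AR(1) shared state s and individual states e evolve over
conversation intervals; participant p's latent is
coupling·s + (1−coupling)·e_p + divergence_p, with an AR(1) divergence
term (scale 0.4) so partners can disagree, as real partners do. Baseline
intervals have latent exactly zero (rest), which makes
baseline-normalized features affine in the conversation latents. Within
an interval a slow common process (≈3 s timescale), mixed by the same
coupling weight, modulates heart rate, respiration rate, EDA and
temperature, so signal-level synchrony increases monotonically with
`coupling`. Channels: an ECG-like train of narrow pulses whose spacing
follows an arousal-modulated rate (8 bpm per unit latent) — unambiguous
R-peaks are what downstream code consumes, not morphology; EDA as tonic
drift plus SCR bumps (smoothstep rise completing in 1–2.5 s, 4 s
exponential decay, amplitudes ≥ 0.08 µS) with Poisson rate increasing in
arousal; respiration as a rate-modulated oscillation; temperature as slow
drift with a weak valence trend. Ratings are 5 + 1.5·latent (+ Gaussian
noise, SD 0.5 by default), rounded half-up and clipped to 1–9; observer
ratings map the dyad-mean latent. Participant characteristics draw from
the cohort's reported distributions, clipped to instrument ranges.
Defaults: 41 dyads, 10 conversation intervals of 120 s, 100 Hz sampling
(600 Hz available by config; no extracted feature depends on content
above ~50 Hz, and 100 Hz keeps desk-scale runtime).

What the generator does not emulate: realistic ECG/EDA morphology, motion
artifacts, missing channels, rater idiosyncrasies, or any claim about the
distributional form of real recordings. Passing tests therefore
demonstrate that the pipeline recovers structure it is pointed at — not
field performance on human data.

A feature-level generator (`synthetic_feature_table`) builds normalized
feature tables directly, with labels either an affine function of three
named features (two individual, one synchrony-only) plus noise (SD 0.5)
or independent of all features. The stochastic recovery checks run at
this level — 41-dyad cohorts, 20 replicates, single MLP candidate
(MRMR, k = 10) — because the signal path's correctness is covered by its
own deterministic tests and repeating it per replicate adds cost, not
evidence.

## Numerical choices and limitations

* DTW tie-breaks (minimum cost, then minimum path length) are explicit so
  the implementation and its enumeration oracle agree exactly.
* The Lomb–Scargle band powers are relative, not calibrated ms²; only
  comparisons and the LF/HF ratio should be interpreted.
* Degenerate inputs: flat signals raise quality errors at detection
  (fewer than 2 peaks), yield missing features downstream, or flagged
  degenerate pairs in synchrony; constant training labels short-circuit
  every estimator to that constant; an empty rating pool is an error.
* The acceptance script runs the full three-goal protocol on a 41-dyad
  synthetic cohort with a reduced validation grid (both selectors,
  k ∈ {5, 10}, one penalty variant per method) — the package's chosen
  desk-scale configuration; the full grid is available through
  `evaluation.default_candidates`.
* Dyad-specific models (8 training rows, 56 candidate features) overfit
  by construction; that regime is reported, not fixed, and the
  training-vs-test error gap is part of the standard report.
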