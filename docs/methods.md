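# Methods

## Problem and data model

`keydyn` analyses short touchscreen typing sessions for signs of early
Parkinsonian fine-motor decline. A session is an ordered list of keystroke
events, each carrying a press timestamp, a release timestamp (both integer
milliseconds) and the OS-reported normalised pressure in [0, 1]. The
content of the text is never used: the method is privacy-aware by
construction. Sessions typed slower than 20 characters per minute
(N keys over last-release-minus-first-press; the bound is inclusive, and a
single-event session has an undefined rate and fails) are excluded, since
windowed statistics of extremely sparse typing are not meaningful.

## Variable sequences

Hold times HT_n = t^r_n − t^p_n and pressures NP_n are used raw. Flight
times FT_n = t^p_{n+1} − t^r_n are conditionally filtered into normalised
flight times (NFT) in three ordered steps:

1. remove values above 3 s (reading pauses and interruptions);
2. subtract the mean of the survivors (one global detrend per session);
3. remove detrended values outside [−1.27, 1.7] s, the 99% interval of a
   real-life reference distribution, taken as a fixed constant.

The order matters and is pinned by tests against a permuted-order oracle.
Because step 3 can remove mass asymmetrically, the post-filter mean is only
approximately zero (exactly zero when step 3 removes nothing); no
re-detrending is applied. Negative raw flight times (overlapping taps) are
retained through step 1 — the 3 s threshold is an upper bound only — and
handled by step 3's lower bound. Timestamps are integers in ms on disk and
converted to seconds internally, so features live on the seconds scale.

## Windowing

Each sequence is split into non-overlapping 15 s windows, with the clock
starting at the session's first press. An element belongs to window i when
its anchor interval lies inside the window: for HT the anchors are the
key's press and release, for NP the press alone, for NFT the first key's
release and the next key's press. The upper edge is strict (an element
straddling a boundary belongs to neither window); the lower edge is
inclusive so that the session's first keystroke, whose press time defines
t = 0, belongs to window 1 — with a strict lower edge it would always be
discarded, which cannot be the intent. Windows with fewer than five
elements are dropped; a session with no valid window contributes no feature
vector for that variable.

## Window statistics and the feature vector

Per window: mean μ; sample standard deviation σ with an (n−1) denominator;
skewness S and raw (non-excess) kurtosis K as the third and fourth powers
of (a_k − μ)/σ averaged with an n denominator. The mixed convention
(σ with n−1, S and K with n) is deliberate and pinned by brute-force
oracle tests; it differs from scipy's population-moment convention by
((n−1)/n)^{3/2} resp. ((n−1)/n)^2. Windows with zero dispersion are
dropped (their standardized moments are undefined) with a logged warning.

Each window also gets a Gaussian-kernel density estimate
f(x) = (1/(n b)) Σ_k φ((x − a_k)/b) evaluated on a fixed 10-point grid with
fixed per-variable bandwidths b = 0.0060 (HT), 0.0289 (NFT), 0.0300 (NP) —
external reference constants, not re-estimated. Grids are fixed per
variable (HT on [0, 1] s, NFT on [−1.27, 1.7] s, NP on [0, 1]) and shared
by all windows and sessions; window-dependent grids would make the
between-window covariances incoherent. The sample covariance between
window PDFs over the L = 10 grid points, C(i,j) = Σ_X (f^i − f̄^i)(f^j −
f̄^j)/(L−1), is summarised over its strict upper triangle (diagonal
excluded — with W windows C_U has W(W−1)/2 entries; inclusion of the
diagonal is a plausible alternative and the choice is centralised in
`pdf_covariance`).

The session vector aggregates mean and std (ddof = 1) of each moment
across windows plus the three C_U summaries: 11 components for HT and NP,
9 for NFT (μ̄ and σ_μ omitted because NFT is zero-mean by construction).
Degenerate cases: a single-window session gets zero across-window stds and
zero covariance summaries (C_U is empty), keeping the vector length fixed.

## Two-stage classification under LOSO

For every left-out subject, the remaining sessions are split 80/20 at the
session level, stratified by label, with one split shared by all three
variables so the test part yields complete probability triplets. The
literal session-level random split is the default; a subject-grouped split
is available via `PipelineConfig(subject_grouped_split=True)`. On the 80%
part, each variable gets a first-stage model: recursive feature
elimination (least-important feature dropped per round) down to at most
five features, ranked by Lasso (alpha = 0.01) or Ridge (alpha = 1.0)
coefficient magnitudes on the 0/1 labels or by random-forest Gini
importances; then a grid search over a small fixed hyperparameter grid
with an inner stratified 4-fold cross-validation scored by AUC (consistent
with the ROC-based evaluation), refit on the full training part.
Supported classifiers: linear SVM, logistic regression, random forest,
k-nearest neighbours; the default configuration is ridge selection with a
random forest. The first-stage models score the 20% part; sessions with
all three probabilities present train the logistic-regression fusion
(same inner-CV grid search). The left-out subject's sessions pass through
both stages — a missing channel probability (e.g. NFT emptied by the
filter) is imputed with 0.5 and logged — and the mean (or median) of the
fused probabilities is the subject's score, thresholded at 0.5 outside ROC
analysis. The 80/20 split is re-drawn (seeded) in every loop; one master
seed drives splits, selectors and classifiers, and every loop asserts that
the left-out subject's sessions are absent from all training inputs.

Inner folds degrade gracefully: the fold count is capped at the minority
class count, and when CV is infeasible the model is fitted plainly with a
logged warning.

## Evaluation

Bootstrap ROC resamples subjects — the unit of classification — with
replacement (1,000 draws by default); single-class resamples are redrawn
and counted. Reported: the point ROC curve and AUC, the bootstrap mean
AUC, the percentile 95% interval, and the equal-cost operating point
(Youden's sensitivity + specificity maximum, trapezoidal ROC with
simultaneous threshold crossing for ties). The AUC-vs-session-count curve
re-votes each subject over random subsets of s of their fused
probabilities (all of them when fewer exist), averaged over seeded
repeats, for both mean and median voting.

Group-level feature comparisons use the two-sided Mann-Whitney U test over
sessions pooled per group, via scipy's auto method: exact enumeration for
small tie-free samples, normal approximation with tie correction
otherwise; constant features are reported as degenerate rather than given
a p-value. Feature-clinical-score relationships use Spearman rank
correlation of per-subject feature means (aggregation over a subject's
sessions is by mean) against UPDRS Part III item scores; controls score
zero on every item, which skews the item variables and is exactly why a
rank-based coefficient is used.

## Synthetic cohorts

No public dataset exists for this task, so the generator emulates the
study conditions. Per keystroke, hold time is log-normal with the
profile's mean and std; flight time is log-normal with the profile's mean
and a shape parameter, replaced with probability 0.02 by a uniform draw on
[3.5, 10] s (a reading stall the 3 s filter must remove); pressure is
normal truncated to [0, 1]. Timestamps accumulate and are rounded to
integer milliseconds, so the sequence extractors recover the drawn values
exactly. Group anchors: control HT 0.09/0.02 s, NP 0.60; PD HT 0.15/0.03 s,
NP 0.51 — the reported group statistics. The flight-time shapes (0.89
control, 0.477 PD) were moment-matched by simulation so that the
cohort-level mean of the windowed NFT skewness equals the reported
1.51 / 0.90 after the full conditional filter; matching had to be done at
the windowed, post-filter, cohort level because sample skewness of
~5-40-element windows is biased relative to the population value, the
interval filter trims the upper tail, and the between-subject shape jitter
enters nonlinearly.

Cohorts draw a latent severity u ~ U(0, 1) per subject, which produces
unit-mean multiplicative jitter of the timing/pressure parameters
(between-subject heterogeneity) and, for PD subjects, monotone noisy UPDRS
Part III item scores (right-hand items linked most strongly — the emulated
cohort types right-handed), planting a recoverable feature-score
association. Controls score zero on every item. Crucially, each channel's
subject effect is only partly the shared severity (weight 0.55) and partly
an independent channel-specific component of equal variance: typists
differ in *which* keystroke variable carries their deficit (one may show
only longer holds, another mainly softer presses). This cross-channel
heterogeneity is what the two-stage multi-model design exploits; a
generator with one fully shared severity would make the three channels
redundant and stacking pointless. The flight-time shape receives a
median-one log-normal subject multiplier (log-sd 0.4, severity-linked
through the same mixing), sized so the across-session spread of the
windowed NFT skewness matches the reported group stds (~0.5-0.7) —
without it every subject shares the group's flight-time shape and the NFT
channel becomes unrealistically clean.
Session-to-session variation is a unit-mean log-normal timing multiplier
(log-sd 0.24) plus a pressure-mean shift (sd 0.035); together with the
between-subject components these defaults were set so the across-session
standard deviations of the headline session features match the reported
group spreads (PD HT μ̄ ≈ 0.15/0.06, HT σ̄ ≈ 0.03/0.01, NP μ̄ ≈ 0.51/0.06;
control analogues likewise). The split of that total spread between its
between-subject and within-subject parts is not fixed by the group
summaries, so it was calibrated against the reported classification
behaviour instead: with the defaults, single-channel subject-level AUCs on
default cohorts land around 0.8-0.95 and the fused AUC around 0.93-0.98,
reproducing the reported ordering in which every individual keystroke
variable performs clearly worse than their fusion. The
parameter jitter is applied in
parameter space with unit mean — rather than by jittering the severity
coordinate — so cohort expectations stay exactly on the group anchors;
`make_profile(group, severity=s)` still provides the monotone control-to-PD
interpolation (severity 0 reproduces the control profile, 1 the PD
profile). Excerpt lengths are uniform on 46-115 characters, 10 sessions
per subject by default, and the default cohort shape is 18 PD / 15
controls.

What the generator does not emulate: key-identity or layout effects,
fatigue or learning across sessions, correlated hold/flight dynamics
within a burst, device differences, and the full heavy-tailed
between-subject heterogeneity of real cohorts. Passing tests therefore
demonstrate internal correctness and parameter recovery under the stated
distributional assumptions, not clinical performance on real data.

## Problem sizes used by the test suite and acceptance script

The parameter-recovery study uses the study's session counts: 18 PD
subjects × 8 sessions (144 PD sessions) and 14 control subjects × 10
sessions, of which the first 131 are used. Recovered statistics are
reported with subject-level (cluster) standard errors, since sessions
share their subject's jittered parameters; the acceptance test requires
agreement with the generating value within two such standard errors. The
pipeline-property study runs 20 replicate cohorts of 18 PD / 15 controls
× 10 sessions through full LOSO with the default configuration at 15
trees per forest, and checks: fused subject-level AUC at least the best
single-variable AUC in ≥ 16/20 replicates; the session-count AUC curve
non-decreasing from 1 to 10 sessions within Monte-Carlo error; and mean
voting at least matching median voting at 10 sessions in a majority of
replicates. Bootstrap sizes are 1,000 for reported intervals and reduced
(100-200) inside invariance tests.

## Known limitations

* The KDE grid ranges and the diagonal-exclusion convention for C_U are
  package choices where the design was open; both are centralised and
  documented above for sensitivity analysis.
* The fusion stage needs both classes among the complete probability
  triplets of the 20% split; with very small cohorts it falls back to
  imputed triplets and a plain fit, with warnings.
* Bootstrap resampling is at the subject level only; session-level
  resampling would understate subject-level uncertainty.
* The real study cohort's headline discrimination cannot be reproduced
  here because that dataset is private; all empirical results in this
  repository are computed on synthetic cohorts by the tests and the
  acceptance script.
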