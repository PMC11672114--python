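# Methods

This note documents the models, estimator settings and design choices behind
`earsim`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## Study design emulated by the synthetic generator

The pipeline targets a two-device overnight setting: a clinical PSG system
sampling at 256 Hz and a single-channel in-ear EEG device at 250 Hz,
recorded simultaneously, each staged independently by three experts in
30-second epochs over {W, N1, N2, N3, REM, MOVEMENT, UNKNOWN}. The three
non-REM stages are merged into NREM, so all analyses run on the 3-class
alphabet {W, NREM, REM}; MOVEMENT/UNKNOWN epochs are carried with an
exclusion flag and never enter any statistic. The 21 analysed PSG channels
(set *Q*) are the two mastoids, six bipolar and six unipolar scalp-EEG
derivations, four bipolar and two unipolar EOG derivations, and M2-M1;
the in-ear channel is called CH1.

`earsim.synth` emulates exactly the statistical structure the analysis
relies on, and nothing more:

* **Stages** follow a first-order Markov chain over {W, NREM, REM} (rows of
  the default transition matrix: W [0.90, 0.10, 0], NREM [0.02, 0.93, 0.05],
  REM [0.05, 0.15, 0.80]), or a caller-supplied fixed sequence for
  controlled experiments.
* **Signals**: each electrode's 30-s epoch is a mixture of band-limited
  Gaussian noise (4th-order Butterworth bands δ 0.5–4, θ 4–8, α 8–12,
  σ 12–16, β 16–30, γ 30–35 Hz), mixed with per-stage relative power
  weights, over a 1/f background at 20 % relative power. Default weights
  make W α/β-rich, NREM δ/σ-dominant and REM θ-mixed — caricatures of sleep
  EEG chosen once as "realistic enough to rank bands correctly", not fitted
  to anything.
* **The in-ear channel** is the mean of the scalp electrodes,
  polyphase-resampled 256→250 Hz, attenuated (gain 0.6) and contaminated
  with white noise (sd 0.3 × source sd). "Similar but degraded" is thereby
  true by construction, which is what the recovery experiment exploits.
* **Scorer panels** draw each epoch's label from a per-scorer 3×3 confusion
  matrix conditioned on the true stage, with an optional probability of
  MOVEMENT/UNKNOWN insertion. Label noise and signal noise are strictly
  orthogonal: the signal generator never produces artifact labels.

What the generator does **not** model: sleep microstructure (spindles,
K-complexes, arousals), eye-movement waveforms in the EOG channels, real
inter-channel covariance structure, non-stationarity within epochs, or any
artifact taxonomy beyond flat (constant) segments. Passing tests on this
synthetic data therefore demonstrate *internal correctness and parameter
recovery*, not clinical validity on real recordings.

## Preprocessing

* Band-pass: 0.2–35 Hz for PSG, 0.5–35 Hz for the in-ear channel, 4th-order
  Butterworth applied forward–backward (`sosfiltfilt`, zero phase). Order
  and edges are config keys; only the edges are part of the study design.
* In-ear amplitude scaling: the in-ear signal is multiplied by the ratio of
  a PSG reference standard deviation to its own. The reference defaults to
  the **mean std across scalp-EEG derivations** (robust to a single bad
  channel) and can be pinned to any named channel. Which PSG channel(s)
  should define the ratio is genuinely open; the mean-scalp rule is this
  package's documented default, not a convention of the field.
* Alignment: a per-subject config offset (seconds) replaces manual
  artifact-based synchronization; both recordings are then cropped to their
  overlapping wall-clock interval and the epoch grid is anchored at the
  common start (no partial first or last epoch).
* Epoching: non-overlapping 30-s epochs at each channel's native rate —
  256 Hz and 250 Hz epochs deliberately differ in sample count; nothing is
  resampled after the in-ear synthesis step.
* Noisy-epoch rule: an epoch is flagged when its peak-to-peak amplitude is
  ≤ `flat_tol` (default 1e-9 in signal units — "no signal"); a channel is
  excluded when its flagged fraction exceeds `channel_exclude_frac`
  (default 0.5, comfortably below the 79–82 % that motivates the rule).

## Consensus and agreement

Soft-agreement of scorer *j*: one-hot encode the other *J*−1 scorers'
labels, sum per epoch, normalize by the per-epoch maximum count (so every
stage in the others' majority-or-tie set scores 1), and average the value at
scorer *j*'s own label over epochs. Epochs where **any** scorer assigned
MOVEMENT/UNKNOWN are removed first, keeping K = 3 in the encoding. The
consensus is the strict per-epoch majority; tied epochs take the label of
the top-ranked scorer by soft-agreement, with equal scores broken by
ascending scorer index — a documented determinism choice for the case of
equal reliability scores. Consensus is computed per subject and per
source; the feature track uses only epochs where the PSG and in-ear
consensus agree (the intersection).

Cohen's κ is computed from the closed form (p_o − p_e)/(1 − p_e) with
marginal-product p_e, returning 1 in the degenerate p_o = p_e = 1 case;
pairwise comparisons drop the union of the two hypnograms'
MOVEMENT/UNKNOWN epochs. Fleiss' κ comes from statsmodels; the
all-raters-one-category case is reported as NaN with a warning. Landis–Koch
bands: poor < 0, slight ≤ 0.20, fair ≤ 0.40, moderate ≤ 0.60, substantial
≤ 0.80, almost-perfect above. Per-stage precision/recall/F1 use the PSG
consensus as gold; a stage never predicted yields precision 0 with an
explicit flag (keeping cross-subject averages defined), and a stage absent
from both sides is reported missing.

## Feature bank

Every epoch is divided by its maximum absolute value before feature
extraction, so amplitude-dependent features (std, IQR, max first
difference, Hjorth activity, spectral energy) compensate for gain
differences between devices; the remaining features are scale-invariant.

PSD: Welch periodogram, 5-s Hamming segments, 50 % overlap, **median**
averaging across the 11 segments of a 30-s epoch (damps isolated
artifacts; scipy's median-bias-corrected estimator). The grid spacing is
1/5 s = 0.2 Hz at any sampling rate.

Time block (18 features): std, IQR, skewness, excess kurtosis, max |first
difference|, zero crossings, approximate entropy, sample entropy, SVD
entropy, permutation entropy, Lempel–Ziv complexity, DFA exponent, Hjorth
activity/mobility/complexity, Katz/Higuchi/Petrosian fractal dimensions.

Frequency block (27 features): spectral energy (integrated PSD of the
max-normalized epoch over 0.5–35 Hz); six relative band powers (band edges
half-open [lo, hi), γ closing at 35 Hz, so the bands tile the analysis
range and relative powers sum to 1); the nine band ratios δ/θ, δ/σ, δ/β,
θ/α, δ/α, α/β, δ/(α+β), θ/(α+β), δ/(α+β+θ); spectral mean, variance,
skewness, excess kurtosis (treating the normalized PSD as a distribution
over the frequency grid); normalized spectral entropy (base 2; 1 for a flat
density); Rényi entropy (order 2); spectral centroid, crest factor
(max/mean), flatness (geometric/arithmetic mean), roll-off (85 %
cumulative power) and spread.

Estimator settings, all exposed in `FeatureParams` and chosen as the
conventional defaults: ApEn/SampEn m = 2, r = 0.2 × epoch std (Chebyshev
metric; SampEn excludes self-matches over the first n−m templates, ApEn
includes them); permutation/SVD entropy order 3, delay 1, normalized;
Lempel–Ziv on the median-binarized epoch via LZ76 exhaustive parsing,
normalized by n/log₂n; DFA over log-spaced windows from 16 to n/4 samples
with linear detrending; Higuchi k_max = 10. ApEn/SampEn share one
sorted-template counting sweep and LZ76 uses a longest-match scan, both
numba-compiled; tests pin them to brute-force oracles.

Degenerate inputs: a constant epoch returns std = 0, zero crossings = 0 and
NaN for entropies/fractal dimensions; a zero-power spectrum returns NaN for
the frequency block. NaNs propagate as flagged missing values and are
dropped **per feature** at PDF-estimation time, never by discarding whole
epochs.

## Feature selection

Datasets are built per (channel, stage) from intersection epochs and
z-scored per dataset (population std; constant columns flagged and
excluded). The pairwise dissimilarity is the maximal information
compression index — the smaller eigenvalue of the 2×2 covariance of a
feature pair:

λ₂ = (v_x + v_y − sqrt((v_x + v_y)² − 4 v_x v_y (1 − ρ²))) / 2,

zero iff the pair is perfectly linearly dependent; on z-scored columns it
reduces exactly to 1 − |ρ|, an identity used as a test oracle. Selection
repeatedly keeps the feature whose k-th nearest neighbour is closest,
discards those k neighbours, and shrinks k when fewer features remain. The
initial k is scanned over 1…min(10, N−2) and chosen to maximize the
representation entropy of the selected subset (entropy of normalized
covariance eigenvalues, natural log), ties broken toward lower redundancy
rate (mean |ρ| over distinct pairs), then smaller k — fully deterministic.

Two deliberate interpretations, flagged as such: (1) the dissimilarity is
the original published MICI rather than any of the modified variants in
circulation, whose definitions are not openly documented; (2) selection runs once per
channel pair on the row-wise concatenation of the two z-scored datasets, so
both sides of a comparison share one feature list — the alternative
(independent selection per dataset) would leave the index comparing
different feature sets.

## JSD-FSI

For each selected feature, both samples (after NaN removal; minimum size
M_min = 5, below which the feature is skipped and excluded from N) are
turned into discrete PDFs: Gaussian KDE with Scott bandwidth evaluated on
one shared 256-point grid spanning the union range padded by three
bandwidths, renormalized to sum to 1; zero-variance samples become a point
mass on the nearest grid cell. A shared-bin histogram estimator is
available as a config alternative because absolute JSD values depend on the
estimator — which also means JSD-FSI magnitudes are comparable only within
one estimator setting, and published values from other PDF estimators
cannot be expected to match digit-for-digit.

JSD uses base-2 logarithms, making it 0 for identical and exactly 1 for
disjoint distributions (a natural-log mode exists but is not the default;
the mixture-average form is required for symmetry and boundedness). The
JSD-FSI of a pair is the mean of (1 − JSD_n) over the selected features.
Stages with fewer than M_min intersection epochs are skipped per subject —
the same rule that removes REM for subjects without REM agreement. For each
stage and subject the pipeline emits 21 {q, CH1} scores and, as a
reference, the 210 unordered PSG-to-PSG scores, tagged scalp-to-scalp,
scalp-to-EOG or EOG-to-EOG (the mastoid-to-mastoid derivation is analysed
among the scalp set).

## Statistical battery and reports

Groups of scores (e.g. in-ear JSD-FSI by stage) are compared with a
Shapiro–Wilk gate at α = 0.05: only if **every** group passes does the
parametric branch run (one-way ANOVA, pairwise t-tests); otherwise
Kruskal–Wallis with pairwise Mann–Whitney U. Exactly one branch runs per
comparison; raw p-values are reported (a Bonferroni/Holm option exists but
defaults off). Groups below 3 values are skipped with a record. Summary
tables render per-subject × stage scores as "x.xx ± x.xx" with a pooled
Average row and a dash for absent stages; stage-count tables print counts
with one-decimal percentages of the row total.

## Problem sizes and validation

The test suite and the acceptance script run the pipeline at deliberately
small scale: single synthetic subjects of 18–36 epochs (6–12 per stage),
the full 21-channel montage for the combinatorics and pipeline checks, and
2 PSG channels for the replicated recovery experiment. The stage-recovery
experiment (20 seeded replicates) asks whether, per stage, the mean JSD-FSI
between PSG channels and the matched in-ear channel exceeds the mean
against a surrogate in-ear channel synthesized with cyclically shifted
stage band weights; with the default generator settings the margin is
large (≈ 0.3–0.4) and recovery succeeds in 100 % of replicates.

## Known limitations

* Feature-bank estimator settings (entropy tolerances, embedding orders,
  roll-off percentile, Rényi order) are conventional defaults chosen by
  this package; JSD-FSI magnitudes shift with the PDF estimator, bandwidth
  and grid, so scores are comparable only within one configuration.
* The synthetic EOG channels carry no ocular dynamics, so scalp-vs-EOG
  contrasts on synthetic data are weaker than on real recordings.
* Consensus supports hard labels only (no probabilistic consensus) and
  exactly the 3-class alphabet after mapping.
* EDF support covers plain 16-bit EDF with one-second records — sufficient
  for interchange here, not a general EDF+ implementation.
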