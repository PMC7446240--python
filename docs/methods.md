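# Methods

This note documents the models, estimators, numerical choices and
simulation designs implemented in `spatemp_rsa`, in the package's own
terms. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## The analysis problem

A condition-rich motor experiment presents 26 hand movements while
recording hand kinematics (14-channel fiber-optic data glove, 60 Hz),
muscle activity (15-channel surface EMG), fMRI-like voxel time series on
a cortical surface, and source-reconstructed MEG-like virtual sensors
(31 sources, 600 Hz). RSA reduces each modality to a condition ×
condition representational dissimilarity matrix (RDM) and asks where and
when the *neural* RDM mirrors a candidate *model* RDM.

## Model RDMs

- **Kinematic / muscle models.** Condition-average channel timecourses
  are correlated per channel (Pearson, over samples), Fisher
  z-transformed, averaged over channels, transformed back, and expressed
  as `1 − r`. At `r = ±1` the correlation is clipped to `±(1 − 1e−10)`
  before `atanh` so noiseless fixtures stay finite. A channel whose
  timecourse is constant for either member of a pair is dropped from
  that pair's average with a logged warning. EMG trials pass through
  multivariate noise normalization (below) before correlation.
- **Ethological model.** Binary: 0 within an action category
  (precision-prehensile, power-prehensile, nonprehensile), 1 across.
  The per-movement category assignment (6 precision, 4 power, 16
  nonprehensile) is made from the movement descriptions and is part of
  the package's fixture, as is the binary coding; a graded coding could
  be substituted by supplying a different matrix.
- **Onset detection.** Envelope = |analytic signal| (Hilbert), optional
  moving-average smoothing (5 ms default for EMG, none for glove);
  adaptive threshold = envelope mean + 1 SD recomputed per trial; onset
  = first sample of the first suprathreshold run lasting ≥ 200 ms.
  Edge ringing of the envelope spreads detected step edges by up to
  ~15 ms at 1 kHz; sine-burst onsets are recovered within ~2 ms.
  Trials where no channel yields an onset are flagged (`None`), not
  dropped silently.
- **Display utilities.** Hierarchical clustering is average-linkage
  (UPGMA) implemented with a deterministic lowest-index tie-break, so an
  all-equal RDM yields the identity leaf order (library linkage
  routines do not guarantee this tie rule, which is why the
  agglomeration loop is written out; n ≤ 26 makes cost irrelevant).
  MDS is metric SMACOF (scikit-learn), 100 random restarts, best by raw
  stress, reported as normalized Kruskal stress-1; an all-zero RDM
  short-circuits to coincident points.

## Crossnobis machinery

- **Noise covariance.** Σ̂ = RᵀR/T from residuals, blended toward its
  diagonal with either a fixed fraction or an analytic
  (Ledoit–Wolf-style, Schäfer–Strimmer) intensity. Inversions apply a
  relative eigenvalue floor of 1e−8 × the largest eigenvalue. Shrinkage
  is necessary because searchlight-sized V approaches the available T.
- **Covariance scope.** Estimated locally per searchlight (or per
  source set) from run-wise residuals, never over the whole feature
  field: a whole-field V × V inverse square root is neither
  statistically nor computationally justified at these sizes.
- **Distance.** Fold A = one run/partition, fold B = mean of the rest,
  every fold serving once as A ("leave-one-fold-out"); an
  all-unordered-pairs scheme is available (`scheme="pairs"`), and the
  two coincide for two folds. Distances are divided by the feature
  count V so searchlights of unequal size are comparable
  (`normalize_by_features=False` turns this off). Entries are unbiased
  and may be negative; the suite verifies both the noiseless oracle
  equivalence (against a directly computed squared Mahalanobis
  distance, to 1e−8) and the null sign-symmetry (sign test over 1000
  pure-noise simulations).
- **Comparison.** Spearman ρ over the condensed lower triangle,
  average ranks for ties; the partial variant rank-transforms all three
  vectors and applies the first-order partial-correlation identity.
  The implementation is checked against an independent partial
  correlation routine (pingouin) in the tests.
- **Noise ceiling.** Upper bound = mean Spearman correlation of each
  subject's RDM with the unweighted cross-subject mean RDM. Because
  each subject is included in the mean, the bound is optimistic on pure
  noise — the tests demonstrate (rather than correct) this bias. A
  leave-one-out lower bound is provided as a companion utility.
  By convention a constant rank vector yields ρ = 0 so degenerate
  cohorts (e.g. rank-opposite subjects averaging to a constant RDM)
  produce finite ceilings.

## Spatial pipeline

- **GLM.** Per run: one boxcar regressor per condition convolved with a
  single-gamma HRF (unit peak at 6 s, no undershoot — common defaults),
  plus its temporal derivative, plus an intercept: 52 condition
  regressors for 26 movements. OLS via least squares; rank-deficient
  designs are rejected with the offending columns named. No
  autocorrelation prewhitening is applied; the synthetic AR(1) noise
  (coefficient 0.3, a typical fMRI value) mildly violates OLS
  assumptions, which is acceptable for rank-based ρ statistics and is
  exactly the situation the recovery simulations measure.
- **Searchlights.** Graph-geodesic neighbourhoods (Dijkstra over mesh
  edges with Euclidean lengths) of diameter 10 mm by default, own
  vertex always included; verified against an independent shortest-path
  oracle. Gray-matter or trans-sulcal masking of real cortical
  surfaces is out of scope — the mesh `feature_map` abstraction stands
  in for it.
- **Inference.** Fixed-effects randomization: condition labels of each
  searchlight's data RDM are permuted (an index gather on the condensed
  vector — equivalent to relabeling before distance computation under
  the null, and standard practice); the spatial peak ρ of each
  permutation forms the maximum distribution; the threshold is the
  k-th largest null maximum with k = ⌊α(B+1)⌋, giving exact level
  k/(B+1) ≈ α. A full re-fit permutation mode is intentionally not the
  default (cost grows with the map size and the RDM-permutation is the
  exchangeable-null equivalent).
- **Group level.** Binary suprathreshold masks are summed into a
  heatmap; the kinematic-vs-muscle style contrast is a one-sided
  Wilcoxon signed-rank per vertex (exact null for n ≤ 25 without
  zeros), Benjamini–Hochberg FDR at α = 0.05 over analyzed vertices;
  all-zero difference vertices get p = 1.

## Temporal pipeline

- **Windows.** Half-open `[s, s + width)` with the end-strict rule
  `s + width < epoch_end`: a 2 s epoch at 20 ms / 5 ms yields 396
  windows. When the width spans the whole epoch the single full-epoch
  window is admitted (the strict rule alone would yield zero).
- **Features.** Per window, the feature vector concatenates the raw
  band-filtered samples of all sources — the literal reading of
  "frequency-filtered signal"; amplitude-envelope features can be
  obtained by transforming the epochs before windowing.
- **Filtering.** Zero-phase 4th-order Butterworth (`sosfiltfilt`); band
  presets alpha 7–14, beta 15–30, gamma 30–100, broadband 7–100 Hz.
  A broadband 5–100 Hz variant can be requested explicitly as a tuple.
- **Partitions.** Trials are shuffled (seeded) per condition and dealt
  round-robin: 50 trials → 10 partitions of 5; 43 trials → sizes
  {5, 5, 5, 4 × 7}, every trial used once.
- **Cluster inference.** Null = model-RDM label shuffles (1000 by
  default); cluster-forming threshold = per-window (1 − 0.01) quantile
  of the null *including the observed timecourse* (the identity member
  of the randomization distribution — excluding it measurably inflates
  the type-I rate, which the suite checks by Monte-Carlo); clusters =
  maximal suprathreshold runs scored by mass (sum of ρ; the choice of
  mass over extent is a convention); cluster p = (1 + #{null max-mass ≥
  observed}) / (B + 1); significant at α = 0.001 by default.

## Synthetic data: what is emulated, and what is not

Generators plant a known geometry so that recovery is measurable:

- **Correlation plants (glove/EMG).** The target RDM D is mapped to the
  correlation matrix C = exp(−D/max D) (positive definite for
  Euclidean-embeddable targets; 1 − C is strictly increasing in D, so
  the recovered 1 − r model is rank-identical to the target — the
  tests assert Spearman ρ = 1.0 exactly at zero noise). Condition
  timecourses are built on an orthonormalized raised-cosine bump basis
  with coefficient Gram matrix C, scaled to unit RMS so `noise_sd` is
  in units of signal RMS; channels differ by positive gains (Pearson
  is affine-invariant, so channel gain structure is free). An affine
  map C = 1 − αD was tried first and rejected: its PSD constraint
  forces α below floating-point rank resolution.
- **Pattern plants (fMRI/MEG).** Classical-MDS embedding of D (exact
  for Euclidean targets; verified to 1e−10 against brute-force
  distance recomputation), padded and randomly rotated into the feature
  space. fMRI betas carry the patterns inside the planted mesh region
  and unit-variance condition noise outside; time series = design ×
  betas + AR(1) noise. MEG sources carry the patterns as amplitudes on
  a band-limited carrier (sine at band centre, smooth taper, then
  band-pass filtered 10% inside the band edges so adjacent-band
  analyses see essentially nothing) on 1/f background noise.
- **Not emulated:** biomechanics, electrode physics, scanner/sensor
  artifacts, head motion, leadfields and source leakage, spatial
  autocorrelation of fMRI noise beyond AR(1) in time, inter-subject
  anatomical variability. Passing recovery tests therefore demonstrates
  the *pipeline's* correctness and calibration, not robustness to every
  real-data pathology.

**Effect-size calibration.** The MEG carrier gain is a one-time
calibrated constant (0.025): at the full default problem size (31
sources, 600 Hz, 50 trials, 10 partitions) and `signal_scale = 1`, the
sliding-window model fit peaks near ρ ≈ 0.85. A weaker ρ ≈ 0.3 effect
was tried first and sits exactly at the cluster-forming threshold of the
randomization test (the null ρ spread is ~0.11 because condensed
crossnobis entries are strongly correlated across pairs), making
end-to-end recovery unattainable even with ten-subject fixed-effects
averaging; the calibration was therefore set, once, to a level the
prescribed inference can reliably detect.

## Simulation designs (problem sizes)

Monte-Carlo acceptance runs use reduced sizes chosen for coverage:

- *Spatial recovery / FWER*: 12 conditions, 42-vertex icosphere
  (12 mm radius), 6-vertex planted patch, 4 runs of 8 s blocks, 14 mm
  searchlights; recovery 100 seeded datasets, FWER 200 null datasets ×
  500 permutations at α = 0.01.
- *Temporal recovery*: 26 conditions, 16 sources, 300 Hz, epoch
  [−400, 200) ms, 25 trials, 5 partitions, 200 shuffles, FWE α = 0.005;
  `signal_scale = 8` preserves the full-size calibrated effect (peak
  ρ ≈ 0.85) at this reduced per-window SNR. The gamma-band analysis of
  the same datasets is required to stay at its own false-positive floor
  (≤ 5/100; a literal zero is impossible since the gamma test has FWER
  ≈ 0.005 per run).
- *Temporal type-I*: 8 conditions, 8 sources, 10 trials, 5 partitions,
  500 null datasets; the significant-cluster rate must fall in the
  central 95% binomial interval around α = 0.005.

## Known limitations

- OLS without autocorrelation modeling slightly miscalibrates GLM
  residual covariances under AR(1) noise; the permutation inference is
  calibrated empirically regardless.
- The upper-bound noise ceiling is biased upward on noise-only cohorts
  (documented behavior, demonstrated in the tests).
- Euclidean mesh fixtures stand in for cortical geometry; geodesic
  distances on a real pial surface will differ from the icosphere's.
- Non-Euclidean target RDMs are realized in the least-squares sense
  (eigenvalue clipping), so rank recovery is exact only for
  Euclidean-embeddable targets such as those the generator produces.
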