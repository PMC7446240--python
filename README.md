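# spatemp-rsa

Spatiotemporal representational similarity analysis (RSA) for multi-modal
motor neuroscience: a tested, reusable pipeline for asking **where** (on a
cortical surface, from fMRI-like data) and **when** (in time and frequency,
from MEG-like source data) a candidate representational geometry — e.g. the
kinematic or muscle structure of a set of hand movements — is encoded in
patterns of brain activity.

The package is aimed at researchers running condition-rich multivariate
experiments (here: 26 naturalistic hand movements) who want to compare
candidate model RDMs against neural data with cross-validated distances and
permutation inference, and at methodologists who need a fully synthetic,
seed-deterministic test bed in which the ground-truth geometry is known and
recoverable.

## What it computes

**Model RDMs** (`spatemp_rsa.model_rdms`). From epoched channel data
(14-channel data glove at 60 Hz, 15-channel EMG envelopes), the kinematic and
muscle models are built per movement pair as

    d(a, b) = 1 − tanh( mean over channels of atanh r_ch(a, b) )

(Pearson correlation per channel, Fisher z-averaged); a categorical
ethological model marks whether two movements share an action category
(precision-prehensile / power-prehensile / nonprehensile). Includes
Hilbert-envelope onset detection (adaptive threshold, 200 ms duration
criterion), multivariate noise normalization across channels, hierarchical
clustering order and stress-based (SMACOF) MDS for display.

**Crossnobis core** (`spatemp_rsa.crossnobis`). Noise covariance from GLM
residuals, Σ̂ = RᵀR/T (with Ledoit–Wolf-style shrinkage toward the diagonal);
spatial prewhitening P\* = P Σ̂^(−1/2); the cross-validated squared
Mahalanobis (crossnobis) distance

    d²(k, l) = (P*_k − P*_l)_A · (P*_k − P*_l)_Bᵀ / V

averaged over fold assignments — unbiased, so null distances straddle zero
and may legitimately be negative. RDM agreement uses Spearman's ρ on the
condensed entries, with a partial-Spearman variant to discount a control
model, and upper-bound noise ceilings for subject cohorts.

**Spatial searchlight** (`spatemp_rsa.searchlight`). First-level OLS GLM
(boxcar × gamma HRF + temporal derivative per condition: 52 regressors for
26 movements), 10 mm geodesic searchlights on a triangulated surface,
per-vertex crossnobis RDM → Spearman ρ maps, and an omnibus (max-statistic)
permutation threshold at α = 0.01; group heatmaps and a one-sided Wilcoxon
signed-rank model contrast with Benjamini–Hochberg FDR.

**Temporal RSA** (`spatemp_rsa.temporal`). Band-pass filtering (alpha 7–14,
beta 15–30, gamma 30–100, broadband 7–100 Hz), baselining, 10-partition
cross-validation, sliding-window crossnobis RDM timecourses (20 ms windows,
5 ms steps — 396 windows across a 2 s epoch), model/partial-model ρ(t), and
cluster-based permutation inference (model-label shuffles, cluster-forming
P < 0.01, max-cluster-mass FWE at α = 0.001), plus time-resolved noise
ceilings.

**Synthetic sessions** (`spatemp_rsa.synth`). Every input is generated with
a *planted* geometry: a target RDM is embedded into glove/EMG condition
templates (via a Gaussian-kernel correlation structure — the recovered
1 − r model is rank-identical to the target), into fMRI voxel betas on a
mesh patch (via classical-MDS pattern embedding — squared distances match
the target exactly), or into band- and window-limited MEG source amplitudes.
Generators are bit-deterministic given a seed.

## Worked example

`examples/04_temporal_rsa.py` plants a beta-band geometry in a pre-movement
window (−210 to −90 ms) and asks when and in which band it is encoded:

```
epochs: 650 trials x 16 sources, -400 to +197 ms
sliding windows: 116 (20 ms width, 5 ms step)
[beta] peak rho = 0.771 at -160 ms
  significant cluster -235 to -65 ms (mass 18.3, p = 0.0050)
[gamma] peak rho = 0.174 at +5 ms
  no significant cluster — the plant is confined to the beta band
group (fixed-effects) peak rho = 0.952; noise ceiling there = 0.872
```

Reading: the model-fit timecourse ρ(t) peaks inside the planted window; the
cluster test marks a significant span covering it (p is the rank of the
cluster's mass in the null max-mass distribution); the same data analyzed in
the gamma band shows nothing, demonstrating band specificity; averaging
subject RDM timecourses (fixed effects) raises the fit toward — and here,
for the true generating model, past — the upper-bound noise ceiling.

The other examples cover model-RDM construction (`01`), the crossnobis
machinery step by step (`02`), the surface searchlight with omnibus
thresholding, group heatmaps and the model contrast (`03`), and the
YAML-configured end-to-end pipeline with a reproducibility manifest (`05`).

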