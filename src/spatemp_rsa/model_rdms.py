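"""Model RDM construction from epoched channel data.

Three candidate models describe how the 26 hand movements may be encoded:

* **kinematic** — built from data-glove displacement signals: per-channel
  Pearson correlation between condition-average timecourses, Fisher
  z-transformed, averaged over channels, back-transformed, and expressed
  as the dissimilarity ``1 - r``;
* **muscle** — the same construction applied to rectified EMG envelopes
  after multivariate noise normalization across electrodes;
* **ethological** — a categorical model that groups movements into
  precision-prehensile, power-prehensile and nonprehensile actions.

The module also provides Hilbert-envelope onset detection used to align
epochs to movement onset, and display utilities (hierarchical clustering
order, stress-based MDS embedding).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import hilbert
from sklearn.manifold import smacof

from .types import RDM, ChannelEpochs, MovementSet

__all__ = [
    "detect_onset",
    "earliest_onset",
    "average_by_condition",
    "channel_correlation_rdm",
    "mnn_trials",
    "error_covariance",
    "ethological_rdm",
    "cluster_order",
    "mds_embed",
]

logger = logging.getLogger(__name__)

# clip |r| below 1 so the Fisher transform stays finite on noiseless data
_R_CLIP = 1.0 - 1e-10


def detect_onset(
    signal: np.ndarray,
    fs: float,
    duration_threshold_ms: float = 200.0,
    smoothing_ms: float = 5.0,
    n_sd: float = 1.0,
) -> int | None:
    """Adaptive-threshold onset detection on the Hilbert envelope.

    The envelope (magnitude of the analytic signal) is moving-average
    smoothed over ``smoothing_ms`` and compared to an adaptive threshold
    recomputed for every call: the envelope mean plus ``n_sd`` standard
    deviations over the whole epoch.  The onset is the first sample at
    which the envelope stays above threshold continuously for at least
    ``duration_threshold_ms``.

    Returns
    -------
    int or None
        Onset sample index, or ``None`` when no sufficiently long
        suprathreshold segment exists (including constant signals).
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("detect_onset expects a 1-D signal")
    dur_samples = max(int(round(duration_threshold_ms * fs / 1000.0)), 1)
    if len(x) <= dur_samples:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than the "
            f"{dur_samples}-sample duration threshold"
        )
    env = np.abs(hilbert(x))
    win = int(round(smoothing_ms * fs / 1000.0))
    if win > 1:
        kernel = np.ones(win) / win
        env = np.convolve(env, kernel, mode="same")
    thresh = env.mean() + n_sd * env.std()
    above = env > thresh
    if not above.any():
        return None
    # run-length encode suprathreshold segments
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    for s, e in zip(starts, ends):
        if e - s >= dur_samples:
            return int(s)
    return None


def earliest_onset(
    epochs: ChannelEpochs,
    trial: int,
    duration_threshold_ms: float = 200.0,
    smoothing_ms: float = 0.0,
) -> float | None:
    """Earliest detected onset across channels for one trial, in ms.

    A conservative movement-onset estimate: onset detection runs on every
    channel independently and the minimum onset time is returned.  Trials
    in which no channel yields an onset are flagged with ``None`` so the
    caller can exclude them.
    """
    onsets = []
    for ch in range(epochs.n_channels):
        idx = detect_onset(
            epochs.data[trial, ch], epochs.fs, duration_threshold_ms, smoothing_ms
        )
        if idx is not None:
            onsets.append(epochs.t0_ms + 1000.0 * idx / epochs.fs)
    if not onsets:
        return None
    return float(min(onsets))


def average_by_condition(epochs: ChannelEpochs) -> tuple[np.ndarray, list[str]]:
    """Per-condition trial averages.

    Returns
    -------
    averages : ndarray, shape (n_conditions, n_channels, n_samples)
    conditions : list of str
        Condition names in order of first appearance.
    """
    conditions = epochs.conditions
    labels = np.asarray(epochs.labels)
    missing = [c for c in conditions if not np.any(labels == c)]
    if missing:  # pragma: no cover - conditions derive from labels
        raise ValueError(f"conditions without trials: {missing}")
    out = np.stack([epochs.data[labels == c].mean(axis=0) for c in conditions])
    return out, conditions


def channel_correlation_rdm(
    cond_avgs: np.ndarray, conditions: list[str]
) -> RDM:
    """One-minus-correlation model RDM from condition-average timecourses.

    For every condition pair, each channel's two timecourses are Pearson
    correlated over samples; the correlations are Fisher z-transformed,
    averaged over channels, transformed back, and the dissimilarity is
    ``1 - r``.  Channels whose timecourse is constant for either
    condition have an undefined correlation and are dropped from that
    pair's average with a logged warning.
    """
    avgs = np.asarray(cond_avgs, dtype=float)
    if avgs.ndim != 3:
        raise ValueError("cond_avgs must be (conditions, channels, samples)")
    n_cond, n_chan, n_samp = avgs.shape
    if n_samp < 2:
        raise ValueError("need at least 2 samples per channel")
    centered = avgs - avgs.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    valid = norms > 1e-12  # (cond, chan): non-constant timecourses
    values = np.zeros((n_cond, n_cond))
    for a in range(n_cond):
        for b in range(a + 1, n_cond):
            ok = valid[a] & valid[b]
            if not ok.any():
                raise ValueError(
                    f"no channel has non-constant timecourses for conditions "
                    f"{conditions[a]!r} and {conditions[b]!r}"
                )
            if not ok.all():
                logger.warning(
                    "dropping %d constant channel(s) from pair (%s, %s)",
                    (~ok).sum(), conditions[a], conditions[b],
                )
            r = np.einsum("cs,cs->c", centered[a, ok], centered[b, ok])
            r /= norms[a, ok] * norms[b, ok]
            z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
            values[a, b] = values[b, a] = 1.0 - np.tanh(z.mean())
    # float noise can push 1 - r a hair outside [0, 2]
    values = np.clip(values, 0.0, 2.0)
    return RDM(values, conditions, kind="model_1mr")


def error_covariance(epochs: ChannelEpochs) -> np.ndarray:
    """Channel-by-channel error covariance from within-condition deviations.

    Every (trial, sample) deviation from its condition-mean timecourse is
    an observation of the noise; the covariance is taken across channels
    over all such observations.
    """
    labels = np.asarray(epochs.labels)
    for c in epochs.conditions:
        if (labels == c).sum() < 2:
            raise ValueError(
                f"condition {c!r} has fewer than 2 trials; cannot estimate "
                "error covariance"
            )
    dev = np.empty_like(epochs.data)
    for c in epochs.conditions:
        m = labels == c
        dev[m] = epochs.data[m] - epochs.data[m].mean(axis=0)
    obs = dev.transpose(0, 2, 1).reshape(-1, epochs.n_channels)  # (N, channels)
    return obs.T @ obs / obs.shape[0]


def mnn_trials(epochs: ChannelEpochs, shrinkage: float = 0.0) -> ChannelEpochs:
    """Multivariate noise normalization of trials across channels.

    Channels are re-weighted by the inverse square root of the
    shrinkage-regularized error covariance, so that after normalization
    the pooled error covariance is approximately the identity and noisy
    channels no longer dominate multivariate distances.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    cov = error_covariance(epochs)
    cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    w, v = np.linalg.eigh(cov)
    if w.min() <= 1e-12 * max(w.max(), 1e-30):
        raise ValueError(
            "error covariance is singular; use shrinkage > 0 to regularize"
        )
    inv_sqrt = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
    data = np.einsum("tcs,cd->tds", epochs.data, inv_sqrt)
    return ChannelEpochs(data, epochs.fs, epochs.t0_ms, epochs.labels)


def ethological_rdm(movements: MovementSet) -> RDM:
    """Categorical model RDM: 0 within an action category, 1 across.

    Categories follow the ethological-map view of motor cortex:
    precision-prehensile, power-prehensile and nonprehensile actions.
    """
    known = {"precision-prehensile", "power-prehensile", "nonprehensile"}
    cats = [movements.categories[lab] for lab in movements.labels]
    bad = sorted(set(cats) - known)
    if bad:
        raise ValueError(f"unknown categories {bad}; expected {sorted(known)}")
    c = np.asarray(cats)
    values = (c[:, None] != c[None, :]).astype(float)
    return RDM(values, movements.labels, kind="model_categorical")


def cluster_order(rdm: RDM) -> np.ndarray:
    """Leaf order of an average-linkage dendrogram built on the RDM.

    Deterministic agglomeration: at every step the pair of clusters with
    the smallest average inter-cluster dissimilarity is merged, exact
    ties broken by the lowest condition index; the lower-indexed
    cluster's leaves precede the other's.  On an all-equal RDM this
    yields the identity permutation.  The returned permutation is
    applied to condition axes for visualization.
    """
    values = np.asarray(rdm.values, dtype=float)
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > 1e-9:
        raise ValueError("cluster_order requires a symmetric RDM")
    n = values.shape[0]
    if n < 2:
        return np.arange(n)
    # clusters: list of (lowest original index, [leaf indices])
    clusters: list[list[int]] = [[i] for i in range(n)]
    dist = values.copy().astype(float)
    active = list(range(n))
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                key = (min(i, j), max(i, j))
                cand = (d[key], i, j)
                if best is None or cand < best:
                    best = cand
        _, i, j = best  # i < j by construction of the scan order
        # UPGMA update: average linkage weighted by cluster sizes
        for k in active:
            if k in (i, j):
                continue
            ki, kj = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            d[ki] = (sizes[i] * d[ki] + sizes[j] * d[kj]) / (sizes[i] + sizes[j])
        clusters[i] = clusters[i] + clusters[j]
        sizes[i] += sizes[j]
        active.remove(j)
    return np.asarray(clusters[active[0]], dtype=int)


def mds_embed(
    rdm: RDM,
    n_dims: int = 3,
    seed: int = 0,
    n_restarts: int = 100,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Nonclassical (stress-majorization) MDS embedding of an RDM.

    Metric SMACOF minimizes raw stress over ``n_restarts`` random
    initializations; the best embedding and its normalized stress
    (Kruskal stress-1) are returned.  Deterministic given ``seed``.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    n = rdm.n_conditions
    if n_dims >= n:
        raise ValueError(f"n_dims must be < n_conditions ({n})")
    d = np.asarray(rdm.values, dtype=float)
    total = 0.5 * np.sum(d**2)
    if total <= 0:  # all-zero RDM: every condition at the origin
        return np.zeros((n, n_dims)), 0.0
    coords, stress = smacof(
        d,
        n_components=n_dims,
        metric=True,
        n_init=n_restarts,
        max_iter=max_iter,
        eps=1e-9,
        random_state=seed,
        normalized_stress=False,
    )
    stress1 = float(np.sqrt(stress / total))
    return coords, stress1
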