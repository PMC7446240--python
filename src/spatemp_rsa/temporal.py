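"""Sliding-window temporal RSA for source-space MEG-like data.

Epoched virtual-sensor trials are band-pass filtered (alpha 7-14 Hz,
beta 15-30 Hz, gamma 30-100 Hz, broadband 7-100 Hz), baselined, split
into partitions, and averaged within partition.  A sliding window (20 ms
width, 5 ms step by default — 396 windows across a 2 s epoch) turns the
partition means into per-window feature vectors (all sources times
within-window samples); crossnobis distances across partitions give one
data RDM per window.

Model fit over time is the Spearman correlation of each window's RDM
with a candidate model (optionally a partial correlation discounting a
control model).  Inference shuffles the model RDM's condition labels to
build per-window null distributions, forms clusters of contiguous
suprathreshold windows, and compares each observed cluster's mass (sum
of rho) against the permutation distribution of the maximal cluster
mass — family-wise error control over time.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.stats import rankdata

from .crossnobis import crossnobis_rdm, noise_ceiling_upper
from .searchlight import condensed_permutation_index
from .types import (
    RDM,
    ChannelEpochs,
    ClusterResult,
    FoldPatterns,
    RdmTimecourse,
    WindowScheme,
)

__all__ = [
    "BAND_PRESETS",
    "bandpass",
    "baseline_correct",
    "partition_average",
    "PartitionMeans",
    "sliding_rdms",
    "model_timecourse",
    "cluster_inference",
    "temporal_noise_ceiling",
    "average_rdm_timecourses",
]

#: Frequency-band presets, Hz.
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "alpha": (7.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 100.0),
    "broadband": (7.0, 100.0),
}


def bandpass(
    epochs: ChannelEpochs, band: str | tuple[float, float], order: int = 4
) -> ChannelEpochs:
    """Zero-phase Butterworth band-pass filter of all trials.

    ``band`` is a preset name or an explicit ``(lo, hi)`` pair in Hz; the
    upper edge must be below Nyquist.
    """
    if isinstance(band, str):
        if band not in BAND_PRESETS:
            raise ValueError(f"unknown band {band!r}; presets: {sorted(BAND_PRESETS)}")
        lo, hi = BAND_PRESETS[band]
        name = band
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}Hz"
    nyq = epochs.fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist ({nyq} Hz)")
    if lo <= 0 or lo >= hi:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=epochs.fs, output="sos")
    data = sosfiltfilt(sos, epochs.data, axis=-1)
    out = ChannelEpochs(data, epochs.fs, epochs.t0_ms, epochs.labels)
    out.band = name  # type: ignore[attr-defined]
    return out


def baseline_correct(
    epochs: ChannelEpochs, baseline_window_ms: tuple[float, float]
) -> ChannelEpochs:
    """Subtract the per-trial, per-channel mean over a baseline window."""
    t = epochs.times_ms
    b0, b1 = baseline_window_ms
    if b0 < t[0] - 1e-9 or b1 > t[-1] + 1000.0 / epochs.fs + 1e-9 or b1 <= b0:
        raise ValueError(
            f"baseline window [{b0}, {b1}) ms outside epoch [{t[0]}, "
            f"{t[-1] + 1000.0 / epochs.fs}) ms"
        )
    m = (t >= b0) & (t < b1)
    if not m.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, m].mean(axis=2, keepdims=True)
    return ChannelEpochs(epochs.data - base, epochs.fs, epochs.t0_ms, epochs.labels)


# ---------------------------------------------------------------------------
# Partitioning


class PartitionMeans:
    """Partition-averaged condition responses.

    ``data`` has shape ``(n_partitions, n_conditions, n_channels,
    n_samples)``; partitions play the role of cross-validation folds.
    """

    def __init__(self, data: np.ndarray, conditions: list[str], fs: float, t0_ms: float):
        self.data = np.asarray(data, dtype=float)
        self.conditions = list(conditions)
        self.fs = fs
        self.t0_ms = t0_ms
        if self.data.ndim != 4:
            raise ValueError("partition means must be 4-D")

    @property
    def n_partitions(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.data.shape[3]) / self.fs


def partition_average(
    epochs: ChannelEpochs, n_partitions: int = 10, seed: int = 0
) -> PartitionMeans:
    """Assign trials to partitions (shuffled round-robin) and average.

    Within each condition, trials are shuffled deterministically given
    ``seed`` and dealt to partitions as evenly as possible: with ``r``
    leftover trials, the first ``r`` partitions receive one extra.
    Every trial is used exactly once.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    labels = np.asarray(epochs.labels)
    conditions = epochs.conditions
    rng = np.random.default_rng(seed)
    out = np.empty(
        (n_partitions, len(conditions), epochs.n_channels, epochs.n_samples)
    )
    for c, cond in enumerate(conditions):
        idx = np.flatnonzero(labels == cond)
        if len(idx) < n_partitions:
            raise ValueError(
                f"condition {cond!r} has {len(idx)} trials; need at least "
                f"{n_partitions} for {n_partitions} partitions"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), n_partitions)
        start = 0
        for p in range(n_partitions):
            size = base + (1 if p < rem else 0)
            out[p, c] = epochs.data[idx[start : start + size]].mean(axis=0)
            start += size
    return PartitionMeans(out, conditions, epochs.fs, epochs.t0_ms)


# ---------------------------------------------------------------------------
# Sliding-window RDMs


def sliding_rdms(
    pm: PartitionMeans,
    scheme: WindowScheme,
    noise_cov: np.ndarray | None = None,
    band: str = "broadband",
    scheme_cv: str = "loo",
) -> RdmTimecourse:
    """Crossnobis RDM per sliding window.

    Each window's feature vector concatenates all sources and within-
    window samples.  If ``noise_cov`` (a channel-by-channel error
    covariance, e.g. from :func:`spatemp_rsa.model_rdms.error_covariance`)
    is given, partition means are noise-normalized by its inverse square
    root before windowing.  Cross-validation treats each partition in
    turn as fold A against the mean of the rest.
    """
    if pm.n_partitions < 2:
        raise ValueError("cross-validated RDMs require at least 2 partitions")
    data = pm.data
    if noise_cov is not None:
        w, v = np.linalg.eigh(np.asarray(noise_cov, dtype=float))
        floor = 1e-8 * max(w.max(), 1e-300)
        inv_sqrt = v @ np.diag(1.0 / np.sqrt(np.maximum(w, floor))) @ v.T
        data = np.einsum("pcks,kl->pcls", data, inv_sqrt)
    starts = scheme.starts_ms()
    if starts.size == 0:
        raise ValueError("window scheme yields no windows")
    width_samp = max(int(round(scheme.width_ms * pm.fs / 1000.0)), 1)
    n_samp = data.shape[3]
    rdms = []
    for s in starts:
        i0 = int(round((s - pm.t0_ms) * pm.fs / 1000.0))
        i1 = min(i0 + width_samp, n_samp)
        if i1 <= i0:
            raise ValueError(f"window starting at {s} ms contains no samples")
        feats = data[:, :, :, i0:i1].reshape(data.shape[0], data.shape[1], -1)
        folds = FoldPatterns(list(feats), pm.conditions)
        rdms.append(crossnobis_rdm(folds, scheme=scheme_cv))
    return RdmTimecourse(starts, rdms, band=band, width_ms=scheme.width_ms)


# ---------------------------------------------------------------------------
# Model timecourses and cluster inference


def _normalized_ranks(vec: np.ndarray) -> np.ndarray:
    r = rankdata(vec)
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    return r / nrm if nrm > 0 else r


def _rank_matrix(condensed: np.ndarray) -> np.ndarray:
    return np.stack([_normalized_ranks(row) for row in condensed])


def _partial_from_components(rxy, rxz, ryz):
    """Vectorized first-order partial correlation with safe denominators."""
    denom = np.sqrt(np.maximum((1.0 - rxz**2) * (1.0 - ryz**2), 1e-30))
    return np.clip((rxy - rxz * ryz) / denom, -1.0, 1.0)


def _validate_models(model: RDM, control: RDM | None) -> None:
    if np.ptp(model.condensed()) == 0:
        raise ValueError("model RDM is constant; rank correlation undefined")
    if control is not None:
        if np.ptp(control.condensed()) == 0:
            raise ValueError("control RDM is constant")
        if np.allclose(model.condensed(), control.condensed()):
            raise ValueError("control RDM is identical to the model RDM")


def model_timecourse(
    rdm_tc: RdmTimecourse, model: RDM, control: RDM | None = None
) -> np.ndarray:
    """Spearman (or partial Spearman) model fit per window."""
    if rdm_tc.labels != model.labels:
        raise ValueError("timecourse and model RDMs must share labels")
    _validate_models(model, control)
    ranks = _rank_matrix(rdm_tc.condensed_matrix())  # (W, P)
    mr = _normalized_ranks(model.condensed())
    rxy = ranks @ mr
    if control is None:
        return rxy
    cr = _normalized_ranks(control.condensed())
    rxz = ranks @ cr
    ryz = float(mr @ cr)
    return _partial_from_components(rxy, rxz, ryz)


def _clusters_above(rho: np.ndarray, thresh: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of windows with rho > threshold; (start, stop, mass)."""
    above = rho > thresh
    out = []
    w = 0
    n = len(rho)
    while w < n:
        if above[w]:
            s = w
            while w < n and above[w]:
                w += 1
            out.append((s, w, float(rho[s:w].sum())))
        else:
            w += 1
    return out


def cluster_inference(
    rdm_tc: RdmTimecourse,
    model: RDM,
    control: RDM | None = None,
    n_perm: int = 1000,
    cluster_p: float = 0.01,
    fwe_alpha: float = 0.001,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation inference on the model-fit timecourse.

    The model RDM's condition labels are shuffled ``n_perm`` times and
    the fit timecourse recomputed, giving a per-window null whose
    ``(1 - cluster_p)`` quantile is the cluster-forming threshold.
    Observed clusters (contiguous suprathreshold runs) are scored by
    mass (sum of rho) against the permutation distribution of the
    maximal cluster mass; a cluster is significant when its p-value is
    at most ``fwe_alpha``.
    """
    if fwe_alpha * n_perm < 1:
        raise ValueError(
            f"n_perm={n_perm} too small to estimate the alpha={fwe_alpha} "
            "quantile; need fwe_alpha * n_perm >= 1"
        )
    if not 0 < cluster_p < 1:
        raise ValueError("cluster_p must lie in (0, 1)")
    if rdm_tc.labels != model.labels:
        raise ValueError("timecourse and model RDMs must share labels")
    _validate_models(model, control)

    ranks = _rank_matrix(rdm_tc.condensed_matrix())  # (W, P)
    mr = _normalized_ranks(model.condensed())
    n_cond = model.n_conditions
    rng = np.random.default_rng(seed)
    perm_idx = np.stack(
        [condensed_permutation_index(n_cond, rng.permutation(n_cond)) for _ in range(n_perm)]
    )  # (n_perm, P)
    mr_perm = mr[perm_idx]  # (n_perm, P): normalized ranks of shuffled models

    rxy_null = ranks @ mr_perm.T  # (W, n_perm)
    rxy_obs = ranks @ mr
    if control is not None:
        cr = _normalized_ranks(control.condensed())
        rxz = ranks @ cr  # (W,)
        ryz_null = mr_perm @ cr  # (n_perm,)
        rho_null = _partial_from_components(rxy_null, rxz[:, None], ryz_null[None, :])
        rho_obs = _partial_from_components(rxy_obs, rxz, float(mr @ cr))
    else:
        rho_null = rxy_null
        rho_obs = rxy_obs

    # the observed timecourse is the identity member of the randomization
    # distribution; including it when forming the cluster thresholds keeps
    # observed and null draws exchangeable (validated type-I control)
    rho_all = np.concatenate([rho_obs[:, None], rho_null], axis=1)
    thresh = np.quantile(rho_all, 1.0 - cluster_p, axis=1, method="higher")
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        cl = _clusters_above(rho_null[:, p], thresh)
        if cl:
            null_max[p] = max(m for *_, m in cl)

    starts = rdm_tc.window_starts_ms
    width = rdm_tc.width_ms
    clusters = []
    for s, e, mass in _clusters_above(rho_obs, thresh):
        pval = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        clusters.append(
            {
                "start_ms": float(starts[s]),
                "end_ms": float(starts[e - 1] + width),
                "mass": mass,
                "p": float(pval),
                "window_slice": (s, e),
            }
        )
    return ClusterResult(
        clusters, cluster_p, fwe_alpha, rho=rho_obs, window_starts_ms=starts
    )


def average_rdm_timecourses(tcs: list[RdmTimecourse]) -> RdmTimecourse:
    """Unweighted average of subject RDM timecourses (fixed-effects input)."""
    if not tcs:
        raise ValueError("need at least one timecourse")
    ref = tcs[0]
    for tc in tcs[1:]:
        if not np.array_equal(tc.window_starts_ms, ref.window_starts_ms):
            raise ValueError("timecourses use different window schemes")
        if tc.labels != ref.labels:
            raise ValueError("timecourses use different condition labels")
    rdms = [
        RDM(
            np.mean([tc.rdms[w].values for tc in tcs], axis=0),
            ref.labels,
            "data_crossnobis",
        )
        for w in range(ref.n_windows)
    ]
    return RdmTimecourse(ref.window_starts_ms, rdms, band=ref.band, width_ms=ref.width_ms)


def temporal_noise_ceiling(subject_rdm_tcs: list[RdmTimecourse]) -> np.ndarray:
    """Upper-bound noise ceiling per window across a subject cohort."""
    if len(subject_rdm_tcs) < 2:
        raise ValueError("noise ceiling requires at least 2 subjects")
    ref = subject_rdm_tcs[0]
    for tc in subject_rdm_tcs[1:]:
        if not np.array_equal(tc.window_starts_ms, ref.window_starts_ms):
            raise ValueError("timecourses use different window schemes")
    return np.array(
        [
            noise_ceiling_upper([tc.rdms[w] for tc in subject_rdm_tcs])
            for w in range(ref.n_windows)
        ]
    )
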