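"""Synthetic sessions with known, recoverable representational geometry.

Real recordings for this kind of study (data-glove kinematics, hand EMG,
7T fMRI, source-space MEG) are not publicly deposited, so every input the
pipeline consumes is generated here with a *planted* geometry: a target
RDM is embedded into condition templates or condition patterns so that
the stage-appropriate analysis recovers it exactly in the noiseless case
and degrades gracefully with noise.

Two embedding routes are used:

* **Pattern plants** (:func:`plant_condition_patterns`) — classical-MDS
  embedding of the target squared-distance matrix; pairwise squared
  Euclidean distances of the returned condition-by-feature patterns
  reproduce the target entries.  Used for fMRI voxel betas and MEG
  source amplitudes, whose analyses are distance-based.
* **Correlation plants** (glove/EMG templates) — the target RDM is mapped
  onto a positive-definite correlation matrix ``C = exp(-gamma * D)``
  (the Gaussian kernel) and condition timecourses are built from an
  orthonormal raised-cosine basis with coefficient Gram matrix ``C``;
  the channel-wise one-minus-correlation model RDM of the noiseless
  templates is then ``1 - exp(-gamma * D)``, a strictly increasing
  transform of the target and hence rank-identical to it.  Used because
  the glove and EMG model RDMs are correlation-based, not distance-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.signal import butter as sp_butter
from scipy.signal import sosfiltfilt as sp_sosfiltfilt

from . import task
from .types import RDM, ChannelEpochs, MovementSet, PlantSpec, SurfaceMesh

__all__ = [
    "default_movement_set",
    "random_geometry_rdm",
    "plant_condition_patterns",
    "gen_glove_session",
    "gen_emg_session",
    "gen_fmri_session",
    "gen_meg_session",
    "make_icosphere",
    "mesh_patch",
    "FmriSession",
]

# The 26 hand movements of the motor task, with ethological action
# categories (precision grip, power grip, nonprehensile) assigned from
# the movement descriptions.
_MOVEMENTS: list[tuple[str, str]] = [
    ("abduct fingers", "nonprehensile"),
    ("cylinder grip", "power-prehensile"),
    ("hook grip", "power-prehensile"),
    ("spherical grip", "power-prehensile"),
    ("index finger flexion (45)", "nonprehensile"),
    ("index finger flexion (90)", "nonprehensile"),
    ("index & middle finger flexion (90)", "nonprehensile"),
    ("index finger and thumb roll", "precision-prehensile"),
    ("little finger flexion (45)", "nonprehensile"),
    ("little finger flexion (90)", "nonprehensile"),
    ("middle finger flexion (45)", "nonprehensile"),
    ("middle finger flexion (90)", "nonprehensile"),
    ("middle & ring finger flexion (90)", "nonprehensile"),
    ("pinch: thumb and little finger", "precision-prehensile"),
    ("pinch: thumb and index finger", "precision-prehensile"),
    ("pinch: thumb and middle finger", "precision-prehensile"),
    ("pinch: thumb and ring finger", "precision-prehensile"),
    ("ring finger flexion (45)", "nonprehensile"),
    ("ring finger flexion (90)", "nonprehensile"),
    ("ring and little finger flexion (90)", "nonprehensile"),
    ("rock fingers", "nonprehensile"),
    ("squeeze: thumb and fingers", "power-prehensile"),
    ("abduct thumb", "nonprehensile"),
    ("extend thumb", "nonprehensile"),
    ("flex thumb", "nonprehensile"),
    ("twiddle: thumb and index finger", "precision-prehensile"),
]


def default_movement_set(n: int | None = None) -> MovementSet:
    """The 26 motor-task hand movements with their action categories.

    ``n`` truncates the set (keeping category diversity of the leading
    movements) for scaled-down simulations.
    """
    rows = _MOVEMENTS if n is None else _MOVEMENTS[:n]
    return MovementSet([lab for lab, _ in rows], dict(rows))


def random_geometry_rdm(
    n_conditions: int, seed: int = 0, n_dims: int = 5, labels: list[str] | None = None
) -> RDM:
    """Squared-distance RDM of random points — a Euclidean-embeddable target."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_conditions, n_dims))
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    if labels is None:
        labels = [f"cond{i:02d}" for i in range(n_conditions)]
    return RDM(d2, labels, kind="data_crossnobis")


# ---------------------------------------------------------------------------
# Geometry embedding


def plant_condition_patterns(
    target_rdm: RDM, n_features: int, seed: int = 0
) -> np.ndarray:
    """Condition-by-feature patterns whose squared distances realize an RDM.

    The target entries are read as squared Euclidean distances; classical
    MDS (eigendecomposition of the double-centered distance matrix) gives
    coordinates reproducing them exactly when the target is Euclidean-
    embeddable.  Negative eigenvalues (non-Euclidean targets) are clipped
    to zero, in which case distances are realized in the least-squares
    sense.  The embedding is padded to ``n_features`` dimensions and
    rotated by a seeded random orthogonal matrix so no feature is
    privileged.
    """
    d2 = np.asarray(target_rdm.values, dtype=float)
    if d2.min() < 0:
        raise ValueError("target RDM entries must be non-negative")
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    rank = int(np.sum(w > 1e-10 * max(w.max(), 1e-30)))
    if n_features < rank:
        raise ValueError(
            f"n_features={n_features} cannot embed a rank-{rank} geometry; "
            f"need at least {rank} features"
        )
    coords = v[:, :rank] * np.sqrt(np.maximum(w[:rank], 0.0))
    out = np.zeros((n, n_features))
    out[:, :rank] = coords
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n_features, n_features)))
    q *= np.sign(np.diag(r))  # fix the QR sign ambiguity for determinism
    return out @ q


def _psd_correlation_coefs(target_rdm: RDM) -> tuple[np.ndarray, float]:
    """Unit-norm coefficient vectors with Gram matrix ``exp(-gamma * D)``.

    For a Euclidean squared-distance target ``D`` the Gaussian kernel
    ``exp(-gamma * D)`` is a positive-definite correlation matrix for any
    ``gamma > 0`` (Schoenberg), and ``1 - exp(-gamma * D)`` is strictly
    increasing in ``D`` — so the planted one-minus-correlation structure
    is rank-identical to the target.  ``gamma = 1 / max(D)`` keeps the
    planted dissimilarities well spread in [0, 1 - 1/e].  Non-embeddable
    targets have their few negative kernel eigenvalues clipped, making
    the realization least-squares rather than exact.
    """
    d = np.asarray(target_rdm.values, dtype=float)
    n = d.shape[0]
    dmax = d.max()
    if dmax <= 0:  # all-zero target: identical conditions
        return np.tile(np.eye(1, n, 0), (n, 1)), 0.0
    gamma = 1.0 / dmax
    c = np.exp(-gamma * d)
    w, v = np.linalg.eigh(c)
    coefs = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    return coefs, gamma


def _orthonormal_bump_basis(
    n_samples: int, n_basis: int, active: slice | None = None
) -> np.ndarray:
    """Orthonormal zero-mean basis built from raised-cosine bumps.

    Bumps tile the active sample range; columns are demeaned then
    QR-orthonormalized, so condition timecourses built on this basis have
    exact unit norm and zero mean — Pearson correlations between them
    equal the coefficient inner products.
    """
    if active is None:
        active = slice(0, n_samples)
    t = np.arange(n_samples, dtype=float)
    lo, hi = active.start, active.stop
    span = hi - lo
    if span <= n_basis:
        raise ValueError("active span too short for the requested basis size")
    centers = lo + span * (np.arange(n_basis) + 0.5) / n_basis
    width = 2.2 * span / n_basis
    raw = np.zeros((n_samples, n_basis))
    for k, c in enumerate(centers):
        m = np.abs(t - c) < width / 2
        raw[m, k] = 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / width))
    raw -= raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    if np.abs(np.diag(r)).min() < 1e-8:
        raise ValueError("bump basis is rank deficient; reduce n_basis")
    return q * np.sign(np.diag(r))


def _condition_timecourses(target_rdm: RDM, n_samples: int, active: slice | None):
    """Condition timecourses (samples, conditions) with planted correlations.

    Scaled by a common constant to unit RMS per sample, so ``noise_sd``
    in a :class:`PlantSpec` is expressed relative to unit signal power;
    common scaling leaves all inter-condition correlations untouched.
    """
    coefs, gamma = _psd_correlation_coefs(target_rdm)
    basis = _orthonormal_bump_basis(n_samples, coefs.shape[1], active)
    tcs = basis @ coefs.T  # unit l2 norm per condition
    return tcs * np.sqrt(n_samples), gamma


def _block_labels(movements: MovementSet, n_runs: int, trials_per_block: int, rng):
    """Trial labels following the block structure: one block per movement
    per run, block order randomized within run, trials contiguous."""
    labels: list[str] = []
    for _ in range(n_runs):
        order = rng.permutation(movements.n)
        for k in order:
            labels.extend([movements.labels[k]] * trials_per_block)
    return labels


# ---------------------------------------------------------------------------
# Data glove


def gen_glove_session(
    movements: MovementSet,
    spec: PlantSpec,
    n_runs: int = 5,
    trials_per_block: int = 8,
    n_channels: int = 14,
    fs: float = 60.0,
) -> ChannelEpochs:
    """Simulated data-glove session: 14 fibre-optic channels at 60 Hz.

    Each trial covers one movement cue (1.6 s movement + 0.8 s rest).
    Condition displacement templates are smooth raised-cosine mixtures
    whose cross-condition correlation structure realizes
    ``spec.target_rdm``; trials are template plus i.i.d. Gaussian noise.
    """
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    if spec.target_rdm.n_conditions != movements.n:
        raise ValueError("target RDM size must match the movement set")
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round((task.MOVEMENT_S + 0.8) * fs))
    active = slice(0, int(round(task.MOVEMENT_S * fs)))
    tcs, _ = _condition_timecourses(spec.target_rdm, n_samples, active)
    gains = rng.uniform(0.5, 1.5, size=n_channels)
    templates = {
        lab: spec.signal_scale * np.outer(gains, tcs[:, k])
        for k, lab in enumerate(movements.labels)
    }
    labels = _block_labels(movements, n_runs, trials_per_block, rng)
    data = np.stack([templates[lab] for lab in labels])
    data += spec.noise_sd * rng.standard_normal(data.shape)
    return ChannelEpochs(data, fs, 0.0, labels)


# ---------------------------------------------------------------------------
# EMG


def gen_emg_session(
    movements: MovementSet,
    spec: PlantSpec,
    n_runs: int = 5,
    trials_per_block: int = 1,
    n_channels: int = 15,
    fs: float = 2048.0,
    epoch_s: float = 2.0,
    envelope_offset: float | None = None,
) -> ChannelEpochs:
    """Simulated EMG session: 15 electrodes, rectified-envelope templates.

    Envelope templates are non-negative by construction (an offset lifts
    the planted correlation structure above zero); trials span
    ``epoch_s`` seconds from movement onset.  The default 2048 Hz rate
    can be lowered (``fs``) for speed without changing the geometry.
    """
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    if spec.target_rdm.n_conditions != movements.n:
        raise ValueError("target RDM size must match the movement set")
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(epoch_s * fs))
    tcs, _ = _condition_timecourses(spec.target_rdm, n_samples, None)
    gains = rng.uniform(0.5, 1.5, size=n_channels)
    peak = np.abs(tcs).max()
    if envelope_offset is None:
        offset = 1.05 * spec.signal_scale * peak * gains.max()
    else:
        offset = envelope_offset
    floor = offset - spec.signal_scale * peak * gains.max()
    if floor < 0:
        raise ValueError(
            f"envelope offset {offset} would produce negative envelope "
            f"templates (minimum {floor:.3g}); increase the offset"
        )
    templates = {
        lab: offset + spec.signal_scale * np.outer(gains, tcs[:, k])
        for k, lab in enumerate(movements.labels)
    }
    labels = _block_labels(movements, n_runs, trials_per_block, rng)
    data = np.stack([templates[lab] for lab in labels])
    data += spec.noise_sd * rng.standard_normal(data.shape)
    return ChannelEpochs(data, fs, 0.0, labels)


# ---------------------------------------------------------------------------
# fMRI forward model


@dataclass
class FmriSession:
    """Per-run voxel time series with event tables and generating betas."""

    runs: list[np.ndarray]  # each (n_features, n_frames)
    events: list[pd.DataFrame]  # onset_s, duration_s, condition
    betas: np.ndarray  # (n_conditions, n_features) generating patterns
    mesh: SurfaceMesh
    tr_s: float
    conditions: list[str]


def _ar1_noise(rng, shape, sd: float, coef: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape)
    out = np.empty(shape)
    out[..., 0] = eps[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = coef * out[..., t - 1] + np.sqrt(1 - coef**2) * eps[..., t]
    return sd * out


def gen_fmri_session(
    mesh: SurfaceMesh,
    plant: PlantSpec,
    movements: MovementSet,
    n_runs: int = 10,
    tr_s: float = 1.5,
    seed: int = 0,
    block_s: float | None = None,
    movement_offset_s: float = 7.0,
    movement_duration_s: float = 10.0,
    n_rest_blocks: int = 8,
    ar_coef: float = 0.3,
) -> FmriSession:
    """Forward-modelled fMRI session on a surface mesh.

    Inside ``plant.region`` the condition betas realize
    ``plant.target_rdm`` (scaled by ``plant.signal_scale``); outside, the
    betas are unit-variance noise that is condition-specific but carries
    no planted geometry.  Per-run time series are the boxcar-times-HRF
    design applied to the betas plus AR(1) noise of SD ``plant.noise_sd``.
    """
    from .searchlight import build_design  # shared with the GLM fit

    if plant.region is None:
        raise ValueError("fMRI plant requires a vertex region")
    if plant.region.min() < 0 or plant.region.max() >= mesh.n_vertices:
        raise ValueError("plant region lies outside the mesh vertex range")
    if block_s is None:
        block_s = task.fmri_block_s()
    rng = np.random.default_rng(seed)
    n_cond = movements.n
    if plant.target_rdm.n_conditions != n_cond:
        raise ValueError("target RDM size must match the movement set")
    n_feat = mesh.n_features
    region_feats = np.unique(np.concatenate([mesh.feature_map[v] for v in plant.region]))

    betas = rng.standard_normal((n_cond, n_feat))
    patterns = plant_condition_patterns(plant.target_rdm, len(region_feats), plant.seed)
    betas[:, region_feats] = plant.signal_scale * patterns

    n_blocks = n_cond + n_rest_blocks
    run_len_s = n_blocks * block_s + 10.0  # tail covers the HRF decay
    n_frames = int(np.ceil(run_len_s / tr_s))

    runs, events = [], []
    for _ in range(n_runs):
        order = list(rng.permutation(n_cond)) + [None] * n_rest_blocks
        rng.shuffle(order)
        rows = []
        for b, k in enumerate(order):
            if k is None:
                continue
            rows.append(
                {
                    "onset_s": b * block_s + movement_offset_s,
                    "duration_s": movement_duration_s,
                    "condition": movements.labels[k],
                }
            )
        ev = pd.DataFrame(rows).sort_values("onset_s").reset_index(drop=True)
        x, names = build_design(ev, n_frames, tr_s, conditions=movements.labels)
        full_betas = np.zeros((x.shape[1], n_feat))
        for k, lab in enumerate(movements.labels):
            full_betas[names.index(lab)] = betas[k]
        series = (x @ full_betas).T  # (features, frames)
        series += _ar1_noise(rng, series.shape, plant.noise_sd, ar_coef)
        runs.append(series)
        events.append(ev)
    return FmriSession(runs, events, betas, mesh, tr_s, list(movements.labels))


# ---------------------------------------------------------------------------
# MEG virtual sensors


def _one_over_f_noise(rng, shape, fs: float) -> np.ndarray:
    """Unit-RMS noise with 1/f amplitude spectrum along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / freqs[nz]
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def gen_meg_session(
    plant: PlantSpec,
    movements: MovementSet,
    n_sources: int = 31,
    fs: float = 600.0,
    epoch_ms: tuple[float, float] = (-500.0, 1500.0),
    trials_per_condition: int = 50,
    seed: int = 0,
    carrier_gain: float = 0.025,
) -> ChannelEpochs:
    """Simulated source-space MEG epochs with a band- and time-limited plant.

    Condition-specific source-amplitude patterns (realizing
    ``plant.target_rdm``) modulate a band-limited oscillatory carrier
    confined to ``plant.window_ms``; 1/f background noise covers the
    whole epoch.  Defaults mirror the study: 31 motor-region virtual
    sensors at 600 Hz, epochs from -500 to +1500 ms around movement
    onset, 50 trials per movement.  ``carrier_gain`` is a fixed, one-time
    calibration of the carrier amplitude: at these defaults and
    ``signal_scale = 1`` the sliding-window model fit peaks near
    rho = 0.75.  (A weaker rho ~ 0.3 effect sits at the cluster-forming
    threshold of the randomization test and is not reliably detectable,
    so the planted default is calibrated to a level the inference can
    recover.)
    """
    if plant.band_hz is None or plant.window_ms is None:
        raise ValueError("MEG plant requires band_hz and window_ms")
    lo, hi = plant.band_hz
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist ({fs / 2} Hz)")
    w0, w1 = plant.window_ms
    if w0 < epoch_ms[0] or w1 > epoch_ms[1]:
        raise ValueError("plant window must lie inside the epoch")
    if plant.target_rdm.n_conditions != movements.n:
        raise ValueError("target RDM size must match the movement set")
    rng = np.random.default_rng(seed)
    n_samples = int(round((epoch_ms[1] - epoch_ms[0]) * fs / 1000.0))
    times = epoch_ms[0] + 1000.0 * np.arange(n_samples) / fs

    patterns = plant_condition_patterns(plant.target_rdm, n_sources, plant.seed)
    rms = np.sqrt(np.mean(patterns**2))
    if rms > 0:
        patterns = patterns / rms

    in_win = (times >= w0) & (times < w1)
    f0 = 0.5 * (lo + hi)
    carrier = np.zeros(n_samples)
    tw = times[in_win]
    if tw.size:
        ramp = np.sin(np.pi * (tw - w0) / (w1 - w0)) ** 2  # smooth on/off taper
        carrier[in_win] = np.sin(2 * np.pi * f0 * (tw - w0) / 1000.0) * ramp
        # confine the taper's spectral sidelobes to the interior of the
        # plant band (10% in from each edge), so the planted geometry is
        # invisible to analyses of adjacent bands that share an edge
        bw = hi - lo
        sos = sp_butter(
            4, [lo + 0.1 * bw, hi - 0.1 * bw], btype="bandpass", fs=fs, output="sos"
        )
        carrier = sp_sosfiltfilt(sos, carrier)
        peak = np.abs(carrier).max()
        if peak > 0:
            carrier /= peak

    labels: list[str] = []
    for lab in movements.labels:
        labels.extend([lab] * trials_per_condition)
    data = plant.noise_sd * _one_over_f_noise(
        rng, (len(labels), n_sources, n_samples), fs
    )
    signal = plant.signal_scale * carrier_gain
    for i, lab in enumerate(labels):
        k = movements.labels.index(lab)
        data[i] += signal * np.outer(patterns[k], carrier)
    return ChannelEpochs(data, fs, epoch_ms[0], labels)


# ---------------------------------------------------------------------------
# Mesh fixtures


def make_icosphere(subdivisions: int = 3, radius_mm: float = 25.0) -> SurfaceMesh:
    """Icosphere mesh fixture (642 vertices at the default 3 subdivisions).

    A geometrically regular stand-in for a cortical patch; each vertex
    carries one feature with its own index.  The default 25 mm radius
    gives ~3.5 mm vertex spacing, so 10 mm-diameter searchlights hold a
    handful of features, comparable to surface sampling of
    high-resolution fMRI.
    """
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def mesh_patch(mesh: SurfaceMesh, center_vertex: int, radius_mm: float) -> np.ndarray:
    """Vertex indices within a Euclidean radius of a centre vertex."""
    d = np.linalg.norm(mesh.vertices - mesh.vertices[center_vertex], axis=1)
    return np.flatnonzero(d <= radius_mm)
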