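"""Shared containers for the spatiotemporal RSA pipeline.

The pipeline moves data through a small set of typed containers:

* :class:`ChannelEpochs` — epoched multi-channel recordings (data glove,
  EMG envelopes, or source-reconstructed MEG "virtual sensors").
* :class:`RDM` — a condition-by-condition representational dissimilarity
  matrix.  Model RDMs (``model_1mr``, ``model_categorical``) are bounded;
  data RDMs built from cross-validated Mahalanobis distances
  (``data_crossnobis``) are unbiased and may be negative.
* :class:`FoldPatterns` — per-fold condition-by-feature pattern matrices
  used for cross-validated distances.
* :class:`SurfaceMesh` / :class:`SearchlightSet` — a triangulated cortical
  surface stand-in and per-vertex feature neighbourhoods.
* :class:`StatMap`, :class:`WindowScheme`, :class:`RdmTimecourse`,
  :class:`ClusterResult` — inference outputs for the spatial and temporal
  analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RDM",
    "ChannelEpochs",
    "FoldPatterns",
    "SurfaceMesh",
    "SearchlightSet",
    "StatMap",
    "WindowScheme",
    "RdmTimecourse",
    "ClusterResult",
    "MovementSet",
    "PlantSpec",
]

#: Valid RDM kinds.
RDM_KINDS = ("model_1mr", "model_categorical", "data_crossnobis")

_SYM_ATOL = 1e-9


@dataclass
class RDM:
    """Square symmetric condition-by-condition dissimilarity matrix.

    Parameters
    ----------
    values
        ``(n, n)`` symmetric matrix with zero diagonal.
    labels
        Condition names, one per row/column.
    kind
        ``"model_1mr"`` (one-minus-correlation, entries in [0, 2]),
        ``"model_categorical"`` (entries in {0, 1}) or
        ``"data_crossnobis"`` (cross-validated distances, sign-unrestricted).
    """

    values: np.ndarray
    labels: list[str]
    kind: str = "data_crossnobis"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {self.values.shape}")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a {self.values.shape[0]}-condition RDM"
            )
        asym = np.max(np.abs(self.values - self.values.T)) if self.values.size else 0.0
        if asym > _SYM_ATOL:
            raise ValueError(f"RDM is asymmetric (max |a - a.T| = {asym:.3g})")
        # exact symmetry and zero diagonal after validation
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)
        if self.kind not in RDM_KINDS:
            raise ValueError(f"unknown RDM kind {self.kind!r}; expected one of {RDM_KINDS}")
        if self.kind == "model_1mr":
            if self.values.min() < -_SYM_ATOL or self.values.max() > 2 + _SYM_ATOL:
                raise ValueError("model_1mr entries must lie in [0, 2]")
        elif self.kind == "model_categorical":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("model_categorical entries must be 0 or 1")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Lower-triangle off-diagonal entries as a flat vector.

        Ordering follows ``np.tril_indices(n, -1)`` (row-major over the
        lower triangle); length ``n * (n - 1) / 2``.
        """
        i, j = np.tril_indices(self.n_conditions, -1)
        return self.values[i, j]

    def permuted(self, order: np.ndarray) -> "RDM":
        """RDM with conditions reordered by ``order`` (rows and columns)."""
        order = np.asarray(order)
        return RDM(
            self.values[np.ix_(order, order)],
            [self.labels[k] for k in order],
            self.kind,
        )


@dataclass
class ChannelEpochs:
    """Epoched multi-channel trials.

    ``data`` has shape ``(n_trials, n_channels, n_samples)``; ``t0_ms`` is
    the time of the first sample relative to the aligning event (movement
    onset or go cue); ``labels`` holds the condition name of every trial.
    """

    data: np.ndarray
    fs: float
    t0_ms: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 3:
            raise ValueError(f"epochs data must be 3-D, got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("epochs contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to the aligning event."""
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    @property
    def conditions(self) -> list[str]:
        """Unique condition names in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)


@dataclass
class FoldPatterns:
    """Per-fold condition-by-feature matrices for cross-validated distances."""

    folds: list[np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        self.folds = [np.asarray(f, dtype=float) for f in self.folds]
        self.labels = list(self.labels)
        if not self.folds:
            raise ValueError("need at least one fold")
        shape = self.folds[0].shape
        for k, f in enumerate(self.folds):
            if f.ndim != 2 or f.shape != shape:
                raise ValueError(
                    f"fold {k} has shape {f.shape}, expected {shape} for all folds"
                )
        if shape[0] != len(self.labels):
            raise ValueError(f"{len(self.labels)} labels for {shape[0]}-condition folds")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def n_features(self) -> int:
        return self.folds[0].shape[1]

    def restrict(self, feature_idx: np.ndarray) -> "FoldPatterns":
        """Patterns restricted to a feature subset (e.g. one searchlight)."""
        idx = np.asarray(feature_idx, dtype=int)
        return FoldPatterns([f[:, idx] for f in self.folds], self.labels)


@dataclass
class SurfaceMesh:
    """Triangulated surface with a vertex-to-feature map.

    ``feature_map[v]`` lists the feature (voxel) indices sampled at vertex
    ``v``; by default each vertex carries a single feature with its own
    index.
    """

    vertices: np.ndarray
    faces: np.ndarray
    feature_map: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces reference invalid vertex indices")
        if not self.feature_map:
            self.feature_map = [np.array([v]) for v in range(len(self.vertices))]
        if len(self.feature_map) != len(self.vertices):
            raise ValueError("feature_map must have one entry per vertex")
        self.feature_map = [np.asarray(f, dtype=int) for f in self.feature_map]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_features(self) -> int:
        if not len(self.feature_map):
            return 0
        return int(max((f.max() for f in self.feature_map if f.size), default=-1)) + 1


@dataclass
class SearchlightSet:
    """Per-vertex feature neighbourhoods of a fixed geodesic diameter."""

    feature_indices: list[np.ndarray]
    diameter_mm: float

    def __post_init__(self) -> None:
        self.feature_indices = [np.asarray(f, dtype=int) for f in self.feature_indices]

    @property
    def n_vertices(self) -> int:
        return len(self.feature_indices)


@dataclass
class StatMap:
    """Per-vertex statistic map with optional permutation threshold/mask."""

    values: np.ndarray
    threshold: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.threshold is not None and self.mask is None:
            self.mask = self.values >= self.threshold
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class WindowScheme:
    """Sliding-window scheme with half-open windows ``[s, s + width)``.

    The end-strict convention admits a window only while
    ``s + width < epoch_end``; with a 2 s epoch, 20 ms width and 5 ms step
    this yields 396 windows.
    """

    width_ms: float
    step_ms: float
    epoch_ms: tuple[float, float]

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_ms
        if self.step_ms <= 0:
            raise ValueError("step must be positive")
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if self.width_ms > t1 - t0:
            raise ValueError("window width exceeds epoch length")

    def starts_ms(self) -> np.ndarray:
        """Window start times under the end-strict convention.

        A window whose end coincides with the epoch end is excluded —
        except when the width spans the whole epoch, where the single
        full-epoch window is admitted.
        """
        t0, t1 = self.epoch_ms
        starts = []
        s = t0
        while s + self.width_ms < t1 - 1e-9:
            starts.append(s)
            s += self.step_ms
        if not starts:
            starts = [t0]
        return np.asarray(starts, dtype=float)

    @property
    def n_windows(self) -> int:
        return len(self.starts_ms())


@dataclass
class RdmTimecourse:
    """Ordered per-window RDMs from the sliding-window analysis."""

    window_starts_ms: np.ndarray
    rdms: list[RDM]
    band: str = "broadband"
    width_ms: float = 0.0

    def __post_init__(self) -> None:
        self.window_starts_ms = np.asarray(self.window_starts_ms, dtype=float)
        if len(self.rdms) != len(self.window_starts_ms):
            raise ValueError("one RDM per window start required")
        if np.any(np.diff(self.window_starts_ms) <= 0):
            raise ValueError("window starts must be strictly increasing")
        labels = self.rdms[0].labels if self.rdms else []
        for r in self.rdms:
            if r.labels != labels:
                raise ValueError("all RDMs in a timecourse must share labels")

    @property
    def n_windows(self) -> int:
        return len(self.rdms)

    @property
    def labels(self) -> list[str]:
        return self.rdms[0].labels if self.rdms else []

    def condensed_matrix(self) -> np.ndarray:
        """``(n_windows, n_pairs)`` matrix of condensed RDM vectors."""
        return np.stack([r.condensed() for r in self.rdms])


@dataclass
class ClusterResult:
    """Clusters of contiguous suprathreshold windows with permutation p-values."""

    clusters: list[dict]
    cluster_forming_p: float
    fwe_alpha: float
    rho: np.ndarray | None = None
    window_starts_ms: np.ndarray | None = None

    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] <= self.fwe_alpha]


# ---------------------------------------------------------------------------
# Synthetic-study specification types


@dataclass
class MovementSet:
    """A set of movement conditions with ethological categories."""

    labels: list[str]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("movement labels must be unique")
        missing = [lab for lab in self.labels if lab not in self.categories]
        if missing:
            raise ValueError(f"movements without a category: {missing}")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class PlantSpec:
    """Where and how strongly to plant a representational geometry.

    ``region`` is a vertex/feature index set for spatial plants; temporal
    plants use ``window_ms`` (half-open, ms) and ``band_hz`` instead.
    ``signal_scale`` sets the amplitude of the condition structure and
    ``noise_sd`` the additive noise level.
    """

    target_rdm: RDM
    signal_scale: float = 1.0
    noise_sd: float = 1.0
    region: np.ndarray | None = None
    window_ms: tuple[float, float] | None = None
    band_hz: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.target_rdm.values.min() < 0:
            raise ValueError("plant target RDM must have non-negative entries")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=int)
            if self.region.size == 0:
                raise ValueError("plant region must be non-empty")
        if self.window_ms is not None and self.window_ms[1] <= self.window_ms[0]:
            raise ValueError("plant window must be a non-empty half-open interval")
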