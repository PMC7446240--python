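"""Surface-based searchlight RSA for fMRI-like data.

Per run, a first-level GLM (boxcar-times-gamma-HRF regressors plus
temporal derivatives) yields condition patterns and residuals.  On a
triangulated surface, a searchlight of fixed geodesic diameter is centred
at every vertex; within each searchlight the patterns are spatially
prewhitened by the locally estimated noise covariance, a crossnobis RDM
is computed across runs, and its Spearman correlation with a candidate
model RDM is assigned to the central vertex.

Inference is a fixed-effects randomization test: condition labels of the
data RDMs are permuted, the map's spatial peak is recorded per
permutation, and the (1 - alpha) quantile of the resulting
maximum-statistic distribution is the omnibus threshold controlling the
family-wise error over vertices.  Group-level outputs are binary-mask
heatmaps and a one-sided Wilcoxon signed-rank contrast between two
models' rho maps with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import gamma as gamma_dist
from scipy.stats import rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

from .crossnobis import crossnobis_rdm, estimate_noise_cov, spearman_rdm, whiten_patterns
from .types import RDM, FoldPatterns, SearchlightSet, StatMap, SurfaceMesh

__all__ = [
    "gamma_hrf",
    "build_design",
    "fit_glm",
    "build_searchlights",
    "searchlight_rho_map",
    "omnibus_threshold",
    "group_heatmap",
    "contrast_model_maps",
    "condensed_permutation_index",
]

logger = logging.getLogger(__name__)

_DT = 0.1  # design-construction time grid, seconds


def gamma_hrf(dt: float = _DT, duration_s: float = 25.0, peak_s: float = 6.0) -> np.ndarray:
    """Single-gamma haemodynamic response kernel, unit peak, no undershoot."""
    t = np.arange(0, duration_s, dt)
    shape = peak_s + 1.0  # gamma(a, scale=1) peaks at a - 1
    h = gamma_dist.pdf(t, a=shape, scale=1.0)
    return h / h.max()


def build_design(
    events: pd.DataFrame,
    n_frames: int,
    tr_s: float,
    conditions: list[str] | None = None,
    temporal_derivative: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """First-level design matrix from an event table.

    Each condition gets a boxcar regressor (event onsets/durations)
    convolved with the gamma HRF and, optionally, its temporal
    derivative; an intercept column is appended last.

    Returns
    -------
    X : ndarray, shape (n_frames, n_regressors + 1)
    names : list of str
        Column names; derivative columns are ``"<cond>__derivative"``,
        the intercept is ``"intercept"``.
    """
    required = {"onset_s", "duration_s", "condition"}
    if events is None or len(events) == 0:
        raise ValueError("event table is empty")
    if not required.issubset(events.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    if conditions is None:
        conditions = list(dict.fromkeys(events["condition"]))
    unknown = set(events["condition"]) - set(conditions)
    if unknown:
        raise ValueError(f"events reference unknown conditions: {sorted(unknown)}")
    hrf = gamma_hrf()
    n_hi = int(np.ceil(n_frames * tr_s / _DT)) + len(hrf)
    frame_idx = np.round(np.arange(n_frames) * tr_s / _DT).astype(int)
    cols, names = [], []
    for cond in conditions:
        box = np.zeros(n_hi)
        for _, ev in events[events["condition"] == cond].iterrows():
            a = int(round(ev["onset_s"] / _DT))
            b = int(round((ev["onset_s"] + ev["duration_s"]) / _DT))
            box[a:b] = 1.0
        reg = np.convolve(box, hrf)[:n_hi][frame_idx]
        cols.append(reg)
        names.append(cond)
        if temporal_derivative:
            cols.append(np.gradient(reg, tr_s))
            names.append(f"{cond}__derivative")
    cols.append(np.ones(n_frames))
    names.append("intercept")
    return np.column_stack(cols), names


def fit_glm(
    run_series: np.ndarray,
    events: pd.DataFrame,
    tr_s: float,
    conditions: list[str] | None = None,
    temporal_derivative: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ordinary-least-squares first-level GLM for one run.

    Parameters
    ----------
    run_series
        ``(n_features, n_frames)`` voxel time series.
    events
        Event table with ``onset_s``, ``duration_s``, ``condition``.

    Returns
    -------
    patterns : ndarray, shape (n_conditions, n_features)
        Main-regressor parameter estimates per condition.
    residuals : ndarray, shape (n_frames, n_features)
        GLM residuals, the input to noise-covariance estimation.
    conditions : list of str
    """
    y = np.asarray(run_series, dtype=float)
    if y.ndim != 2:
        raise ValueError("run_series must be (n_features, n_frames)")
    n_frames = y.shape[1]
    x, names = build_design(events, n_frames, tr_s, conditions, temporal_derivative)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(x)
        bad = [names[k] for k in np.flatnonzero(np.abs(np.diag(r)) < 1e-8)]
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ beta
    conds = [n for n in names if n != "intercept" and not n.endswith("__derivative")]
    patterns = np.stack([beta[names.index(c)] for c in conds])
    return patterns, resid, conds


# ---------------------------------------------------------------------------
# Searchlight construction


def build_searchlights(mesh: SurfaceMesh, diameter_mm: float = 10.0) -> SearchlightSet:
    """Per-vertex feature neighbourhoods within a geodesic diameter.

    Vertex-to-vertex distances are graph-geodesic along mesh edges with
    Euclidean edge lengths; a vertex's searchlight is the union of the
    features of all vertices within ``diameter_mm / 2``, always including
    its own.  Disconnected vertices yield singleton searchlights with a
    logged warning.
    """
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    n = mesh.n_vertices
    edges = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [0, 2]]]
    )
    edges = np.unique(np.sort(edges, axis=1), axis=0)  # each edge once
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    graph = coo_matrix(
        (np.r_[lengths, lengths], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    ).tocsr()
    radius = diameter_mm / 2.0
    dist = dijkstra(graph, directed=False, limit=radius)
    feature_lists = []
    for v in range(n):
        within = np.flatnonzero(np.isfinite(dist[v]) & (dist[v] <= radius))
        if within.size <= 1 and graph[v].nnz == 0 and n > 1:
            logger.warning("vertex %d is disconnected; singleton searchlight", v)
        within = np.union1d(within, [v])
        feats = np.unique(np.concatenate([mesh.feature_map[u] for u in within]))
        feature_lists.append(feats)
    return SearchlightSet(feature_lists, diameter_mm)


# ---------------------------------------------------------------------------
# Rho maps and omnibus inference


def _vertex_data_rdms(
    fold_patterns: FoldPatterns,
    residuals: list[np.ndarray],
    searchlights: SearchlightSet,
    shrinkage: float | str = "auto",
    scheme: str = "loo",
) -> np.ndarray:
    """Condensed crossnobis RDM per vertex; NaN rows for missing vertices."""
    n_cond = len(fold_patterns.labels)
    n_pairs = n_cond * (n_cond - 1) // 2
    resid_all = np.vstack(residuals)
    out = np.full((searchlights.n_vertices, n_pairs), np.nan)
    for v, feats in enumerate(searchlights.feature_indices):
        if feats.size < 2:
            continue
        local = fold_patterns.restrict(feats)
        cov, _ = estimate_noise_cov(resid_all[:, feats], shrinkage)
        white = FoldPatterns(
            [whiten_patterns(f, cov) for f in local.folds], local.labels
        )
        out[v] = crossnobis_rdm(white, scheme=scheme).condensed()
    return out


def _normalized_ranks(vec: np.ndarray) -> np.ndarray:
    """Centered, unit-norm rank vector (Pearson on these = Spearman)."""
    r = rankdata(vec)
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    return r / nrm if nrm > 0 else r


def condensed_permutation_index(n_conditions: int, perm: np.ndarray) -> np.ndarray:
    """Index map realizing a condition-label permutation on condensed RDMs.

    For a permutation ``perm`` of condition indices,
    ``condensed(V[perm][:, perm]) == condensed(V)[index]``.
    """
    n = n_conditions
    pair_index = np.zeros((n, n), dtype=int)
    i, j = np.tril_indices(n, -1)
    pair_index[i, j] = pair_index[j, i] = np.arange(len(i))
    p = np.asarray(perm)
    return pair_index[p[i], p[j]]


def searchlight_rho_map(
    fold_patterns: FoldPatterns,
    residuals: list[np.ndarray],
    searchlights: SearchlightSet,
    model: RDM,
    shrinkage: float | str = "auto",
) -> StatMap:
    """Unthresholded Spearman rho map: model fit per searchlight centre."""
    data = _vertex_data_rdms(fold_patterns, residuals, searchlights, shrinkage)
    mr = _normalized_ranks(model.condensed())
    rho = np.full(data.shape[0], np.nan)
    for v in range(data.shape[0]):
        if np.isnan(data[v, 0]):
            continue
        rho[v] = float(_normalized_ranks(data[v]) @ mr)
    return StatMap(rho)


def omnibus_threshold(
    fold_patterns: FoldPatterns,
    residuals: list[np.ndarray],
    searchlights: SearchlightSet,
    model: RDM,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    shrinkage: float | str = "auto",
) -> StatMap:
    """Rho map thresholded by the permutation maximum-statistic distribution.

    Condition labels of each searchlight's data RDM are permuted
    ``n_perm`` times; each permutation's spatial peak rho forms the
    maximum distribution whose ``(1 - alpha)`` quantile is the omnibus
    threshold.  Permutation acts on the data RDM rows/columns (an index
    gather on the condensed vector), which is exchangeable under the
    null and avoids re-estimating distances.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    data = _vertex_data_rdms(fold_patterns, residuals, searchlights, shrinkage)
    valid = ~np.isnan(data[:, 0])
    mr = _normalized_ranks(model.condensed())
    ranks = np.stack([_normalized_ranks(data[v]) for v in np.flatnonzero(valid)])
    rho_valid = ranks @ mr
    rho = np.full(data.shape[0], np.nan)
    rho[valid] = rho_valid

    rng = np.random.default_rng(seed)
    n_cond = model.n_conditions
    max_stat = np.empty(n_perm)
    for p in range(n_perm):
        idx = condensed_permutation_index(n_cond, rng.permutation(n_cond))
        max_stat[p] = np.max(ranks[:, idx] @ mr)
    # k-th largest null maximum gives exact level k / (n_perm + 1) when the
    # observed map is exchangeable with the permutations under the null
    k = max(1, int(np.floor(alpha * (n_perm + 1))))
    threshold = float(np.sort(max_stat)[-k])
    mask = np.zeros(data.shape[0], dtype=bool)
    mask[valid] = rho_valid >= threshold
    return StatMap(rho, threshold=threshold, mask=mask)


def group_heatmap(subject_masks: list[StatMap]) -> np.ndarray:
    """Per-vertex count of subjects with suprathreshold model fit."""
    if not subject_masks:
        raise ValueError("need at least one subject mask")
    shape = subject_masks[0].values.shape
    for m in subject_masks:
        if m.mask is None:
            raise ValueError("all subject maps must be thresholded (mask set)")
        if m.mask.shape != shape:
            raise ValueError("subject masks are defined on different meshes")
    return np.sum([m.mask.astype(int) for m in subject_masks], axis=0)


def contrast_model_maps(
    maps_a: list[StatMap],
    maps_b: list[StatMap],
    fdr_alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Wilcoxon signed-rank contrast of two models' rho maps.

    Tests A > B per vertex across subjects (exact null for the small
    cohorts used here), then applies Benjamini-Hochberg FDR over the
    analyzed vertices.  Vertices where every subject difference is zero
    get p = 1.

    Returns
    -------
    p_fdr : ndarray
        FDR-adjusted p-values per vertex (NaN where not analyzable).
    significant : ndarray of bool
    """
    if len(maps_a) != len(maps_b) or len(maps_a) < 5:
        raise ValueError("need the same >= 5 subjects in both map lists")
    a = np.stack([m.values for m in maps_a])  # (subjects, vertices)
    b = np.stack([m.values for m in maps_b])
    if a.shape != b.shape:
        raise ValueError("model maps are defined on different meshes")
    diffs = a - b
    n_vertices = diffs.shape[1]
    pvals = np.full(n_vertices, np.nan)
    for v in range(n_vertices):
        d = diffs[:, v]
        if np.isnan(d).any():
            continue
        if np.all(d == 0):
            pvals[v] = 1.0
            continue
        method = "exact" if len(d) <= 25 and not np.any(d == 0) else "approx"
        pvals[v] = wilcoxon(d, alternative="greater", method=method).pvalue
    analyzed = ~np.isnan(pvals)
    p_fdr = np.full(n_vertices, np.nan)
    significant = np.zeros(n_vertices, dtype=bool)
    if analyzed.any():
        rej, p_adj, *_ = multipletests(pvals[analyzed], alpha=fdr_alpha, method="fdr_bh")
        p_fdr[analyzed] = p_adj
        significant[analyzed] = rej
    return p_fdr, significant
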