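"""Cross-validated Mahalanobis (crossnobis) distances and RDM comparison.

The distance machinery has three stages:

1. **Noise covariance** — from GLM residuals ``R`` (time by features) the
   feature-by-feature noise covariance is estimated as
   ``Sigma = R' R / T``, optionally shrunk toward its diagonal.
2. **Spatial prewhitening** — condition patterns ``P`` are multiplied by
   ``Sigma^(-1/2)``, turning Euclidean distances on the whitened patterns
   into Mahalanobis distances on the raw ones.
3. **Cross-validated distance** — squared distances are computed as the
   inner product of pattern differences across independent data folds:
   ``d2(k, l) = (P*_k - P*_l)_A . (P*_k - P*_l)_B / V``.  Because the two
   factors carry independent noise, the estimate is unbiased: it is zero
   in expectation when two conditions evoke identical patterns, and may
   legitimately be negative.

RDM agreement is assessed with Spearman rank correlation on the condensed
(lower-triangle) entries; a partial variant discounts a control model.
The upper-bound noise ceiling is the mean correlation of each subject's
RDM with the cross-subject average.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .types import RDM, FoldPatterns

__all__ = [
    "estimate_noise_cov",
    "shrinkage_intensity",
    "whiten_patterns",
    "crossnobis_rdm",
    "spearman_rdm",
    "partial_spearman_rdm",
    "noise_ceiling_upper",
    "noise_ceiling_lower",
]

#: relative eigenvalue floor applied when inverting noise covariances
_EIG_FLOOR = 1e-8


def shrinkage_intensity(residuals: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal target.

    Ledoit–Wolf-style estimator (Schafer & Strimmer): the off-diagonal
    entries of the sample covariance are shrunk by the ratio of their
    estimated sampling variance to their squared magnitude.  Returns a
    value in [0, 1].
    """
    r = np.asarray(residuals, dtype=float)
    t = r.shape[0]
    x = r - r.mean(axis=0)
    s = x.T @ x / t
    # var of each covariance entry estimated from the cross-products
    w = np.einsum("ti,tj->tij", x, x)
    var_s = w.var(axis=0) / t
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = np.sum(s[off] ** 2)
    if denom <= 0:
        return 1.0
    lam = np.sum(var_s[off]) / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_noise_cov(
    residuals: np.ndarray, shrinkage: float | str = "auto"
) -> tuple[np.ndarray, float]:
    """Feature-by-feature noise covariance ``R' R / T`` from residuals.

    Parameters
    ----------
    residuals
        ``(T, V)`` residual matrix (time points by features).
    shrinkage
        Fraction in [0, 1] blending the sample covariance with its
        diagonal, or ``"auto"`` for the analytic intensity.  Shrinkage
        keeps the estimate invertible when ``V`` approaches or exceeds
        ``T``, as it does in searchlight-sized neighbourhoods.

    Returns
    -------
    cov : ndarray, shape (V, V)
    shrinkage_used : float
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 2:
        raise ValueError("residuals must be a 2-D (T, V) matrix")
    if r.shape[0] < 2:
        raise ValueError("need at least 2 time points to estimate noise covariance")
    if not np.isfinite(r).all():
        raise ValueError("residuals contain non-finite values")
    t = r.shape[0]
    s = r.T @ r / t
    lam = shrinkage_intensity(r) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    cov = (1.0 - lam) * s + lam * np.diag(np.diag(s))
    return cov, lam


def _inv_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root with a relative eigenvalue floor."""
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    floor = _EIG_FLOOR * max(w.max(), 1e-300)
    w = np.maximum(w, floor)
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def whiten_patterns(patterns: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Spatially prewhiten patterns: ``P* = P Sigma^(-1/2)``."""
    p = np.asarray(patterns, dtype=float)
    c = np.asarray(cov, dtype=float)
    if p.ndim != 2 or c.shape != (p.shape[1], p.shape[1]):
        raise ValueError(
            f"pattern shape {p.shape} incompatible with covariance shape {c.shape}"
        )
    return p @ _inv_sqrt(c)


def crossnobis_rdm(
    folds: FoldPatterns,
    scheme: str = "loo",
    normalize_by_features: bool = True,
) -> RDM:
    """Cross-validated squared (Mahalanobis) distance RDM.

    Patterns are assumed already whitened (or noise-normalized).  Under
    the ``"loo"`` scheme each fold in turn serves as fold A while the
    mean of the remaining folds serves as fold B; ``"pairs"`` instead
    averages over all unordered fold pairs.  Distances are divided by the
    feature count ``V`` (so values are comparable across searchlights of
    unequal size) unless ``normalize_by_features`` is off.
    """
    if folds.n_folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    if scheme not in ("loo", "pairs"):
        raise ValueError(f"unknown scheme {scheme!r}; expected 'loo' or 'pairs'")
    stack = np.stack(folds.folds)  # (F, C, V)
    f = stack.shape[0]
    if scheme == "loo":
        total = stack.sum(axis=0)
        iters = [(stack[i], (total - stack[i]) / (f - 1)) for i in range(f)]
    else:
        iters = [(stack[i], stack[j]) for i in range(f) for j in range(i + 1, f)]
    acc = np.zeros((stack.shape[1], stack.shape[1]))
    for a, b in iters:
        m = a @ b.T
        acc += np.diag(m)[:, None] + np.diag(m)[None, :] - m - m.T
    values = acc / len(iters)
    if normalize_by_features:
        values /= folds.n_features
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return RDM(values, folds.labels, kind="data_crossnobis")


def _check_pair(data: RDM, model: RDM) -> None:
    if data.labels != model.labels:
        raise ValueError("data and model RDMs must share condition labels")


def spearman_rdm(data: RDM, model: RDM) -> tuple[float, int]:
    """Spearman rank correlation between two RDMs' condensed entries.

    Rank-based comparison makes no distributional assumption, so models
    built from different source data (glove, EMG, category labels) can be
    compared on equal footing.  Ties receive average ranks.

    Returns
    -------
    rho : float
    n_pairs : int
    """
    _check_pair(data, model)
    x = data.condensed()
    y = model.condensed()
    if np.ptp(y) == 0:
        raise ValueError("model RDM is constant; rank correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0:
        return 0.0, len(x)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, len(x)


def _partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial Pearson correlation of x and y given z."""
    def corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    rxy, rxz, ryz = corr(x, y), corr(x, z), corr(y, z)
    denom = np.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
    if denom <= 1e-15:
        return 0.0
    return float(np.clip((rxy - rxz * ryz) / denom, -1.0, 1.0))


def partial_spearman_rdm(
    data: RDM, model: RDM, control: RDM
) -> tuple[float, int]:
    """Partial Spearman correlation of data with model, given a control.

    All three condensed vectors are rank-transformed, then the partial
    Pearson correlation removes the control's rank-linear contribution —
    used to assess the kinematic model while discounting the muscle model
    and vice versa.
    """
    _check_pair(data, model)
    _check_pair(data, control)
    if np.ptp(model.condensed()) == 0 or np.ptp(control.condensed()) == 0:
        raise ValueError("model and control RDMs must be non-constant")
    if np.allclose(model.condensed(), control.condensed()):
        raise ValueError("control RDM is identical to the model RDM")
    rx = rankdata(data.condensed())
    ry = rankdata(model.condensed())
    rz = rankdata(control.condensed())
    return _partial_corr(rx, ry, rz), len(rx)


def _mean_rdm(rdms: list[RDM]) -> RDM:
    labels = rdms[0].labels
    for r in rdms:
        if r.labels != labels:
            raise ValueError("subject RDMs must share condition labels")
    return RDM(np.mean([r.values for r in rdms], axis=0), labels, rdms[0].kind)


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation, 0 by convention when either vector is constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])


def noise_ceiling_upper(subject_rdms: list[RDM]) -> float:
    """Upper-bound noise ceiling for a subject cohort.

    Each subject's RDM is Spearman-correlated with the unweighted
    cross-subject average RDM and the correlations are averaged.  Because
    each subject's data contribute to the average, the value bounds from
    above the correlation any condition-label model could attain.
    """
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling requires at least 2 subjects")
    avg = _mean_rdm(subject_rdms).condensed()
    rhos = [_safe_spearman(r.condensed(), avg) for r in subject_rdms]
    return float(np.mean(rhos))


def noise_ceiling_lower(subject_rdms: list[RDM]) -> float:
    """Leave-one-out lower-bound ceiling (companion utility).

    Each subject is correlated with the average of the *other* subjects'
    RDMs, removing the own-data inclusion bias of the upper bound.
    """
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling requires at least 2 subjects")
    stack = np.stack([r.condensed() for r in subject_rdms])
    n = stack.shape[0]
    rhos = []
    for i in range(n):
        others = (stack.sum(axis=0) - stack[i]) / (n - 1)
        rhos.append(_safe_spearman(stack[i], others))
    return float(np.mean(rhos))
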