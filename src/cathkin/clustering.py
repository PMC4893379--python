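"""Unsupervised 2-group discrimination from kinematic features.

k-means (Lloyd, many random restarts, best within-cluster SSE kept) and a
2-component diagonal-covariance Gaussian mixture fitted by EM are run on
standardized stage-1 features to separate experience groups (or equipment
conditions within the expert group). Accuracy against the known labels is
the best match over the two cluster-to-label bijections, reported as
n_correct / n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.special import logsumexp
from scipy.stats import chi2

__all__ = [
    "ClusterResult",
    "standardize",
    "kmeans2",
    "em_gmm2",
    "clustering_accuracy",
    "run_discrimination",
    "EXPERIENCE_FEATURES",
    "EQUIPMENT_FEATURES",
]

EXPERIENCE_FEATURES = ("T_p", "v_d", "a_d", "j_d")
EQUIPMENT_FEATURES = ("T_p", "a_d")


@dataclass
class ClusterResult:
    """Two-cluster assignment with optional label-matched accuracy.

    ``centers`` holds k-means centroids, or component means for EM (with
    ``variances``/``weights`` filled in). ``objective`` is the within-
    cluster SSE (k-means, minimized) or the final log-likelihood (EM,
    maximized). ``ll_history`` records the EM log-likelihood trace, which
    is non-decreasing. ``ellipse_radii`` are the per-axis radii of the 70%
    confidence ellipses of the EM components.
    """

    assignments: np.ndarray
    centers: np.ndarray
    objective: float
    algorithm: str
    variances: np.ndarray | None = None
    weights: np.ndarray | None = None
    ll_history: np.ndarray | None = None
    ellipse_radii: np.ndarray | None = None
    accuracy: float | None = None
    n_correct: int | None = None
    n: int | None = None


def standardize(X) -> np.ndarray:
    """Zero-mean, unit-variance columns (population sd).

    Features carry incommensurate units (seconds, px/s, unitless jerk), so
    clustering distances are only meaningful after standardization. A
    constant column raises, naming the column index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"constant column(s) {np.flatnonzero(sd == 0).tolist()} cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def _sse(X: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(((X - centers[assign]) ** 2).sum())


def kmeans2(X, restarts: int = 100, seed: int = 0, max_iter: int = 100) -> ClusterResult:
    """2-means by Lloyd's algorithm with random restarts.

    Each restart initializes the two centers at distinct random points and
    iterates assignment/update until assignments stabilize; an emptied
    cluster is re-seeded at the point farthest from the surviving center.
    The restart with the lowest within-cluster SSE wins. Deterministic
    under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 points for k = 2")
    n = X.shape[0]
    rng = default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        centers = X[rng.choice(n, 2, replace=False)].copy()
        assign = np.full(n, -1)
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            new_assign = d2.argmin(axis=1)
            for k in (0, 1):
                if not (new_assign == k).any():
                    far = int(d2[:, 1 - k].argmax())
                    new_assign[far] = k
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            centers = np.stack([X[assign == k].mean(axis=0) for k in (0, 1)])
        sse = _sse(X, centers, assign)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, assign.copy(), centers.copy())
    sse, assign, centers = best
    return ClusterResult(assign, centers, sse, "kmeans", n=n)


def em_gmm2(
    X,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
    restarts: int = 50,
) -> ClusterResult:
    """2-component diagonal Gaussian mixture by EM.

    Initialized from the best k-means partition; E/M steps iterate until
    the log-likelihood gain drops below ``tol``. Variances are floored at
    1e-4 of the column variance (full covariances would be singular with a
    dozen points). Assignments are by maximum responsibility; the 70%
    confidence ellipse radii per component are reported for plotting.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("EM on 2 components needs at least 4 points")
    n, d = X.shape
    km = kmeans2(X, restarts=restarts, seed=seed)
    floor = np.maximum(1e-4 * X.var(axis=0), 1e-12)

    means = km.centers.copy()
    variances = np.stack(
        [np.maximum(X[km.assignments == k].var(axis=0), floor) for k in (0, 1)]
    )
    weights = np.array([(km.assignments == k).mean() for k in (0, 1)])
    weights = np.clip(weights, 1e-6, None)
    weights /= weights.sum()

    ll_hist: list[float] = []
    resp = None
    for _ in range(max_iter):
        log_p = np.empty((n, 2))
        for k in (0, 1):
            log_p[:, k] = (
                np.log(weights[k])
                - 0.5 * np.sum(np.log(2 * np.pi * variances[k]))
                - 0.5 * np.sum((X - means[k]) ** 2 / variances[k], axis=1)
            )
        norm = logsumexp(log_p, axis=1)
        ll = float(norm.sum())
        resp = np.exp(log_p - norm[:, None])
        if ll_hist and ll - ll_hist[-1] < tol:
            ll_hist.append(ll)
            break
        ll_hist.append(ll)
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8) or not np.all(np.isfinite(nk)):
            raise ValueError("a mixture component collapsed during EM")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for k in (0, 1):
            variances[k] = np.maximum(
                (resp[:, k][:, None] * (X - means[k]) ** 2).sum(axis=0) / nk[k], floor
            )
    assign = resp.argmax(axis=1)
    ellipse = np.sqrt(variances * chi2.ppf(0.70, df=d))
    return ClusterResult(
        assign,
        means,
        ll_hist[-1],
        "em",
        variances=variances,
        weights=weights,
        ll_history=np.asarray(ll_hist),
        ellipse_radii=ellipse,
        n=n,
    )


def clustering_accuracy(assignments, labels) -> tuple[float, int, int]:
    """Best label-permutation accuracy of a 2-cluster assignment.

    Returns (accuracy, n_correct, n); invariant to cluster relabeling, so
    a perfectly anti-aligned assignment scores 1.0 and a coin flip on
    balanced labels never scores below 0.5.
    """
    assignments = np.asarray(assignments).ravel()
    labels = np.asarray(labels).ravel()
    if assignments.size != labels.size:
        raise ValueError("assignments and labels must have equal length")
    ulab = np.unique(labels)
    if ulab.size > 2:
        raise ValueError(f"expected at most 2 distinct labels, got {ulab.size}")
    if np.unique(assignments).size > 2:
        raise ValueError("expected at most 2 clusters")
    binary = (labels == ulab[-1]).astype(int)
    match = int((assignments == binary).sum())
    n = assignments.size
    n_correct = max(match, n - match)
    return n_correct / n, n_correct, n


def run_discrimination(
    features: pd.DataFrame,
    task: str = "experience",
    feature_combo: tuple[str, ...] | None = None,
    algorithm: str = "kmeans",
    seed: int = 0,
    equipment: str = "conventional",
    restarts: int = 100,
    log_transform: bool = True,
) -> ClusterResult:
    """Cluster stage-1 feature vectors and score against the true labels.

    ``task='experience'`` separates novice vs expert from one equipment
    condition (conventional by default) using features among
    {T_p, v_d, a_d, j_d}; ``task='equipment'`` separates conventional vs
    robotic within the expert group using {T_p, a_d} by default.

    All four kinematic features are strictly positive ratio-scale
    quantities, and the dimensionless jerk in particular spans orders of
    magnitude (its T_p^5 normalization amplifies duration differences), so
    by default each strictly positive column is log10-transformed before
    standardization; a linear z-score of such a column would reduce it to
    a single outlier indicator. Disable with ``log_transform=False``.
    """
    if task == "experience":
        combo = tuple(feature_combo or EXPERIENCE_FEATURES)
        allowed = set(EXPERIENCE_FEATURES)
        unknown = set(combo) - allowed
        if unknown:
            raise ValueError(f"unknown feature(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
        sub = features.query("stage == 1 and equipment == @equipment")
        labels = sub["group"].to_numpy()
    elif task == "equipment":
        combo = tuple(feature_combo or EQUIPMENT_FEATURES)
        unknown = set(combo) - {"T_p", "v_d", "a_d", "j_d"}
        if unknown:
            raise ValueError(f"unknown feature(s) {sorted(unknown)}")
        sub = features.query("stage == 1 and group == 'expert'")
        labels = sub["equipment"].to_numpy()
    else:
        raise ValueError(f"unknown task {task!r}; expected 'experience' or 'equipment'")
    missing = [c for c in combo if c not in sub.columns]
    if missing:
        raise ValueError(f"feature column(s) {missing} absent from the table")
    X = sub[list(combo)].to_numpy(dtype=float)
    if log_transform:
        for j in range(X.shape[1]):
            if np.all(X[:, j] > 0):
                X[:, j] = np.log10(X[:, j])
    X = standardize(X)
    if algorithm == "kmeans":
        result = kmeans2(X, restarts=restarts, seed=seed)
    elif algorithm == "em":
        result = em_gmm2(X, seed=seed, restarts=restarts)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected 'kmeans' or 'em'")
    acc, n_correct, n = clustering_accuracy(result.assignments, labels)
    result.accuracy, result.n_correct, result.n = acc, n_correct, n
    return result
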