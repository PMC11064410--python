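"""Unsupervised clustering of samples on top principal components.

The default protocol mirrors common population-structure practice: detect
the best K and centroids with K-Means (maximum mean silhouette over a K
range), then refine with a full-covariance Gaussian mixture fitted by EM,
taking the best of many restarts — the first seeded at the K-Means
centroids, the rest at random perturbations of them.  K-Means and DBSCAN
are available as standalone alternatives.  Agreement with prior group
labels is scored by optimal one-to-one cluster<->group matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterResult",
    "best_k_kmeans",
    "em_gaussian_cluster",
    "kmeans_cluster",
    "dbscan_cluster",
    "concordance",
]


@dataclass
class ClusterResult:
    labels: np.ndarray              # per-sample cluster id; -1 = DBSCAN noise
    K: int
    method: str                     # "EM-Gaussian" | "K-Means" | "DBSCAN"
    centroids_or_params: Dict[str, np.ndarray]
    log_likelihood: Optional[float] = None      # EM-Gaussian only
    posteriors: Optional[np.ndarray] = None     # n x K responsibilities
    log_likelihood_history: Optional[np.ndarray] = field(default=None, repr=False)


def best_k_kmeans(
    points: np.ndarray, k_min: int = 2, k_max: int = 10, seed: int = 12345
) -> Tuple[int, np.ndarray]:
    """Pick the cluster count maximizing mean silhouette over K-Means fits.

    Ties break toward smaller K; the winning run's centroids seed the EM
    refinement stage.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if not (2 <= k_min <= k_max <= n):
        raise ValueError(f"need 2 <= k_min <= k_max <= n, got ({k_min}, {k_max}, n={n})")
    if n < 2 * k_min:
        raise ValueError(f"too few points ({n}) for k_min={k_min}")
    if np.allclose(points, points[0]):
        raise ValueError("all points identical: zero within-cluster variance for every K")
    best: Tuple[float, int, np.ndarray] | None = None
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
        labels = km.fit_predict(points)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(points, labels)
        if best is None or score > best[0]:  # strict > breaks ties toward smaller K
            best = (score, k, km.cluster_centers_)
    if best is None:
        raise ValueError("no K produced a valid clustering")
    return best[1], best[2]


def _em_once(
    points: np.ndarray,
    means: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run from given means; uniform weights and the pooled data
    covariance as the initial per-component covariance.

    Returns (log_likelihood, posteriors, means, covariances, weights,
    per-iteration log-likelihood trace).  The trace is non-decreasing — the
    standard EM guarantee — and convergence is declared when the relative
    change drops below ``tol``.
    """
    n, d = points.shape
    K = means.shape[0]
    covs = np.tile(np.cov(points.T).reshape(d, d) + reg * np.eye(d), (K, 1, 1))
    weights = np.full(K, 1.0 / K)
    means = means.copy()
    history: List[float] = []
    prev_ll = -np.inf
    resp = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        # E step: log N(x | mu_k, Sigma_k) via Cholesky
        log_prob = np.empty((n, K))
        for k in range(K):
            try:
                L = np.linalg.cholesky(covs[k])
            except np.linalg.LinAlgError:
                return -np.inf, resp, means, covs, weights, np.array(history)
            diff = points - means[k]
            sol = np.linalg.solve(L, diff.T)
            log_det = 2.0 * np.log(np.diag(L)).sum()
            log_prob[:, k] = -0.5 * (
                d * np.log(2 * np.pi) + log_det + (sol ** 2).sum(axis=0)
            )
        log_weighted = log_prob + np.log(weights)
        m = log_weighted.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_weighted - m).sum(axis=1))
        ll = float(log_norm.sum())
        history.append(ll)
        resp = np.exp(log_weighted - log_norm[:, None])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            return -np.inf, resp, means, covs, weights, np.array(history)
        weights = nk / n
        means = (resp.T @ points) / nk[:, None]
        for k in range(K):
            diff = points - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k] + reg * np.eye(d)
    return history[-1], resp, means, covs, weights, np.array(history)


def em_gaussian_cluster(
    points: np.ndarray,
    K: int,
    init_centroids: Optional[np.ndarray] = None,
    n_restarts: int = 1000,
    seed: int = 12345,
) -> ClusterResult:
    """Best-of-restarts Gaussian mixture fit on PC coordinates.

    Restart 1 initializes at ``init_centroids`` (typically the K-Means
    solution); restarts 2..n_restarts perturb them with seeded Gaussian
    noise at the per-dimension data scale.  The restart with the highest
    converged log-likelihood wins; hard labels are argmax posteriors.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    if init_centroids is None:
        init_centroids = points[rng.choice(n, size=K, replace=False)]
    init_centroids = np.asarray(init_centroids, dtype=np.float64)
    scale = points.std(axis=0)
    best = None
    for r in range(n_restarts):
        means0 = init_centroids if r == 0 else (
            init_centroids + rng.normal(scale=scale, size=init_centroids.shape)
        )
        ll, resp, means, covs, weights, history = _em_once(points, means0)
        if np.isfinite(ll) and (best is None or ll > best[0]):
            best = (ll, resp, means, covs, weights, history)
    if best is None:
        raise ValueError("all EM restarts degenerated")
    ll, resp, means, covs, weights, history = best
    return ClusterResult(
        labels=resp.argmax(axis=1),
        K=K,
        method="EM-Gaussian",
        centroids_or_params={"means": means, "covariances": covs, "weights": weights},
        log_likelihood=ll,
        posteriors=resp,
        log_likelihood_history=history,
    )


def kmeans_cluster(points: np.ndarray, K: int, seed: int = 12345) -> ClusterResult:
    points = np.asarray(points, dtype=np.float64)
    if K > points.shape[0]:
        raise ValueError(f"K={K} exceeds the number of samples ({points.shape[0]})")
    km = KMeans(n_clusters=K, n_init=10, init="k-means++", random_state=seed)
    labels = km.fit_predict(points)
    return ClusterResult(
        labels=labels,
        K=K,
        method="K-Means",
        centroids_or_params={"means": km.cluster_centers_},
    )


def dbscan_cluster(
    points: np.ndarray, eps: Optional[float] = None, min_pts: int = 4
) -> ClusterResult:
    """Density-based clustering; noise points get label -1.  When eps is
    unset it defaults to the mean distance to the 4th nearest neighbor."""
    points = np.asarray(points, dtype=np.float64)
    if eps is None:
        k = min(4, points.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
        dist, _ = nn.kneighbors(points)
        eps = float(dist[:, -1].mean())
    if eps <= 0:
        raise ValueError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
    clusters = np.unique(labels[labels >= 0])
    means = np.array([points[labels == c].mean(axis=0) for c in clusters]) \
        if clusters.size else np.empty((0, points.shape[1]))
    return ClusterResult(
        labels=labels,
        K=int(clusters.size),
        method="DBSCAN",
        centroids_or_params={"means": means},
    )


def concordance(pred_labels: Sequence, prior_groups: Sequence[str]) -> float:
    """Best one-to-one matching accuracy between predicted clusters and
    prior groups (Hungarian assignment on the confusion matrix).  Samples
    with prior group "NA" are excluded from the score."""
    pred = np.asarray(pred_labels)
    prior = np.asarray(prior_groups, dtype=object)
    if pred.shape[0] != prior.shape[0]:
        raise ValueError("pred_labels and prior_groups must cover the same samples")
    scored = prior != "NA"
    pred, prior = pred[scored], prior[scored]
    if pred.size == 0:
        raise ValueError("no samples carry a prior group label")
    clusters = np.unique(pred)
    groups = np.unique(prior)
    conf = np.zeros((clusters.size, groups.size))
    for ci, c in enumerate(clusters):
        for gi, g in enumerate(groups):
            conf[ci, gi] = np.count_nonzero((pred == c) & (prior == g))
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / pred.size)
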