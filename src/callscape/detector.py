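"""GMM-UBM detector: EM training, means-only MAP adaptation, LLR scoring.

The background model is a diagonal-covariance Gaussian mixture trained
with EM; the target model shares its weights and variances and differs
only in the component means, which are shifted toward the target data's
posterior means with a relevance factor.  Frames are scored by the
log-likelihood ratio of the two mixtures and thresholded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = ["UbmModel", "TargetModel", "train_ubm", "adapt_means", "score", "decide"]

_LOG_2PI = np.log(2.0 * np.pi)


def _component_log_densities(X: np.ndarray, weights, means, variances) -> np.ndarray:
    """log(w_k * N(x | m_k, diag v_k)) for every frame x and component k -> (n, K)."""
    inv_v = 1.0 / variances  # (K, D)
    logdet = np.sum(np.log(variances), axis=1)  # (K,)
    quad = (
        (X**2) @ inv_v.T
        - 2.0 * X @ (means * inv_v).T
        + np.sum(means**2 * inv_v, axis=1)
    )
    return np.log(weights) - 0.5 * (X.shape[1] * _LOG_2PI + logdet + quad)


@dataclass
class UbmModel:
    """Universal background model: diagonal-covariance Gaussian mixture."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    variances: np.ndarray  # (K, D)
    feature_stats_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-frame mixture log-density (log-sum-exp over components)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_dims:
            raise ValueError(f"expected {self.n_dims}-dim frames, got {X.shape[1]}")
        return logsumexp(_component_log_densities(X, self.weights, self.means, self.variances), axis=1)

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        lg = _component_log_densities(X, self.weights, self.means, self.variances)
        return np.exp(lg - logsumexp(lg, axis=1, keepdims=True))

    def to_json(self) -> str:
        return json.dumps({
            "format": "callscape-gmm-v1",
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "feature_stats_id": self.feature_stats_id,
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "UbmModel":
        obj = json.loads(text)
        return cls(np.asarray(obj["weights"]), np.asarray(obj["means"]),
                   np.asarray(obj["variances"]), obj.get("feature_stats_id", ""),
                   obj.get("seed"))


@dataclass
class TargetModel:
    """Target model derived from a UBM by means-only MAP adaptation.

    Weights and variances are the UBM's (bitwise); only the means differ.
    """

    ubm: UbmModel
    adapted_means: np.ndarray
    relevance_factor: float

    def __post_init__(self) -> None:
        self.adapted_means = np.asarray(self.adapted_means, dtype=np.float64)
        if self.adapted_means.shape != self.ubm.means.shape:
            raise ValueError("adapted means must match the UBM shape")
        if self.relevance_factor < 0:
            raise ValueError("relevance factor must be non-negative")

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.ubm.n_dims:
            raise ValueError(f"expected {self.ubm.n_dims}-dim frames, got {X.shape[1]}")
        return logsumexp(
            _component_log_densities(X, self.ubm.weights, self.adapted_means, self.ubm.variances),
            axis=1,
        )

    def to_json(self) -> str:
        return json.dumps({
            "format": "callscape-target-v1",
            "adapted_means": self.adapted_means.tolist(),
            "relevance_factor": self.relevance_factor,
            "ubm": json.loads(self.ubm.to_json()),
        })

    @classmethod
    def from_json(cls, text: str) -> "TargetModel":
        obj = json.loads(text)
        ubm = UbmModel.from_json(json.dumps(obj["ubm"]))
        return cls(ubm, np.asarray(obj["adapted_means"]), obj["relevance_factor"])


def _kmeans_pp_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding of component means."""
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = X[rng.integers(n)]
            continue
        centers[k] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[k]) ** 2, axis=1))
    return centers


def train_ubm(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
    variance_floor_frac: float = 1e-4,
    return_history: bool = False,
):
    """Fit a K-component diagonal GMM with EM (k-means++ initialization).

    The per-dimension variance floor is ``variance_floor_frac`` times the
    global data variance.  Training stops when the relative log-likelihood
    improvement drops below ``tol`` or after ``max_iter`` iterations.
    Components whose soft count collapses are re-seeded from the component
    with the largest total variance (logged).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be (n_frames, n_dims)")
    n, d = X.shape
    if K > n:
        raise ValueError(f"K={K} exceeds the number of frames ({n})")
    rng = np.random.default_rng(seed)
    global_var = np.var(X, axis=0)
    floor = np.maximum(variance_floor_frac * global_var, 1e-12)

    means = _kmeans_pp_init(X, K, rng)
    # hard-assignment initialization of weights/variances
    d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2) if n * K * d <= 2e8 else None
    if d2 is None:
        d2 = np.empty((n, K))
        for k in range(K):
            d2[:, k] = np.sum((X - means[k]) ** 2, axis=1)
    assign = np.argmin(d2, axis=1)
    weights = np.full(K, 1.0 / K)
    variances = np.tile(np.maximum(global_var, floor), (K, 1))
    for k in range(K):
        members = X[assign == k]
        if len(members) > 1:
            weights[k] = len(members) / n
            variances[k] = np.maximum(np.var(members, axis=0), floor)
    weights /= weights.sum()

    history: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        lg = _component_log_densities(X, weights, means, variances)
        frame_ll = logsumexp(lg, axis=1)
        ll = float(frame_ll.mean())
        history.append(ll)
        resp = np.exp(lg - frame_ll[:, None])
        nk = resp.sum(axis=0)
        empty = nk < 1e-8
        if np.any(empty):
            donor = int(np.argmax(variances.sum(axis=1)))
            for k in np.flatnonzero(empty):
                logger.warning("re-seeding empty component %d from component %d", k, donor)
                means[k] = means[donor] + rng.normal(scale=np.sqrt(variances[donor]))
                variances[k] = variances[donor]
                nk[k] = 1.0
        weights = nk / nk.sum()
        means = (resp.T @ X) / nk[:, None]
        ex2 = (resp.T @ (X**2)) / nk[:, None]
        variances = np.maximum(ex2 - means**2, floor)
        if it > 0 and ll - prev_ll < tol * abs(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

    model = UbmModel(weights, means, variances, seed=seed)
    if return_history:
        return model, history
    return model


def adapt_means(ubm: UbmModel, target_features: np.ndarray,
                relevance_factor: float = 16.0) -> TargetModel:
    """Classical MAP means-only update toward the target data.

    For component k with soft count ``n_k`` and posterior-weighted mean
    ``E_k``: ``m_k' = a_k E_k + (1 - a_k) m_k`` with
    ``a_k = n_k / (n_k + r)``.  Weights and variances are untouched.
    """
    X = np.atleast_2d(np.asarray(target_features, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("cannot adapt on an empty target set")
    if X.shape[1] != ubm.n_dims:
        raise ValueError("target features do not match UBM dimensionality")
    resp = ubm.responsibilities(X)
    nk = resp.sum(axis=0)  # (K,)
    ek = np.where(nk[:, None] > 0, (resp.T @ X) / np.maximum(nk, 1e-300)[:, None], ubm.means)
    alpha = nk / (nk + relevance_factor)
    adapted = alpha[:, None] * ek + (1.0 - alpha[:, None]) * ubm.means
    return TargetModel(ubm, adapted, relevance_factor)


def score(frames: np.ndarray, ubm: UbmModel, target: TargetModel) -> np.ndarray:
    """Per-frame log-likelihood ratio log p(x|target) - log p(x|ubm), in nats."""
    if target.ubm.n_dims != ubm.n_dims:
        raise ValueError("models disagree on feature dimensionality")
    return target.log_likelihood(frames) - ubm.log_likelihood(frames)


def decide(llr: np.ndarray, threshold: float) -> np.ndarray:
    """Frame decisions: llr >= threshold."""
    return np.asarray(llr) >= threshold
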