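"""Soft-cluster emission model and conversion of event features to densities.

Elementary behavioural events (e.g. swim bouts) are described by ``d``-dim
feature vectors and soft-clustered with a Gaussian mixture whose emission
densities ``q(y | c)`` are shared across datasets while the cluster weights
may differ per dataset (so that the same behavioural alphabet describes, say,
a control and a treatment group).  The per-event density rows ``rho_ij =
q(y_i | j)`` are the sole input to the motif-learning machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import linalg


@dataclass
class EventSequence:
    """One individual's sequence of event feature vectors (L x d)."""

    sequence_id: str
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] < 1:
            raise ValueError("sequence must contain at least one event")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"sequence {self.sequence_id}: missing values")


@dataclass
class SymbolProbSequence:
    """Per-event emission densities over the K-character alphabet."""

    sequence_id: str
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if np.any(self.rho < 0):
            raise ValueError("emission densities must be nonnegative")

    @property
    def posteriors(self) -> np.ndarray:
        """Row-normalized p(c | y), assuming equal prior weights."""
        tot = self.rho.sum(axis=1, keepdims=True)
        return self.rho / tot


@dataclass
class EmissionModel:
    """Gaussian emission densities q(y|c), shared across datasets.

    ``weights`` holds one K-simplex vector per dataset (mixture weights are
    the only dataset-specific part of the model).
    """

    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    weights: List[np.ndarray]  # per dataset, each (K,)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        for w in self.weights:
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("each weight vector must sum to 1")
        for S in self.covariances:
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError("covariances must be symmetric")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def densities(self, X: np.ndarray) -> np.ndarray:
        """Component densities q(y_i | j) for each row of X; shape (n, K)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.d}"
            )
        n = X.shape[0]
        out = np.empty((n, self.K))
        for j in range(self.K):
            out[:, j] = _gauss_pdf(X, self.means[j], self.covariances[j])
        return out

    def log_densities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        out = np.empty((n, self.K))
        for j in range(self.K):
            out[:, j] = _gauss_logpdf(X, self.means[j], self.covariances[j])
        return out

    def posteriors(self, X: np.ndarray, dataset: int = 0) -> np.ndarray:
        logd = self.log_densities(X) + np.log(self.weights[dataset])
        logd -= logd.max(axis=1, keepdims=True)
        w = np.exp(logd)
        return w / w.sum(axis=1, keepdims=True)

    def sample_sequence(self, labels: Sequence[int],
                        rng: np.random.Generator) -> np.ndarray:
        """Draw one observation per label from the component Gaussians."""
        out = np.empty((len(labels), self.d))
        for t, c in enumerate(labels):
            out[t] = rng.multivariate_normal(self.means[c], self.covariances[c])
        return out

    def to_json(self) -> dict:
        return {
            "schema": 1,
            "K": self.K,
            "d": self.d,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": [w.tolist() for w in self.weights],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "EmissionModel":
        return cls(
            means=np.array(obj["means"], float),
            covariances=np.array(obj["covariances"], float),
            weights=[np.array(w, float) for w in obj["weights"]],
        )


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mean.shape[0]
    chol = linalg.cholesky(cov, lower=True)
    dev = linalg.solve_triangular(chol, (X - mean).T, lower=True)
    maha = np.sum(dev * dev, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _gauss_pdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return np.exp(_gauss_logpdf(X, mean, cov))


def emission_densities(model: EmissionModel, events: EventSequence) -> SymbolProbSequence:
    """Convert an event sequence to its emission-density representation."""
    return SymbolProbSequence(
        sequence_id=events.sequence_id, rho=model.densities(events.features)
    )


def hard_label_rho(labels: Sequence[int], K: int, floor: float = 1e-8) -> np.ndarray:
    """Near-one-hot density rows for integer-labelled (hard-clustered) data."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError("labels out of range for alphabet size K")
    rho = np.full((labels.shape[0], K), floor)
    rho[np.arange(labels.shape[0]), labels] = 1.0
    return rho


# ------------------------------------------------------------------ fitting
def _js_divergence(weights: List[np.ndarray]) -> float:
    """JS divergence of per-dataset weight vectors from their pooled mean."""
    wbar = np.mean(weights, axis=0)
    js = 0.0
    for w in weights:
        mask = w > 0
        js += np.sum(w[mask] * np.log(w[mask] / wbar[mask])) / len(weights)
    return float(js)


def fit_shared_gmm(
    datasets: Sequence[np.ndarray],
    K: int,
    js_penalty_weight: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-7,
    reg_covar: float = 1e-6,
    seed: int = 0,
    subsample_equal: bool = True,
    init: Tuple[np.ndarray, np.ndarray, List[np.ndarray]] | None = None,
) -> EmissionModel:
    """EM fit of a Gaussian mixture with shared emissions per-dataset weights.

    Maximizes the sum of per-dataset log-likelihoods plus ``js_penalty_weight``
    times the Jensen-Shannon divergence between the per-dataset cluster
    weights (a positive weight pushes datasets toward *different* weight
    profiles while sharing the same components).  Datasets are subsampled to
    a common size before fitting so no dataset dominates the shared emissions.

    ``init`` may supply ``(means, covariances, weights)`` to start from;
    otherwise k-means++ style seeding on the pooled data is used.
    """
    rng = np.random.default_rng(seed)
    datasets = [np.atleast_2d(np.asarray(X, float)) for X in datasets]
    d = datasets[0].shape[1]
    if any(X.shape[1] != d for X in datasets):
        raise ValueError("datasets must share the feature dimension")
    if subsample_equal and len(datasets) > 1:
        n_min = min(X.shape[0] for X in datasets)
        datasets = [
            X if X.shape[0] == n_min
            else X[rng.choice(X.shape[0], n_min, replace=False)]
            for X in datasets
        ]
    pooled = np.vstack(datasets)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > np.unique(pooled, axis=0).shape[0]:
        raise ValueError("K exceeds the number of distinct data points")

    if init is not None:
        means, covs, weights = init
        means = np.array(means, float).copy()
        covs = np.array(covs, float).copy()
        weights = [np.array(w, float).copy() for w in weights]
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(pooled)
        means = km.cluster_centers_.copy()
        covs = np.empty((K, d, d))
        for j in range(K):
            pts = pooled[labels == j]
            if pts.shape[0] <= d:
                covs[j] = np.cov(pooled.T) + reg_covar * np.eye(d)
            else:
                covs[j] = np.cov(pts.T, bias=False).reshape(d, d) + reg_covar * np.eye(d)
        weights = [np.full(K, 1.0 / K) for _ in datasets]

    prev_obj = -np.inf
    model = EmissionModel(means, covs, weights)
    for _ in range(max_iter):
        # E-step
        resp_list = []
        obj = 0.0
        for k, X in enumerate(datasets):
            logd = model.log_densities(X) + np.log(np.clip(model.weights[k], 1e-300, None))
            mx = logd.max(axis=1, keepdims=True)
            w = np.exp(logd - mx)
            tot = w.sum(axis=1, keepdims=True)
            resp_list.append(w / tot)
            obj += float(np.sum(np.log(tot) + mx))
        obj += js_penalty_weight * _js_divergence(model.weights)

        # M-step: shared means/covariances, per-dataset weights
        nk_total = np.zeros(K)
        mean_acc = np.zeros((K, d))
        for X, resp in zip(datasets, resp_list):
            nk_total += resp.sum(axis=0)
            mean_acc += resp.T @ X
        means = mean_acc / np.maximum(nk_total[:, None], 1e-300)
        covs = np.zeros((K, d, d))
        for X, resp in zip(datasets, resp_list):
            for j in range(K):
                dev = X - means[j]
                covs[j] += (resp[:, j][:, None] * dev).T @ dev
        covs /= np.maximum(nk_total[:, None, None], 1e-300)
        covs += reg_covar * np.eye(d)[None, :, :]
        if np.any(nk_total < 1e-8):
            raise ValueError(
                "degenerate component: a cluster captured no data; reduce K"
            )

        new_weights = []
        for k, (X, resp) in enumerate(zip(datasets, resp_list)):
            w = resp.mean(axis=0)
            if js_penalty_weight != 0.0:
                w = _penalized_weight_update(
                    w, [model.weights[i] for i in range(len(datasets))], k,
                    js_penalty_weight / X.shape[0]
                )
            new_weights.append(w)
        model = EmissionModel(means, covs, new_weights)

        if abs(obj - prev_obj) < tol * max(1.0, abs(obj)):
            break
        prev_obj = obj
    return model


def _penalized_weight_update(
    w: np.ndarray, all_weights: List[np.ndarray], k: int, scale: float
) -> np.ndarray:
    """One projected-gradient adjustment of dataset-k weights for the JS term.

    The JS penalty has no closed-form M-step; a single small ascent step on
    the penalty gradient (projected back to the simplex) after the standard
    update is sufficient to bias the weights apart, and keeps EM stable.
    """
    wbar = np.mean(all_weights, axis=0)
    grad = np.log(np.clip(w, 1e-12, None) / np.clip(wbar, 1e-12, None)) / len(all_weights)
    w = np.clip(w + scale * grad, 1e-10, None)
    return w / w.sum()


def held_out_log_likelihood(
    model: EmissionModel, datasets: Sequence[np.ndarray]
) -> float:
    """Pooled per-event log-likelihood of held-out data under the model."""
    total, n = 0.0, 0
    for k, X in enumerate(datasets):
        k_eff = min(k, len(model.weights) - 1)
        logd = model.log_densities(X) + np.log(model.weights[k_eff])
        mx = logd.max(axis=1, keepdims=True)
        total += float(np.sum(np.log(np.exp(logd - mx).sum(axis=1)) + mx.ravel()))
        n += X.shape[0]
    return total / n


def select_n_components(
    datasets: Sequence[np.ndarray],
    K_range: Sequence[int],
    held_out_fraction: float = 0.25,
    seed: int = 0,
    **fit_kwargs,
) -> Tuple[int, dict]:
    """Choose K by per-event log-likelihood on a held-out split."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for X in datasets:
        idx = rng.permutation(X.shape[0])
        cut = int(round(X.shape[0] * (1 - held_out_fraction)))
        train.append(X[idx[:cut]])
        test.append(X[idx[cut:]])
    scores = {}
    for K in K_range:
        try:
            model = fit_shared_gmm(train, K, seed=seed, **fit_kwargs)
        except ValueError:
            continue
        scores[K] = held_out_log_likelihood(model, test)
    best = max(scores, key=scores.get)
    return best, scores
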