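"""Principal-component embedding and Gaussian-mixture clustering with BIC.

The embedding centers samples by the training mean (no variance scaling) and
keeps the top right-singular directions; each component is oriented so that
its correlation with training age is non-negative, making downstream
trajectories reproducible.  The mixture model is fitted by EM under six
covariance families (spherical/diagonal/full, each shared across components
or free per component), and the (k, family) pair is chosen by minimizing
``n_params * ln(n) - 2 * log_likelihood``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .datasets import InputError

logger = logging.getLogger(__name__)

COVARIANCE_FAMILIES = (
    "spherical-shared",
    "spherical-free",
    "diagonal-shared",
    "diagonal-free",
    "full-shared",
    "full-free",
)

_VAR_FLOOR = 1e-6


class DegenerateFitError(RuntimeError):
    """Raised when every candidate mixture fit is degenerate."""


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EmbeddingModel:
    """Centered PCA basis over the selected sites.

    ``basis`` has shape (n_sites, n_components) with orthonormal columns;
    ``explained_variance`` are the corresponding sample-covariance eigenvalues
    in non-increasing order.
    """

    training_mean: np.ndarray
    basis: np.ndarray
    explained_variance: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise InputError("basis columns are not orthonormal")
        if (np.diff(self.explained_variance) > 1e-12).any():
            raise InputError("explained_variance must be non-increasing")


def fit_embedding(train_betas: np.ndarray, n_components: int = 2,
                  ages: Optional[np.ndarray] = None) -> EmbeddingModel:
    """Fit the embedding on a (sites x samples) training matrix.

    With ``ages`` given, each component is sign-fixed so its training scores
    correlate non-negatively with age; otherwise the largest-|loading| entry
    is made positive.
    """
    X = np.asarray(train_betas, dtype=float).T      # samples x sites
    n_samples, n_sites = X.shape
    if n_samples <= n_components:
        raise InputError("need more samples than components")
    if n_sites < n_components:
        raise InputError("need at least n_components sites")
    mean = X.mean(axis=0)
    Xc = X - mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise InputError(f"n_components={n_components} exceeds data rank {rank}")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    basis = vt[:n_components].T
    explained = s[:n_components] ** 2 / (n_samples - 1)

    scores = Xc @ basis
    for comp in range(n_components):
        if ages is not None and np.ptp(np.asarray(ages, dtype=float)) > 0:
            orient = np.corrcoef(scores[:, comp], ages)[0, 1]
        else:
            orient = basis[np.argmax(np.abs(basis[:, comp])), comp]
        if orient < 0:
            basis[:, comp] = -basis[:, comp]
    return EmbeddingModel(training_mean=mean, basis=basis,
                          explained_variance=explained, n_components=n_components)


def embed(model: EmbeddingModel, betas: np.ndarray) -> np.ndarray:
    """Project a (sites x samples) matrix; returns (samples x n_components)."""
    X = np.asarray(betas, dtype=float).T
    if X.shape[1] != model.training_mean.shape[0]:
        raise InputError(
            f"site dimension {X.shape[1]} does not match model "
            f"({model.training_mean.shape[0]})")
    return (X - model.training_mean) @ model.basis


# ---------------------------------------------------------------------------
# Gaussian mixture with six covariance families
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GMMModel:
    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray               # (k, d)
    covariances: np.ndarray         # (k, d, d), expanded to full form
    log_likelihood: float
    n_params: int
    loglik_history: list = dataclasses.field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise InputError("mixture weights must sum to 1")
        for cov in self.covariances:
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise InputError("covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise InputError("covariance not positive definite")

    def component_logpdf(self, coords: np.ndarray) -> np.ndarray:
        """Log density of each component at each coordinate: (n, k)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n, d = coords.shape
        out = np.empty((n, self.k))
        for c in range(self.k):
            chol = np.linalg.cholesky(self.covariances[c])
            diff = (coords - self.means[c]).T
            z = np.linalg.solve(chol, diff)
            maha = (z ** 2).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            out[:, c] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        return out

    def responsibilities(self, coords: np.ndarray) -> np.ndarray:
        logw = np.log(self.weights)
        joint = self.component_logpdf(coords) + logw
        return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))

    def predict(self, coords: np.ndarray) -> np.ndarray:
        logw = np.log(self.weights)
        return np.argmax(self.component_logpdf(coords) + logw, axis=1)

    def score(self, coords: np.ndarray) -> float:
        logw = np.log(self.weights)
        return float(logsumexp(self.component_logpdf(coords) + logw, axis=1).sum())


def _count_params(k: int, d: int, family: str) -> int:
    shape, sharing = family.split("-")
    cov = {"spherical": 1, "diagonal": d, "full": d * (d + 1) // 2}[shape]
    if sharing == "free":
        cov *= k
    return (k - 1) + k * d + cov


def _mstep_covariances(X, resp, means, family) -> np.ndarray:
    n, d = X.shape
    k = means.shape[0]
    nk = resp.sum(axis=0)
    shape, sharing = family.split("-")
    covs = np.empty((k, d, d))
    scatters = np.empty((k, d, d))
    for c in range(k):
        diff = X - means[c]
        scatters[c] = (resp[:, c, None] * diff).T @ diff
    if sharing == "shared":
        pooled = scatters.sum(axis=0) / n
        per = np.repeat(pooled[None, :, :], k, axis=0)
    else:
        per = scatters / nk[:, None, None]
    for c in range(k):
        s = per[c]
        if shape == "spherical":
            s = np.eye(d) * max(np.trace(s) / d, _VAR_FLOOR)
        elif shape == "diagonal":
            s = np.diag(np.maximum(np.diag(s), _VAR_FLOOR))
        else:
            eig = np.linalg.eigvalsh(s).min()
            if eig < _VAR_FLOOR:
                logger.debug("regularizing covariance (min eig %.3g)", eig)
                s = s + (_VAR_FLOOR - min(eig, 0.0) + 1e-12) * np.eye(d)
        covs[c] = 0.5 * (s + s.T)
    return covs


def fit_gmm(coords: np.ndarray, k: int, family: str = "full-free",
            seed: int = 0, tol: float = 1e-8, max_iter: int = 500) -> GMMModel:
    """EM fit with k-means seeded initialization.

    The observed-data log-likelihood is recorded per iteration and is
    non-decreasing; convergence when the per-sample change drops below
    ``tol``.  Degenerate covariances are floored at 1e-6 on the variances
    and logged.
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    n, d = X.shape
    if k < 1:
        raise InputError("k must be >= 1")
    if k > n:
        raise InputError(f"k={k} exceeds sample count {n}")
    if family not in COVARIANCE_FAMILIES:
        raise InputError(f"unknown covariance family {family!r}")

    if k == 1:
        resp = np.ones((n, 1))
        means = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        resp = np.zeros((n, k))
        resp[np.arange(n), km.labels_] = 1.0
        means = km.cluster_centers_

    weights = resp.sum(axis=0) / n
    covs = _mstep_covariances(X, resp, means, family)
    model = GMMModel(k=k, family=family, weights=weights, means=means,
                     covariances=covs, log_likelihood=-np.inf,
                     n_params=_count_params(k, d, family), loglik_history=[])

    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logw = np.log(np.maximum(model.weights, 1e-300))
        joint = model.component_logpdf(X) + logw
        ll = float(logsumexp(joint, axis=1).sum())
        model.loglik_history.append(ll)
        resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise DegenerateFitError("a mixture component lost all responsibility")
        model.weights = nk / n
        model.means = (resp.T @ X) / nk[:, None]
        model.covariances = _mstep_covariances(X, resp, model.means, family)
        if np.isfinite(prev) and (ll - prev) / n < tol:
            converged = True
            prev = ll
            break
        prev = ll
    model.log_likelihood = float(model.score(X))
    model.loglik_history.append(model.log_likelihood)
    model.converged = converged
    return model


def bic(model: GMMModel, n_samples: int) -> float:
    """``n_params * ln(n) - 2 * log_likelihood`` — lower is better."""
    return model.n_params * np.log(n_samples) - 2.0 * model.log_likelihood


def select_gmm(coords: np.ndarray, k_range: Sequence[int],
               families: Sequence[str] = COVARIANCE_FAMILIES,
               seed: int = 0) -> GMMModel:
    """Fit every (k, family) pair and return the minimum-BIC model.

    Ties are broken by smaller k, then by family order as listed in
    ``COVARIANCE_FAMILIES``.
    """
    k_range = sorted(k_range)
    if not k_range:
        raise InputError("k_range is empty")
    n = np.atleast_2d(coords).shape[0]
    best: Tuple[float, GMMModel] = (np.inf, None)
    for k in k_range:
        for family in families:
            try:
                model = fit_gmm(coords, k=k, family=family, seed=seed)
            except (DegenerateFitError, np.linalg.LinAlgError) as exc:
                logger.warning("fit k=%d family=%s failed: %s", k, family, exc)
                continue
            score = bic(model, n)
            if score < best[0]:
                best = (score, model)
    if best[1] is None:
        raise DegenerateFitError("every candidate mixture fit was degenerate")
    return best[1]
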