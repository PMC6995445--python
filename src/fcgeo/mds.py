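"""Non-metric multidimensional scaling of FC distance matrices.

High-dimensional distance structure (e.g. a 2N x 2N matrix of geodesic
distances between train and test FC matrices) is embedded into a few
Euclidean dimensions so that inter-point distances preserve, as well as
possible, the *rank order* of the input dissimilarities.  The objective is
the (squared) Kruskal stress

    S = sum_{i<j} (dhat_ij - ||x_i - x_j||)^2 / sum_{i<j} dhat_ij^2,

where the disparities ``dhat`` are a monotone transform of the input
dissimilarities fitted by isotonic regression (ties averaged).  The
optimizer alternates a SMACOF majorization update of the configuration with
the isotonic disparity update; disparities keep the norm of the input
dissimilarities, which makes each half-step provably non-increasing in S.

Depending only on ranks makes the embedding invariant to any monotone
rescaling of the input distances — appropriate here because geodesic and
Pearson measures have arbitrary, non-comparable units.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

logger = logging.getLogger("fcgeo")

__all__ = [
    "DissimilarityMatrix",
    "Embedding",
    "stress",
    "nonmetric_mds",
]


@dataclass
class DissimilarityMatrix:
    """A symmetric, zero-diagonal, non-negative K x K dissimilarity matrix."""

    values: np.ndarray
    item_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.item_ids)
        if self.values.shape != (k, k):
            raise ValueError("dissimilarity matrix shape must match item_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dissimilarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, rtol=1e-10, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if self.values.min() < 0:
            raise ValueError("dissimilarity entries must be non-negative")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Embedding:
    """A low-dimensional configuration with its stress and convergence info."""

    points: np.ndarray
    stress: float
    n_iterations_run: int
    converged: bool
    item_ids: list[str]
    stress_trace: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding points must be finite")
        if self.stress < 0:
            raise ValueError("stress must be >= 0")


def stress(
    D: DissimilarityMatrix,
    X: np.ndarray,
    disparities: np.ndarray | None = None,
    normalization: str = "disparity",
) -> float:
    """Normalized squared stress of a configuration.

    Without disparities: ``sum_{i<j} (d_ij - ||x_i - x_j||)^2 / sum d_ij^2``
    (plain Euclidean norm between embedded points, not its square).  With
    disparities, they replace ``d`` in the numerator and — under the default
    ``"disparity"`` normalization — in the denominator too; ``"raw"`` keeps
    the input dissimilarities in the denominator.
    """
    d = D.condensed()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != D.n_items:
        raise ValueError("configuration has wrong number of points")
    emb = pdist(X)
    target = d if disparities is None else np.asarray(disparities, dtype=float)
    if target.ndim == 2:
        target = squareform(target, checks=False)
    if target.shape != emb.shape:
        raise ValueError("disparities have wrong shape")
    denom_vec = d if (disparities is None or normalization == "raw") else target
    denom = float(np.sum(denom_vec**2))
    if denom == 0:
        raise ValueError("all dissimilarities are zero; stress undefined")
    return float(np.sum((target - emb) ** 2) / denom)


def _fit_disparities(d: np.ndarray, emb: np.ndarray, norm_d: float) -> np.ndarray:
    """Ties-averaged isotonic fit of embedded distances onto the order of d.

    Equal input dissimilarities are pooled into one group (Kruskal's
    secondary approach), which also makes the fit invariant to item
    permutations.  The fitted disparities are rescaled to the norm of d;
    over the monotone cone intersected with that sphere this is the exact
    least-squares minimizer, so the stress update never increases S.
    """
    uvals, inv = np.unique(d, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    means = np.bincount(inv, weights=emb) / counts
    fit = isotonic_regression(means, sample_weight=counts, increasing=True)
    dhat = fit[inv]
    norm_hat = float(np.linalg.norm(dhat))
    if norm_hat == 0:
        # collapsed configuration: fall back to the raw dissimilarities
        return d.copy()
    return dhat * (norm_d / norm_hat)


def _guttman_step(X: np.ndarray, dhat: np.ndarray, emb: np.ndarray) -> np.ndarray:
    """SMACOF majorization update of the configuration for fixed disparities."""
    k = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(emb > 0, dhat / emb, 0.0)
    w = squareform(ratio, checks=False)
    bmat = -w
    np.fill_diagonal(bmat, w.sum(axis=1))
    return bmat @ X / k


def _classical_init(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson scaling of the squared dissimilarities, sign-fixed per column."""
    k = D.shape[0]
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (D**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[order], 0.0, None)
    X = v[:, order] * np.sqrt(lam)
    for c in range(X.shape[1]):  # deterministic sign under item permutation
        col = X[:, c]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            X[:, c] = -col
    return X


def _random_init(item_ids: list[str], dim: int, seed: int, restart: int) -> np.ndarray:
    """Per-item coordinate streams keyed on the item id, so permuting the
    input permutes the initial configuration identically."""
    X = np.empty((len(item_ids), dim))
    for i, pid in enumerate(item_ids):
        key = zlib.crc32(str(pid).encode())
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(restart, key)))
        X[i] = rng.standard_normal(dim)
    return X


def _smacof(
    d: np.ndarray, X: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    norm_d = float(np.linalg.norm(d))
    emb = pdist(X)
    dhat = _fit_disparities(d, emb, norm_d)
    denom = norm_d**2
    trace = [float(np.sum((dhat - emb) ** 2) / denom)]
    converged = False
    for _ in range(max_iter):
        X = _guttman_step(X, dhat, emb)
        emb = pdist(X)
        dhat = _fit_disparities(d, emb, norm_d)
        s = float(np.sum((dhat - emb) ** 2) / denom)
        trace.append(s)
        if trace[-2] - s <= tol * max(trace[-2], np.finfo(float).tiny):
            converged = True
            break
    return X, trace[-1], np.array(trace), converged


def nonmetric_mds(
    D: DissimilarityMatrix,
    dim: int = 3,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 4,
    tol: float = 1e-8,
) -> Embedding:
    """Embed a dissimilarity matrix into ``dim`` Euclidean dimensions.

    Alternates SMACOF majorization of the configuration with isotonic
    disparity updates until the relative stress change falls below ``tol``
    or ``max_iter`` iterations are reached.  The first start is a classical
    (Torgerson) scaling of the input — exact when the dissimilarities are
    already Euclidean — and the remaining ``n_restarts - 1`` starts are
    random; the lowest-stress solution is returned.
    """
    k = D.n_items
    if k < dim + 1:
        raise ValueError(f"need at least dim + 1 = {dim + 1} items, got {k}")
    d = D.condensed()
    if np.all(d == 0):
        raise ValueError("all dissimilarities are zero; embedding undefined")
    offdiag = d[d > 0]
    if offdiag.size and np.all(offdiag == offdiag[0]) and np.all(d > 0):
        logger.warning(
            "degenerate input: all off-diagonal dissimilarities equal; "
            "returning best-effort configuration"
        )
    best: tuple[np.ndarray, float, np.ndarray, bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            X0 = _classical_init(D.values, dim)
        else:
            X0 = _random_init(D.item_ids, dim, seed, restart)
        result = _smacof(d, X0, max_iter=max_iter, tol=tol)
        if best is None or result[1] < best[1]:
            best = result
    X, s, trace, converged = best
    return Embedding(
        points=X - X.mean(axis=0),
        stress=s,
        n_iterations_run=len(trace) - 1,
        converged=converged,
        item_ids=list(D.item_ids),
        stress_trace=trace,
    )
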