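"""Functional connectivity matrices on the positive-semidefinite cone.

Sample correlation matrices of regional brain-activity time series are
symmetric positive-semidefinite (PSD): they live on the PSD cone, a
non-Euclidean manifold.  This module builds correlation matrices from
ROI x time data and compares them with two proximity measures:

* the affine-invariant geodesic distance
  ``d_G(Q1, Q2) = sqrt(sum_i log^2(lambda_i))`` where ``lambda_i`` are the
  eigenvalues of ``Q1^{-1/2} Q2 Q1^{-1/2}`` — a true metric on the cone; and
* the Pearson dissimilarity ``d_P = (1 - corr(q1, q2)) / 2`` between the
  column-stacked matrices — bounded in [0, 1] but not a metric.

Rank-deficient sample correlations (fewer frames than ROIs) are handled by
adding a multiple of the identity to every matrix in a comparison set, so
one consistent distance function applies across all pairs of an experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger("fcgeo")

Measure = Literal["geodesic", "pearson"]

__all__ = [
    "ROITimeSeries",
    "FCMatrix",
    "FCDatabase",
    "DistanceMatrix",
    "NotPositiveDefiniteError",
    "correlation_from_timeseries",
    "regularize_database",
    "geodesic_distance",
    "pearson_dissimilarity",
    "pairwise_distances",
]


class NotPositiveDefiniteError(ValueError):
    """Raised when a matrix required to be strictly positive definite is not."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ROITimeSeries:
    """One run of ROI-level activity: a ``T x R`` matrix plus metadata.

    Rows are frames (one per TR), columns are regions of interest.
    """

    data: np.ndarray
    participant_id: str
    condition: str = "rest"
    run: int = 1
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series data must be a 2-D (frames x ROIs) array")
        t, r = self.data.shape
        if t < 2 or r < 2:
            raise ValueError(f"need at least 2 frames and 2 ROIs, got shape {t}x{r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.run < 1:
            raise ValueError("run must be >= 1")
        if self.tr_seconds is not None and self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ROITimeSeries":
        """New series with the same metadata but different frames/ROIs."""
        return ROITimeSeries(
            data=np.array(data, dtype=float),
            participant_id=self.participant_id,
            condition=self.condition,
            run=self.run,
            tr_seconds=self.tr_seconds,
        )


@dataclass
class FCMatrix:
    """An ``R x R`` symmetric PSD functional connectivity matrix."""

    values: np.ndarray
    participant_id: str = ""
    condition: str = "rest"
    run: int = 1
    regularization_tau: float = 0.0
    validate: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.regularization_tau < 0:
            raise ValueError("regularization_tau must be >= 0")
        if self.validate:
            v = self.values
            scale = max(np.abs(v).max(), 1.0)
            if not np.allclose(v, v.T, rtol=1e-12, atol=1e-12 * scale):
                raise ValueError("FC matrix is not symmetric")
            if not np.all(np.isfinite(v)):
                raise ValueError("FC matrix contains non-finite values")
            wmin = float(np.linalg.eigvalsh(v)[0])
            if wmin < -1e-8 * scale:
                raise ValueError(
                    f"FC matrix is not positive semidefinite (min eigenvalue {wmin:.3e})"
                )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def regularized(self, tau: float) -> "FCMatrix":
        """Return a copy with ``tau * I`` added (eigenvalues shift by ``tau``)."""
        out = replace(self, values=self.values + tau * np.eye(self.n_rois))
        out.regularization_tau = self.regularization_tau + tau
        return out


@dataclass
class FCDatabase:
    """An ordered, labeled collection of same-dimension FC matrices.

    One database is the train (or test) side of an identification
    experiment: one matrix per participant, all from the same condition
    and run.
    """

    matrices: list[FCMatrix]
    participant_ids: list[str] = field(default_factory=list)
    condition: str = "rest"
    run: int = 1

    def __post_init__(self) -> None:
        if not self.participant_ids:
            self.participant_ids = [m.participant_id for m in self.matrices]
        if len(self.matrices) != len(self.participant_ids):
            raise ValueError("matrices and participant_ids must have equal length")
        if len(self.matrices) == 0:
            raise ValueError("FCDatabase must contain at least one matrix")
        dims = {m.n_rois for m in self.matrices}
        if len(dims) != 1:
            raise ValueError(f"all FC matrices must share one dimension, got {sorted(dims)}")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_rois(self) -> int:
        return self.matrices[0].n_rois

    def stacked(self) -> np.ndarray:
        """All matrices as one ``(N, R, R)`` array."""
        return np.stack([m.values for m in self.matrices])

    def min_eigenvalue(self) -> float:
        return float(min(np.linalg.eigvalsh(self.stacked())[:, 0]))

    @classmethod
    def from_timeseries(
        cls, series: Sequence[ROITimeSeries], condition: str | None = None, run: int | None = None
    ) -> "FCDatabase":
        mats = [correlation_from_timeseries(ts) for ts in series]
        return cls(
            matrices=mats,
            participant_ids=[ts.participant_id for ts in series],
            condition=condition if condition is not None else series[0].condition,
            run=run if run is not None else series[0].run,
        )


@dataclass
class DistanceMatrix:
    """Pairwise distances between a test and a train database.

    Rows index test items, columns train items; ``values[i, j]`` is the
    chosen measure between test matrix ``i`` and train matrix ``j``.
    """

    values: np.ndarray
    measure: Measure
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("distance matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("distance matrix shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if self.values.min() < 0:
            raise ValueError("distance matrix contains negative entries")
        if self.measure == "pearson" and self.values.max() > 1 + 1e-12:
            raise ValueError("Pearson dissimilarity entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def transposed(self) -> "DistanceMatrix":
        """The reversed-direction matrix (valid because both measures are symmetric)."""
        return DistanceMatrix(
            values=self.values.T.copy(),
            measure=self.measure,
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def correlation_from_timeseries(ts: ROITimeSeries) -> FCMatrix:
    """Pearson correlation matrix of the ROI columns of a run.

    Each column is mean-centered and scaled to unit variance with the same
    1/T denominator for variance and covariance, so the diagonal is exactly
    one.  The result is PSD by construction (it is a Gram matrix of the
    standardized columns).

    Raises
    ------
    ValueError
        If any ROI column has zero variance (the column index is named).
    """
    x = ts.data
    sd = x.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"ROI column {int(zero[0])} has zero variance; cannot correlate")
    q = np.corrcoef(x, rowvar=False)
    q = (q + q.T) / 2.0
    np.fill_diagonal(q, 1.0)
    return FCMatrix(
        values=q,
        participant_id=ts.participant_id,
        condition=ts.condition,
        run=ts.run,
        regularization_tau=0.0,
    )


def _resolve_eig_tol(eig_tol: float | None, max_eig: float) -> float:
    # default: 1e-10 relative to the largest eigenvalue in play
    return 1e-10 * max_eig if eig_tol is None else float(eig_tol)


def regularize_database(
    dbs: Sequence[FCDatabase], tau: float = 1.0, eig_tol: float | None = None
) -> list[FCDatabase]:
    """Add ``tau * I`` to every matrix if any matrix is near-singular.

    The identity perturbation is applied to the *entire* comparison set
    whenever any member's minimum eigenvalue falls below ``eig_tol``, so the
    geodesic distance is one consistent function across all pairs of an
    experiment.  If all matrices are safely positive definite the inputs are
    returned unchanged.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    stacks = [db.stacked() for db in dbs]
    eigs = [np.linalg.eigvalsh(s) for s in stacks]
    max_eig = max(float(e.max()) for e in eigs)
    tol = _resolve_eig_tol(eig_tol, max_eig)
    if tol < 0:
        raise ValueError("eig_tol must be >= 0")
    min_eig = min(float(e[:, 0].min()) for e in eigs)
    if min_eig >= tol:
        return list(dbs)
    logger.info(
        "regularizing %d database(s): min eigenvalue %.3e < %.3e, adding %.3g * I",
        len(dbs), min_eig, tol, tau,
    )
    out = []
    for db in dbs:
        out.append(
            FCDatabase(
                matrices=[m.regularized(tau) for m in db.matrices],
                participant_ids=list(db.participant_ids),
                condition=db.condition,
                run=db.run,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Proximity measures
# ---------------------------------------------------------------------------


def _values(q: FCMatrix | np.ndarray) -> np.ndarray:
    return q.values if isinstance(q, FCMatrix) else np.asarray(q, dtype=float)


def _inv_sqrt(q: np.ndarray, eig_tol: float | None) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    w, v = np.linalg.eigh(q)
    tol = _resolve_eig_tol(eig_tol, float(w[-1]))
    if w[0] <= tol:
        raise NotPositiveDefiniteError(
            f"matrix is not strictly positive definite (min eigenvalue {w[0]:.3e}); "
            "apply regularize_database first"
        )
    return (v * (1.0 / np.sqrt(w))) @ v.T


def geodesic_distance(
    q1: FCMatrix | np.ndarray, q2: FCMatrix | np.ndarray, eig_tol: float | None = None
) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    Computed as ``sqrt(sum_i log^2 lambda_i)`` where ``lambda_i`` are the
    eigenvalues of the (explicitly symmetrized) inner matrix
    ``Q1^{-1/2} Q2 Q1^{-1/2}``.  Both arguments must be strictly positive
    definite; rank-deficient inputs should be regularized first.
    """
    a, b = _values(q1), _values(q2)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    s = _inv_sqrt(a, eig_tol)
    inner = s @ b @ s
    inner = (inner + inner.T) / 2.0
    lam = np.linalg.eigvalsh(inner)
    tol = _resolve_eig_tol(eig_tol, float(lam[-1]))
    if lam[0] <= tol:
        raise NotPositiveDefiniteError(
            f"second matrix is not strictly positive definite (min eigenvalue {lam[0]:.3e}); "
            "apply regularize_database first"
        )
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def _vectorize(q: np.ndarray, include_diagonal: bool) -> np.ndarray:
    if include_diagonal:
        return q.ravel(order="F")  # stack full columns
    iu = np.triu_indices(q.shape[0], k=1)
    return q[iu]


def pearson_dissimilarity(
    q1: FCMatrix | np.ndarray,
    q2: FCMatrix | np.ndarray,
    include_diagonal: bool = True,
) -> float:
    """Pearson dissimilarity ``(1 - corr(q1_vec, q2_vec)) / 2`` in [0, 1].

    Vectorization stacks full columns (diagonal included) by default; the
    off-diagonal-only variant is available behind ``include_diagonal=False``.
    """
    a, b = _values(q1), _values(q2)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    va = _vectorize(a, include_diagonal)
    vb = _vectorize(b, include_diagonal)
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("vectorized matrix is constant (zero variance); dissimilarity undefined")
    r = float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
    return (1.0 - r) / 2.0


# ---------------------------------------------------------------------------
# Pairwise distance matrices
# ---------------------------------------------------------------------------

_CHUNK_ROWS = 64  # test rows per batched geodesic block; caps peak memory


def _pairwise_geodesic(train: np.ndarray, test: np.ndarray, eig_tol: float | None) -> np.ndarray:
    """Batched geodesic distances: stacked eigendecompositions per chunk."""
    wtr = np.linalg.eigvalsh(train)
    wte, vte = np.linalg.eigh(test)
    max_eig = max(float(wtr.max()), float(wte.max()))
    tol = _resolve_eig_tol(eig_tol, max_eig)
    for name, w in (("train", wtr), ("test", wte)):
        if w[:, 0].min() <= tol:
            bad = int(np.argmin(w[:, 0]))
            raise NotPositiveDefiniteError(
                f"{name} matrix {bad} is not strictly positive definite "
                f"(min eigenvalue {w[bad, 0]:.3e}); apply regularize_database first"
            )
    # S_i = V diag(w^-1/2) V' per test matrix
    s = vte * (1.0 / np.sqrt(wte))[:, None, :]
    s = s @ vte.transpose(0, 2, 1)
    n_te, n_tr = test.shape[0], train.shape[0]
    out = np.empty((n_te, n_tr))
    for lo in range(0, n_te, _CHUNK_ROWS):
        hi = min(lo + _CHUNK_ROWS, n_te)
        blk = s[lo:hi, None] @ train[None, :] @ s[lo:hi, None]  # (chunk, n_tr, R, R)
        blk = (blk + blk.transpose(0, 1, 3, 2)) / 2.0
        lam = np.linalg.eigvalsh(blk)
        if lam.min() <= 0:
            i, j = np.unravel_index(int(np.argmin(lam[..., 0])), lam[..., 0].shape)
            raise NotPositiveDefiniteError(
                f"inner matrix for test row {lo + i}, train column {j} is not positive "
                "definite; apply regularize_database first"
            )
        out[lo:hi] = np.sqrt(np.sum(np.log(lam) ** 2, axis=-1))
    return out


def _pairwise_pearson(train: np.ndarray, test: np.ndarray, include_diagonal: bool) -> np.ndarray:
    def vecs(stack: np.ndarray) -> np.ndarray:
        n, r, _ = stack.shape
        if include_diagonal:
            v = stack.reshape(n, r * r)
        else:
            iu = np.triu_indices(r, k=1)
            v = stack[:, iu[0], iu[1]]
        v = v - v.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"matrix {bad} vectorizes to a constant; dissimilarity undefined")
        return v / norms[:, None]

    corr = vecs(test) @ vecs(train).T
    return (1.0 - np.clip(corr, -1.0, 1.0)) / 2.0


def pairwise_distances(
    train: FCDatabase,
    test: FCDatabase,
    measure: Measure = "geodesic",
    eig_tol: float | None = None,
    include_diagonal: bool = True,
) -> DistanceMatrix:
    """All test-to-train distances under one measure, computed once.

    The resulting matrix is the single input to identification and to the
    bootstrap (which only re-indexes it and never recomputes distances).
    When ``test is train`` the geodesic matrix is made exactly symmetric
    with a zero diagonal.
    """
    if train.n_rois != test.n_rois:
        raise ValueError(f"dimension mismatch: train R={train.n_rois}, test R={test.n_rois}")
    tr, te = train.stacked(), test.stacked()
    if measure == "geodesic":
        vals = _pairwise_geodesic(tr, te, eig_tol)
        if test is train:
            vals = (vals + vals.T) / 2.0
            np.fill_diagonal(vals, 0.0)
    elif measure == "pearson":
        vals = _pairwise_pearson(tr, te, include_diagonal)
        if test is train:
            vals = (vals + vals.T) / 2.0
            np.fill_diagonal(vals, 0.0)
    else:
        raise ValueError(f"unknown measure {measure!r}; expected 'geodesic' or 'pearson'")
    return DistanceMatrix(
        values=vals,
        measure=measure,
        row_ids=list(test.participant_ids),
        col_ids=list(train.participant_ids),
    )
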