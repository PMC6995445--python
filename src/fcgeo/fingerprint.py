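"""Participant identification ("fingerprinting") by nearest neighbor.

An unknown test FC matrix is labeled with the identity of the closest
matrix in a training database (1-NN).  Accuracy is the fraction of test
participants labeled correctly; because the choice of which run serves as
the database is arbitrary, the roles of the two runs are swapped and the
two accuracies averaged.  Cross-condition transfer asks the same question
with train and test drawn from different scanning conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    FCDatabase,
    Measure,
    pairwise_distances,
    regularize_database,
)

logger = logging.getLogger("fcgeo")

__all__ = [
    "FCDatabase",
    "IdentificationResult",
    "TransferResult",
    "identify_1nn",
    "accuracy_from_distance",
    "symmetric_accuracy",
    "transfer_matrix",
]


@dataclass
class IdentificationResult:
    """Symmetric 1-NN identification outcome for one condition pair."""

    predicted_ids_dir1: list[str]
    predicted_ids_dir2: list[str]
    accuracy_dir1: float
    accuracy_dir2: float
    measure: Measure
    participant_ids: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return (self.accuracy_dir1 + self.accuracy_dir2) / 2.0

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "accuracy_dir1": self.accuracy_dir1,
            "accuracy_dir2": self.accuracy_dir2,
            "mean_accuracy": self.mean_accuracy,
            "participant_ids": self.participant_ids,
            "predicted_ids_dir1": self.predicted_ids_dir1,
            "predicted_ids_dir2": self.predicted_ids_dir2,
        }


def identify_1nn(dist: DistanceMatrix) -> list[str]:
    """Label every test row with the train identifier at its argmin.

    Ties are broken toward the lowest column index (with a warning) so runs
    are reproducible.
    """
    vals = dist.values
    if vals.size == 0:
        raise ValueError("empty distance matrix")
    mins = vals.min(axis=1, keepdims=True)
    n_ties = int(((vals == mins).sum(axis=1) > 1).sum())
    if n_ties:
        logger.warning("%d test row(s) had tied nearest neighbors; lowest index kept", n_ties)
    idx = vals.argmin(axis=1)
    return [dist.col_ids[j] for j in idx]


def accuracy_from_distance(dist: DistanceMatrix) -> float:
    """Fraction of test rows whose nearest train column is their own identity."""
    preds = identify_1nn(dist)
    correct = sum(p == t for p, t in zip(preds, dist.row_ids))
    return correct / len(preds)


def _align(db: FCDatabase, order: list[str]) -> FCDatabase:
    if db.participant_ids == order:
        return db
    pos = {pid: i for i, pid in enumerate(db.participant_ids)}
    missing = [pid for pid in order if pid not in pos]
    if missing or len(db) != len(order):
        raise ValueError(f"participant sets differ (missing: {missing[:5]})")
    return FCDatabase(
        matrices=[db.matrices[pos[pid]] for pid in order],
        participant_ids=list(order),
        condition=db.condition,
        run=db.run,
    )


def symmetric_accuracy(
    run1: FCDatabase,
    run2: FCDatabase,
    measure: Measure = "geodesic",
    tau: float = 1.0,
    eig_tol: float | None = None,
    auto_regularize: bool = True,
) -> IdentificationResult:
    """Identification accuracy with each run serving once as the database.

    Direction 1 trains on run 1 and tests on run 2; direction 2 swaps the
    roles.  Both measures are symmetric in their arguments, so the second
    direction reuses the transposed distance matrix.  For the geodesic
    measure, near-singular databases are identity-regularized as one set.
    """
    order = list(run1.participant_ids)
    run2 = _align(run2, order)
    if measure == "geodesic" and auto_regularize:
        run1, run2 = regularize_database([run1, run2], tau=tau, eig_tol=eig_tol)
    d_fwd = pairwise_distances(train=run1, test=run2, measure=measure, eig_tol=eig_tol)
    d_rev = d_fwd.transposed
    preds1 = identify_1nn(d_fwd)
    preds2 = identify_1nn(d_rev)
    acc1 = sum(p == t for p, t in zip(preds1, order)) / len(order)
    acc2 = sum(p == t for p, t in zip(preds2, order)) / len(order)
    return IdentificationResult(
        predicted_ids_dir1=preds1,
        predicted_ids_dir2=preds2,
        accuracy_dir1=acc1,
        accuracy_dir2=acc2,
        measure=measure,
        participant_ids=order,
    )


@dataclass
class TransferResult:
    """Condition-by-condition identification accuracy with off-diagonal means.

    ``table.loc[test_cond, train_cond]`` is the symmetric accuracy when
    ``train_cond`` provides the database and ``test_cond`` the queries.
    Row/column means exclude the diagonal (within-condition) entry.
    """

    table: pd.DataFrame
    measure: Measure

    @property
    def row_means(self) -> pd.Series:
        return self._offdiag_mean(axis=1)

    @property
    def col_means(self) -> pd.Series:
        return self._offdiag_mean(axis=0)

    def _offdiag_mean(self, axis: int) -> pd.Series:
        vals = self.table.values.astype(float).copy()
        np.fill_diagonal(vals, np.nan)
        if vals.shape[0] < 2:
            data = [np.nan] * vals.shape[0]
        else:
            data = np.nanmean(vals, axis=axis)
        idx = self.table.index if axis == 1 else self.table.columns
        return pd.Series(data, index=idx)


def transfer_matrix(
    dbs: dict[str, tuple[FCDatabase, FCDatabase]],
    measure: Measure = "geodesic",
    tau: float = 1.0,
    eig_tol: float | None = None,
) -> TransferResult:
    """Cross-condition identification accuracy table.

    ``dbs`` maps condition name to its (run 1, run 2) databases; all
    conditions must share the participant set.  Entry ``(test, train)``
    averages the two run directions: train-run1 vs test-run2 and train-run2
    vs test-run1.  For the geodesic measure all databases are regularized
    together so one distance function applies across the whole table.
    """
    conds = list(dbs)
    if not conds:
        raise ValueError("no conditions given")
    order = list(dbs[conds[0]][0].participant_ids)
    aligned: dict[str, tuple[FCDatabase, FCDatabase]] = {}
    for c in conds:
        r1, r2 = dbs[c]
        aligned[c] = (_align(r1, order), _align(r2, order))
    if measure == "geodesic":
        flat = [db for pair in aligned.values() for db in pair]
        flat = regularize_database(flat, tau=tau, eig_tol=eig_tol)
        aligned = {c: (flat[2 * i], flat[2 * i + 1]) for i, c in enumerate(conds)}
    table = pd.DataFrame(index=conds, columns=conds, dtype=float)
    for test_c in conds:
        for train_c in conds:
            tr1, tr2 = aligned[train_c]
            te1, te2 = aligned[test_c]
            d1 = pairwise_distances(train=tr1, test=te2, measure=measure, eig_tol=eig_tol)
            d2 = pairwise_distances(train=tr2, test=te1, measure=measure, eig_tol=eig_tol)
            acc = (accuracy_from_distance(d1) + accuracy_from_distance(d2)) / 2.0
            table.loc[test_c, train_c] = acc
    table.index.name = "test_condition"
    table.columns.name = "train_condition"
    return TransferResult(table=table, measure=measure)
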