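"""Two-level bootstrap inference for identification accuracy.

Identification accuracy is a property of the *group*: whether participant B
is mislabeled can depend on whether a look-alike participant A is in the
database.  The group is therefore the unit of inference, and variability is
assessed by bootstrap resampling participants with replacement.  One mean
difference score averages the geodesic-minus-Pearson accuracy difference
over M resamples; repeating B times yields the distribution of mean
differences, which is Fisher-z transformed and tested against zero with a
one-sample two-tailed t-test.

All resampling happens on precomputed distance matrices: the inner loops
only index, so their cost is independent of the FC matrix dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DistanceMatrix,
    FCDatabase,
    Measure,
    ROITimeSeries,
    pairwise_distances,
    regularize_database,
)

logger = logging.getLogger("fcgeo")

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "resample_accuracy",
    "bootstrap_mean_differences",
    "bootstrap_accuracies",
    "fisher_z_ttest",
    "segment_length_curve",
    "bonferroni_reference_alpha",
]


@dataclass
class BootstrapConfig:
    """Two-level bootstrap sizes: M resamples per mean, B means."""

    M: int = 1000
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.B < 1:
            raise ValueError("M and B must be >= 1")


@dataclass
class BootstrapResult:
    """B mean difference scores and the derived p-value."""

    delta_bars: np.ndarray
    p_value: float
    mean_of_means: float

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "mean_of_means": self.mean_of_means,
            "B": int(len(self.delta_bars)),
            "delta_bars": [float(x) for x in self.delta_bars],
        }


def _check_pair(pair: Sequence[DistanceMatrix], name: str) -> tuple[np.ndarray, np.ndarray]:
    if len(pair) != 2:
        raise ValueError(f"{name} must be a (forward, reverse) pair of distance matrices")
    fwd, rev = pair
    n = fwd.values.shape[0]
    for d in (fwd, rev):
        if d.values.shape != (n, n):
            raise ValueError(f"{name}: distance matrices must be square and same size")
        if d.row_ids != d.col_ids:
            raise ValueError(f"{name}: rows and columns must index the same participants")
    if fwd.row_ids != rev.row_ids:
        raise ValueError(f"{name}: the two directions must share participant order")
    return fwd.values, rev.values


def resample_accuracy(values: np.ndarray, idx: np.ndarray) -> float:
    """1-NN accuracy on a bootstrap resample of a precomputed distance matrix.

    ``idx`` is a multiset of original participant indices.  Every copy of a
    duplicated participant enters as a test item, and the train database is
    restricted to the same multiset of columns; a prediction is correct when
    the nearest column belongs to the same original participant (any copy).
    Column ties resolve to the lowest index.
    """
    sub = values[np.ix_(idx, idx)]
    preds = idx[np.argmin(sub, axis=1)]
    return float(np.mean(preds == idx))


def _symmetric_resample_accuracy(fwd: np.ndarray, rev: np.ndarray, idx: np.ndarray) -> float:
    return (resample_accuracy(fwd, idx) + resample_accuracy(rev, idx)) / 2.0


def _rng_for_mean(seed: int, b: int) -> np.random.Generator:
    # one stream per mean; the (M, N) draw is C-ordered so the first M
    # resamples are a prefix of any larger M, and distinct b never share draws
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))


def bootstrap_mean_differences(
    dist_g: Sequence[DistanceMatrix],
    dist_p: Sequence[DistanceMatrix],
    cfg: BootstrapConfig,
) -> BootstrapResult:
    """Distribution of mean accuracy differences (geodesic minus Pearson).

    ``dist_g`` and ``dist_p`` each hold the two run-direction distance
    matrices for one measure, all over the same participants.  For each of
    B repetitions, M groups of N participants are redrawn with replacement;
    each group's symmetric accuracy difference is computed purely by
    re-indexing the precomputed matrices, and the M differences are
    averaged into one mean difference score.
    """
    g_fwd, g_rev = _check_pair(dist_g, "dist_g")
    p_fwd, p_rev = _check_pair(dist_p, "dist_p")
    if g_fwd.shape != p_fwd.shape:
        raise ValueError("geodesic and Pearson matrices must have identical size")
    if dist_g[0].row_ids != dist_p[0].row_ids:
        raise ValueError("geodesic and Pearson matrices must share participant order")
    n = g_fwd.shape[0]
    delta_bars = np.empty(cfg.B)
    for b in range(cfg.B):
        rng = _rng_for_mean(cfg.seed, b)
        draws = rng.integers(0, n, size=(cfg.M, n))
        deltas = np.empty(cfg.M)
        for m in range(cfg.M):
            idx = draws[m]
            f_g = _symmetric_resample_accuracy(g_fwd, g_rev, idx)
            f_p = _symmetric_resample_accuracy(p_fwd, p_rev, idx)
            deltas[m] = f_g - f_p
        delta_bars[b] = deltas.mean()
    p = fisher_z_ttest(delta_bars)
    return BootstrapResult(
        delta_bars=delta_bars, p_value=p, mean_of_means=float(delta_bars.mean())
    )


def bootstrap_accuracies(
    dist_pair: Sequence[DistanceMatrix], n_iters: int, seed: int = 0
) -> np.ndarray:
    """Single-measure analog: symmetric accuracy on ``n_iters`` resamples."""
    fwd, rev = _check_pair(dist_pair, "dist_pair")
    n = fwd.shape[0]
    rng = _rng_for_mean(seed, 0)
    draws = rng.integers(0, n, size=(n_iters, n))
    return np.array(
        [_symmetric_resample_accuracy(fwd, rev, draws[m]) for m in range(n_iters)]
    )


_CLIP = 1.0 - 1e-12


def fisher_z_ttest(values: Sequence[float], transform: bool = True) -> float:
    """Two-tailed one-sample t-test of mean zero after a Fisher-z transform.

    Accuracy differences are bounded scores, so they are arctanh-transformed
    (after clipping at +/-(1 - 1e-12)) to make their distribution closer to
    normal before the t-test.  ``transform=False`` skips the arctanh, for
    callers that transformed the accuracies before differencing.

    Degenerate zero-variance inputs follow a logged convention: all values
    exactly zero gives p = 1, all values equal and nonzero gives p = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("need a 1-D sequence of values")
    if transform:
        v = np.arctanh(np.clip(v, -_CLIP, _CLIP))
    if np.all(v == v[0]):
        if v[0] == 0.0:
            logger.warning("all values are exactly 0; p = 1 by convention")
            return 1.0
        logger.warning("all values identical and nonzero; p = 0 by convention")
        return 0.0
    res = stats.ttest_1samp(v, popmean=0.0, alternative="two-sided")
    return float(res.pvalue)


def bonferroni_reference_alpha(n_comparisons: int, alpha: float = 0.05) -> float:
    """Reference alpha = alpha / k, reported alongside uncorrected p-values."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def segment_length_curve(
    run1: Sequence[ROITimeSeries],
    run2: Sequence[ROITimeSeries],
    lengths: Sequence[int],
    n_segments: int = 50,
    boot_iters: int = 1000,
    measure: Measure = "geodesic",
    seed: int = 0,
    tau: float = 1.0,
    eig_tol: float | None = None,
) -> pd.DataFrame:
    """Identification accuracy as a function of segment length.

    For each length, ``n_segments`` random-start windows are drawn per run
    (the same starts applied to every participant, so each segment is a
    coherent group dataset).  Each segment's FC databases feed one pair of
    distance matrices; its score is the mean symmetric accuracy over
    ``boot_iters`` participant resamples (``boot_iters=0`` scores the plain
    symmetric accuracy without resampling).  Returns a table with the mean
    and standard error over segments per length.
    """
    if len(run1) != len(run2):
        raise ValueError("run1 and run2 must have the same number of participants")
    ids = [ts.participant_id for ts in run1]
    if [ts.participant_id for ts in run2] != ids:
        raise ValueError("run1 and run2 must share participant order")
    t_min = min(min(ts.n_frames for ts in run1), min(ts.n_frames for ts in run2))
    if max(lengths) > t_min:
        raise ValueError(f"max length {max(lengths)} exceeds shortest run ({t_min} frames)")
    rows = []
    for li, length in enumerate(lengths):
        n_starts = t_min - length + 1
        n_seg = min(n_segments, n_starts)
        if n_seg < n_segments:
            logger.warning(
                "length %d: only %d distinct starts (requested %d)", length, n_starts, n_segments
            )
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, li)))
        starts1 = rng.choice(n_starts, size=n_seg, replace=False)
        starts2 = rng.choice(n_starts, size=n_seg, replace=False)
        scores = np.empty(n_seg)
        for k in range(n_seg):
            db1 = FCDatabase.from_timeseries(
                [ts.with_data(ts.data[starts1[k] : starts1[k] + length]) for ts in run1]
            )
            db2 = FCDatabase.from_timeseries(
                [ts.with_data(ts.data[starts2[k] : starts2[k] + length]) for ts in run2]
            )
            if measure == "geodesic":
                db1, db2 = regularize_database([db1, db2], tau=tau, eig_tol=eig_tol)
            fwd = pairwise_distances(train=db1, test=db2, measure=measure, eig_tol=eig_tol)
            pair = (fwd, fwd.transposed)
            if boot_iters == 0:
                idx = np.arange(len(ids))
                scores[k] = _symmetric_resample_accuracy(fwd.values, pair[1].values, idx)
            else:
                accs = bootstrap_accuracies(pair, n_iters=boot_iters, seed=seed + 7919 * li + k)
                scores[k] = accs.mean()
        se = scores.std(ddof=1) / np.sqrt(n_seg) if n_seg > 1 else 0.0
        rows.append(
            {
                "length": int(length),
                "mean_accuracy": float(scores.mean()),
                "se": float(se),
                "n_segments": int(n_seg),
            }
        )
    return pd.DataFrame(rows)
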