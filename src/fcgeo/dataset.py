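"""Time-series conditioning and ROI/subnetwork selection.

Task runs interleave stimulus blocks with fixation; fixation behaves like a
mini resting period that leaks participant-specific signal, so only
task-related frames are retained.  To compare conditions of different
durations, runs are trimmed to a common length by keeping the middle
window.  For segment-length experiments, contiguous windows with random,
distinct starting points are drawn.  Subnetwork experiments restrict time
series or FC matrices to named groups of ROIs (principal submatrices keep
the PSD property).

All operations are pure: inputs are never mutated and metadata is carried
through to the outputs.  Frame indexing is 0-based with half-open ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence, overload

import numpy as np

from .core import FCMatrix, ROITimeSeries

logger = logging.getLogger("fcgeo")

__all__ = [
    "Parcellation",
    "BlockSchedule",
    "trim_task_blocks",
    "equate_length",
    "sample_segments",
    "select_subnetworks",
    "yeo7_parcellation",
    "YEO7_SIZES",
]

# Subnetwork sizes of the 7-network grouping of a 300-ROI cortical
# parcellation used throughout the identification experiments.
YEO7_SIZES: dict[str, int] = {
    "visual": 47,
    "somatomotor": 57,
    "dorsal_attention": 34,
    "ventral_attention": 34,
    "limbic": 20,
    "frontoparietal": 40,
    "default": 68,
}


@dataclass
class Parcellation:
    """Mapping from 0-based ROI index to subnetwork name."""

    roi_labels: list[str]
    network_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roi_labels:
            raise ValueError("parcellation must label at least one ROI")
        if not self.network_names:
            seen: dict[str, None] = {}
            for lab in self.roi_labels:
                seen.setdefault(lab, None)
            self.network_names = list(seen)
        missing = set(self.roi_labels) - set(self.network_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from network_names")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def sizes(self) -> dict[str, int]:
        out = {name: 0 for name in self.network_names}
        for lab in self.roi_labels:
            out[lab] += 1
        return out

    def indices(self, networks: Sequence[str]) -> np.ndarray:
        """ROI indices of the union of the named subnetworks, in original order."""
        bad = [n for n in networks if n not in self.network_names]
        if bad:
            raise ValueError(
                f"unknown subnetwork(s) {bad}; valid names: {self.network_names}"
            )
        wanted = set(networks)
        return np.array([i for i, lab in enumerate(self.roi_labels) if lab in wanted], dtype=int)


def yeo7_parcellation() -> Parcellation:
    """The bundled 300-ROI, 7-subnetwork parcellation fixture.

    ROIs are laid out as contiguous blocks per subnetwork in the order of
    ``YEO7_SIZES`` (a synthetic ordering; real atlases interleave networks
    across the cortex, which does not affect any principal-submatrix
    operation).
    """
    labels: list[str] = []
    for name, size in YEO7_SIZES.items():
        labels.extend([name] * size)
    return Parcellation(roi_labels=labels, network_names=list(YEO7_SIZES))


@dataclass
class BlockSchedule:
    """Stimulus block timing for one task run.

    Each block is ``(onset_seconds, offset_seconds, has_cue)``; cued blocks
    start with a ``cue_seconds`` cue whose response must also be discarded.
    """

    blocks: list[tuple[float, float, bool]]
    cue_seconds: float = 3.0
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.cue_seconds < 0:
            raise ValueError("cue_seconds must be >= 0")
        prev_off = -math.inf
        for onset, offset, _ in self.blocks:
            if offset <= onset:
                raise ValueError(f"block ({onset}, {offset}) has non-positive duration")
            if onset < prev_off:
                raise ValueError("blocks must be ordered and non-overlapping")
            prev_off = offset


def trim_task_blocks(
    ts: ROITimeSeries,
    sched: BlockSchedule,
    lag_drop_trs: int = 4,
    lag_keep_trs: int = 4,
    cue_shift_seconds: float = 12.0,
) -> ROITimeSeries:
    """Concatenate the task-related frames of each block, in temporal order.

    Uncued block: frames ``[onset_TR + lag_drop_trs, offset_TR + lag_keep_trs)``
    — the first ``lag_drop_trs`` frames are discarded to let the hemodynamic
    response develop, and ``lag_keep_trs`` post-block frames are kept because
    the response outlasts the stimulus.  Cued block: frames
    ``[ceil((onset + cue_shift_seconds) / tr), offset_TR + round(3 / tr))``.
    Seconds are converted to frames with ``ceil`` for onsets and ``round``
    for the 3-second tail; per-block tails are clipped at the run end.
    """
    tr = sched.tr_seconds
    t = ts.n_frames
    keep: list[np.ndarray] = []
    for onset_s, offset_s, has_cue in sched.blocks:
        onset_tr = math.ceil(onset_s / tr)
        offset_tr = math.ceil(offset_s / tr)
        if offset_tr > t:
            raise ValueError(
                f"block ({onset_s}, {offset_s}) extends past the run ({t} frames at {tr}s TR)"
            )
        if has_cue:
            start = math.ceil((onset_s + cue_shift_seconds) / tr)
            stop = offset_tr + round(3.0 / tr)
        else:
            start = onset_tr + lag_drop_trs
            stop = offset_tr + lag_keep_trs
        stop = min(stop, t)
        if start < stop:
            keep.append(np.arange(start, stop))
    if not keep:
        raise ValueError("no task frames: trimming left an empty series")
    idx = np.concatenate(keep)
    return ts.with_data(ts.data[idx])


def equate_length(ts: ROITimeSeries, target_len: int = 138) -> ROITimeSeries:
    """Keep the centered window of ``target_len`` frames.

    Frames are deleted symmetrically from the beginning and end; when the
    excess is odd the extra frame comes off the end.
    """
    t = ts.n_frames
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if t < target_len:
        raise ValueError(f"run has {t} frames, fewer than target {target_len}")
    left = (t - target_len) // 2
    return ts.with_data(ts.data[left : left + target_len])


def sample_segments(
    ts: ROITimeSeries,
    seg_len: int,
    n_segments: int = 50,
    seed: int | np.random.Generator = 0,
) -> list[ROITimeSeries]:
    """Contiguous windows of ``seg_len`` frames with distinct random starts.

    Start indices are drawn uniformly without replacement from
    ``{0, ..., T - seg_len}``.  If fewer than ``n_segments`` distinct starts
    exist, all of them are returned with a warning rather than an error, so
    short runs remain usable.
    """
    t = ts.n_frames
    if seg_len < 2:
        raise ValueError("seg_len must be >= 2")
    if seg_len > t:
        raise ValueError(f"seg_len {seg_len} exceeds run length {t}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    n_starts = t - seg_len + 1
    n_draw = min(n_segments, n_starts)
    if n_draw < n_segments:
        logger.warning(
            "only %d distinct starts exist for seg_len=%d (requested %d segments)",
            n_starts, seg_len, n_segments,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.choice(n_starts, size=n_draw, replace=False)
    return [ts.with_data(ts.data[s : s + seg_len]) for s in starts]


@overload
def select_subnetworks(
    obj: ROITimeSeries, parc: Parcellation, networks: Sequence[str]
) -> ROITimeSeries: ...
@overload
def select_subnetworks(
    obj: FCMatrix, parc: Parcellation, networks: Sequence[str]
) -> FCMatrix: ...


def select_subnetworks(obj, parc, networks):
    """Restrict a time series or FC matrix to the union of named subnetworks.

    Original ROI order is preserved.  For an FC matrix this is the principal
    submatrix over the selected ROIs — it keeps all within- and
    between-network entries of the selected set, and remains PSD (principal
    submatrices of PSD matrices are PSD).
    """
    idx = parc.indices(networks)
    if isinstance(obj, ROITimeSeries):
        if obj.n_rois != parc.n_rois:
            raise ValueError(f"series has {obj.n_rois} ROIs but parcellation {parc.n_rois}")
        return obj.with_data(obj.data[:, idx])
    if isinstance(obj, FCMatrix):
        if obj.n_rois != parc.n_rois:
            raise ValueError(f"matrix has {obj.n_rois} ROIs but parcellation {parc.n_rois}")
        sub = obj.values[np.ix_(idx, idx)].copy()
        return replace(obj, values=sub)
    raise TypeError(f"expected ROITimeSeries or FCMatrix, got {type(obj).__name__}")
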