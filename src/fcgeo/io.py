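"""Plain-text and binary IO for the pipeline's artifacts.

TSV is the universal tabular interchange (identifier headers throughout);
large matrices can optionally go to ``.npy`` with a JSON metadata sidecar.
File-name convention for time series: ``<participant>_<condition>_run<k>.tsv``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DistanceMatrix, FCDatabase, FCMatrix, ROITimeSeries
from .dataset import BlockSchedule, Parcellation


class DataFormatError(ValueError):
    """A malformed input file (reported with file name and location)."""


# --------------------------------------------------------------------- time series

_TS_NAME = re.compile(r"^(?P<pid>.+)_(?P<cond>[^_]+)_run(?P<run>\d+)\.tsv$")


def timeseries_filename(ts: ROITimeSeries) -> str:
    return f"{ts.participant_id}_{ts.condition}_run{ts.run}.tsv"


def write_timeseries_tsv(ts: ROITimeSeries, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / timeseries_filename(ts)
    df = pd.DataFrame(ts.data, columns=[f"roi_{i}" for i in range(ts.n_rois)])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_timeseries_tsv(path: str | Path, tr_seconds: float | None = None) -> ROITimeSeries:
    path = Path(path)
    m = _TS_NAME.match(path.name)
    if not m:
        raise DataFormatError(
            f"{path}: name must follow <participant>_<condition>_run<k>.tsv"
        )
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise DataFormatError(f"{path}: missing value at row {row}")
    return ROITimeSeries(
        data=df.to_numpy(dtype=float),
        participant_id=m["pid"],
        condition=m["cond"],
        run=int(m["run"]),
        tr_seconds=tr_seconds,
    )


def read_timeseries_dir(directory: str | Path, tr_seconds: float | None = None) -> list[ROITimeSeries]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise DataFormatError(f"{directory}: no .tsv time series found")
    return [read_timeseries_tsv(p, tr_seconds) for p in paths]


# --------------------------------------------------------------------- FC matrices


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fc(fc: FCMatrix, path: str | Path, binary: bool = False) -> Path:
    """Write one FC matrix as TSV (ROI headers) or ``.npy``, plus metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = [f"roi_{i}" for i in range(fc.n_rois)]
    if binary:
        np.save(path.with_suffix(".npy"), fc.values)
        path = path.with_suffix(".npy")
    else:
        pd.DataFrame(fc.values, index=labels, columns=labels).to_csv(
            path, sep="\t", float_format="%.12g"
        )
    meta = {
        "participant_id": fc.participant_id,
        "condition": fc.condition,
        "run": fc.run,
        "regularization_tau": fc.regularization_tau,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_fc(path: str | Path) -> FCMatrix:
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        try:
            values = pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
        except Exception as exc:
            raise DataFormatError(f"{path}: {exc}") from exc
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return FCMatrix(
        values=values,
        participant_id=meta.get("participant_id", path.stem),
        condition=meta.get("condition", "rest"),
        run=int(meta.get("run", 1)),
        regularization_tau=float(meta.get("regularization_tau", 0.0)),
    )


def write_fc_database(db: FCDatabase, directory: str | Path, binary: bool = False) -> list[Path]:
    directory = Path(directory)
    out = []
    for m in db.matrices:
        name = f"{m.participant_id}_{m.condition}_run{m.run}"
        out.append(write_fc(m, directory / f"{name}.tsv", binary=binary))
    return out


def read_fc_database(directory: str | Path, condition: str | None = None, run: int | None = None) -> FCDatabase:
    directory = Path(directory)
    pattern = "*.npy" if list(directory.glob("*.npy")) else "*.tsv"
    mats = [read_fc(p) for p in sorted(directory.glob(pattern))]
    if condition is not None:
        mats = [m for m in mats if m.condition == condition]
    if run is not None:
        mats = [m for m in mats if m.run == run]
    if not mats:
        raise DataFormatError(f"{directory}: no FC matrices matching condition={condition} run={run}")
    return FCDatabase(
        matrices=mats,
        condition=condition or mats[0].condition,
        run=run or mats[0].run,
    )


# --------------------------------------------------------------------- distance matrices


def write_distance(dm: DistanceMatrix, path: str | Path, binary: bool = False, **meta) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if binary:
        path = path.with_suffix(".npy")
        np.save(path, dm.values)
    else:
        pd.DataFrame(dm.values, index=dm.row_ids, columns=dm.col_ids).to_csv(
            path, sep="\t", float_format="%.12g"
        )
    sidecar = {"measure": dm.measure, "row_ids": dm.row_ids, "col_ids": dm.col_ids, **meta}
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_distance(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    if path.suffix == ".npy":
        values = np.load(path)
        row_ids, col_ids = meta["row_ids"], meta["col_ids"]
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise DataFormatError(f"{path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        row_ids, col_ids = [str(i) for i in df.index], [str(c) for c in df.columns]
    return DistanceMatrix(
        values=values,
        measure=meta.get("measure", "geodesic"),
        row_ids=row_ids,
        col_ids=col_ids,
    )


# --------------------------------------------------------------------- parcellation & schedule


def write_parcellation_tsv(parc: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"roi_index": range(parc.n_rois), "network_name": parc.roi_labels}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_parcellation_tsv(path: str | Path) -> Parcellation:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if not {"roi_index", "network_name"} <= set(df.columns):
        raise DataFormatError(f"{path}: expected columns roi_index, network_name")
    df = df.sort_values("roi_index")
    if list(df["roi_index"]) != list(range(len(df))):
        raise DataFormatError(f"{path}: roi_index must cover 0..R-1 exactly once")
    return Parcellation(roi_labels=[str(x) for x in df["network_name"]])


def read_block_schedule_tsv(
    path: str | Path, tr_seconds: float, cue_seconds: float = 3.0
) -> BlockSchedule:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if not {"onset_s", "offset_s", "has_cue"} <= set(df.columns):
        raise DataFormatError(f"{path}: expected columns onset_s, offset_s, has_cue")
    blocks = [
        (float(r.onset_s), float(r.offset_s), bool(r.has_cue)) for r in df.itertuples()
    ]
    return BlockSchedule(blocks=blocks, cue_seconds=cue_seconds, tr_seconds=tr_seconds)
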