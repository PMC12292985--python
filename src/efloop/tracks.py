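"""Cell-migration metrics from tracked-position tables.

Consumes the long-format CSV produced by particle-tracking tools (one row
per cell per frame, default Trackpy column names ``particle,frame,x,y``)
and computes the standard electrotaxis metrics: migration speed,
instantaneous and displacement directedness (cosine of the angle between a
displacement vector and the field axis), the recruitment index, and the
immobile-cell filter applied before population statistics.

Undefined values (zero displacement, too-short tracks) propagate as NaN and
are excluded from aggregates; they are never coerced to 0, which would bias
the recruitment index's neutral band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "TrackTable",
    "TrackFormatError",
    "load_tracks",
    "migration_speed",
    "instantaneous_directedness",
    "displacement_directedness",
    "recruitment_index",
    "filter_immobile",
    "population_summary",
    "per_cell_metrics",
]

DEFAULT_COLUMNS = {"cell_id": "particle", "frame": "frame", "x": "x", "y": "y"}
FIELD_AXIS_X = (1.0, 0.0)


class TrackFormatError(ValueError):
    """Raised when an input table cannot be interpreted as tracks."""


@dataclass
class TrackTable:
    """Tracked cell positions over frames.

    ``data`` holds columns ``cell_id, frame, x, y`` sorted by
    (cell_id, frame); ``frame_interval`` is the imaging period in minutes.
    """

    data: pd.DataFrame
    frame_interval: float = 5.0
    n_dropped_rows: int = 0
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 minutes")
        required = ["cell_id", "frame", "x", "y"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise TrackFormatError(f"track table missing columns {missing}")
        df = self.data[required].copy()
        df["frame"] = df["frame"].astype(np.int64)
        if (df["frame"] < 0).any():
            raise TrackFormatError("negative frame index in track table")
        df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(["cell_id", "frame"])
        if dup.any():
            pairs = df.loc[dup, ["cell_id", "frame"]].itertuples(index=False)
            listing = ", ".join(f"({c}, {f})" for c, f in list(pairs)[:5])
            raise TrackFormatError(f"duplicate (cell_id, frame) pairs: {listing}")
        self.data = df

    @property
    def n_cells(self) -> int:
        return self.data["cell_id"].nunique()

    def cells(self):
        """Iterate (cell_id, per-cell DataFrame sorted by frame)."""
        return self.data.groupby("cell_id", sort=True)

    def to_csv(self, path) -> None:
        out = self.data.rename(columns={"cell_id": "particle"})
        out.to_csv(path, index=False)


def load_tracks(
    path,
    column_map: dict[str, str] | None = None,
    frame_interval: float = 5.0,
) -> TrackTable:
    """Read a tracking CSV into a validated, sorted :class:`TrackTable`.

    ``column_map`` maps logical names (``cell_id, frame, x, y``) to the
    file's column names; the default is the Trackpy dialect
    ``particle,frame,x,y``.  Rows with missing coordinates are dropped and
    counted in ``n_dropped_rows``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise TrackFormatError(f"unknown logical column names {sorted(unknown)}")
        cols.update(column_map)
    raw = pd.read_csv(path)
    missing = [src for src in cols.values() if src not in raw.columns]
    if missing:
        raise TrackFormatError(
            f"cannot resolve column(s) {missing} in {path}; "
            f"available columns: {list(raw.columns)}"
        )
    df = raw[[cols["cell_id"], cols["frame"], cols["x"], cols["y"]]].copy()
    df.columns = ["cell_id", "frame", "x", "y"]
    n_before = len(df)
    df = df.dropna(subset=["x", "y"])
    return TrackTable(
        data=df,
        frame_interval=frame_interval,
        n_dropped_rows=n_before - len(df),
    )


def _as_cell_frame(track) -> pd.DataFrame:
    if isinstance(track, TrackTable):
        if track.n_cells != 1:
            raise ValueError("expected a single cell's track")
        return track.data
    return track


def migration_speed(track, frame_interval: float = 5.0) -> float:
    """Mean step speed: total distance over adjacent frames / elapsed time.

    Only steps between consecutive observed frames (frame difference of
    exactly 1) contribute; gaps in the track are skipped entirely.  Returns
    NaN for tracks with fewer than two frames or no adjacent-frame steps.
    Units: length units per minute.
    """
    df = _as_cell_frame(track)
    if len(df) < 2:
        return math.nan
    frames = df["frame"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    adjacent = np.diff(frames) == 1
    if not adjacent.any():
        return math.nan
    dist = np.hypot(np.diff(x), np.diff(y))[adjacent]
    return float(dist.sum() / (adjacent.sum() * frame_interval))


def _unit_axis(field_axis) -> np.ndarray:
    v = np.asarray(field_axis, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("field_axis must be a nonzero 2-vector")
    return v / norm


def instantaneous_directedness(
    track,
    lag_frames: int = 6,
    field_axis=FIELD_AXIS_X,
) -> pd.DataFrame:
    """Cosine between each lagged displacement and the field axis.

    For each observed frame i whose frame i + lag is also observed, the
    value is <Delta, axis>/||Delta|| with Delta the displacement over the
    lag (default 6 frames = 30 min at 5 min/frame).  Zero displacement over
    the lag yields NaN.  Returns a DataFrame (frame, value) indexed like
    the input track; frames whose lag partner is missing are omitted.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    axis = _unit_axis(field_axis)
    df = _as_cell_frame(track)
    by_frame = df.set_index("frame")
    frames = by_frame.index.to_numpy()
    partner = pd.Index(frames + lag_frames)
    has_partner = partner.isin(by_frame.index)
    start = by_frame.loc[frames[has_partner]]
    end = by_frame.loc[partner[has_partner]]
    dx = end["x"].to_numpy() - start["x"].to_numpy()
    dy = end["y"].to_numpy() - start["y"].to_numpy()
    norm = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(norm > 0, (dx * axis[0] + dy * axis[1]) / norm, np.nan)
    return pd.DataFrame({"frame": frames[has_partner], "value": value})


def displacement_directedness(track, field_axis=FIELD_AXIS_X) -> pd.DataFrame:
    """Cosine between displacement from the first tracked position and the axis.

    The classical directedness metric: at each frame the displacement is
    measured from the cell's first observed position.  The first frame (and
    any frame the cell has returned exactly to its origin) is NaN.
    """
    axis = _unit_axis(field_axis)
    df = _as_cell_frame(track)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    dx = x - x[0]
    dy = y - y[0]
    norm = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(norm > 0, (dx * axis[0] + dy * axis[1]) / norm, np.nan)
    return pd.DataFrame({"frame": df["frame"].to_numpy(), "value": value})


def recruitment_index(values, threshold: float = 0.01) -> float:
    """Percent difference between field-aligned and anti-aligned cells.

    RI = (C_A - C_C) / C_T * 100 where C_A counts directedness values above
    ``threshold``, C_C those below -threshold, and C_T every defined value
    including the neutral band.  NaN inputs are ignored; an empty (or
    all-NaN) input returns NaN.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan
    above = int(np.sum(v > threshold))
    below = int(np.sum(v < -threshold))
    return (above - below) / v.size * 100.0


def filter_immobile(
    table: TrackTable, percentile: float = 25.0
) -> tuple[TrackTable, int]:
    """Drop cells whose migration speed is strictly below a percentile cutoff.

    The cutoff is the given percentile (linear interpolation between order
    statistics) of the per-cell speed distribution over cells with a
    defined speed.  Cells with undefined speed (single-frame tracks) are
    retained: the strict "<" comparison cannot classify them.  Returns the
    filtered table and the number of removed cells.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    speeds = {
        cid: migration_speed(df, table.frame_interval) for cid, df in table.cells()
    }
    defined = [s for s in speeds.values() if not math.isnan(s)]
    if not defined or percentile == 0:
        return table, 0
    cutoff = float(np.percentile(defined, percentile))
    keep = [cid for cid, s in speeds.items() if math.isnan(s) or not s < cutoff]
    removed = len(speeds) - len(keep)
    out = TrackTable(
        data=table.data[table.data["cell_id"].isin(keep)].reset_index(drop=True),
        frame_interval=table.frame_interval,
        n_dropped_rows=table.n_dropped_rows,
    )
    return out, removed


def per_cell_metrics(
    table: TrackTable,
    lag_frames: int = 6,
    field_axis=FIELD_AXIS_X,
) -> pd.DataFrame:
    """Long-format per-cell metric table.

    Columns: cell_id, frame, speed (per-cell constant), directedness_inst,
    directedness_disp.  Frames lacking an instantaneous value within the
    lag of the track end carry NaN there.
    """
    parts = []
    for cid, df in table.cells():
        inst = instantaneous_directedness(df, lag_frames, field_axis)
        disp = displacement_directedness(df, field_axis)
        merged = pd.DataFrame({"cell_id": cid, "frame": df["frame"].to_numpy()})
        merged = merged.merge(
            inst.rename(columns={"value": "directedness_inst"}), on="frame", how="left"
        ).merge(
            disp.rename(columns={"value": "directedness_disp"}), on="frame", how="left"
        )
        merged.insert(2, "speed", migration_speed(df, table.frame_interval))
        parts.append(merged)
    return pd.concat(parts, ignore_index=True)


def population_summary(
    table: TrackTable,
    lag_frames: int = 6,
    threshold: float = 0.01,
    field_axis=FIELD_AXIS_X,
) -> pd.DataFrame:
    """Per-frame population aggregation of instantaneous directedness.

    For each frame: the count of cells with a defined value, their mean and
    sample standard deviation, and the recruitment index.  Frames with no
    defined values are omitted.
    """
    if table.data.empty:
        raise ValueError("track table is empty")
    metrics = per_cell_metrics(table, lag_frames, field_axis)
    rows = []
    for frame, grp in metrics.groupby("frame"):
        vals = grp["directedness_inst"].dropna().to_numpy()
        if vals.size == 0:
            continue
        rows.append(
            {
                "frame": frame,
                "n_cells": vals.size,
                "mean_directedness": float(vals.mean()),
                "std_directedness": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "ri": recruitment_index(vals, threshold),
            }
        )
    return pd.DataFrame(rows)
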