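"""Tabular I/O for calcium traces, FISH intensity tables, ROI maps, and reports.

All interchange formats are plain CSV with a header row:

* trace table — first column ``frame`` (0-based index), one column per cell,
  header row holds cell IDs; an *empty* cell marks a frame where the ROI was
  not tracked (zero is a legal intensity and is never treated as missing);
* FISH table — columns ``roi_id, mean_intensity``;
* ROI map — columns ``calcium_roi_id, fish_roi_id``;
* reports — one row per cell (metrics) or per comparison (statistics).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "RoiMap",
    "FishIntensityTable",
    "read_trace_table",
    "read_fish_table",
    "read_roi_map",
    "write_metrics_report",
    "write_comparisons_report",
    "read_report",
]


@dataclass
class FluorescenceTrace:
    """One cell's raw fluorescence intensity series.

    Parameters
    ----------
    cell_id
        ROI identifier from the tracking export.
    values
        Intensity per frame, arbitrary fluorescence units; NaN where untracked.
    valid_mask
        True where the frame had a tracked ROI.
    frame_interval
        Seconds between frames; the default 8 s corresponds to 0.125 Hz
        acquisition, i.e. a 900-frame recording spans 2 h.
    start_frame
        0-based index of the first frame in ``values`` within the recording.
    """

    cell_id: str
    values: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    frame_interval: float = 8.0
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError(f"trace {self.cell_id!r}: values must be a non-empty 1-D sequence")
        if self.frame_interval <= 0:
            raise ValueError(f"trace {self.cell_id!r}: frame_interval must be > 0")
        if self.valid_mask is None:
            self.valid_mask = ~np.isnan(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError(f"trace {self.cell_id!r}: valid_mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError(f"trace {self.cell_id!r}: non-finite intensity in tracked frames")
        if np.any(self.values[self.valid_mask] < 0):
            raise ValueError(f"trace {self.cell_id!r}: negative intensity")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_hours(self) -> float:
        return self.n_frames * self.frame_interval / 3600.0


@dataclass
class RoiMap:
    """One-to-one mapping between calcium ROI IDs and FISH ROI IDs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ca = [p[0] for p in self.pairs]
        fi = [p[1] for p in self.pairs]
        if len(set(ca)) != len(ca) or len(set(fi)) != len(fi):
            raise ValueError("ROI map is not one-to-one: duplicate IDs present")

    def calcium_to_fish(self) -> dict[str, str]:
        return dict(self.pairs)

    def fish_to_calcium(self) -> dict[str, str]:
        return {f: c for c, f in self.pairs}

    def unmapped(
        self, calcium_ids: Iterable[str], fish_ids: Iterable[str]
    ) -> tuple[list[str], list[str]]:
        """IDs on either side absent from the map (reported, never dropped silently)."""
        ca = set(p[0] for p in self.pairs)
        fi = set(p[1] for p in self.pairs)
        return (
            [c for c in calcium_ids if c not in ca],
            [f for f in fish_ids if f not in fi],
        )


@dataclass
class FishIntensityTable:
    """Per-cell FISH mean intensities for one plate."""

    plate_id: str
    records: pd.DataFrame = field(repr=False)  # columns: fish_roi_id, mean_intensity

    def __post_init__(self) -> None:
        required = {"fish_roi_id", "mean_intensity"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"FISH table missing column(s): {sorted(missing)}")
        if len(self.records) < 1:
            raise ValueError("FISH table has no rows")
        if (self.records["mean_intensity"] < 0).any():
            bad = self.records.loc[self.records["mean_intensity"] < 0, "fish_roi_id"].iloc[0]
            raise ValueError(f"negative FISH intensity for ROI {bad!r}")

    def __len__(self) -> int:
        return len(self.records)


def read_trace_table(path: str | Path, frame_interval: float = 8.0) -> list[FluorescenceTrace]:
    """Read a trace CSV (frame column + one column per cell) into traces.

    Empty cells mark untracked frames. Column order is preserved. Duplicate
    cell IDs and non-numeric intensities are hard errors naming the offender.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header = next(csv.reader(fh))
    cell_ids = [h.strip() for h in header[1:]]
    seen: set[str] = set()
    for cid in cell_ids:
        if cid in seen:
            raise ValueError(f"duplicate cell ID {cid!r} in {path.name}")
        seen.add(cid)

    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    traces: list[FluorescenceTrace] = []
    for col_idx, cid in enumerate(cell_ids, start=1):
        raw = df.iloc[:, col_idx]
        vals = np.full(len(raw), np.nan)
        for row_idx, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                continue
            try:
                vals[row_idx] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric intensity {cell!r} at row {row_idx}, column {cid!r} in {path.name}"
                ) from exc
        traces.append(FluorescenceTrace(cell_id=cid, values=vals, frame_interval=frame_interval))
    return traces


def write_trace_table(traces: Sequence[FluorescenceTrace], path: str | Path) -> None:
    """Write traces as a trace CSV; untracked frames become empty cells."""
    if not traces:
        raise ValueError("no traces to write")
    n = max(t.n_frames for t in traces)
    data: dict[str, list] = {"frame": list(range(n))}
    for t in traces:
        col = [""] * n
        for i in range(t.n_frames):
            if t.valid_mask[i]:
                col[i] = repr(float(t.values[i]))
        data[t.cell_id] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_fish_table(path: str | Path, plate_id: str) -> FishIntensityTable:
    """Read a FISH intensity CSV (roi_id, mean_intensity) for one plate."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    roi_col = cols.get("roi_id") or cols.get("fish_roi_id")
    int_col = cols.get("mean_intensity")
    if roi_col is None:
        raise ValueError(f"FISH table {Path(path).name} missing column 'roi_id'")
    if int_col is None:
        raise ValueError(f"FISH table {Path(path).name} missing column 'mean_intensity'")
    rec = pd.DataFrame(
        {
            "fish_roi_id": df[roi_col].astype(str),
            "mean_intensity": pd.to_numeric(df[int_col]),
        }
    )
    return FishIntensityTable(plate_id=plate_id, records=rec)


def read_roi_map(path: str | Path) -> RoiMap:
    """Read an ROI co-registration CSV (calcium_roi_id, fish_roi_id)."""
    df = pd.read_csv(path, dtype=str)
    if not {"calcium_roi_id", "fish_roi_id"} <= set(df.columns):
        raise ValueError(
            f"ROI map {Path(path).name} needs columns calcium_roi_id, fish_roi_id"
        )
    return RoiMap(pairs=list(zip(df["calcium_roi_id"], df["fish_roi_id"])))


_FLOAT_FMT = "%.12g"  # 12 significant digits: report round-trips exactly enough


def write_metrics_report(metrics: Sequence, path: str | Path) -> None:
    """Write per-cell metric rows (one row per cell, one column per quantity)."""
    if not metrics:
        raise ValueError("empty metrics collection; refusing to write an empty report")
    rows = [m.to_row() for m in metrics]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_comparisons_report(comparisons: Sequence, path: str | Path) -> None:
    """Write group-comparison rows (one row per comparison)."""
    if not comparisons:
        raise ValueError("empty comparison collection; refusing to write an empty report")
    rows = [c.to_row() for c in comparisons]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a metrics or comparison report written by this module."""
    return pd.read_csv(path)
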