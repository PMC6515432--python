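"""FISH score computation and calcium-FISH phenotype joining.

Each cell's FISH mean intensity F is normalized by the plate background F0,
the average of the five dimmest cells on the same plate, giving the
dimensionless FISH score F/F0. A cell is "positive" for the probed marker at
multiplier m when its score is >= m; the default 2.0 ("200% of background")
is the primary positivity call, with 3.0 and 4.0 evaluated in the same pass
for threshold-sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_tables import FishIntensityTable, RoiMap
from .metrics import CellMetrics

__all__ = ["FishRecord", "compute_fish_scores", "join_phenotype", "DEFAULT_EXPRESSION_THRESHOLDS"]

DEFAULT_EXPRESSION_THRESHOLDS = (2.0, 3.0, 4.0)
DEFAULT_BACKGROUND_N = 5


@dataclass
class FishRecord:
    """Plate-normalized FISH score and positivity calls for one cell."""

    fish_roi_id: str
    mean_intensity: float
    background: float
    fish_score: float
    positive_at: dict[float, bool]

    def to_row(self) -> dict:
        row: dict = {
            "fish_roi_id": self.fish_roi_id,
            "mean_intensity": self.mean_intensity,
            "background": self.background,
            "fish_score": self.fish_score,
        }
        for m, pos in self.positive_at.items():
            row[f"positive_at_{m:g}x"] = pos
        return row


def compute_fish_scores(
    table: FishIntensityTable,
    expression_thresholds: tuple[float, ...] = DEFAULT_EXPRESSION_THRESHOLDS,
    background_n: int = DEFAULT_BACKGROUND_N,
) -> list[FishRecord]:
    """Score every cell on the plate as F/F0.

    F0 is the mean of the ``background_n`` (default five) smallest mean
    intensities on the plate; ties among the dimmest are broken by ROI ID so
    the background set is deterministic. Every cell is scored, including the
    background cells themselves (scores < 1 are legitimate).
    """
    df = table.records
    if len(df) < background_n:
        raise ValueError(
            f"plate {table.plate_id!r}: need >= {background_n} cells for the background, got {len(df)}"
        )
    dimmest = df.sort_values(["mean_intensity", "fish_roi_id"]).head(background_n)
    f0 = float(dimmest["mean_intensity"].mean())
    if f0 == 0:
        raise ValueError(f"plate {table.plate_id!r}: degenerate background (F0 = 0)")
    records = []
    for _, row in df.iterrows():
        score = float(row["mean_intensity"]) / f0
        records.append(
            FishRecord(
                fish_roi_id=str(row["fish_roi_id"]),
                mean_intensity=float(row["mean_intensity"]),
                background=f0,
                fish_score=score,
                positive_at={m: score >= m for m in expression_thresholds},
            )
        )
    return records


def join_phenotype(
    metrics: list[CellMetrics],
    fish: list[FishRecord],
    roi_map: RoiMap,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join per-cell metrics with FISH records via the ROI map.

    Returns the joined table (metric columns + fish_score + positivity calls,
    keyed by calcium cell_id) and a count summary of cells left unmatched on
    either side; nothing is dropped silently.
    """
    fish_to_ca = roi_map.fish_to_calcium()
    metric_rows = {m.cell_id: m.to_row() for m in metrics}
    if len(metric_rows) != len(metrics):
        raise ValueError("duplicate cell_id among metrics")

    joined_rows = []
    matched_ca = set()
    for rec in fish:
        ca_id = fish_to_ca.get(rec.fish_roi_id)
        if ca_id is None or ca_id not in metric_rows:
            continue
        row = dict(metric_rows[ca_id])
        fr = rec.to_row()
        fr.pop("fish_roi_id")
        row.update(fr)
        joined_rows.append(row)
        matched_ca.add(ca_id)

    counts = {
        "n_metrics": len(metrics),
        "n_fish": len(fish),
        "n_joined": len(joined_rows),
        "n_metrics_unmatched": len(metrics) - len(matched_ca),
        "n_fish_unmatched": len(fish) - len(joined_rows),
    }
    columns = None
    if joined_rows:
        columns = list(joined_rows[0].keys())
    return pd.DataFrame(joined_rows, columns=columns), counts
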