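"""Track-contiguity filtering and asymmetric-least-squares detrending.

Cells must be tracked for a minimum number of *contiguous* frames (default
600, i.e. 45 min at 0.125 Hz) to enter the analysis; the kept trace is the
longest contiguous run, never a gap-interpolated series, because the
entropy and Hurst metrics downstream are sensitive to fabricated dynamics.

Slow multiplicative drift (photobleaching, focus, dye redistribution) is
removed with the Eilers–Boelen asymmetric least squares (AsLS) baseline:
the baseline b minimizes

    sum_i w_i (y_i - b_i)^2 + lam * sum_i (Delta^2 b_i)^2,

with w_i = p for y_i > b_i and 1 - p otherwise, iterated to weight
convergence.  Small p makes the baseline hug the lower envelope, so brief
positive calcium transients are preserved while the drift is subtracted.
The correction is additive and mean-preserving — the mean-centered baseline
is subtracted, y - (b - mean(b)), so mean(corrected) = mean(raw) exactly —
which keeps "percent of baseline" spike thresholds interpretable on the
original intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .io_tables import FluorescenceTrace

__all__ = ["DetrendedTrace", "filter_contiguous_tracks", "detrend_asls", "longest_true_run"]

DEFAULT_MIN_FRAMES = 600


@dataclass
class DetrendedTrace:
    """A baseline-corrected trace, same units as the raw intensities."""

    cell_id: str
    values: np.ndarray
    baseline_estimate: np.ndarray
    source_mean: float
    frame_interval: float = 8.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.baseline_estimate = np.asarray(self.baseline_estimate, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_hours(self) -> float:
        return self.n_frames * self.frame_interval / 3600.0


def longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True; ties resolve to the earliest."""
    mask = np.asarray(mask, dtype=bool)
    best_start, best_len = 0, 0
    start, run = 0, 0
    for i, v in enumerate(mask):
        if v:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_start, best_len = start, run
        else:
            run = 0
    return best_start, best_len


def filter_contiguous_tracks(
    traces: list[FluorescenceTrace], min_frames: int = DEFAULT_MIN_FRAMES
) -> tuple[list[FluorescenceTrace], list[tuple[FluorescenceTrace, str]]]:
    """Keep cells tracked for >= ``min_frames`` contiguous frames.

    Kept traces are truncated to their longest contiguous run (earliest run on
    ties). Dropped cells are returned with a human-readable reason rather than
    silently discarded.
    """
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    kept: list[FluorescenceTrace] = []
    dropped: list[tuple[FluorescenceTrace, str]] = []
    for tr in traces:
        start, length = longest_true_run(tr.valid_mask)
        if length >= min_frames:
            kept.append(
                FluorescenceTrace(
                    cell_id=tr.cell_id,
                    values=tr.values[start : start + length],
                    valid_mask=np.ones(length, dtype=bool),
                    frame_interval=tr.frame_interval,
                    start_frame=tr.start_frame + start,
                )
            )
        else:
            dropped.append(
                (tr, f"longest contiguous run {length} < {min_frames} frames")
            )
    return kept, dropped


def detrend_asls(
    trace: FluorescenceTrace,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 10,
) -> DetrendedTrace:
    """Remove slow drift with the asymmetric-least-squares baseline.

    Parameters
    ----------
    smoothness
        Penalty ``lam`` on the squared second differences of the baseline;
        1e5 keeps the baseline far slower than multi-frame spikes at 8 s frames.
    asymmetry
        Weight ``p`` given to points above the baseline (0 < p < 1); small
        values stop positive transients from pulling the baseline up.
    max_iter
        Weight-reassignment iterations; returns the last iterate with
        ``converged=False`` if weights still change, never raises.
    """
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must lie in (0, 1)")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    y = np.asarray(trace.values, dtype=float)
    if y.size < 10:
        raise ValueError(f"trace {trace.cell_id!r}: need >= 10 frames to detrend, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"trace {trace.cell_id!r}: non-finite values; filter the track first")

    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (D.T @ D)
    w = np.ones(n)
    b = y
    converged = False
    for _ in range(max_iter):
        W = sparse.diags(w, format="csc")
        b = spsolve(W + penalty, w * y)
        w_new = np.where(y > b, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new

    mean_y = float(np.mean(y))
    corrected = y - (b - float(np.mean(b)))  # mean-preserving by construction
    return DetrendedTrace(
        cell_id=trace.cell_id,
        values=corrected,
        baseline_estimate=b,
        source_mean=mean_y,
        frame_interval=trace.frame_interval,
        converged=converged,
    )
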