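"""Synthetic trace populations and FISH tables with known ground truth.

The generator emulates a 2-hour recording sampled at 0.125 Hz (900 frames at
8 s): a constant baseline with optional slow multiplicative drift, a
fractional-Gaussian-noise component with a chosen Hurst index, and transient
rectangular spikes (>= 2 frames) with Poisson onsets and amplitudes in the
125%–800%-of-baseline regime the analysis thresholds. FISH intensities are
drawn log-normally per population, with a dim background subpopulation of at
least five cells per plate so the F/F0 score is well defined.

Every draw is keyed by (seed, cell_index) through a ``SeedSequence``, so
populations are reproducible element-wise and across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import FluorescenceTrace, RoiMap, FishIntensityTable, write_trace_table

__all__ = ["FishModel", "SyntheticSpec", "SpikeTruth", "generate_fgn", "generate_trace",
           "generate_population", "progenitor_like_spec", "differentiated_like_spec",
           "structured_trace_suite"]


@dataclass(frozen=True)
class FishModel:
    """FISH-intensity model for one population's plate.

    positive cells draw intensities around ``positive_score_mean`` times the
    background level; negatives around the background level itself (score ~1).
    """

    positive_fraction: float = 0.8
    positive_score_mean: float = 3.0
    background_cells: int = 5
    background_level: float = 10.0
    sigma_log: float = 0.15  # lognormal shape of intensity scatter

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.background_cells < 5:
            raise ValueError("need >= 5 background cells (F0 averages five)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one simulated cell population."""

    n_cells: int = 50
    n_frames: int = 900
    frame_interval: float = 8.0
    baseline_level: float = 100.0
    drift_kind: str = "linear"  # none | linear | exponential
    drift_magnitude: float = 0.2  # fraction of baseline over the recording
    noise_sd: float = 0.05  # fraction of baseline
    hurst_index: float = 0.5
    spike_rate_per_hour: float = 6.0
    spike_amplitude: tuple[float, float] = (1.25, 8.0)  # x baseline, uniform
    spike_duration_frames: tuple[int, int] = (2, 5)  # uniform integer
    spike_shape: str = "rectangular"  # rectangular | decay (instant rise, exp decay)
    fish_model: FishModel = field(default_factory=FishModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_duration_frames[0] < 2:
            raise ValueError("spike duration must be >= 2 frames")
        if not 0.0 < self.hurst_index < 1.0:
            raise ValueError("hurst_index must lie in (0, 1)")
        if self.noise_sd < 0 or self.spike_rate_per_hour < 0:
            raise ValueError("rates and noise must be >= 0")
        if self.drift_kind not in ("none", "linear", "exponential"):
            raise ValueError(f"unknown drift kind {self.drift_kind!r}")
        if self.spike_shape not in ("rectangular", "decay"):
            raise ValueError(f"unknown spike shape {self.spike_shape!r}")


@dataclass
class SpikeTruth:
    """Ground truth for one cell: injected (merged) spike runs and Hurst index."""

    cell_id: str
    spike_onsets: list[int]
    spike_durations: list[int]
    spike_amplitudes: list[float]
    hurst_index: float

    @property
    def n_spikes(self) -> int:
        return len(self.spike_onsets)


def generate_fgn(n: int, hurst_index: float, seed: int | np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by Davies–Harte circulant embedding.

    The exact target autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2
    is embedded in a circulant matrix whose eigenvalues come from one FFT; if
    the embedding is not positive semi-definite for extreme (n, H) the
    generator falls back to spectral synthesis with a warning.
    """
    if not 0.0 < hurst_index < 1.0:
        raise ValueError("hurst_index must lie in (0, 1)")
    if n < 16:
        raise ValueError("need n >= 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    H = hurst_index
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    m = row.size
    if lam.min() < -1e-8 * lam.max():
        warnings.warn("circulant embedding not PSD; falling back to spectral synthesis")
        return _fgn_spectral(n, H, rng)
    lam = np.clip(lam, 0.0, None)
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # real part of FFT(sqrt(lam/m) * w) has exactly the target covariance
    z = np.fft.fft(np.sqrt(lam / m) * w)
    return z.real[:n]


def _fgn_spectral(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn from the fGn spectral density (fallback path)."""
    m = 2 * n
    freqs = np.fft.rfftfreq(m)[1:]
    # power-law spectral density ~ f^(1-2H), normalized afterwards
    s = freqs ** (0.5 - H)
    phases = rng.standard_normal(s.size) + 1j * rng.standard_normal(s.size)
    spec = np.concatenate([[0.0], s * phases])
    x = np.fft.irfft(spec, n=m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _drift_profile(spec: SyntheticSpec) -> np.ndarray:
    t = np.linspace(0.0, 1.0, spec.n_frames)
    if spec.drift_kind == "none":
        return np.zeros(spec.n_frames)
    if spec.drift_kind == "linear":
        return spec.drift_magnitude * t
    return spec.drift_magnitude * (np.exp(2.0 * t) - 1.0) / (np.exp(2.0) - 1.0)


def _merge_spikes(
    onsets: list[int], durations: list[int], amplitudes: list[float]
) -> tuple[list[int], list[int], list[float]]:
    """Merge overlapping injected spikes into single ground-truth runs."""
    if not onsets:
        return [], [], []
    order = np.argsort(onsets)
    merged: list[list] = []
    for i in order:
        o, d, a = onsets[i], durations[i], amplitudes[i]
        if merged and o <= merged[-1][0] + merged[-1][1]:
            last = merged[-1]
            last[1] = max(last[1], o + d - last[0])
            last[2] = max(last[2], a)
        else:
            merged.append([o, d, a])
    return [m[0] for m in merged], [m[1] for m in merged], [m[2] for m in merged]


def generate_trace(
    spec: SyntheticSpec, cell_index: int, cell_id: str | None = None
) -> tuple[FluorescenceTrace, SpikeTruth]:
    """One cell's trace: baseline x (1 + drift) + fGn noise + rectangular spikes."""
    if cell_id is None:
        cell_id = f"cell_{cell_index:04d}"
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(cell_index,))
    rng = np.random.default_rng(ss)
    n = spec.n_frames
    base = spec.baseline_level
    values = base * (1.0 + _drift_profile(spec))
    if spec.noise_sd > 0:
        values = values + base * spec.noise_sd * generate_fgn(n, spec.hurst_index, rng)

    duration_hours = n * spec.frame_interval / 3600.0
    n_spikes = rng.poisson(spec.spike_rate_per_hour * duration_hours)
    onsets, durations, amps = [], [], []
    lo_d, hi_d = spec.spike_duration_frames
    for _ in range(n_spikes):
        d = int(rng.integers(lo_d, hi_d + 1))
        o = int(rng.integers(0, max(1, n - d)))
        a = float(rng.uniform(*spec.spike_amplitude))
        onsets.append(o)
        durations.append(d)
        amps.append(a)
        if spec.spike_shape == "rectangular":
            values[o : o + d] += (a - 1.0) * base
        else:
            # instant rise, exponential decay with time constant = duration
            span = min(3 * d, n - o)
            t = np.arange(span)
            values[o : o + span] += (a - 1.0) * base * np.exp(-t / d)
    values = np.clip(values, 0.0, None)

    truth = SpikeTruth(cell_id, *_merge_spikes(onsets, durations, amps), spec.hurst_index)
    trace = FluorescenceTrace(
        cell_id=cell_id,
        values=values,
        valid_mask=np.ones(n, dtype=bool),
        frame_interval=spec.frame_interval,
    )
    return trace, truth


def _fish_intensities(
    spec: SyntheticSpec, n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(intensities, is_positive) for the mapped cells of one population."""
    fm = spec.fish_model
    pos = rng.random(n_cells) < fm.positive_fraction
    mu_pos = fm.background_level * fm.positive_score_mean
    mu_neg = fm.background_level
    intensities = np.where(
        pos,
        mu_pos * rng.lognormal(0.0, fm.sigma_log, n_cells),
        mu_neg * rng.lognormal(0.0, fm.sigma_log, n_cells),
    )
    return intensities, pos


def generate_population(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    labels: tuple[str, str] = ("popA", "popB"),
    out_dir: str | Path | None = None,
) -> dict:
    """Two-population dataset: traces, FISH tables, ROI map, and ground truth.

    Cells of population A are FISH-positive for marker A on plate A at the
    stated positive fraction (and analogously for B); each plate additionally
    carries ``background_cells`` dim FISH-only rows (no calcium counterpart)
    that anchor F0. Writes trace.csv / fish_<label>.csv / roimap_<label>.csv /
    truth.csv when ``out_dir`` is given.
    """
    if spec_a.n_cells + spec_b.n_cells < 12:
        raise ValueError("combined population too small (need >= 12 cells)")
    traces: list[FluorescenceTrace] = []
    truth_rows = []
    fish_tables: dict[str, FishIntensityTable] = {}
    roi_maps: dict[str, RoiMap] = {}

    for pop_idx, (spec, label) in enumerate(zip((spec_a, spec_b), labels)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(10_000 + pop_idx,))
        )
        intensities, pos = _fish_intensities(spec, spec.n_cells, rng)
        pairs = []
        fish_rows = []
        for i in range(spec.n_cells):
            cell_id = f"{label}_{i:04d}"
            trace, truth = generate_trace(spec, i, cell_id=cell_id)
            traces.append(trace)
            fish_roi = f"{label}_fish_{i:04d}"
            pairs.append((cell_id, fish_roi))
            fish_rows.append({"fish_roi_id": fish_roi, "mean_intensity": float(intensities[i])})
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "population": label,
                    "n_spikes_true": truth.n_spikes,
                    "hurst_true": truth.hurst_index,
                    "fish_positive_true": bool(pos[i]),
                }
            )
        fm = spec.fish_model
        for j in range(fm.background_cells):
            fish_rows.append(
                {
                    "fish_roi_id": f"{label}_bg_{j:04d}",
                    "mean_intensity": float(
                        fm.background_level * rng.lognormal(0.0, 0.02)
                    ),
                }
            )
        fish_tables[label] = FishIntensityTable(
            plate_id=f"plate_{label}", records=pd.DataFrame(fish_rows)
        )
        roi_maps[label] = RoiMap(pairs=pairs)

    truth = pd.DataFrame(truth_rows)
    result = {"traces": traces, "fish": fish_tables, "roi_maps": roi_maps, "truth": truth,
              "labels": labels}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trace_table(traces, out / "trace.csv")
        for label in labels:
            fish_tables[label].records.to_csv(out / f"fish_{label}.csv", index=False)
            pd.DataFrame(roi_maps[label].pairs, columns=["calcium_roi_id", "fish_roi_id"]).to_csv(
                out / f"roimap_{label}.csv", index=False
            )
        truth.to_csv(out / "truth.csv", index=False)
    return result


def progenitor_like_spec(n_cells: int = 60, seed: int = 0, **overrides) -> SyntheticSpec:
    """Population preset: frequent low-amplitude spiking on memoryless noise.

    Emulates immature, progenitor-like cells: many brief transients barely
    above baseline (1.3-1.8x), short durations, and an uncorrelated (H = 0.5)
    noise floor.
    """
    params = dict(
        n_cells=n_cells, seed=seed, spike_rate_per_hour=20.0,
        spike_amplitude=(1.3, 1.8), spike_duration_frames=(2, 4),
        hurst_index=0.5, noise_sd=0.05, drift_kind="linear", drift_magnitude=0.2,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def differentiated_like_spec(n_cells: int = 60, seed: int = 1, **overrides) -> SyntheticSpec:
    """Population preset: sparse high-amplitude spiking on persistent noise.

    Emulates committed, differentiated-like cells: infrequent large transients
    (3.5-6x baseline) lasting longer, riding on long-memory (H = 0.8) noise.
    """
    params = dict(
        n_cells=n_cells, seed=seed, spike_rate_per_hour=5.0,
        spike_amplitude=(3.5, 6.0), spike_duration_frames=(3, 8),
        hurst_index=0.8, noise_sd=0.05, drift_kind="linear", drift_magnitude=0.2,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def structured_trace_suite(n_traces: int = 50, seed: int = 0) -> list[FluorescenceTrace]:
    """Mixed spike + long-memory traces for the randomization controls.

    Half the traces follow the progenitor-like model, half the
    differentiated-like model, all 900 frames at 8 s without drift (the
    controls operate on detrended data).
    """
    half = n_traces // 2
    spec_a = progenitor_like_spec(n_cells=half, seed=seed, drift_kind="none")
    spec_b = differentiated_like_spec(
        n_cells=n_traces - half, seed=seed + 1, drift_kind="none"
    )
    traces = [generate_trace(spec_a, i)[0] for i in range(half)]
    traces += [generate_trace(spec_b, i)[0] for i in range(n_traces - half)]
    return traces
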