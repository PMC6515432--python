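"""Group comparisons, correlations, and randomization controls.

The comparison machinery implements an effect-size-gated nonparametric test:
two cell populations differ on a metric only if the Bonferroni-adjusted
two-sample Kolmogorov–Smirnov p-value is below alpha (0.05) AND the absolute
Cohen's d exceeds 0.2 — large samples alone cannot manufacture significance.

Two randomization controls guard the sequence-sensitive metrics:

* shuffle control — each trace is resampled (with replacement by default,
  mirroring MATLAB ``randsample`` semantics) to its own length, destroying
  sequential structure; the Hurst estimate should fall to ~0.5 and the
  Markovian entropy rise to ~1;
* label randomization — cells from two marker experiments are pooled, sorted
  by FISH score and split in half; on exchangeable data no metric should
  differ between the halves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import hurst_rs, markovian_entropy
from .preprocess import DetrendedTrace

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "ShuffleControlSummary",
    "cohens_d",
    "compare_groups",
    "correlate_expression",
    "run_comparison_design",
    "shuffle_control",
    "label_randomization_control",
    "kruskal_wallis_expression",
    "metric_columns",
]

ALPHA = 0.05
D_MIN = 0.2


@dataclass
class GroupComparison:
    """One metric compared between two labeled cell populations."""

    metric_name: str
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    ks_statistic: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    significant: bool
    family_size: int
    underpowered: bool = False
    note: str = ""

    def to_row(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "group_a_label": self.group_a_label,
            "group_b_label": self.group_b_label,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "ks_statistic": self.ks_statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "cohens_d": self.cohens_d,
            "significant": self.significant,
            "family_size": self.family_size,
            "underpowered": self.underpowered,
            "note": self.note,
        }


@dataclass
class CorrelationResult:
    """Linear (Pearson) and nonlinear (penalized-spline R^2) association."""

    metric_name: str
    pearson_r: float
    gam_r2: float
    n: int

    def to_row(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "pearson_r": self.pearson_r,
            "gam_r2": self.gam_r2,
            "n": self.n,
        }


@dataclass
class ShuffleControlSummary:
    """Across-cell mean +/- SD of Hurst and entropy on shuffled traces."""

    hurst_mean: float
    hurst_sd: float | None
    entropy_mean: float
    entropy_sd: float | None
    n_traces: int
    n_seeds: int
    seed: int


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference, a minus b (Cohen's original)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return float(diff / math.sqrt(pooled_var))


def compare_groups(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    family_size: int = 1,
    metric_name: str = "",
    group_a_label: str = "a",
    group_b_label: str = "b",
    alpha: float = ALPHA,
    d_min: float = D_MIN,
) -> GroupComparison:
    """Two-sample K-S test with Bonferroni correction and the Cohen's d gate.

    ``significant`` is True iff p_adjusted < alpha AND |d| > d_min. P-values
    come from the asymptotic two-sample K-S distribution (samples here are
    typically hundreds of cells); below n = 20 a note flags the small sample.
    If the pooled SD is zero with unequal means, d is +/-inf and significance
    is decided by p alone, flagged in the note.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if a.size < 5 or b.size < 5:
        return GroupComparison(
            metric_name, group_a_label, group_b_label, a.size, b.size,
            float("nan"), float("nan"), float("nan"), float("nan"),
            significant=False, family_size=family_size, underpowered=True,
            note=f"underpowered: n_a={a.size}, n_b={b.size} (< 5)",
        )
    note = ""
    if min(a.size, b.size) < 20:
        note = "asymptotic K-S p with n < 20"
    res = sps.ks_2samp(a, b, method="asymp")
    p_adj = min(1.0, float(res.pvalue) * family_size)
    d = cohens_d(a, b)
    if math.isinf(d):
        significant = p_adj < alpha
        note = (note + "; " if note else "") + "zero pooled SD: significance by p only"
    else:
        significant = (p_adj < alpha) and (abs(d) > d_min)
    return GroupComparison(
        metric_name, group_a_label, group_b_label, a.size, b.size,
        float(res.statistic), float(res.pvalue), p_adj, d,
        significant=significant, family_size=family_size, note=note,
    )


def gam_r2(x: np.ndarray, y: np.ndarray, df: int = 10) -> float:
    """R^2 = 1 - RSS/TSS of a univariate penalized B-spline smooth of y on x.

    The B-spline basis and difference penalty come from statsmodels; the
    penalty weight is chosen by generalized cross-validation over a log-spaced
    grid (GCV(a) = n*RSS(a) / (n - edf(a))^2). The basis dimension adapts to
    small samples. Smoothing only ever lowers R^2 relative to the unpenalized
    spline fit, so a perfectly functional relationship still scores ~1.
    """
    from statsmodels.gam.api import BSplines

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    df = int(min(df, max(4, n // 3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bs = BSplines(x[:, None], df=[df], degree=[3])
    B = np.column_stack([np.ones(n), bs.basis])
    P = np.zeros((B.shape[1], B.shape[1]))
    P[1:, 1:] = bs.penalty_matrices[0]
    BtB = B.T @ B
    Bty = B.T @ y
    best_rss, best_gcv = None, np.inf
    for alpha in np.logspace(-6, 6, 25):
        try:
            A = np.linalg.solve(BtB + alpha * P + 1e-10 * np.eye(B.shape[1]), Bty)
        except np.linalg.LinAlgError:
            continue
        fitted = B @ A
        rss = float(np.sum((y - fitted) ** 2))
        # effective degrees of freedom = tr(B (BtB + aP)^-1 Bt)
        edf = float(np.trace(np.linalg.solve(
            BtB + alpha * P + 1e-10 * np.eye(B.shape[1]), BtB)))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if gcv < best_gcv:
            best_gcv, best_rss = gcv, rss
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0 or best_rss is None:
        raise ValueError("zero variance in the response")
    return max(0.0, 1.0 - best_rss / tss)


def correlate_expression(joined: pd.DataFrame, metric_name: str) -> CorrelationResult:
    """Pearson r and penalized-spline R^2 of a metric against the FISH score."""
    pairs = joined[["fish_score", metric_name]].dropna()
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 paired observations, got {len(pairs)}")
    x = pairs["fish_score"].to_numpy(float)
    y = pairs[metric_name].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in fish_score or metric")
    r = float(sps.pearsonr(x, y).statistic)
    r2 = gam_r2(x, y)
    return CorrelationResult(metric_name=metric_name, pearson_r=r, gam_r2=r2, n=len(pairs))


def metric_columns(joined: pd.DataFrame) -> list[str]:
    """The per-cell metric columns present in a joined table."""
    cols = [c for c in joined.columns if c.startswith("spikes_per_hour_")]
    cols += [c for c in ("average_power", "hurst", "entropy") if c in joined.columns]
    return cols


def run_comparison_design(
    joined: pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame],
    design: str,
    markers: tuple[str, ...],
    expression_threshold: float = 2.0,
    metric_names: list[str] | None = None,
    alpha: float = ALPHA,
    d_min: float = D_MIN,
) -> list[GroupComparison]:
    """Run one of the two population-comparison designs over all metrics.

    ``pos_vs_neg`` splits a single marker experiment's joined table into
    marker-positive (fish_score >= threshold) and marker-negative cells.
    ``posA_vs_posB`` takes a pair of joined tables (one per marker experiment)
    and compares the positive cells of each. The Bonferroni family is all
    tests launched in the invocation; an underpowered group (< 5 cells) is
    reported as such, never silently skipped.
    """
    if design == "pos_vs_neg":
        if not isinstance(joined, pd.DataFrame):
            raise TypeError("pos_vs_neg expects a single joined table")
        (marker,) = markers
        pos = joined[joined["fish_score"] >= expression_threshold]
        neg = joined[joined["fish_score"] < expression_threshold]
        label_a, label_b = f"{marker}+", f"{marker}-"
        table_a, table_b = pos, neg
    elif design == "posA_vs_posB":
        table_a_full, table_b_full = joined
        marker_a, marker_b = markers
        table_a = table_a_full[table_a_full["fish_score"] >= expression_threshold]
        table_b = table_b_full[table_b_full["fish_score"] >= expression_threshold]
        label_a, label_b = f"{marker_a}+", f"{marker_b}+"
    else:
        raise ValueError(f"unknown design {design!r}")

    if metric_names is None:
        metric_names = metric_columns(table_a if len(table_a) else table_b)
    family = len(metric_names)
    return [
        compare_groups(
            table_a[m].to_numpy(float) if m in table_a.columns else np.array([]),
            table_b[m].to_numpy(float) if m in table_b.columns else np.array([]),
            family_size=family,
            metric_name=m,
            group_a_label=label_a,
            group_b_label=label_b,
            alpha=alpha,
            d_min=d_min,
        )
        for m in metric_names
    ]


def shuffle_control(
    traces: list[DetrendedTrace],
    n_seeds: int = 1,
    seed: int = 0,
    replace: bool = True,
) -> ShuffleControlSummary:
    """Hurst and entropy on shuffled traces; structure should be destroyed.

    Each trace's values are resampled to the same length (with replacement by
    default, matching ``randsample``; ``replace=False`` gives a permutation —
    both destroy sequential order). Mean and SD are taken across all
    (trace, seed) realizations; SD is None when only one realization exists.
    """
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = ss.spawn(n_seeds)
    hs: list[float] = []
    es: list[float] = []
    for child in child_seeds:
        rng = np.random.default_rng(child)
        for tr in traces:
            v = np.asarray(tr.values, float)
            shuffled = rng.choice(v, size=v.size, replace=replace)
            sh = DetrendedTrace(
                cell_id=tr.cell_id, values=shuffled,
                baseline_estimate=np.full(v.size, v.mean()),
                source_mean=float(v.mean()), frame_interval=tr.frame_interval,
            )
            try:
                hs.append(hurst_rs(sh))
            except ValueError:
                pass  # constant trace: no Hurst, entropy still defined
            es.append(markovian_entropy(sh))
    def _sd(x: list[float]) -> float | None:
        return float(np.std(x, ddof=1)) if len(x) > 1 else None
    return ShuffleControlSummary(
        hurst_mean=float(np.mean(hs)) if hs else float("nan"),
        hurst_sd=_sd(hs),
        entropy_mean=float(np.mean(es)) if es else float("nan"),
        entropy_sd=_sd(es),
        n_traces=len(traces),
        n_seeds=n_seeds,
        seed=seed,
    )


def label_randomization_control(
    joined_a: pd.DataFrame,
    joined_b: pd.DataFrame,
    seed: int = 0,
    alpha: float = ALPHA,
    d_min: float = D_MIN,
) -> list[GroupComparison]:
    """Pool two marker experiments, sort by FISH score, split in half, compare.

    The halves mix cells of both experiments, so on exchangeable populations
    no metric should reach joint significance. The seed only breaks FISH-score
    ties; an odd pooled count puts the extra cell in the first half.
    """
    if len(joined_a) == 0 or len(joined_b) == 0:
        raise ValueError("both joined tables must be non-empty")
    pooled = pd.concat([joined_a, joined_b], ignore_index=True)
    rng = np.random.default_rng(seed)
    pooled = pooled.assign(_tie=rng.random(len(pooled)))
    pooled = pooled.sort_values(["fish_score", "_tie"]).drop(columns="_tie")
    half = (len(pooled) + 1) // 2
    lo, hi = pooled.iloc[:half], pooled.iloc[half:]
    metrics = metric_columns(pooled)
    family = len(metrics)
    return [
        compare_groups(
            lo[m].to_numpy(float), hi[m].to_numpy(float),
            family_size=family, metric_name=m,
            group_a_label="low_fish_half", group_b_label="high_fish_half",
            alpha=alpha, d_min=d_min,
        )
        for m in metrics
    ]


def kruskal_wallis_expression(
    fractions_by_stage: dict[str, list[float]],
) -> tuple[float, float]:
    """Kruskal–Wallis H and p for per-plate positive-cell percentages across stages.

    Requires >= 2 stage groups with >= 3 observations each. If every value is
    identical across all groups the test is undefined and p = 1 by convention.
    """
    groups = [np.asarray(v, float) for v in fractions_by_stage.values()]
    if len(groups) < 2 or any(g.size < 3 for g in groups):
        raise ValueError("need >= 2 stages with >= 3 observations each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
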