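import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caflux.stats import (
    cohens_d, compare_groups, correlate_expression, run_comparison_design,
    shuffle_control, label_randomization_control, kruskal_wallis_expression,
)

from conftest import as_detrended


def brute_force_ks(a, b):
    """Independent oracle: sup |ECDF_a - ECDF_b| over all observed points."""
    pts = sorted(set(a) | set(b))
    best = 0.0
    for p in pts:
        fa = sum(x <= p for x in a) / len(a)
        fb = sum(x <= p for x in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestCompareGroups:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(50)
        c = compare_groups(a, a.copy())
        assert c.ks_statistic == 0.0
        assert c.cohens_d == 0.0
        assert not c.significant

    def test_unit_shift_detected(self, rng):
        hits, ds = 0, []
        for _ in range(20):
            c = compare_groups(rng.standard_normal(100), rng.standard_normal(100) + 1.0)
            hits += c.significant
            ds.append(c.cohens_d)
        assert hits == 20
        assert np.mean(np.abs(ds)) == pytest.approx(1.0, abs=0.2)

    def test_bonferroni_arithmetic(self, rng):
        # force a comparison whose raw p is moderate, then scale the family
        a = rng.standard_normal(100)
        b = rng.standard_normal(100) + 0.35
        c = compare_groups(a, b, family_size=10)
        assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 10))
        if c.p_raw >= 0.005:
            assert not c.significant or c.p_adjusted < 0.05

    def test_underpowered_reported_not_skipped(self):
        c = compare_groups([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert c.underpowered and not c.significant
        assert math.isnan(c.p_raw)

    def test_ks_matches_brute_force(self, rng):
        """KS statistic equals the ECDF sup-difference oracle on 1,000 pairs."""
        for _ in range(1000):
            na, nb = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            a = rng.standard_normal(na)
            b = rng.standard_normal(nb) + rng.uniform(-1, 1)
            c = compare_groups(a, b)
            assert c.ks_statistic == pytest.approx(
                brute_force_ks(a.tolist(), b.tolist()), abs=1e-12
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_d_antisymmetric_p_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + rng.uniform(-1, 1)
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        assert ab.cohens_d == pytest.approx(-ba.cohens_d)
        assert ab.p_raw == pytest.approx(ba.p_raw)

    def test_zero_pooled_sd_flagged(self):
        c = compare_groups([1.0] * 10, [2.0] * 10)
        assert math.isinf(c.cohens_d)
        assert "by p only" in c.note


class TestCorrelateExpression:
    def _joined(self, x, y):
        return pd.DataFrame({"fish_score": x, "metric": y})

    def test_perfect_linear(self, rng):
        x = rng.uniform(1, 5, 50)
        res = correlate_expression(self._joined(x, x.copy()), "metric")
        assert res.pearson_r == pytest.approx(1.0, abs=1e-6)
        assert res.gam_r2 == pytest.approx(1.0, abs=1e-6)

    def test_independence_both_small(self, rng):
        x = rng.uniform(1, 5, 200)
        res = correlate_expression(self._joined(x, rng.standard_normal(200)), "metric")
        assert abs(res.pearson_r) < 0.2
        assert res.gam_r2 < 0.1

    def test_symmetric_nonlinearity_found_by_gam_only(self, rng):
        x = np.concatenate([rng.uniform(1, 5, 100), 6 - rng.uniform(1, 5, 100)])
        y = (x - x.mean()) ** 2 + 0.05 * rng.standard_normal(200)
        res = correlate_expression(self._joined(x, y), "metric")
        assert abs(res.pearson_r) < 0.2
        assert res.gam_r2 > 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_expression(self._joined(np.ones(20), np.arange(20.0)), "metric")


class TestComparisonDesigns:
    def _joined_pop(self, rng, n, rate_shift=0.0, score=3.0):
        return pd.DataFrame({
            "fish_score": score + 0.1 * rng.standard_normal(n),
            "spikes_per_hour_1.25x": 10.0 + rate_shift + rng.standard_normal(n),
            "spikes_per_hour_3x": 1.0 + np.abs(rng.standard_normal(n)),
            "average_power": np.abs(rng.standard_normal(n)),
            "hurst": 0.5 + 0.05 * rng.standard_normal(n),
            "entropy": 0.9 + 0.01 * rng.standard_normal(n),
        })

    def test_pos_vs_neg_flags_injected_difference(self, rng):
        pos = self._joined_pop(rng, 60, rate_shift=20.0, score=3.0)
        neg = self._joined_pop(rng, 60, rate_shift=0.0, score=1.0)
        joined = pd.concat([pos, neg], ignore_index=True)
        results = run_comparison_design(joined, "pos_vs_neg", ("gad1.1",))
        by_name = {c.metric_name: c for c in results}
        assert by_name["spikes_per_hour_1.25x"].significant
        assert by_name["spikes_per_hour_1.25x"].cohens_d > 0.2

    def test_no_spikes_anywhere_not_significant(self, rng):
        pos = self._joined_pop(rng, 30, score=3.0)
        neg = self._joined_pop(rng, 30, score=1.0)
        for df in (pos, neg):
            df["spikes_per_hour_8x"] = 0.0
        joined = pd.concat([pos, neg], ignore_index=True)
        results = {c.metric_name: c for c in
                   run_comparison_design(joined, "pos_vs_neg", ("m",))}
        c = results["spikes_per_hour_8x"]
        assert c.ks_statistic == 0.0 and not c.significant

    def test_family_size_is_total_test_count(self, rng):
        joined = pd.concat(
            [self._joined_pop(rng, 30, score=3.0), self._joined_pop(rng, 30, score=1.0)],
            ignore_index=True,
        )
        results = run_comparison_design(joined, "pos_vs_neg", ("m",))
        assert all(c.family_size == len(results) for c in results)


class TestControls:
    def test_shuffle_control_destroys_structure(self, rng):
        traces = []
        for i in range(20):
            v = np.tile([1.0, 2.0, 3.0, 4.0], 225) + 0.05 * rng.standard_normal(900)
            traces.append(as_detrended(v + 10, cell_id=f"c{i}"))
        summary = shuffle_control(traces, n_seeds=1, seed=3)
        assert summary.entropy_mean > 0.99
        assert 0.42 <= summary.hurst_mean <= 0.52

    def test_shuffle_control_deterministic_in_seed(self, rng):
        traces = [as_detrended(100 + rng.standard_normal(900), cell_id="c")]
        s1 = shuffle_control(traces, seed=5)
        s2 = shuffle_control(traces, seed=5)
        assert s1.entropy_mean == s2.entropy_mean
        assert s1.hurst_mean == s2.hurst_mean

    def test_shuffled_constant_trace_entropy_zero(self):
        summary = shuffle_control([as_detrended(np.full(900, 4.0))], seed=0)
        assert summary.entropy_mean == 0.0

    def test_label_randomization_on_exchangeable_data(self, rng):
        def pop():
            return pd.DataFrame({
                "fish_score": rng.uniform(0.5, 4.0, 41),
                "spikes_per_hour_1.25x": rng.standard_normal(41),
                "average_power": np.abs(rng.standard_normal(41)),
                "hurst": 0.5 + 0.05 * rng.standard_normal(41),
                "entropy": 0.9 + 0.01 * rng.standard_normal(41),
            })
        results = label_randomization_control(pop(), pop(), seed=1)
        # odd pooled count: halves differ by one cell, never dropped
        sizes = {(c.n_a, c.n_b) for c in results}
        assert sizes == {(41, 41)}


class TestKruskalWallis:
    def test_identical_distributions_large_p(self, rng):
        groups = {s: (50 + 10 * rng.standard_normal(30)).tolist() for s in "abc"}
        _, p = kruskal_wallis_expression(groups)
        assert p > 0.05

    def test_shifted_stage_detected(self, rng):
        hits = 0
        for _ in range(10):
            groups = {
                "st14": (50 + 5 * rng.standard_normal(10)).tolist(),
                "st18": (50 + 5 * rng.standard_normal(10)).tolist(),
                "st22": (80 + 5 * rng.standard_normal(10)).tolist(),
            }
            _, p = kruskal_wallis_expression(groups)
            hits += p < 0.05
        assert hits >= 9

    def test_all_identical_values_p_one(self):
        _, p = kruskal_wallis_expression({"a": [5.0] * 5, "b": [5.0] * 5})
        assert p == 1.0

    def test_two_groups_nonnegative_h(self, rng):
        h, _ = kruskal_wallis_expression(
            {"a": rng.standard_normal(10).tolist(), "b": rng.standard_normal(10).tolist()}
        )
        assert h >= 0.0
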