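"""HPDIs, probability of direction, contrasts and back-transformations."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urbanvar.dhglm import PosteriorDraws
from urbanvar.summaries import (
    back_transform_dispersion,
    classify_evidence,
    habitat_variance_contrast,
    hpdi,
    prob_direction,
    round_half_away,
    summarize_model,
)


def exhaustive_hpdi(draws, prob):
    """Every contiguous window of ceil(prob n) sorted draws; shortest wins,
    ties to the lower window."""
    x = np.sort(np.asarray(draws))
    m = max(int(math.ceil(prob * len(x))), 1)
    if m >= len(x):
        return float(x[0]), float(x[-1])
    best = None
    for i in range(len(x) - m + 1):
        w = (float(x[i]), float(x[i + m - 1]))
        if best is None or (w[1] - w[0]) < (best[1] - best[0]) - 0:
            best = w
    return best


class TestHpdi:
    def test_point_mass(self):
        assert hpdi([3.0] * 7, 0.95) == (3.0, 3.0)

    def test_normal_draws_approach_the_quantile_limits(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hpdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    @pytest.mark.parametrize("seed,prob", list(itertools.product(range(5), [0.5, 0.8, 0.95])))
    def test_matches_exhaustive_window_oracle_on_20_draws(self, seed, prob):
        x = np.random.default_rng(seed).gamma(2.0, size=20)
        assert hpdi(x, prob) == exhaustive_hpdi(x, prob)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_width_nondecreasing_in_probability(self, seed):
        x = np.random.default_rng(seed).standard_normal(60)
        widths = [hpdi(x, p)[1] - hpdi(x, p)[0] for p in (0.3, 0.5, 0.8, 0.95)]
        assert all(a <= b + 1e-12 for a, b in zip(widths, widths[1:]))

    def test_midpoint_near_median_for_symmetric_draws(self):
        x = np.random.default_rng(1).standard_normal(50_000)
        lo, hi = hpdi(x, 0.9)
        assert (lo + hi) / 2 == pytest.approx(np.median(x), abs=0.03)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            hpdi([], 0.95)


class TestProbDirection:
    def test_all_positive(self):
        assert prob_direction([0.1, 2.0, 5.0], "positive") == 1.0

    def test_sign_symmetric(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        assert prob_direction(x, "positive") == 0.5

    def test_zeros_count_half_each_way(self):
        x = np.array([0.0, 0.0, 1.0, -1.0])
        assert prob_direction(x, "positive") == 0.5
        assert prob_direction(x, "positive") + prob_direction(x, "negative") == 1.0

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 200))
    def test_directions_sum_to_one(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        assert prob_direction(x, "positive") + prob_direction(x, "negative") == pytest.approx(1.0)

    def test_weak_evidence_rule_triggers_only_above_0_90(self):
        # 91 positive draws of 100 -> pd = 0.91 > 0.90, HPDI overlaps zero
        rng = np.random.default_rng(0)
        weak = np.concatenate([rng.uniform(0.01, 1.0, 91), rng.uniform(-1.0, -0.01, 9)])
        assert classify_evidence(weak, "positive").value == "weak"
        none = np.concatenate([rng.uniform(0.01, 1.0, 89), rng.uniform(-1.0, -0.01, 11)])
        assert classify_evidence(none, "positive").value == "none"

    def test_hpdi_excluding_zero_is_evidence(self):
        x = np.random.default_rng(0).normal(5.0, 0.5, 500)
        assert classify_evidence(x, "positive").value == "evidence"


def _draws_with(names_values: dict, n=400) -> PosteriorDraws:
    names = list(names_values)
    arr = np.stack([np.broadcast_to(v, (2, n)).astype(float) for v in names_values.values()], axis=-1)
    return PosteriorDraws(names, arr.copy())


class TestVarianceContrast:
    def test_identical_variances_give_pd_half(self):
        d = _draws_with({"sd_cluster_urban": 0.3, "sd_cluster_forest": 0.3})
        c = habitat_variance_contrast(d, "cluster_mean")
        assert np.all(c.diff == 0.0)
        assert c.pd == 0.5  # ties split evenly

    def test_pd_is_the_positive_difference_proportion(self):
        rng = np.random.default_rng(0)
        n = 500
        arr = np.stack(
            [rng.uniform(0.3, 0.6, (2, n)), rng.uniform(0.2, 0.5, (2, n))], axis=-1
        )
        d = PosteriorDraws(["sd_cluster_urban", "sd_cluster_forest"], arr)
        c = habitat_variance_contrast(d, "cluster_mean")
        expected = float(np.mean(c.diff > 0))
        assert c.pd == pytest.approx(expected)

    def test_published_point_estimates_ratio_near_four(self):
        # among-cluster variances for great tit adult tarsus: urban 0.234,
        # forest 0.056 -> the urban/forest ratio is approximately 4
        d = _draws_with(
            {"sd_cluster_urban": math.sqrt(0.234), "sd_cluster_forest": math.sqrt(0.056)}
        )
        c = habitat_variance_contrast(d, "cluster_mean")
        assert float(np.mean(c.ratio)) == pytest.approx(4.0, abs=0.25)

    def test_dispersion_level_uses_dispersion_blocks(self):
        d = _draws_with(
            {"sd_disp_cluster_urban": 0.4, "sd_disp_cluster_forest": 0.2,
             "sd_cluster_urban": 0.1, "sd_cluster_forest": 0.9}
        )
        c = habitat_variance_contrast(d, "cluster_dispersion")
        assert np.all(c.var_urban == pytest.approx(0.16))
        assert c.pd == 1.0

    def test_isa_mode_fit_raises(self):
        d = _draws_with({"sd_cluster": 0.3, "sd_disp_cluster": 0.2})
        with pytest.raises(ValueError, match="categorical"):
            habitat_variance_contrast(d, "cluster_mean")


class TestBackTransform:
    @pytest.mark.parametrize(
        "coef,pct,digits",
        [(0.109, 11.5, 1), (0.223, 25.0, 0), (0.04, 4.1, 1), (0.0, 0.0, 1)],
    )
    def test_percent_increase_closed_form(self, coef, pct, digits):
        got, _, _ = back_transform_dispersion(coef)
        assert round_half_away(got, digits) == pct

    def test_strictly_increasing_in_the_coefficient(self):
        pcts = [back_transform_dispersion(g)[0] for g in np.linspace(-0.5, 0.5, 11)]
        assert all(a < b for a, b in zip(pcts, pcts[1:]))

    def test_residual_sds_in_original_units(self):
        pct, sd_f, sd_u = back_transform_dispersion(0.1, baseline_log_sd=-0.5, trait_sd=2.0)
        assert sd_f == pytest.approx(2.0 * math.exp(-0.5))
        assert sd_u == pytest.approx(2.0 * math.exp(-0.4))
        assert sd_u / sd_f == pytest.approx(1.0 + pct / 100.0)


class TestSummarizeModel:
    @staticmethod
    def _fixture_draws():
        rng = np.random.default_rng(6)
        n = 500
        values = {
            "b_mean[intercept]": rng.normal(0.2, 0.1, (2, n)),
            "b_mean[habitat_urban]": rng.normal(-0.3, 0.05, (2, n)),
            "b_disp[intercept]": rng.normal(-0.5, 0.1, (2, n)),
            "b_disp[habitat_urban]": rng.normal(0.1, 0.2, (2, n)),
            "sd_cluster_forest": np.abs(rng.normal(0.2, 0.05, (2, n))),
            "sd_cluster_urban": np.abs(rng.normal(0.5, 0.05, (2, n))),
            "r_system": np.clip(rng.normal(0.0, 0.3, (2, n)), -0.99, 0.99),
        }
        arr = np.stack(list(values.values()), axis=-1)
        d = PosteriorDraws(list(values), arr)
        d.meta["mean_names"] = ["intercept", "habitat_urban"]
        d.meta["disp_names"] = ["intercept", "habitat_urban"]
        return d, values

    def test_rows_match_hand_computed_statistics(self):
        d, values = self._fixture_draws()
        rows = {(r.part, r.term): r for r in summarize_model(d)}
        x = values["b_mean[habitat_urban]"].reshape(-1)
        row = rows[("mean", "habitat_urban")]
        assert row.estimate == pytest.approx(x.mean())
        assert row.median == pytest.approx(np.median(x))
        assert row.hpdi95 == hpdi(x, 0.95)
        assert row.evidence == "evidence"  # well away from zero

    def test_hpdi50_nested_in_hpdi95(self):
        d, _ = self._fixture_draws()
        for r in summarize_model(d):
            assert r.hpdi95[0] <= r.hpdi50[0] <= r.hpdi50[1] <= r.hpdi95[1]

    def test_random_effects_use_the_0_001_lower_bound_rule(self):
        d, _ = self._fixture_draws()
        rows = {(r.kind, r.term): r for r in summarize_model(d)}
        assert rows[("sd", "sd_cluster_urban")].evidence == "evidence"
        tiny = _draws_with({"sd_cluster_forest": 0.0005})
        tiny.meta["mean_names"] = []
        tiny.meta["disp_names"] = []
        (sd_row, var_row) = summarize_model(tiny)[:2]
        assert sd_row.evidence == "none"

    def test_every_term_appears_exactly_once_with_both_scales(self):
        d, values = self._fixture_draws()
        rows = summarize_model(d)
        terms = [(r.part, r.kind, r.term) for r in rows]
        assert len(terms) == len(set(terms))
        kinds = {k for _, k, _ in terms}
        assert kinds == {"fixed", "sd", "variance", "correlation"}
        assert ("mean", "variance", "var_cluster_urban") in terms


def test_contrast_plot_smoke(tmp_path):
    rng = np.random.default_rng(0)
    d = PosteriorDraws(
        ["sd_cluster_urban", "sd_cluster_forest", "sd_disp_cluster_urban", "sd_disp_cluster_forest"],
        np.abs(rng.normal(0.3, 0.05, (2, 200, 4))),
    )
    from urbanvar.summaries import plot_contrast

    contrasts = [habitat_variance_contrast(d, lv) for lv in ("cluster_mean", "cluster_dispersion")]
    out = tmp_path / "contrast.png"
    plot_contrast(contrasts, out)
    assert out.stat().st_size > 0
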