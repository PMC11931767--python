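import numpy as np
import pandas as pd
import pytest

from microconc import (
    SyntheticConfig,
    boston_like_config,
    compute_repeat_indicators,
    generate_bernoulli_series,
    generate_case_series,
    generate_network,
    uniform_repeat_probability,
)
from microconc.trend import DegenerateOutcomeError, RepeatTrendModel


def small_config(**overrides):
    base = dict(
        n_segments=40,
        n_intersections=20,
        year_start=2007,
        year_end=2010.75,
        annual_counts={y: 50.0 for y in range(2007, 2011)},
        hot_fraction=0.1,
        hot_weight0=4.0,
        weight_decay=0.9,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_segments=-1),
            dict(n_segments=0, n_intersections=0),
            dict(hot_fraction=1.5),
            dict(weight_decay=0.0),
            dict(weight_decay=1.2),
            dict(hot_weight0=0.0),
            dict(annual_counts={2007: -3.0}),
            dict(year_end=2000.0),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            small_config(**bad)

    def test_year_fraction(self):
        cfg = small_config()
        assert cfg.year_fraction(2008) == 1.0
        assert cfg.year_fraction(2010) == pytest.approx(0.75)
        assert cfg.years == [2007, 2008, 2009, 2010]


class TestCaseGeneration:
    def test_deterministic(self):
        net = generate_network(40, 20, seed=5)
        a = generate_case_series(net, small_config())
        b = generate_case_series(net, small_config())
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_ids_exist_in_network(self):
        net = generate_network(40, 20, seed=5)
        series = generate_case_series(net, small_config())
        assert len(series) > 0
        assert all(mp in net for mp in series.data["microplace_id"])

    def test_empty_when_counts_zero(self):
        net = generate_network(40, 20, seed=5)
        cfg = small_config(annual_counts={y: 0.0 for y in range(2007, 2011)})
        assert len(generate_case_series(net, cfg)) == 0

    def test_final_partial_year_truncated(self):
        net = generate_network(40, 20, seed=5)
        series = generate_case_series(net, small_config())
        last = series.data.loc[series.data["date"].dt.year == 2010, "date"]
        # 0.75 of 2010 ends around the start of October
        assert last.max() < pd.Timestamp("2010-10-02")

    def test_uniform_allocation_matches_birthday_form(self):
        # hot_weight0 = 1: allocation is uniform, so the mean repeat
        # probability has the closed form 1 - (1 - 1/M)^(n-1)
        net = generate_network(300, 100, seed=2)
        m = len(net)
        emp, theo = [], []
        for s in range(15):
            cfg = small_config(
                n_segments=300, n_intersections=100, hot_weight0=1.0, seed=s,
                annual_counts={y: 60.0 for y in range(2007, 2011)},
            )
            series = compute_repeat_indicators(generate_case_series(net, cfg))
            emp.append(series.data["repeat"].mean())
            theo.append(uniform_repeat_probability(m, len(series)))
        diff = np.mean(emp) - np.mean(theo)
        se = np.std(np.array(emp) - np.array(theo)) / np.sqrt(15)
        assert abs(diff) < max(4 * se, 0.02)

    def test_hot_weighting_raises_concentration(self):
        net = generate_network(300, 100, seed=2)
        flat = small_config(n_segments=300, n_intersections=100, hot_weight0=1.0)
        hot = small_config(n_segments=300, n_intersections=100, hot_weight0=50.0)
        r_flat = compute_repeat_indicators(generate_case_series(net, flat))
        r_hot = compute_repeat_indicators(generate_case_series(net, hot))
        assert r_hot.data["repeat"].mean() > r_flat.data["repeat"].mean()


class TestPreset:
    def test_preset_shape(self):
        cfg = boston_like_config(seed=0)
        assert cfg.n_segments == 19071
        assert cfg.n_intersections == 12081
        assert cfg.year_start == 2007 and cfg.year_end == 2021.75
        assert cfg.annual_counts[2007] == pytest.approx(309.0)
        assert cfg.annual_counts[2019] == pytest.approx(156.0)
        # 2020 spike sits above the local downward trend
        assert cfg.annual_counts[2020] > cfg.annual_counts[2019]
        total = sum(
            cfg.annual_counts[y] * cfg.year_fraction(y) for y in cfg.years
        )
        assert total == pytest.approx(3341, abs=10)

    def test_scaled_preset(self):
        cfg = boston_like_config(seed=0, scale=0.1)
        assert cfg.n_segments == 1907
        assert cfg.annual_counts[2007] == pytest.approx(30.9)


class TestBernoulliSeries:
    def test_flat_trend_pooled_frequency(self):
        series = generate_bernoulli_series(0.576, 1.0, 5, 4000, seed=3)
        pooled = series.data["repeat"].mean()
        assert pooled == pytest.approx(0.576, abs=0.01)

    def test_probability_out_of_range_names_year(self):
        with pytest.raises(ValueError, match="year index 4"):
            generate_bernoulli_series(0.6, 1.14, 5, 10, seed=0)

    def test_boundary_all_ones_degenerate_fit(self):
        series = generate_bernoulli_series(1.0, 1.0, 3, 50, seed=0)
        assert series.data["repeat"].eq(1).all()
        with pytest.raises(DegenerateOutcomeError):
            RepeatTrendModel.from_case_series(series).fit()

    def test_declining_trend_recovered(self):
        series = generate_bernoulli_series(0.576, 0.982, 15, 10_000, seed=42)
        fit = RepeatTrendModel.from_case_series(series).fit()
        lo, hi = fit.ci95
        assert lo < 0.982 < hi
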