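"""Monte Carlo spurious-trend estimator: oracles and invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from puffnull import (
    CellSummary,
    Channel,
    DrawScale,
    Location,
    MCConfig,
    TrendCriterion,
    ValidationError,
    mc_spurious_trend,
    mc_sweep,
    mc_variants,
    slope_sign_probability,
    table1_noise_model,
    trend_statistic,
)

IOPS = (6.0, 13.0, 43.0)


def cells(means, sds, loc=Location.UPPER_SAME, ch=Channel.PM25, n=4):
    return [
        CellSummary(iop, loc, ch, n, m, s) for iop, m, s in zip(IOPS, means, sds)
    ]


class TestTrendStatistic:
    def test_constant_response_slope_zero_r_flagged(self):
        t = trend_statistic([(6, 0.0), (13, 0.0), (43, 0.0)])
        assert t.slope == 0.0
        assert math.isnan(t.pearson_r) and math.isnan(t.p_two_sided)

    def test_three_point_closed_form(self):
        # x=(6,13,43), y=(1,2,3): Sxx=6954/9, Sxy=37 -> slope=0.0478861,
        # r=37/sqrt(Sxx*2)=0.9412189 (hand-derived, checked vs linregress)
        t = trend_statistic([(6, 1.0), (13, 2.0), (43, 3.0)])
        assert t.slope == pytest.approx(0.0478861, abs=1e-6)
        assert t.pearson_r == pytest.approx(0.9412189, abs=1e-6)
        ref = stats.linregress([6, 13, 43], [1, 2, 3])
        assert t.slope == pytest.approx(ref.slope, rel=1e-12)
        assert t.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_negating_values_negates_slope_and_r(self):
        pts = [(6, 0.4), (13, -0.2), (43, 1.1), (43, 0.3)]
        t = trend_statistic(pts)
        tn = trend_statistic([(x, -y) for x, y in pts])
        assert tn.slope == pytest.approx(-t.slope)
        assert tn.pearson_r == pytest.approx(-t.pearson_r)
        assert tn.p_two_sided == pytest.approx(t.p_two_sided)

    def test_identical_iops_rejected(self):
        with pytest.raises(ValidationError):
            trend_statistic([(6, 1.0), (6, 2.0)])


class TestSpuriousTrend:
    def test_noiseless_increasing_means_give_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = mc_spurious_trend(cells((0.1, 0.2, 0.3), (0, 0, 0)),
                                  MCConfig(n_replicates=200, seed=1))
        assert r.p_hat == 1.0

    def test_symmetric_null_gives_half(self):
        r = mc_spurious_trend(cells((0.0, 0.0, 0.0), (0.3, 0.3, 0.3)),
                              MCConfig(seed=2))
        assert abs(r.p_hat - 0.5) <= 3 * r.mc_se

    def test_reproducible_and_seed_sensitive(self, upper_same_cells):
        c = upper_same_cells[Channel.PM10]
        a = mc_spurious_trend(c, MCConfig(seed=5))
        b = mc_spurious_trend(c, MCConfig(seed=5))
        d = mc_spurious_trend(c, MCConfig(seed=6))
        assert a.p_hat == b.p_hat
        assert a.p_hat != d.p_hat

    def test_shift_invariance_of_trend_probability(self):
        base = cells((0.1, -0.2, 0.3), (0.4, 0.2, 0.5))
        shifted = cells((2.1, 1.8, 2.3), (0.4, 0.2, 0.5))
        a = mc_spurious_trend(base, MCConfig(seed=3))
        b = mc_spurious_trend(shifted, MCConfig(seed=4))
        assert abs(a.p_hat - b.p_hat) <= 3 * math.hypot(a.mc_se, b.mc_se)

    def test_mc_se_halves_with_quadruple_replicates(self, upper_same_cells):
        c = upper_same_cells[Channel.PM10]
        small = mc_spurious_trend(c, MCConfig(n_replicates=2500, seed=8))
        large = mc_spurious_trend(c, MCConfig(n_replicates=10000, seed=8))
        # binomial scaling: se ~ 1/sqrt(R)
        assert large.mc_se == pytest.approx(small.mc_se / 2, rel=0.1)

    def test_significant_criterion_rarer_than_sign_criterion(self, upper_same_cells):
        c = upper_same_cells[Channel.PM10]
        sign = mc_spurious_trend(c, MCConfig(seed=9))
        sig = mc_spurious_trend(
            c, MCConfig(seed=9, criterion=TrendCriterion.SLOPE_SIGNIFICANT_POSITIVE)
        )
        assert sig.p_hat < sign.p_hat

    def test_null_significant_positive_rate_near_alpha_over_two(self):
        r = mc_spurious_trend(
            cells((0.0, 0.0, 0.0), (0.3, 0.3, 0.3)),
            MCConfig(seed=10, criterion=TrendCriterion.SLOPE_SIGNIFICANT_POSITIVE),
        )
        assert abs(r.p_hat - 0.025) <= 3 * r.mc_se + 0.005

    def test_pearson_criterion_matches_slope_criterion(self, upper_same_cells):
        c = upper_same_cells[Channel.PM25]
        a = mc_spurious_trend(c, MCConfig(seed=11))
        b = mc_spurious_trend(
            c, MCConfig(seed=11, criterion=TrendCriterion.PEARSON_POSITIVE)
        )
        assert a.p_hat == b.p_hat  # same draws, sign-identical criteria

    def test_wrong_cell_count_rejected(self, upper_same_cells):
        with pytest.raises(ValidationError):
            mc_spurious_trend(upper_same_cells[Channel.PM25][:1])


@pytest.mark.parametrize("seed", range(20))
def test_sign_probability_matches_analytic_gaussian(seed):
    """Closed-form oracle: the OLS slope of Gaussian draws is Gaussian, so
    P(slope>0) = Phi(E[slope]/SD[slope]); the MC estimate must agree within
    3 mc_se on random cell configurations."""
    rng = np.random.default_rng(1000 + seed)
    means = rng.normal(0, 0.3, 3)
    sds = rng.uniform(0.05, 0.8, 3)
    k = int(rng.integers(1, 6))
    scale = DrawScale.SD if seed % 2 else DrawScale.SEM
    config = MCConfig(n_replicates=4000, samples_per_cell=k, seed=seed,
                      draw_scale=scale)
    c = cells(means, sds)
    r = mc_spurious_trend(c, config)
    analytic = slope_sign_probability(c, config)
    assert abs(r.p_hat - analytic) <= 3 * max(r.mc_se, 1e-3)


class TestSweep:
    def test_default_sweep_has_8_results(self):
        results = mc_sweep(table1_noise_model(), MCConfig(n_replicates=500, seed=0))
        assert len(results) == 8
        assert len({(r.location, r.channel) for r in results}) == 8

    def test_sweep_deterministic(self):
        cfg = MCConfig(n_replicates=500, seed=21)
        a = mc_sweep(table1_noise_model(), cfg)
        b = mc_sweep(table1_noise_model(), cfg)
        assert [r.p_hat for r in a] == [r.p_hat for r in b]

    def test_upper_same_pm10_exceeds_pm25(self):
        """Directional check from the study: the spurious-trend probability
        at the upper-same location is larger for PM10 than PM2.5."""
        for seed in (0, 1, 2):
            results = {
                (r.location, r.channel): r.p_hat
                for r in mc_sweep(table1_noise_model(), MCConfig(seed=seed))
            }
            assert (
                results[(Location.UPPER_SAME, Channel.PM10)]
                > results[(Location.UPPER_SAME, Channel.PM25)]
            )


def test_variant_grid_runs_all_combinations(upper_same_cells):
    grid = mc_variants(upper_same_cells[Channel.PM10], n_replicates=500, seed=0)
    assert len(grid) == 8  # 2 criteria x 2 sample counts x 2 scales
    assert all(0 <= r.p_hat <= 1 for r in grid.values())
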