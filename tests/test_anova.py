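"""Balanced two-way ANOVA: oracle checks and invariants.

statsmodels' OLS + anova_lm is the independent reference implementation;
the package's sums-of-squares engine must agree with it to numerical
precision on random balanced datasets, and the summary-statistics path
must be identical to the raw path.
"""

import math

import numpy as np
import pandas as pd
import pytest

from puffnull import (
    AnovaModel,
    CellSummary,
    Channel,
    DeltaRecord,
    Location,
    ValidationError,
    anova_from_summary,
    anova_two_way,
    summarize_cells,
)

IOPS = (6.0, 13.0, 43.0)


def random_deltas(rng, n_per_cell=4, scale=1.0, mean=0.0):
    deltas = []
    for iop in IOPS:
        for loc in Location:
            vals = rng.normal(mean, scale, size=(n_per_cell, 2))
            for t, (v25, v10) in enumerate(vals):
                deltas.append(
                    DeltaRecord(f"P{int(iop):02d}", iop, loc, t + 1,
                                d_pm25=v25, d_pm10=v10)
                )
    return deltas


def statsmodels_pvalues(deltas, channel, model):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "y": [d.value(channel) for d in deltas],
            "iop": [str(d.iop) for d in deltas],
            "loc": [d.location.value for d in deltas],
        }
    )
    formula = (
        "y ~ C(iop) + C(loc)"
        if model is AnovaModel.MAIN_EFFECTS
        else "y ~ C(iop) * C(loc)"
    )
    table = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=2)
    return {
        "iop": table.loc["C(iop)", "PR(>F)"],
        "location": table.loc["C(loc)", "PR(>F)"],
        "ss_iop": table.loc["C(iop)", "sum_sq"],
        "ss_location": table.loc["C(loc)", "sum_sq"],
        "ss_residual": table.loc["Residual", "sum_sq"],
    }


@pytest.mark.parametrize("model", list(AnovaModel))
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_statsmodels_reference(model, seed):
    rng = np.random.default_rng(seed)
    deltas = random_deltas(rng)
    for ch in Channel:
        ours = anova_two_way(deltas, ch, model)
        ref = statsmodels_pvalues(deltas, ch, model)
        assert ours.row("iop").ss == pytest.approx(ref["ss_iop"], rel=1e-9)
        assert ours.row("location").ss == pytest.approx(ref["ss_location"], rel=1e-9)
        assert ours.p_value("iop") == pytest.approx(ref["iop"], abs=1e-10)
        assert ours.p_value("location") == pytest.approx(ref["location"], abs=1e-10)
        if model is AnovaModel.MAIN_EFFECTS:
            # balanced design: type II factor SS equal ours; residual too
            assert ours.row("residual").ss == pytest.approx(
                ref["ss_residual"], rel=1e-9
            )


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("model", list(AnovaModel))
def test_summary_path_identical_to_raw_path(seed, model):
    """The printed mean/SD/n table carries all the information the balanced
    ANOVA uses: both paths must give the same table to 1e-9."""
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(2, 7))
    deltas = random_deltas(rng, n_per_cell=n, scale=rng.uniform(0.1, 2.0))
    summaries = summarize_cells(deltas)
    for ch in Channel:
        raw = anova_two_way(deltas, ch, model)
        summ = anova_from_summary(summaries, ch, model)
        for r_raw, r_sum in zip(raw.rows, summ.rows):
            assert r_raw.source == r_sum.source and r_raw.df == r_sum.df
            assert r_sum.ss == pytest.approx(r_raw.ss, rel=1e-9, abs=1e-12)
            if not math.isnan(r_raw.p):
                assert r_sum.p == pytest.approx(r_raw.p, rel=1e-9)


class TestInvariants:
    def test_ss_partition_and_df_sum(self, default_deltas):
        for model in AnovaModel:
            t = anova_two_way(default_deltas, Channel.PM10, model)
            parts = [r for r in t.rows if r.source != "total"]
            total = t.row("total")
            assert sum(r.ss for r in parts) == pytest.approx(total.ss, rel=1e-9)
            assert sum(r.df for r in parts) == total.df

    def test_all_identical_deltas_flagged_degenerate(self):
        deltas = [
            DeltaRecord(f"P{int(iop):02d}", iop, loc, t + 1, 0.3, 0.3)
            for iop in IOPS for loc in Location for t in range(4)
        ]
        t = anova_two_way(deltas, Channel.PM25)
        assert t.row("iop").ss == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(t.row("iop").f) and math.isnan(t.p_value("iop"))

    def test_equal_cell_means_and_sds_give_zero_f(self):
        cells = [
            CellSummary(iop, loc, Channel.PM25, 4, 0.2, 0.5)
            for iop in IOPS for loc in Location
        ]
        t = anova_from_summary(cells, Channel.PM25)
        assert t.row("iop").f == pytest.approx(0.0, abs=1e-12)
        assert t.p_value("iop") == pytest.approx(1.0)
        assert t.p_value("location") == pytest.approx(1.0)

    def test_unbalanced_design_rejected(self, default_deltas):
        with pytest.raises(ValidationError, match="unbalanced"):
            anova_two_way(default_deltas[:-1], Channel.PM25)

    def test_missing_summary_cell_rejected(self, table1_cells):
        with pytest.raises(ValidationError, match="missing cells"):
            anova_from_summary(table1_cells[:-1], Channel.PM10)

    def test_relabeling_locations_preserves_factor_ss(self, default_deltas):
        perm = {
            Location.UPPER_SAME: Location.LOWER_OPPOSITE,
            Location.LOWER_OPPOSITE: Location.UPPER_SAME,
            Location.LOWER_SAME: Location.UPPER_OPPOSITE,
            Location.UPPER_OPPOSITE: Location.LOWER_SAME,
        }
        permuted = [
            DeltaRecord(d.phantom_id, d.iop, perm[d.location], d.test_index,
                        d.d_pm25, d.d_pm10)
            for d in default_deltas
        ]
        a = anova_two_way(default_deltas, Channel.PM10)
        b = anova_two_way(permuted, Channel.PM10)
        assert b.row("location").ss == pytest.approx(a.row("location").ss, rel=1e-12)
        assert b.row("iop").ss == pytest.approx(a.row("iop").ss, rel=1e-12)


def test_table1_significance_pattern(table1_cells):
    """On the study's printed cells: PM10 significant for both factors,
    PM2.5 for neither (the study's qualitative result)."""
    pm10 = anova_from_summary(table1_cells, Channel.PM10)
    pm25 = anova_from_summary(table1_cells, Channel.PM25)
    assert pm10.significant("iop") and pm10.significant("location")
    assert not pm25.significant("iop") and not pm25.significant("location")
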