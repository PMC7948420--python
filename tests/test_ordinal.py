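"""Proportional-odds / adjacent-category fitting and the LR test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ptmforge.ordinal import (
    STATES,
    AdjacentCategoryFit,
    SeparationError,
    ConvergenceError,
    aggregate_counts,
    fit_adjacent_category,
    fit_proportional_odds,
    lr_test,
    significance_label,
)
from ptmforge.synth import gen_methyl_counts


def counts_frame(per_strain: dict) -> pd.DataFrame:
    rows = []
    for strain, reps in per_strain.items():
        for r, counts in enumerate(reps):
            rows.append({"strain": strain, "replicate": r, **dict(zip(STATES, counts))})
    return pd.DataFrame(rows)


class TestProportionalOdds:
    def test_identical_strains_null_effect(self):
        df = counts_frame({"A": [(10, 20, 30, 40)] * 2, "B": [(10, 20, 30, 40)] * 2})
        fit = fit_proportional_odds(df, "A", mode="counts")
        assert fit.coefficients["B"] == pytest.approx(0.0, abs=1e-6)
        assert fit.odds_ratio("B") == pytest.approx(1.0, abs=1e-6)

    def test_single_strain_cutpoints_are_empirical_logits(self):
        counts = (400, 150, 150, 300)
        df = counts_frame({"WT": [counts]})
        fit = fit_proportional_odds(df, "WT", mode="counts")
        cum = np.cumsum(counts)[:3] / sum(counts)
        assert fit.cutpoints == pytest.approx(logit(cum), abs=1e-6)

    def test_matches_statsmodels_oracle(self):
        """Full agreement with an independent generic-optimizer ML fit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 1.2}, effective_n=800, seed=21)
        fit = fit_proportional_odds(df, "WT", mode="counts")

        agg = aggregate_counts(df, mode="counts")
        ys, xs = [], []
        for strain, row in agg.iterrows():
            for j, state in enumerate(STATES):
                ys += [j] * int(row[state])
                xs += [1.0 if strain == "mut" else 0.0] * int(row[state])
        res = OrderedModel(np.array(ys), np.array(xs)[:, None], distr="logit").fit(
            method="bfgs", disp=0
        )
        thresholds = res.model.transform_threshold_params(res.params)[1:4]
        assert fit.coefficients["mut"] == pytest.approx(res.params[0], abs=1e-4)
        assert fit.cutpoints == pytest.approx(thresholds, abs=1e-4)

    def test_recovers_planted_effect(self):
        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 1.5}, effective_n=2000,
                                  n_replicates=1, seed=8)
        fit = fit_proportional_odds(df, "WT", mode="counts")
        lo, hi = fit.odds_ratio_ci("mut")
        assert lo <= np.exp(1.5) <= hi

    def test_reversed_state_order_negates_beta(self):
        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 1.0}, seed=31)
        fit = fit_proportional_odds(df, "WT", mode="counts")
        rev = df.rename(columns={"me0": "me3", "me1": "me2", "me2": "me1", "me3": "me0"})
        fit_rev = fit_proportional_odds(rev, "WT", mode="counts")
        assert fit_rev.coefficients["mut"] == pytest.approx(
            -fit.coefficients["mut"], abs=1e-5
        )

    def test_proportions_mode_uses_declared_effective_n(self):
        frac = [(0.4, 0.15, 0.15, 0.3)]
        df = counts_frame({"WT": frac, "mut": [(0.2, 0.15, 0.2, 0.45)]})
        small = fit_proportional_odds(df, "WT", effective_n=100)
        large = fit_proportional_odds(df, "WT", effective_n=10000)
        assert small.coefficients["mut"] == pytest.approx(
            large.coefficients["mut"], abs=1e-3
        )
        assert small.std_errors["mut"] > 5 * large.std_errors["mut"]

    def test_empty_strain_rejected(self):
        df = counts_frame({"WT": [(10, 10, 10, 10)], "mut": [(0, 0, 0, 0)]})
        with pytest.raises(ValueError):
            fit_proportional_odds(df, "WT", mode="counts")

    def test_degenerate_strain_flagged(self):
        df = counts_frame({"WT": [(100, 100, 100, 700)], "ko": [(1000, 0, 0, 0)]})
        with pytest.raises((SeparationError, ConvergenceError)):
            fit_proportional_odds(df, "WT", mode="counts")


class TestAdjacentCategory:
    def test_identical_strains_zero_slopes(self):
        df = counts_frame({"A": [(10, 20, 30, 40)], "B": [(10, 20, 30, 40)]})
        fit = fit_adjacent_category(df, "A", mode="counts")
        assert fit.slopes["B"] == pytest.approx(np.zeros(3), abs=1e-6)

    def test_nesting_loglikelihood(self):
        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 1.0}, seed=13)
        po = fit_proportional_odds(df, "WT", mode="counts")
        ac = fit_adjacent_category(df, "WT", mode="counts")
        assert ac.log_likelihood >= po.log_likelihood - 1e-9

    def test_po_data_gives_similar_boundary_slopes(self):
        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 1.0}, effective_n=20000, seed=29)
        ac = fit_adjacent_category(df, "WT", mode="counts")
        slopes = ac.slopes["mut"]
        assert np.sign(slopes).tolist() == [1, 1, 1]
        assert slopes.max() - slopes.min() < 0.5


class TestLRTest:
    def test_identical_models_stat_zero(self):
        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 0.5}, seed=3)
        po = fit_proportional_odds(df, "WT", mode="counts")
        stat, dof, p = lr_test(po, po)
        assert stat == 0.0 and p == 1.0

    def test_statistic_nonnegative_with_df(self):
        df, _ = gen_methyl_counts({"WT": 0.0, "mut": 0.7}, seed=5)
        po = fit_proportional_odds(df, "WT", mode="counts")
        ac = fit_adjacent_category(df, "WT", mode="counts")
        stat, dof, p = lr_test(po, ac)
        assert stat >= 0.0 and dof == ac.n_params - po.n_params == 2
        assert 0.0 <= p <= 1.0

    def test_different_data_rejected(self):
        df1, _ = gen_methyl_counts({"WT": 0.0, "mut": 0.7}, seed=5)
        df2, _ = gen_methyl_counts({"WT": 0.0, "mut": 0.7}, seed=6)
        po = fit_proportional_odds(df1, "WT", mode="counts")
        ac = fit_adjacent_category(df2, "WT", mode="counts")
        with pytest.raises(ValueError, match="different data"):
            lr_test(po, ac)


def test_significance_annotation():
    assert significance_label(0.009) == "**"
    assert significance_label(0.011) == ""
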