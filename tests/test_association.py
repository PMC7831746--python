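"""Contingency-table association statistics and their oracles."""

import numpy as np
import pytest
from scipy import stats

from sarcoscore.association import (
    Table2x2,
    allele_table,
    anova_tukey,
    chisq_test,
    counts_from_freq,
    genotype_table,
    model_table,
    odds_ratio_woolf,
)
from sarcoscore.cohort_io import GenotypeCounts
from sarcoscore.power import PowerSpec, group_frequencies
from sarcoscore.synthetic_cohort import sample_group_genotype_counts


class TestTables:
    def test_allele_table_doubles_samples(self):
        cases = GenotypeCounts(10, 31, 4)
        controls = GenotypeCounts(6, 70, 69)
        table = allele_table(cases, controls)
        assert (table.a, table.b) == (51, 39)
        assert table.a + table.b == 2 * cases.n
        assert table.c + table.d == 2 * controls.n

    def test_all_other_homozygotes_contribute_zero(self):
        table = allele_table(GenotypeCounts(0, 0, 20), GenotypeCounts(5, 5, 5))
        assert table.a == 0 and table.b == 40

    @pytest.mark.parametrize(
        "model, exposed, unexposed", [("dominant", 41, 4), ("recessive", 10, 35)]
    )
    def test_model_collapse(self, model, exposed, unexposed):
        table = model_table(GenotypeCounts(10, 31, 4), GenotypeCounts(6, 70, 69), model)
        assert (table.a, table.b) == (exposed, unexposed)

    def test_dominant_exposure_contains_recessive(self):
        cases, controls = GenotypeCounts(7, 20, 18), GenotypeCounts(12, 40, 93)
        dom = model_table(cases, controls, "dominant")
        rec = model_table(cases, controls, "recessive")
        assert dom.a >= rec.a and dom.c >= rec.c


class TestChiSquare:
    def test_reconstructed_allele_table(self):
        # ACTN3 X-allele 2x2 rebuilt from the published frequencies
        chi2, p, df, _ = chisq_test(Table2x2(54, 36, 123, 167))
        assert chi2 == pytest.approx(8.537, abs=1e-3)
        assert p == pytest.approx(0.0035, abs=2e-4)
        assert df == 1

    def test_equal_proportions_give_zero(self):
        chi2, p, _, _ = chisq_test(Table2x2(20, 30, 40, 60))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(51, 39, 82, 208), (5, 9, 13, 2)])
    def test_matches_expected_count_oracle(self, cells):
        obs = np.array(cells, float).reshape(2, 2)
        margins_r, margins_c = obs.sum(axis=1), obs.sum(axis=0)
        expected = np.outer(margins_r, margins_c) / obs.sum()
        chi2, *_ = chisq_test(Table2x2(*cells))
        assert chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum(), rel=1e-12)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_test(Table2x2(0, 10, 0, 20))

    def test_equals_squared_two_proportion_z(self):
        t = Table2x2(51, 39, 82, 208)
        p1, p2 = t.a / (t.a + t.b), t.c / (t.c + t.d)
        pooled = (t.a + t.c) / t.total
        z = (p1 - p2) / np.sqrt(
            pooled * (1 - pooled) * (1 / (t.a + t.b) + 1 / (t.c + t.d))
        )
        chi2, *_ = chisq_test(t)
        assert chi2 == pytest.approx(z**2, rel=1e-9)

    def test_genotype_table_has_two_df(self):
        chi2, p, df, _ = chisq_test(
            genotype_table(GenotypeCounts(10, 31, 4), GenotypeCounts(6, 70, 69))
        )
        assert df == 2 and p < 0.001


class TestWoolfOddsRatio:
    @pytest.mark.parametrize(
        "cells, or_, lo, hi",
        [
            ((51, 39, 82, 208), 3.317, 2.034, 5.409),   # MTHFR C
            ((54, 36, 123, 167), 2.037, 1.258, 3.297),  # ACTN3 X
            ((58, 32, 141, 149), 1.915, 1.174, 3.124),  # NRF2 C
        ],
    )
    def test_published_allele_tables(self, cells, or_, lo, hi):
        res = odds_ratio_woolf(Table2x2(*cells))
        assert res.or_ == pytest.approx(or_, abs=5e-4)
        assert res.ci_low == pytest.approx(lo, abs=2e-3)
        assert res.ci_high == pytest.approx(hi, abs=2e-3)

    def test_balanced_table_spans_one(self):
        res = odds_ratio_woolf(Table2x2(10, 10, 10, 10))
        assert res.or_ == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_group_swap_inverts_or_and_ci(self):
        t = Table2x2(51, 39, 82, 208)
        a, b = odds_ratio_woolf(t), odds_ratio_woolf(t.swapped_groups())
        assert a.or_ == pytest.approx(1 / b.or_, rel=1e-12)
        assert a.ci_low == pytest.approx(1 / b.ci_high, rel=1e-12)

    def test_log_ci_symmetric(self):
        res = odds_ratio_woolf(Table2x2(54, 36, 123, 167))
        assert np.log(res.or_) - np.log(res.ci_low) == pytest.approx(
            np.log(res.ci_high) - np.log(res.or_), rel=1e-9
        )

    def test_zero_cell_gets_haldane_anscombe(self):
        res = odds_ratio_woolf(Table2x2(10, 0, 5, 15))
        assert "haldane_anscombe" in res.flags
        assert res.or_ == pytest.approx((10.5 * 15.5) / (0.5 * 5.5), rel=1e-12)

    def test_double_zero_diagonal_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_woolf(Table2x2(0, 10, 5, 0))


class TestCountReconstruction:
    @pytest.mark.parametrize(
        "freq, n, expected",
        [
            (56.7, 45, 51), (28.3, 145, 82),   # MTHFR C
            (60.0, 45, 54), (42.4, 145, 123),  # ACTN3 X
            (64.4, 45, 58), (48.6, 145, 141),  # NRF2 C
        ],
    )
    def test_published_allele_frequencies(self, freq, n, expected):
        assert counts_from_freq(freq, n, per_allele=True) == expected

    def test_genotype_denominator_and_zero(self):
        assert counts_from_freq(50.0, 44, per_allele=False) == 22
        assert counts_from_freq(0.0, 145, per_allele=True) == 0


class TestAnovaTukey:
    def test_equal_means_give_zero_f(self):
        res = anova_tukey({"AA": [5.0, 5.0, 5.0], "AC": [5.0, 5.0], "CC": [5.0, 5.0]})
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_sum_of_squares_oracle(self):
        groups = {"AA": [24.0, 26.0, 28.0], "AC": [22.0, 23.0, 24.0], "CC": [18.0, 19.0, 20.0]}
        values = [v for g in groups.values() for v in g]
        grand = np.mean(values)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_within = sum((v - np.mean(g)) ** 2 for g in groups.values() for v in g)
        f_oracle = (ss_between / 2) / (ss_within / 6)
        res = anova_tukey(groups)
        assert res.f == pytest.approx(f_oracle, rel=1e-9)

    def test_tukey_p_not_below_unadjusted_pooled_t(self):
        """The studentized-range adjustment can only raise the p-value of a
        contrast relative to the t test with the same pooled variance."""
        groups = {"AA": [24.0, 26.0, 28.0, 25.0], "AC": [22.0, 23.0, 24.0, 21.0],
                  "CC": [18.0, 19.0, 20.0, 22.0]}
        res = anova_tukey(groups)
        ss_within = sum((v - np.mean(g)) ** 2 for g in groups.values() for v in g)
        df = sum(len(g) for g in groups.values()) - len(groups)
        s2 = ss_within / df
        for g1, g2, diff, p_adj in res.pairwise:
            se = np.sqrt(s2 * (1 / len(groups[g1]) + 1 / len(groups[g2])))
            p_unadj = 2 * stats.t.sf(abs(diff) / se, df)
            assert p_adj >= p_unadj - 1e-9

    def test_small_groups_dropped_then_error(self):
        res = anova_tukey({"AA": [1.0, 2.0], "AC": [2.0, 3.0], "CC": [9.9]})
        assert res.dropped == ("CC",)
        with pytest.raises(ValueError, match="two groups"):
            anova_tukey({"AA": [1.0, 2.0], "CC": [9.9]})


def _calibrate_multiplicative_grr(target_or: float, pop_freq: float, prevalence: float) -> float:
    """g1 with g2 = g1^2 whose penetrance-model allelic OR hits the target."""
    def implied_or(g1: float) -> float:
        f = group_frequencies(PowerSpec(pop_freq, prevalence, g1, g1 * g1, 10, 10))
        pa, pu = f.case_allele_freq, f.control_allele_freq
        return (pa / (1 - pa)) / (pu / (1 - pu))

    lo, hi = 1.0, 3.0  # penetrances stay valid on this bracket
    for _ in range(60):
        mid = (lo + hi) / 2
        if implied_or(mid) < target_or:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestOperatingCharacteristics:
    def test_null_rejection_rate_near_alpha(self, rng):
        """Allelic test type-I error at alpha = 0.05 under a null generator."""
        reps, n = 1000, 100  # 100 cases + 100 controls per replicate
        case, control = sample_group_genotype_counts(
            0.35, 1.0, 1.0, 0.237, n, n, rng, size=reps
        )
        rejections = 0
        for i in range(reps):
            t = allele_table(GenotypeCounts(*case[i]), GenotypeCounts(*control[i]))
            _, p, _, _ = chisq_test(t)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_woolf_ci_coverage_at_or_two(self, rng):
        """95% Woolf CI covers the generating allelic OR 2.0 in >= 93% of draws."""
        pop_freq, prevalence = 0.35, 0.237
        g1 = _calibrate_multiplicative_grr(2.0, pop_freq, prevalence)
        reps, n = 500, 2000
        case, control = sample_group_genotype_counts(
            pop_freq, g1, g1 * g1, prevalence, n, n, rng, size=reps
        )
        covered = 0
        for i in range(reps):
            t = allele_table(GenotypeCounts(*case[i]), GenotypeCounts(*control[i]))
            res = odds_ratio_woolf(t)
            covered += res.ci_low <= 2.0 <= res.ci_high
        assert covered / reps >= 0.93
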