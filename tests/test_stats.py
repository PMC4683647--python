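"""Segregation statistics: χ² goodness of fit, exact zero-class tests,
Fisher's exact association, best-fit ranking."""

import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gynomap import (
    MarkerGenotypeMatrix,
    Marker,
    ObservedCounts,
    SexPhenotype,
    best_fit_ratio,
    chisq_gof,
    exact_zero_class_test,
    fisher_exact_2x2,
    marker_sex_association,
    ratio_hypothesis,
)
from gynomap.model import ModelError, RatioHypothesis
from gynomap.stats import adjust_pvalues

from conftest import genotype


class TestChisqGof:
    @pytest.mark.parametrize(
        "obs, label, statistic",
        [
            ((17, 36), "1:3", 1.42),  # selfed heterozygote family
            ((0, 43), "1:3", 14.33),  # all-hermaphrodite self
            ((25, 25), "1:1", 0.0),
            ((15, 15), "7:9", 0.48),  # two-locus epistasis hypothesis
        ],
    )
    def test_reproduces_published_statistics(self, obs, label, statistic):
        res = chisq_gof(ObservedCounts(*obs), ratio_hypothesis(label))
        assert res.statistic == pytest.approx(statistic, abs=0.005)
        assert res.df == 1

    def test_epistasis_hypothesis_exact_value(self):
        # (15-13.125)^2/13.125 + (15-16.875)^2/16.875
        res = chisq_gof(ObservedCounts(15, 15), ratio_hypothesis("7:9"))
        assert res.statistic == pytest.approx(0.47619, abs=1e-5)

    def test_perfect_fit_p_one(self):
        res = chisq_gof(ObservedCounts(25, 25), ratio_hypothesis("1:1"))
        assert res.statistic == 0
        assert res.p_value == 1

    def test_small_family_not_applied(self):
        res = chisq_gof(ObservedCounts(3, 4), ratio_hypothesis("1:1"))
        assert not res.applied
        assert math.isnan(res.statistic)
        # a family of exactly 10 is still tested
        assert chisq_gof(ObservedCounts(6, 4), ratio_hypothesis("1:1")).applied

    def test_zero_class_hypothesis_redirected(self):
        with pytest.raises(ModelError, match="exact_zero_class_test"):
            chisq_gof(ObservedCounts(0, 11), ratio_hypothesis("0:1"))

    @given(
        nf=st.integers(0, 60),
        nh=st.integers(0, 60),
        num=st.integers(1, 5),
        den=st.integers(1, 5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_class_swap_invariance(self, nf, nh, num, den):
        """Swapping the two classes together with their expectations leaves
        the statistic unchanged."""
        if nf + nh < 10:
            return
        hyp = RatioHypothesis("x", Fraction(num, num + den))
        swapped = RatioHypothesis("y", Fraction(den, num + den))
        a = chisq_gof(ObservedCounts(nf, nh), hyp).statistic
        b = chisq_gof(ObservedCounts(nh, nf), swapped).statistic
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    def test_monotone_in_deviation(self):
        hyp = ratio_hypothesis("1:3")
        n = 40
        stats = [
            chisq_gof(ObservedCounts(k, n - k), hyp).statistic for k in range(n + 1)
        ]
        expected_k = n / 4
        for k in range(n):
            if k + 1 <= expected_k:
                assert stats[k] >= stats[k + 1] - 1e-12
            if k >= expected_k:
                assert stats[k] <= stats[k + 1] + 1e-12

    def test_continuity_correction_flag(self):
        plain = chisq_gof(ObservedCounts(17, 36), ratio_hypothesis("1:3"))
        corrected = chisq_gof(
            ObservedCounts(17, 36), ratio_hypothesis("1:3"), continuity_correction=True
        )
        assert corrected.statistic < plain.statistic


class TestExactZeroClass:
    def test_perfect_fit(self):
        res = exact_zero_class_test(ObservedCounts(0, 11), ratio_hypothesis("0:1"))
        assert res.statistic == 0 and res.p_value == 1 and not res.anomaly

    def test_anomalous_observation_rejects(self):
        res = exact_zero_class_test(ObservedCounts(1, 13), ratio_hypothesis("0:1"))
        assert res.p_value == 0 and res.anomaly

    def test_mirror_all_female_hypothesis(self):
        res = exact_zero_class_test(ObservedCounts(5, 0), ratio_hypothesis("1:0"))
        assert res.statistic == 0 and not res.anomaly


def _fisher_enumeration(table):
    """Brute-force two-sided Fisher p: enumerate all tables with the
    observed margins, summing probabilities ≤ the observed table's."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(kmin, kmax + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[8, 0], [0, 33]], 1 / 95_548_245),  # perfect cosegregation, n=41
            ([[5, 5], [5, 5]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
        ],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    @given(
        a=st.integers(0, 10),
        b=st.integers(0, 10),
        c=st.integers(0, 10),
        d=st.integers(0, 10),
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_enumeration_small_tables(self, a, b, c, d):
        if a + b + c + d == 0 or a + b + c + d > 30:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(
            _fisher_enumeration(table), rel=1e-7
        )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ModelError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestBestFit:
    def test_two_locus_family_prefers_epistasis_ratio(self):
        hyps = [ratio_hypothesis(l) for l in ("1:3", "7:9", "0:1")]
        ranked = best_fit_ratio(ObservedCounts(15, 15), hyps)
        assert ranked[0].hypothesis.label == "7:9"

    def test_selfed_family_prefers_one_quarter(self):
        hyps = [ratio_hypothesis(l) for l in ("1:3", "1:1")]
        ranked = best_fit_ratio(ObservedCounts(9, 44), hyps)
        assert ranked[0].hypothesis.label == "1:3"

    def test_all_hermaphrodite_prefers_degenerate(self):
        hyps = [ratio_hypothesis(l) for l in ("1:3", "0:1")]
        ranked = best_fit_ratio(ObservedCounts(0, 43), hyps)
        assert ranked[0].hypothesis.label == "0:1"

    def test_parsimony_breaks_ties(self):
        from gynomap import expected_ratio

        one_het = expected_ratio(
            genotype("mfmf", "rr", "TT"), genotype("mfmf", "Rr", "TT")
        )
        two_het = expected_ratio(
            genotype("MSmf", "RR", "TT"), genotype("mfmf", "Rr", "TT")
        )
        assert one_het.female_fraction == two_het.female_fraction == Fraction(1, 2)
        ranked = best_fit_ratio(ObservedCounts(20, 20), [two_het, one_het])
        assert ranked[0].hypothesis is one_het


def _matrix(calls_by_marker, sexes):
    individuals = [f"I{i}" for i in range(len(sexes))]
    markers = [Marker(mid, *_split(mid)) for mid in calls_by_marker]
    calls = pd.DataFrame(calls_by_marker, index=individuals)
    return MarkerGenotypeMatrix(
        markers=markers,
        calls=calls,
        sex=pd.Series(sexes, index=individuals),
    )


def _split(marker_id):
    chrom, _, pos = marker_id.rpartition("_")
    return chrom, int(pos)


class TestMarkerSexAssociation:
    def test_perfect_cosegregation(self):
        sexes = [SexPhenotype.FEMALE] * 8 + [SexPhenotype.HERMAPHRODITE] * 33
        calls = ["T"] * 8 + ["G/T"] * 22 + ["G"] * 11
        m = _matrix({"Fvb6_35142280": calls}, sexes)
        res, flag = marker_sex_association(m, "Fvb6_35142280")
        assert flag
        assert res.p_value < 1e-7

    def test_balanced_marker_no_association(self):
        sexes = [SexPhenotype.FEMALE] * 4 + [SexPhenotype.HERMAPHRODITE] * 4
        calls = ["T", "T", "G", "G", "T", "T", "G", "G"]
        m = _matrix({"Fvb6_100": calls}, sexes)
        res, flag = marker_sex_association(m, "Fvb6_100")
        assert not flag
        assert res.p_value == pytest.approx(1.0)

    def test_missing_calls_dropped(self):
        sexes = [SexPhenotype.FEMALE] * 3 + [SexPhenotype.HERMAPHRODITE] * 3
        calls = ["T", "T", ".", "G/T", "G", "G"]
        m = _matrix({"Fvb6_100": calls}, sexes)
        res, flag = marker_sex_association(m, "Fvb6_100")
        assert flag  # perfect on the non-missing calls

    def test_monomorphic_not_applied(self):
        sexes = [SexPhenotype.FEMALE] * 2 + [SexPhenotype.HERMAPHRODITE] * 2
        m = _matrix({"Fvb6_100": ["T"] * 4}, sexes)
        res, flag = marker_sex_association(m, "Fvb6_100")
        assert not res.applied and not flag


def test_pvalue_adjustment_methods():
    p = [0.01, 0.02, 0.5]
    assert adjust_pvalues(p) == p
    assert adjust_pvalues(p, "bonferroni") == [0.03, 0.06, 1.0]
    bh = adjust_pvalues(p, "bh")
    assert bh[0] == pytest.approx(0.03) and bh[2] == pytest.approx(0.5)
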