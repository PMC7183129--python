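import numpy as np
import pytest
from scipy.stats import norm

from dqrules.assessment import (AssessmentResult, HospitalRuleStat,
                                PairwiseDiffStat, assess,
                                eligible_hospitals, hospital_rule_stats,
                                pairwise_diff_interval, rank_rules,
                                rule_bias, rule_variance,
                                variance_from_pairs, wilson_interval)
from dqrules.records import DischargeRecord


def make_stat(hospital_id, k, n, lower=None, upper=None, group="teaching",
              rule_id="r1"):
    if lower is None:
        lower, upper = wilson_interval(k, n)
    return HospitalRuleStat(hospital_id=hospital_id, group=group,
                            rule_id=rule_id, n=n, k=k, ci_lower=lower,
                            ci_upper=upper)


def stat_with_range(hospital_id, confidence, ci_range, n=1000, **kw):
    """Stat with an exact confidence and an imposed CI width."""
    k = round(confidence * n)
    lower = max(0.0, confidence - ci_range / 2)
    return make_stat(hospital_id, k, n, lower=lower,
                     upper=lower + ci_range, **kw)


class TestWilson:
    def test_closed_form_fixture(self):
        lower, upper = wilson_interval(5, 10)
        assert lower == pytest.approx(0.2366, abs=5e-5)
        assert upper == pytest.approx(0.7634, abs=5e-5)

    def test_k_zero_lower_exactly_zero(self):
        lower, upper = wilson_interval(0, 10)
        assert lower == 0.0 and 0 < upper < 1

    def test_boundary_counts(self):
        # at k = n the upper bound is exactly 1 and the lower bound
        # stays strictly inside (0, 1); symmetric at k = 0
        for n in (1, 5, 50, 5000):
            lower, upper = wilson_interval(n, n)
            assert upper == pytest.approx(1.0, abs=1e-12)
            assert 0 < lower < 1
            lower0, upper0 = wilson_interval(0, n)
            assert lower0 == pytest.approx(0.0, abs=1e-12)
            assert 0 < upper0 < 1

    def test_width_shrinks_with_n_at_fixed_proportion(self):
        widths = [np.diff(wilson_interval(3 * n, 10 * n))[0]
                  for n in (1, 2, 5, 20, 100)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            expected = proportion_confint(k, n, method="wilson")
            np.testing.assert_allclose(wilson_interval(k, n), expected,
                                       atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 3)


class TestEligibleHospitals:
    def _records(self, volumes):
        out, rid = [], 0
        for hospital, v in volumes.items():
            for _ in range(v):
                out.append(DischargeRecord(rid, hospital, 70,
                                           frozenset({"I21"})))
                rid += 1
        return out

    def test_strict_volume_bound(self):
        records = self._records({"A": 1000, "B": 1001, "C": 50})
        assert eligible_hospitals(records, 1000) == frozenset({"B"})

    def test_none_qualify(self):
        records = self._records({"A": 10})
        assert eligible_hospitals(records) == frozenset()
        result = assess([], records, {"A": "teaching"})
        assert result.biases == [] and result.variances == []


class TestBias:
    def test_worked_fixture(self):
        stats = [stat_with_range("H1", 0.3, 0.2),
                 stat_with_range("H2", 0.5, 0.1)]
        result = rule_bias(stats, reference_confidence=0.5)
        assert result.bias == pytest.approx(0.16)
        assert dict(result.contributions)["H1"] == pytest.approx(0.16)
        assert dict(result.contributions)["H2"] == pytest.approx(0.0)

    def test_zero_when_all_match_reference(self):
        stats = [stat_with_range(f"H{i}", 0.4, 0.1) for i in range(4)]
        assert rule_bias(stats, 0.4).bias == 0.0

    def test_narrower_intervals_never_decrease_bias(self):
        stats = [stat_with_range("H1", 0.3, 0.2),
                 stat_with_range("H2", 0.6, 0.3)]
        halved = [stat_with_range("H1", 0.3, 0.1),
                  stat_with_range("H2", 0.6, 0.15)]
        assert rule_bias(halved, 0.5).bias >= rule_bias(stats, 0.5).bias

    def test_undefined_without_usable_hospitals(self):
        insufficient = HospitalRuleStat("H1", "teaching", "r1", 2, 1,
                                        0.0, 1.0, sufficient=False)
        result = rule_bias([insufficient], 0.5)
        assert not result.defined

    def test_reference_out_of_range(self):
        with pytest.raises(ValueError):
            rule_bias([stat_with_range("H1", 0.3, 0.2)], 1.5)


class TestVariance:
    def test_worked_fixture(self):
        # three hospitals at 0.2/0.4/0.6, every pairwise range 0.5
        pairs = [PairwiseDiffStat(("H1", "H2"), -0.2, -0.45, 0.05),
                 PairwiseDiffStat(("H1", "H3"), -0.4, -0.65, -0.15),
                 PairwiseDiffStat(("H2", "H3"), -0.2, -0.45, 0.05)]
        result = variance_from_pairs("r1", "teaching", pairs)
        assert result.variance == pytest.approx(1.2)

    def test_zero_when_confidences_equal(self):
        stats = [make_stat(f"H{i}", 30, 100) for i in range(3)]
        assert rule_variance(stats).variance == pytest.approx(0.0)

    def test_duplicate_hospital_never_decreases_variance(self):
        stats = [make_stat("H1", 30, 100), make_stat("H2", 60, 100)]
        more = stats + [make_stat("H3", 60, 100)]
        assert rule_variance(more).variance \
            >= rule_variance(stats).variance

    def test_undefined_below_two_hospitals(self):
        assert not rule_variance([make_stat("H1", 30, 100)]).defined

    def test_contribution_weights_in_algebraic_range(self):
        stats = [make_stat("H1", 30, 200), make_stat("H2", 90, 200),
                 make_stat("H3", 10, 200)]
        result = rule_variance(stats)
        for pair in result.pairs:
            assert 0.0 < 2.0 - pair.ci_range <= 2.0


class TestPairwiseInterval:
    def test_group_of_two_equals_two_proportion_score_interval(self):
        s1, s2 = make_stat("H1", 30, 120), make_stat("H2", 50, 160)
        lo, hi = pairwise_diff_interval(s1, s2, group_size=2)
        z = norm.ppf(0.975)
        pooled = (30 + 50) / (120 + 160)
        se = np.sqrt(pooled * (1 - pooled) * (1 / 120 + 1 / 160))
        diff = 30 / 120 - 50 / 160
        assert lo == pytest.approx(diff - z * se, abs=1e-6)
        assert hi == pytest.approx(diff + z * se, abs=1e-6)

    def test_identical_stats_centered_at_zero(self):
        s = make_stat("H1", 40, 100)
        lo, hi = pairwise_diff_interval(s, make_stat("H2", 40, 100), 3)
        assert lo == pytest.approx(-hi)

    def test_width_grows_with_group_size(self):
        s1, s2 = make_stat("H1", 30, 120), make_stat("H2", 50, 160)
        widths = [np.diff(pairwise_diff_interval(s1, s2, k))[0]
                  for k in (2, 3, 5, 8)]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_group_size_below_two_rejected(self):
        s = make_stat("H1", 40, 100)
        with pytest.raises(ValueError):
            pairwise_diff_interval(s, s, 1)


class TestHospitalRuleStats:
    def _records(self):
        out, rid = [], 0
        for hospital, (n_both, n_lhs_only) in {
                "A": (40, 10), "B": (20, 30), "C": (2, 1)}.items():
            for _ in range(n_both):
                out.append(DischargeRecord(rid, hospital, 70,
                                           frozenset({"I21.0", "E11.2"})))
                rid += 1
            for _ in range(n_lhs_only):
                out.append(DischargeRecord(rid, hospital, 70,
                                           frozenset({"I21.0"})))
                rid += 1
        return out

    def _rule(self):
        from dqrules.mining import AssociationRule
        return AssociationRule("r1", frozenset({"I21"}), "E11", "65+", 3,
                               joint_count=60, lhs_count=103, n=103)

    def test_counts_and_sufficiency(self):
        groups = {"A": "teaching", "B": "teaching", "C": "teaching"}
        stats = hospital_rule_stats([self._rule()], self._records(),
                                    groups)
        by_id = {s.hospital_id: s for s in stats}
        assert (by_id["A"].n, by_id["A"].k) == (50, 40)
        assert by_id["B"].confidence == pytest.approx(0.4)
        assert not by_id["C"].sufficient  # below the LHS count floor

    def test_lhs_never_occurring_flagged(self):
        from dqrules.mining import AssociationRule
        rule = AssociationRule("r2", frozenset({"K21"}), "E11", "65+", 3,
                               joint_count=1, lhs_count=1, n=10)
        stats = hospital_rule_stats([rule], self._records(),
                                    {h: "teaching" for h in "ABC"})
        assert all(not s.sufficient and s.n == 0 for s in stats)

    def test_unlabelled_hospital_rejected(self):
        with pytest.raises(ValueError, match="without group"):
            hospital_rule_stats([self._rule()], self._records(),
                                {"A": "teaching"})


class TestRanking:
    def _results(self, values, group="teaching"):
        biases = [rule_bias([stat_with_range("H1", 0.5, 0.1,
                                             rule_id=rid)], ref)
                  for rid, ref in values.items()]
        return AssessmentResult(biases=biases, variances=[], stats=[])

    def test_descending_with_rule_id_tie_break(self):
        # references chosen so bias(r_a)=bias(r_c)=0.18, bias(r_b)=0.09
        results = self._results({"r_c": 0.3, "r_a": 0.3, "r_b": 0.4})
        ranked = rank_rules(results, "bias", top_k=5)["teaching"]
        assert [r.rule_id for r in ranked] == ["r_a", "r_c", "r_b"]

    def test_top_k_truncation_and_short_groups(self):
        results = self._results({f"r{i}": 0.3 for i in range(3)})
        assert len(rank_rules(results, "bias", top_k=2)["teaching"]) == 2
        assert len(rank_rules(results, "bias", top_k=9)["teaching"]) == 3

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            rank_rules(AssessmentResult([], [], []), "lift")
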