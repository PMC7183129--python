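import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dqrules.filtering import (ContingencyTable, association_test,
                               bh_adjust, contingency_for,
                               dagger_asterisk_filter, prune_nested,
                               run_cascade, significance_filter,
                               split_records, stability_filter)
from dqrules.icd import AsteriskRegistry
from dqrules.mining import AssociationRule, TransactionDB
from dqrules.records import DischargeRecord


def make_rule(rule_id, lhs, rhs, joint, lhs_count, n=1000,
              age_group="65+", level=3):
    return AssociationRule(rule_id=rule_id, lhs=frozenset(lhs), rhs=rhs,
                           age_group=age_group, level=level,
                           joint_count=joint, lhs_count=lhs_count, n=n)


def db_from(itemsets, age_group="65+", level=3):
    return TransactionDB(age_group=age_group, level=level,
                         transactions=tuple((i, frozenset(s))
                                            for i, s in
                                            enumerate(itemsets)))


class TestSplit:
    def _records(self, n):
        return [DischargeRecord(i, "H1", 70, frozenset({"I21"}))
                for i in range(n)]

    def test_floor_rounding(self):
        train, val = split_records(self._records(10), 0.7, seed=1)
        assert (len(train), len(val)) == (7, 3)

    def test_deterministic(self):
        records = self._records(50)
        assert split_records(records, 0.7, 4) == split_records(records,
                                                               0.7, 4)

    def test_partition_laws(self):
        records = self._records(37)
        train, val = split_records(records, 0.7, seed=2)
        assert sorted(r.record_id for r in train + val) == list(range(37))
        assert not {r.record_id for r in train} & {r.record_id
                                                   for r in val}

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_records(self._records(1), 0.7, 1)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_records(self._records(10), 1.0, 1)


class TestPruneNested:
    def test_close_confidences_keep_simpler(self):
        simple = make_rule("a", {"X"}, "Y", 50, 100)     # conf 0.50
        nested = make_rule("b", {"X", "Z"}, "Y", 33, 60)  # conf 0.55
        kept, report = prune_nested([simple, nested], 0.1)
        assert [r.rule_id for r in kept] == ["a"]
        assert report.stages[0].removals == [("b", "nested")]

    def test_distant_confidences_keep_both(self):
        simple = make_rule("a", {"X"}, "Y", 50, 100)     # conf 0.50
        nested = make_rule("b", {"X", "Z"}, "Y", 39, 60)  # conf 0.65
        kept, _ = prune_nested([simple, nested], 0.1)
        assert {r.rule_id for r in kept} == {"a", "b"}

    def test_different_rhs_never_pruned(self):
        r1 = make_rule("a", {"X"}, "Y", 50, 100)
        r2 = make_rule("b", {"X", "Z"}, "W", 30, 60)
        kept, _ = prune_nested([r1, r2], 0.1)
        assert len(kept) == 2

    def test_transitive_fixpoint(self):
        # A kills AB (diff .08); ABC survives A (diff .16) and its
        # would-be protector AB is gone, so the comparison set shrinks.
        a = make_rule("a", {"X"}, "Y", 50, 100)            # 0.50
        ab = make_rule("ab", {"X", "Z"}, "Y", 29, 50)      # 0.58
        abc = make_rule("abc", {"X", "Z", "W"}, "Y", 33, 50)  # 0.66
        kept, _ = prune_nested([a, ab, abc], 0.1)
        assert {r.rule_id for r in kept} == {"a", "abc"}

    def test_matches_recursive_oracle_and_input_order(self):
        """Survivorship equals the recursive definition — a rule dies
        iff some *surviving* strict-subset rule with the same RHS has a
        close confidence — and does not depend on input order."""
        rng = np.random.default_rng(17)
        codes = ["A", "B", "C", "D", "E"]
        for trial in range(50):
            rules = []
            for i in range(rng.integers(3, 20)):
                size = int(rng.integers(1, 4))
                lhs = frozenset(str(c) for c in
                                rng.choice(codes, size=size,
                                           replace=False))
                lhs_count = int(rng.integers(20, 200))
                joint = int(rng.integers(1, lhs_count + 1))
                rules.append(make_rule(f"r{i}", lhs, "Y", joint,
                                       lhs_count))
            kept = {r.rule_id for r in prune_nested(rules, 0.1)[0]}

            survives = {}

            def check(r):
                if r.rule_id not in survives:
                    survives[r.rule_id] = not any(
                        s.lhs < r.lhs and s.rhs == r.rhs
                        and abs(s.confidence - r.confidence) < 0.1
                        and check(s)
                        for s in rules)
                return survives[r.rule_id]

            assert kept == {r.rule_id for r in rules if check(r)}

            shuffled = list(rules)
            rng.shuffle(shuffled)
            assert kept == {r.rule_id
                            for r in prune_nested(shuffled, 0.1)[0]}


class TestAssociationTest:
    def test_chi_squared_fixture(self):
        result = association_test(ContingencyTable(30, 10, 20, 40))
        assert result.method == "chi-squared"
        assert result.statistic == pytest.approx(16.667, abs=1e-3)
        assert result.p_value == pytest.approx(4.45e-5, rel=1e-2)

    def test_fisher_fixture(self):
        result = association_test(ContingencyTable(3, 0, 0, 3))
        assert result.method == "fisher"
        assert result.p_value == pytest.approx(0.10, abs=1e-9)

    def test_independent_margins(self):
        result = association_test(ContingencyTable(25, 25, 25, 25))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            result = association_test(ContingencyTable(5, 0, 5, 0))
        assert result.p_value == 1.0 and result.degenerate

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            association_test(ContingencyTable(0, 0, 0, 0))


class TestContingency:
    def test_constructed_fixture(self):
        items = ([{"X", "Y"}] * 30 + [{"X"}] * 10 + [{"Y"}] * 20
                 + [{"W"}] * 40)
        db = db_from(items)
        rule = make_rule("r", {"X"}, "Y", 30, 40, n=100)
        table = contingency_for(rule, db)
        assert (table.a, table.b, table.c, table.d) == (30, 10, 20, 40)
        assert table.a == rule.joint_count

    def test_degenerate_all_present(self):
        db = db_from([{"X", "Y"}] * 5)
        table = contingency_for(make_rule("r", {"X"}, "Y", 5, 5, n=5), db)
        assert (table.a, table.b, table.c, table.d) == (5, 0, 0, 0)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_definition(self, p_values):
        adjusted = bh_adjust(p_values)
        m = len(p_values)
        order = sorted(range(m), key=lambda i: p_values[i])
        # literal step-up: adj(i) = min over j >= i of p(j)*m/(j+1)
        for rank, idx in enumerate(order):
            expected = min(min(1.0, p_values[order[j]] * m / (j + 1))
                           for j in range(rank, m))
            assert adjusted[idx] == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestSignificanceFilter:
    def test_family_of_one_is_unadjusted(self):
        db = db_from([{"X", "Y"}] * 30 + [{"X"}] * 10 + [{"Y"}] * 20
                     + [{"W"}] * 40)
        rule = make_rule("r", {"X"}, "Y", 30, 40, n=100)
        kept, _ = significance_filter([rule], db, alpha=0.05)
        assert kept == [rule]
        assert rule.p_adjusted == pytest.approx(rule.p_value)

    def test_rare_never_cooccurring_rule_removed(self):
        items = ([{"X"}] * 5 + [{"Y"}] * 5 + [{"W"}] * 990)
        db = db_from(items)
        rule = make_rule("r", {"X"}, "Y", 0, 5, n=1000)
        kept, report = significance_filter([rule], db)
        assert kept == []
        assert report.stages[0].removals == [("r", "non-significant")]

    def test_strong_planted_rule_retained(self):
        rng = np.random.default_rng(8)
        items = []
        for _ in range(5000):
            s = set()
            if rng.random() < 0.3:
                s.add("X")
                if rng.random() < 0.8:
                    s.add("Y")
            elif rng.random() < 0.05:
                s.add("Y")
            s.add("Z")
            items.append(s)
        db = db_from(items)
        joint = db.count({"X", "Y"})
        lhs = db.count({"X"})
        rule = make_rule("r", {"X"}, "Y", joint, lhs, n=db.n)
        kept, _ = significance_filter([rule], db)
        assert kept == [rule]
        assert rule.p_adjusted < 1e-10


class TestStabilityFilter:
    def _val_db(self, conf, n_lhs=100):
        k = round(conf * n_lhs)
        items = [{"X", "Y"}] * k + [{"X"}] * (n_lhs - k) + [{"W"}] * 50
        return db_from(items)

    def test_large_difference_removed(self):
        rule = make_rule("r", {"X"}, "Y", 30, 100)  # train conf 0.30
        kept, report = stability_filter([rule], self._val_db(0.37))
        assert kept == []
        assert report.stages[0].removals == [("r", "unstable")]

    def test_small_difference_retained(self):
        rule = make_rule("r", {"X"}, "Y", 30, 100)
        kept, _ = stability_filter([rule], self._val_db(0.33))
        assert kept == [rule]
        assert rule.confidence_validation == pytest.approx(0.33)

    def test_validation_equals_training_keeps_all(self):
        rule = make_rule("r", {"X"}, "Y", 30, 100)
        kept, _ = stability_filter([rule], self._val_db(0.30))
        assert kept == [rule]

    def test_lhs_absent_in_validation(self):
        rule = make_rule("r", {"Q"}, "Y", 30, 100)
        kept, report = stability_filter([rule], self._val_db(0.3))
        assert kept == []
        assert report.stages[0].removals == [
            ("r", "unsupported-in-validation")]


class TestDaggerAsteriskFilter:
    def test_empty_registry_removes_nothing(self):
        rule = make_rule("r", {"A17"}, "G01", 30, 40)
        kept, _ = dagger_asterisk_filter([rule], AsteriskRegistry())
        assert kept == [rule]

    def test_pairing_match_removed_either_direction(self):
        registry = AsteriskRegistry(asterisk_codes=frozenset({"G01"}),
                                    pairings=frozenset({("A17", "G01")}))
        forward = make_rule("f", {"A17"}, "G01", 30, 40)
        backward = make_rule("b", {"G01"}, "A17", 30, 40)
        kept, report = dagger_asterisk_filter([forward, backward],
                                              registry)
        assert kept == []
        assert {r for _, r in report.stages[0].removals} == {
            "dagger-asterisk"}

    def test_four_character_dagger_matches_category_pairing(self):
        registry = AsteriskRegistry(asterisk_codes=frozenset({"G01"}),
                                    pairings=frozenset({("A17", "G01")}))
        rule = make_rule("r", {"A17.0"}, "G01", 30, 40, level=4)
        kept, _ = dagger_asterisk_filter([rule], registry)
        assert kept == []

    def test_unpaired_asterisk_kept_unless_strict(self):
        registry = AsteriskRegistry(asterisk_codes=frozenset({"G01"}),
                                    pairings=frozenset())
        rule = make_rule("r", {"I21"}, "G01", 30, 40)
        assert dagger_asterisk_filter([rule], registry)[0] == [rule]
        assert dagger_asterisk_filter([rule], registry,
                                      strict=True)[0] == []

    def test_rule_without_registry_codes_kept(self):
        registry = AsteriskRegistry(asterisk_codes=frozenset({"G01"}),
                                    pairings=frozenset({("A17", "G01")}))
        rule = make_rule("r", {"I21"}, "E11", 30, 40)
        assert dagger_asterisk_filter([rule], registry)[0] == [rule]


class TestCascade:
    def test_monotone_and_reconciled(self, study_records, study_config):
        from dqrules.mining import (build_transactions, derive_rules,
                                    mine_frequent_itemsets)
        from dqrules.synthetic import default_registry

        train, val = split_records(study_records[:8000], 0.7,
                                   seed=study_config.seed)
        train_db = build_transactions(train, 3, "65+")
        val_db = build_transactions(val, 3, "65+")
        mined = derive_rules(mine_frequent_itemsets(train_db, 20, 3),
                             train_db, 0.05, 20)
        kept, report = run_cascade(mined, train_db, val_db,
                                   default_registry())
        n = len(mined)
        mined_ids = {r.rule_id for r in mined}
        for stage in report.stages:
            assert stage.n_input == stage.n_removed + stage.n_retained
            assert stage.n_input == n
            n = stage.n_retained
        assert n == len(kept)
        assert {r.rule_id for r in kept} <= mined_ids
        # survivors carry the metrics the cascade asserts on
        for r in kept:
            assert r.p_adjusted is not None and r.p_adjusted < 0.05
            assert r.confidence_validation is not None
            assert abs(r.confidence - r.confidence_validation) <= 0.05
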