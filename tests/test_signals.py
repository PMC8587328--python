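"""PRR signal mechanics: entailment, the 2x2 tabulation, and bias under
generalization."""

import pytest

from srsanon import (
    ADRRule,
    PublishedRecord,
    SRSRecord,
    condition_entails,
    evaluate_rule,
    make_qid,
    prr,
    signal_bias,
)

from conftest import record

RULE_AGE = ADRRule(drug="avandia", reaction="MI", attribute="Age", op=">", value=18)


@pytest.fixture(scope="module")
def wide_schema():
    from srsanon import AttributeSchema, binary_gender_tree

    return (
        AttributeSchema(name="Sex", kind="categorical", taxonomy=binary_gender_tree()),
        AttributeSchema(name="Age", kind="numeric", global_min=0, global_max=100),
    )


class TestEntailment:
    def test_generalized_sex_misses_female_condition(self, wide_schema):
        rule = ADRRule(drug="zelnorm", reaction="CVA", attribute="Sex", op="==", value="Female")
        assert not condition_entails(wide_schema, make_qid(wide_schema, ("ANY", 30)), rule)
        assert condition_entails(wide_schema, make_qid(wide_schema, ("Female", 30)), rule)

    def test_interval_entirely_above_threshold(self, wide_schema):
        q = make_qid(wide_schema, ("Male", (30, 35)))
        assert condition_entails(wide_schema, q, RULE_AGE)

    def test_straddling_interval_not_entailed(self, wide_schema):
        q = make_qid(wide_schema, ("Male", (15, 25)))
        assert not condition_entails(wide_schema, q, RULE_AGE)

    def test_generalization_never_gains_entailment(self, wide_schema):
        """Widening an interval can only lose condition entailment."""
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(200):
            age = int(rng.integers(0, 101))
            widen = int(rng.integers(0, 30))
            leaf = make_qid(wide_schema, ("Male", age))
            wide = make_qid(wide_schema, ("Male", (max(0, age - widen), min(100, age + widen))))
            if condition_entails(wide_schema, wide, RULE_AGE):
                assert condition_entails(wide_schema, leaf, RULE_AGE)


class TestPRR:
    def test_hand_arithmetic(self):
        assert prr(4, 6, 16, 74) == pytest.approx(2.25)

    def test_forced_zero_below_three_reports(self):
        assert prr(2, 0, 0, 0) == 0.0

    def test_no_disproportionality_is_one(self):
        assert prr(5, 5, 50, 50) == pytest.approx(1.0)

    def test_scale_invariant(self):
        assert prr(4, 6, 16, 74) == pytest.approx(prr(8, 12, 32, 148))

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            prr(3, 0, 0, 0)


class TestEvaluateRule:
    def _dataset(self, schema):
        rows = []
        cid = 1
        # adults: 4 drug+reaction, 6 drug only, 16 reaction only, 74 neither
        for n, drugs, sens in [(4, {"Avandia"}, {"MI"}), (6, {"Avandia"}, {"X"}),
                               (16, {"Other"}, {"MI"}), (74, {"Other"}, {"X"})]:
            for _ in range(n):
                rows.append(record(schema, cid, 1, ("Male", 40), sens, drugs))
                cid += 1
        # minors: never enter the table
        rows.append(record(schema, cid, 1, ("Male", 10), {"MI"}, {"Avandia"}))
        return rows

    def test_matches_direct_tabulation(self, wide_schema):
        res = evaluate_rule(wide_schema, self._dataset(wide_schema), RULE_AGE)
        assert (res.a, res.b, res.c, res.d) == (4, 6, 16, 74)
        assert res.prr == pytest.approx(2.25)
        assert res.valid

    def test_case_folding_on_names(self, wide_schema):
        rule = ADRRule(drug="AVANDIA", reaction="mi", attribute="Age", op=">", value=18)
        res = evaluate_rule(wide_schema, self._dataset(wide_schema), rule)
        assert res.a == 4

    def test_same_case_rows_count_once(self, wide_schema):
        rows = [record(wide_schema, 1, 1, ("Male", 40), {"MI"}, {"Avandia"}),
                record(wide_schema, 1, 1, ("Male", 40), {"Rash"}, {"Avandia"}),
                record(wide_schema, 2, 1, ("Male", 40), {"MI"}, {"Other"}),
                record(wide_schema, 3, 1, ("Male", 40), {"X"}, {"Other"})]
        res = evaluate_rule(wide_schema, rows, RULE_AGE)
        assert (res.a, res.b, res.c, res.d) == (1, 0, 1, 1)

    def test_fully_generalized_subpopulation_rejected(self, wide_schema):
        rule = ADRRule(drug="zelnorm", reaction="CVA", attribute="Sex", op="==", value="Female")
        rows = [PublishedRecord(case_id=c, quarter=1,
                                qid=make_qid(wide_schema, ("ANY", (20, 60))),
                                drugs=frozenset({"zelnorm"}), sensitive=frozenset({"CVA"}))
                for c in range(1, 6)]
        with pytest.raises(ValueError):
            evaluate_rule(wide_schema, rows, rule)  # everyone drops out

    def test_brute_force_row_scan_agreement(self, wide_schema):
        """Cross-check against an independent per-row scan on a random set."""
        import numpy as np

        rng = np.random.default_rng(3)
        rows = []
        for c in range(1, 401):
            age = int(rng.integers(0, 101))
            drugs = {"Avandia"} if rng.random() < 0.2 else {"Other"}
            sens = {"MI"} if rng.random() < 0.15 else {"Y"}
            rows.append(record(wide_schema, c, 1, ("Male", age), sens, drugs))
        res = evaluate_rule(wide_schema, rows, RULE_AGE)
        a = b = c_ = d = 0
        for r in rows:
            if not r.qid[1][0] > 18:
                continue
            hd = "avandia" in {x.lower() for x in r.drugs}
            hr = "mi" in {x.lower() for x in r.sensitive}
            a, b, c_, d = a + (hd and hr), b + (hd and not hr), \
                c_ + (hr and not hd), d + (not hd and not hr)
        assert (res.a, res.b, res.c, res.d) == (a, b, c_, d)


class TestSignalBias:
    def test_identity_anonymization_is_unbiased(self, wide_schema):
        rows = TestEvaluateRule()._dataset(wide_schema)
        assert signal_bias(wide_schema, rows, rows, RULE_AGE) == (0, pytest.approx(0.0))

    def test_losing_one_count_below_three_kills_the_signal(self, wide_schema):
        """A rare rule at a = 3 with a strong PRR: generalizing one report out
        of the condition invalidates it outright (PRR forced to 0)."""
        rule = ADRRule(drug="Zelnorm", reaction="CVA", attribute="Age", op=">", value=18)
        raw = []
        cid = 1
        for n, drugs, sens in [(3, {"Zelnorm"}, {"CVA"}), (5, {"Zelnorm"}, {"X"}),
                               (10, {"Other"}, {"CVA"}), (180, {"Other"}, {"X"})]:
            for _ in range(n):
                raw.append(record(wide_schema, cid, 1, ("Male", 40), sens, drugs))
                cid += 1
        raw_res = evaluate_rule(wide_schema, raw, rule)
        assert raw_res.a == 3 and raw_res.prr > 2
        anon = [PublishedRecord(case_id=r.case_id, quarter=1,
                                qid=make_qid(wide_schema, ("Male", (10, 60)))
                                if r.case_id == 1 else r.qid,
                                drugs=r.drugs, sensitive=r.sensitive)
                for r in raw]
        cd, prrd = signal_bias(wide_schema, raw, anon, rule)
        assert cd == -1
        assert prrd == pytest.approx(-raw_res.prr)

    def test_root_generalization_loses_all_counts(self, wide_schema):
        rule = ADRRule(drug="zelnorm", reaction="CVA", attribute="Sex", op="==", value="Female")
        raw = [record(wide_schema, c, 1, ("Female", 40),
                      {"CVA"} if c <= 4 else {"X"}, {"Zelnorm"}) for c in range(1, 11)]
        raw += [record(wide_schema, 100 + c, 1, ("Female", 40), {"CVA"}, {"Other"})
                for c in range(12)]
        anon = [PublishedRecord(case_id=r.case_id, quarter=1,
                                qid=make_qid(wide_schema, ("ANY", (20, 60)))
                                if r.case_id <= 2 else r.qid,
                                drugs=r.drugs, sensitive=r.sensitive) for r in raw]
        cd, _ = signal_bias(wide_schema, raw, anon, rule)
        assert cd == -2
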