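import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxp.errors import ValidationError
from gxp.ora import (
    Clause,
    ContingencyTable,
    SelectionCriterion,
    adjust_pvalues,
    build_term_index,
    fisher_exact_greater,
    hypergeom_pmf,
    run_ora,
    select_entities,
)
from oracles import bh_adjust_reference, bonferroni_reference, fisher_greater_exact


class TestSelectEntities:
    def test_numeric_less_than(self, tiny_info):
        crit = SelectionCriterion(clauses=[Clause("log2FC", "<", 0.0)])
        assert select_entities(tiny_info, crit) == {"g1"}

    def test_missing_numeric_never_satisfies(self, tiny_info):
        crit = SelectionCriterion(clauses=[Clause("log2FC", "<", 100.0)])
        assert "g3" not in select_entities(tiny_info, crit)

    def test_explicit_list_with_unknown_id_warns(self, tiny_info):
        crit = SelectionCriterion(id_list=["g1", "gX"])
        with pytest.warns(UserWarning, match="gX"):
            assert select_entities(tiny_info, crit) == {"g1"}

    def test_and_equals_intersection(self, tiny_info):
        c1 = Clause("log2FC", ">", -5.0)
        c2 = Clause("description", "contains", "protein")
        both = select_entities(tiny_info, SelectionCriterion(clauses=[c1, c2]))
        s1 = select_entities(tiny_info, SelectionCriterion(clauses=[c1]))
        s2 = select_entities(tiny_info, SelectionCriterion(clauses=[c2]))
        assert both == s1 & s2

    def test_categorical_equality_uses_split_values(self, tiny_info):
        crit = SelectionCriterion(clauses=[Clause("bin", "=", "9.1")])
        assert select_entities(tiny_info, crit) == {"g1"}

    def test_unknown_column(self, tiny_info):
        with pytest.raises(ValidationError, match="nope"):
            select_entities(tiny_info, SelectionCriterion(clauses=[Clause("nope", "<", 1)]))

    def test_criterion_needs_exactly_one_form(self):
        with pytest.raises(ValidationError):
            SelectionCriterion()


class TestTermIndex:
    def test_multivalue_cell_in_both_terms(self, tiny_info):
        idx = build_term_index(tiny_info, "bin")
        assert "g1" in idx.terms["1.1"]
        assert "g1" in idx.terms["9.1"]

    def test_pair_count_conservation(self, tiny_info):
        idx = build_term_index(tiny_info, "bin")
        pairs = sum(len(col.split_cell(i)) for col in [tiny_info.columns["bin"]]
                    for i in range(3))
        assert sum(len(s) for s in idx.terms.values()) == pairs

    def test_empty_cells_contribute_nothing(self, tiny_info):
        idx = build_term_index(tiny_info, "bin")
        assert all("g3" not in s for s in idx.terms.values())

    def test_planted_term_frequencies(self, ora_bundle):
        idx = build_term_index(ora_bundle.info, "mapman_bin")
        enriched = ora_bundle.truth["enriched"]
        expect = set(enriched["selected_members"]) | set(enriched["background_members"])
        assert idx.terms[enriched["term"]] == expect

    def test_numeric_column_rejected(self, tiny_info):
        with pytest.raises(ValidationError):
            build_term_index(tiny_info, "log2FC")


class TestHypergeomPmf:
    def test_hand_value(self):
        assert hypergeom_pmf(4, 4, 4, 8) == pytest.approx(1 / 70, abs=1e-15)

    def test_degenerate_certainty(self):
        assert hypergeom_pmf(0, 0, 5, 10) == pytest.approx(1.0)

    @given(
        st.integers(min_value=1, max_value=25),
        st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, N, data):
        K = data.draw(st.integers(min_value=0, max_value=N))
        n = data.draw(st.integers(min_value=0, max_value=N))
        total = sum(hypergeom_pmf(k, K, n, N) for k in range(0, n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_rational(self):
        for (k, K, n, N) in [(2, 5, 4, 12), (0, 3, 3, 9), (3, 3, 3, 6)]:
            from oracles import hypergeom_pmf_exact

            assert hypergeom_pmf(k, K, n, N) == pytest.approx(
                float(hypergeom_pmf_exact(k, K, n, N)), abs=1e-14
            )

    def test_domain_violation(self):
        with pytest.raises(ValidationError):
            hypergeom_pmf(1, 5, 4, 3)


class TestFisherExactGreater:
    def test_worked_example(self):
        p = fisher_exact_greater(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(17 / 70, abs=1e-12)

    def test_a_zero_bounded_by_one(self):
        p = fisher_exact_greater(ContingencyTable(0, 10, 5, 15))
        assert 0 < p <= 1.0

    def test_full_term_no_enrichment(self):
        # term annotates everything: only one table possible, p = 1
        p = fisher_exact_greater(ContingencyTable(4, 0, 6, 0))
        assert p == pytest.approx(1.0)

    def test_exhaustive_small_tables(self):
        # all tables with N <= 14 here; the N <= 30 sweep runs in acceptance
        for N in range(1, 15):
            for a in range(N + 1):
                for b in range(N - a + 1):
                    for c in range(N - a - b + 1):
                        d = N - a - b - c
                        got = fisher_exact_greater(ContingencyTable(a, b, c, d))
                        want = float(fisher_greater_exact(a, b, c, d))
                        assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_a_with_fixed_margins(self):
        # shifting one unit from b,c into a,d makes the table more extreme
        prev = 1.1
        for a in range(0, 6):
            t = ContingencyTable(a, 5 - a, 5 - a, 5 + a)
            p = fisher_exact_greater(t)
            assert p <= prev + 1e-15
            prev = p

    def test_never_zero(self):
        p = fisher_exact_greater(ContingencyTable(500, 0, 0, 500))
        assert p > 0.0


class TestAdjustPvalues:
    def test_bonferroni_definition(self):
        assert adjust_pvalues([0.01, 0.5, 1.0, 0.2, 0.03], "bonferroni")[0] == pytest.approx(0.05)

    def test_bh_hand_computed(self):
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini_hochberg")
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_empty_list(self):
        assert adjust_pvalues([], "bonferroni") == []

    def test_output_order_matches_input(self):
        p = [0.04, 0.01, 0.9, 0.2]
        adj = adjust_pvalues(p, "benjamini_hochberg")
        ref = bh_adjust_reference(p)
        assert adj == pytest.approx(ref)

    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_bh_matches_reference_and_dominates_raw(self, pvals):
        adj = adjust_pvalues(pvals, "benjamini_hochberg")
        ref = bh_adjust_reference(pvals)
        assert adj == pytest.approx(ref, abs=1e-12)
        assert all(a >= p - 1e-15 for a, p in zip(adj, pvals))
        assert all(a <= 1.0 for a in adj)
        assert adjust_pvalues(pvals, "bonferroni") == pytest.approx(
            bonferroni_reference(pvals)
        )

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.0], "bonferroni")


class TestRunOra:
    def _criterion(self, bundle):
        sel = bundle.truth["selection"]
        return SelectionCriterion(
            clauses=[Clause(sel["column"], sel["comparator"], sel["threshold"])]
        )

    def test_planted_term_ranked_first(self, ora_bundle):
        res = run_ora(ora_bundle.info, self._criterion(ora_bundle), "mapman_bin")
        assert res.rows[0].term == ora_bundle.truth["enriched"]["term"]
        assert res.rows[0].p_adj < 0.01

    def test_background_is_whole_table(self, ora_bundle):
        res = run_ora(ora_bundle.info, self._criterion(ora_bundle), "mapman_bin")
        assert all(r.N == len(ora_bundle.info.entity_ids) for r in res.rows)

    def test_row_count_equals_term_count(self, ora_bundle):
        res = run_ora(ora_bundle.info, self._criterion(ora_bundle), "mapman_bin")
        idx = build_term_index(ora_bundle.info, "mapman_bin")
        assert len(res.rows) == len(idx.terms)

    def test_universal_term_p_one(self, tiny_info):
        crit = SelectionCriterion(id_list=["g1"])
        res = run_ora(tiny_info, crit, "description")
        # every description term annotates exactly one entity; the one
        # attached to g1 has a=1, K=1, n=1 -> p = 1/3
        assert all(0 < r.p_raw <= 1 for r in res.rows)

    def test_rows_sorted_by_adjusted_p(self, ora_bundle):
        res = run_ora(ora_bundle.info, self._criterion(ora_bundle), "mapman_bin")
        keys = [(r.p_adj, r.term) for r in res.rows]
        assert keys == sorted(keys)
        assert all(r.p_adj >= r.p_raw - 1e-15 for r in res.rows)

    def test_empty_selection_rejected(self, tiny_info):
        crit = SelectionCriterion(clauses=[Clause("log2FC", ">", 1e9)])
        with pytest.raises(ValidationError, match="empty selection"):
            run_ora(tiny_info, crit, "bin")

    def test_tsv_output(self, ora_bundle):
        res = run_ora(ora_bundle.info, self._criterion(ora_bundle), "mapman_bin")
        text = res.to_tsv()
        header = text.splitlines()[0].split("\t")
        assert header == ["term", "a", "term_size", "selection_size", "N", "p_raw", "p_adj"]

    def test_type_one_error_conservative(self):
        # selection and term membership drawn independently: the exact test
        # must not exceed its nominal level (binomial slack at 200 runs)
        rng = np.random.default_rng(0)
        runs, hits = 200, 0
        for _ in range(runs):
            N, n_sel, K = 120, 30, 25
            sel = set(rng.choice(N, n_sel, replace=False).tolist())
            term = set(rng.choice(N, K, replace=False).tolist())
            a = len(sel & term)
            t = ContingencyTable(a, n_sel - a, K - a, N - n_sel - (K - a))
            hits += fisher_exact_greater(t) < 0.05
        assert hits / runs <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / runs)
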