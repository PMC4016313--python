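"""Association rule mining: counts, indexes, filter cascade, query engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from coexmine import (
    AssociationCounts,
    PlantedModule,
    QueryParams,
    SyntheticSpec,
    association_table,
    chi2_pvalue,
    co_expression,
    co_presence,
    count_associations,
    generate_store,
    is_defined,
    lift,
    run_query,
)
from conftest import make_pattern_store

PERMISSIVE = dict(co_pres_min_pct=0.0, lift_min=0.0, chi2_p_max=1.0)


def counts_from_cells(a, b, c, d):
    """Build counts whose co-present 2x2 table is exactly (a, b, c, d)."""
    n_tp_xp = a + b + c + d
    return AssociationCounts(
        n_tp=n_tp_xp, n_tp_xp=n_tp_xp, n_tm_xm=a, n_tm_xp=a + b, n_tp_xm=a + c
    )


class TestCounts:
    def test_hand_enumerated_four_comparison_store(self):
        # target present in c0..c2, modulated in c0, c1;
        # candidate present in c0, c1, c3, modulated in c0
        records, pmap = make_pattern_store({"T": "uup.", "X": "up.p"})
        c = count_associations(records, "T", "X", pmap, QueryParams(target="T"))
        assert (c.n_tp, c.n_tp_xp, c.n_tm_xm, c.n_tm_xp, c.n_tp_xm) == (3, 2, 1, 2, 1)

    def test_candidate_never_co_measured(self):
        records, pmap = make_pattern_store({"T": "uuu", "X": "..."})
        c = count_associations(records, "T", "X", pmap, QueryParams(target="T"))
        assert (c.n_tp, c.n_tp_xp, c.n_tm_xm, c.n_tm_xp, c.n_tp_xm) == (3, 0, 0, 0, 0)

    def test_self_pairing_degeneracy(self):
        records, pmap = make_pattern_store({"T": "uup.n"})
        c = count_associations(records, "T", "T", pmap, QueryParams(target="T"))
        assert c.n_tp_xp == c.n_tp
        assert c.n_tm_xm == c.n_tm_xp == c.n_tp_xm

    def test_unusable_target_is_error(self):
        records, pmap = make_pattern_store({"T": "uu", "X": "pp"})
        with pytest.raises(ValueError, match="target not usable"):
            count_associations(records, "ZZZ", "X", pmap, QueryParams(target="ZZZ"))

    def test_count_chain_invariant(self):
        with pytest.raises(ValueError):
            AssociationCounts(n_tp=5, n_tp_xp=6, n_tm_xm=0, n_tm_xp=0, n_tp_xm=0)
        with pytest.raises(ValueError):
            AssociationCounts(n_tp=5, n_tp_xp=3, n_tm_xm=2, n_tm_xp=1, n_tp_xm=2)


class TestIndexes:
    def test_co_presence_formula(self):
        c = AssociationCounts(50, 20, 5, 10, 10)
        assert co_presence(c) == pytest.approx(0.40)
        full = AssociationCounts(50, 50, 0, 0, 0)
        assert co_presence(full) == 1.0
        none = AssociationCounts(50, 0, 0, 0, 0)
        assert co_presence(none) == 0.0

    def test_co_presence_undefined_without_target(self):
        with pytest.raises(ValueError, match="never present"):
            co_presence(AssociationCounts(0, 0, 0, 0, 0))

    def test_co_expression_formula(self):
        assert co_expression(AssociationCounts(200, 100, 30, 60, 50)) == pytest.approx(0.30)
        assert co_expression(AssociationCounts(200, 100, 0, 60, 50)) == 0.0
        assert co_expression(AssociationCounts(200, 100, 100, 100, 100)) == 1.0
        assert not is_defined(co_expression(AssociationCounts(5, 0, 0, 0, 0)))

    def test_lift_formula(self):
        assert lift(AssociationCounts(200, 100, 30, 60, 50)) == pytest.approx(1.0)
        assert lift(AssociationCounts(200, 100, 40, 40, 50)) == pytest.approx(2.0)
        assert lift(AssociationCounts(200, 100, 0, 40, 50)) == 0.0
        assert not is_defined(lift(AssociationCounts(200, 100, 0, 0, 50)))

    def test_chi2_independence_table_gives_p_one(self):
        assert chi2_pvalue(counts_from_cells(25, 25, 25, 25)) == 1.0

    def test_chi2_matches_reference_implementation(self):
        c = counts_from_cells(30, 10, 10, 30)
        expected = chi2_contingency([[30, 10], [10, 30]], correction=False).pvalue
        assert chi2_pvalue(c) == pytest.approx(expected, abs=1e-10)

    def test_chi2_zero_marginal_is_undefined(self):
        assert not is_defined(chi2_pvalue(counts_from_cells(0, 0, 10, 30)))
        assert not is_defined(chi2_pvalue(counts_from_cells(0, 10, 0, 30)))

    def test_chi2_negative_cell_is_error(self):
        bad = AssociationCounts(n_tp=10, n_tp_xp=10, n_tm_xm=0, n_tm_xp=6, n_tp_xm=6)
        # d = 10 - 6 - 6 + 0 < 0: counts are chain-consistent but table-invalid
        with pytest.raises(ValueError, match="negative"):
            chi2_pvalue(bad)

    def test_chi2_empty_table_is_undefined(self):
        assert not is_defined(chi2_pvalue(AssociationCounts(5, 0, 0, 0, 0)))


class TestRunQuery:
    def test_vectorized_counts_agree_with_reference_path(self):
        records, pmap = make_pattern_store(
            {"T": "uudp.pn.u", "X": "upu..npdu", "Y": "nnuppu..d", "Z": ".........u"[:9]},
            oriented=[True, False] * 4 + [True],
        )
        params = QueryParams(target="T", **PERMISSIVE)
        table, _ = association_table(records, pmap, params)
        for gene, counts in table:
            assert counts == count_associations(records, "T", gene, pmap, params)

    def test_directional_query_agrees_with_reference_path(self):
        records, pmap = make_pattern_store(
            {"T": "uudd.pu", "X": "uddu.uu"}, oriented=[True, True, False, True, True, True, False]
        )
        params = QueryParams(target="T", target_sign=1, gene_sign=-1, **PERMISSIVE)
        table, _ = association_table(records, pmap, params)
        for gene, counts in table:
            assert counts == count_associations(records, "T", gene, pmap, params)

    def test_unsatisfiable_co_presence_filter_empties_output(self):
        records, pmap = make_pattern_store({"T": "uuuu", "X": "uuuu"})
        rows, _ = run_query(records, pmap, QueryParams(target="T", co_pres_min_pct=101.0))
        assert rows == []

    def test_perfect_association_passes_default_filters(self):
        # candidate modulated in exactly the target's comparisons
        records, pmap = make_pattern_store({"T": "uuuupppp", "X": "uuuupppp"})
        rows, summary = run_query(records, pmap, QueryParams(target="T"))
        assert [r.gene for r in rows] == ["X"]
        assert summary.n_target_present == 8
        assert summary.n_target_modulated == 4
        assert rows[0].indexes.lift == pytest.approx(2.0)
        assert rows[0].indexes.co_expr == pytest.approx(0.5)

    def test_planted_gene_found_with_lift_above_one(self):
        spec = SyntheticSpec(
            n_comparisons=200,
            n_genes=40,
            planted_modules=(PlantedModule("G0000", ("G0001",), co_modulation_prob=0.9),),
            seed=13,
        )
        records, pmap, _ = generate_store(spec)
        rows, _ = run_query(records, pmap, QueryParams(target="G0000"))
        assert "G0001" in [r.gene for r in rows]
        planted = next(r for r in rows if r.gene == "G0001")
        assert planted.indexes.lift > 1.0

    def test_rows_ordered_by_lift_then_chi2_then_symbol(self):
        records, pmap = make_pattern_store(
            {"T": "uuuuuppp", "A": "uuuupppp", "B": "uuuppppp", "C": "uuuupppp"}
        )
        rows, _ = run_query(
            records, pmap, QueryParams(target="T", co_pres_min_pct=0, lift_min=0, chi2_p_max=1)
        )
        lifts = [r.indexes.lift for r in rows]
        assert lifts == sorted(lifts, reverse=True)
        keys = [(-r.indexes.lift, r.indexes.chi2_p, r.gene) for r in rows]
        assert keys == sorted(keys)
        # A and C have identical patterns: full tie resolved by symbol
        genes = [r.gene for r in rows]
        assert genes.index("A") < genes.index("C")

    def test_lift_min_zero_disables_lift_filter(self):
        # X has a defined lift of 8*2/(4*3) = 4/3, below the default threshold
        records, pmap = make_pattern_store({"T": "uuuupppp", "X": "uupppppu"})
        strict, _ = run_query(records, pmap, QueryParams(target="T", co_pres_min_pct=0, lift_min=2.0, chi2_p_max=1))
        relaxed, _ = run_query(records, pmap, QueryParams(target="T", co_pres_min_pct=0, lift_min=0.0, chi2_p_max=1))
        assert strict == []
        assert [r.gene for r in relaxed] == ["X"]
        assert relaxed[0].indexes.lift == pytest.approx(4 / 3)

    def test_unmapped_probe_can_surface_as_candidate(self):
        records, pmap = make_pattern_store({"T": "uuuupppp", "X": "uuuupppp"})
        # graft an unmapped probe, modulated alongside half the target's
        # modulated comparisons and quiet elsewhere
        from coexmine import ComparisonRecord, ProbeMeasure

        grafted = [
            ComparisonRecord(
                r.comparison_id,
                r.dataset_id,
                r.oriented,
                r.measures
                + (ProbeMeasure("orphan_probe", 2.0 if ci < 2 else 0.1, 0.001, 0.01),),
            )
            for ci, r in enumerate(records)
        ]
        rows, _ = run_query(grafted, pmap, QueryParams(target="T", **PERMISSIVE))
        assert "orphan_probe" in [r.gene for r in rows]
        with pytest.raises(ValueError, match="target not usable"):
            run_query(grafted, pmap, QueryParams(target="orphan_probe"))


class TestStatisticalProperties:
    def test_lift_and_chi2_symmetric_in_target_and_candidate(self):
        records, pmap = make_pattern_store(
            {"T": "uudp.pnu", "X": "upu.npdu"}, oriented=True
        )
        fwd = count_associations(records, "T", "X", pmap, QueryParams(target="T", **PERMISSIVE))
        rev = count_associations(records, "X", "T", pmap, QueryParams(target="X", **PERMISSIVE))
        # the two role-swapped count vectors swap n_tm_xp and n_tp_xm
        assert (fwd.n_tm_xp, fwd.n_tp_xm) == (rev.n_tp_xm, rev.n_tm_xp)
        if is_defined(lift(fwd)):
            assert lift(fwd) == pytest.approx(lift(rev))
            assert chi2_pvalue(fwd) == pytest.approx(chi2_pvalue(rev), abs=1e-12)

    def test_filter_monotonicity_on_fixed_store(self):
        records, pmap, _ = generate_store(SyntheticSpec(n_comparisons=100, n_genes=120, seed=8))
        sizes = []
        for lift_min in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0):
            rows, _ = run_query(
                records, pmap,
                QueryParams(target="G0000", co_pres_min_pct=0, lift_min=lift_min, chi2_p_max=1.0),
            )
            sizes.append(len(rows))
        assert sizes == sorted(sizes, reverse=True)
        sizes = []
        for chi2_max in (1.0, 0.5, 0.1, 0.05, 0.01):
            rows, _ = run_query(
                records, pmap,
                QueryParams(target="G0000", co_pres_min_pct=0, lift_min=0, chi2_p_max=chi2_max),
            )
            sizes.append(len(rows))
        assert sizes == sorted(sizes, reverse=True)
        sizes = []
        for co_pres in (0.0, 20.0, 40.0, 60.0, 80.0, 101.0):
            rows, _ = run_query(
                records, pmap,
                QueryParams(target="G0000", co_pres_min_pct=co_pres, lift_min=0, chi2_p_max=1.0),
            )
            sizes.append(len(rows))
        assert sizes == sorted(sizes, reverse=True)

    def test_null_chi2_rate_near_nominal_level(self):
        """With independent modulation the chi-square test rejects at roughly
        its nominal level; small expected cell counts leave a discreteness
        error on top of the Monte-Carlo one."""
        spec = SyntheticSpec(
            n_comparisons=200, n_genes=801, probes_per_gene=(1.0, 0.0),
            presence_rate=0.7, null_modulation_rate=0.2, seed=21,
        )
        records, pmap, _ = generate_store(spec)
        table, _ = association_table(records, pmap, QueryParams(target="G0000", **PERMISSIVE))
        pvals = [chi2_pvalue(c) for _, c in table]
        pvals = [p for p in pvals if is_defined(p)]
        assert len(pvals) > 700
        rate = np.mean([p <= 0.05 for p in pvals])
        assert abs(rate - 0.05) <= 0.03


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.sampled_from(".npud"), st.sampled_from(".npud"), st.booleans()),
        min_size=1,
        max_size=8,
    ),
)
def test_counts_chain_invariant_on_random_stores(data):
    """Every computed count vector satisfies
    n_tm_xm <= min(n_tm_xp, n_tp_xm) <= n_tp_xp <= n_tp (validated on
    construction) and the reference and vectorized paths agree."""
    t_states = "".join(d[0] for d in data)
    x_states = "".join(d[1] for d in data)
    oriented = [d[2] for d in data]
    if not any(s in "npud" for s in t_states):
        return
    records, pmap = make_pattern_store({"T": t_states, "X": x_states}, oriented=oriented)
    if not records:
        return
    params = QueryParams(target="T", **PERMISSIVE)
    c = count_associations(records, "T", "X", pmap, params)
    assert c.n_tm_xm <= min(c.n_tm_xp, c.n_tp_xm)
    assert max(c.n_tm_xp, c.n_tp_xm) <= c.n_tp_xp <= c.n_tp
    table, _ = association_table(records, pmap, params)
    vec = dict(table)
    if "X" in vec:
        assert vec["X"] == c
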