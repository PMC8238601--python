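"""Hypergeometric enrichment, intervention terms, coverage, model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_hypergeom_upper_tail

from netpharm import (
    GeneSetCollection,
    compare_models,
    coverage_proportion,
    enrich,
    enriched_terms,
    intervention_terms,
)


def collection_of(universe_size: int, set_genes: dict) -> GeneSetCollection:
    universe = [f"g{i}" for i in range(universe_size)]
    return GeneSetCollection.from_sets(set_genes, universe=universe)


class TestEnrich:
    def test_worked_combinatorial_example(self):
        # universe 20, set 5, query 6, overlap 4:
        # p = [C(5,4)C(15,2) + C(5,5)C(15,1)] / C(20,6) = 540/38760
        coll = collection_of(20, {"t": [f"g{i}" for i in range(5)]})
        query = [f"g{i}" for i in (0, 1, 2, 3, 10, 11)]
        row = enrich(query, coll)[0]
        assert row.overlap_count == 4
        assert row.p_value == pytest.approx(540 / 38760, abs=1e-12)
        assert row.enriched  # 0.0139 < 0.05

    def test_zero_overlap_has_p_one(self):
        coll = collection_of(20, {"t": ["g0", "g1"]})
        row = enrich(["g10", "g11"], coll)[0]
        assert row.overlap_count == 0 and row.p_value == 1.0 and not row.enriched

    def test_degenerate_query_equals_universe(self):
        coll = collection_of(5, {"t": [f"g{i}" for i in range(5)]})
        row = enrich([f"g{i}" for i in range(5)], coll)[0]
        assert row.p_value == 1.0

    def test_disjoint_query_rejected(self):
        coll = collection_of(5, {"t": ["g0"]})
        with pytest.raises(ValueError, match="universe"):
            enrich(["zzz"], coll)

    def test_rows_sorted_by_p_then_term(self):
        coll = collection_of(
            30, {"b": ["g0", "g1", "g2"], "a": ["g0", "g1", "g2"], "c": ["g20"]}
        )
        rows = enrich(["g0", "g1", "g2"], coll)
        assert [r.term for r in rows] == ["a", "b", "c"]

    @given(
        M=st.integers(6, 25),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_enumeration_oracle(self, M, data):
        K = data.draw(st.integers(1, M))
        N = data.draw(st.integers(1, M))
        genes = [f"g{i}" for i in range(M)]
        coll = GeneSetCollection.from_sets({"t": genes[:K]}, universe=genes)
        rng = np.random.default_rng(M * 100 + K * 10 + N)
        query = [genes[i] for i in rng.choice(M, size=N, replace=False)]
        row = enrich(query, coll)[0]
        expected = brute_hypergeom_upper_tail(M, K, N, row.overlap_count)
        assert row.p_value == pytest.approx(expected, abs=1e-12)

    def test_p_monotone_decreasing_in_overlap(self):
        M, K, N = 40, 10, 12
        ps = [brute_hypergeom_upper_tail(M, K, N, k) for k in range(0, 11)]
        genes = [f"g{i}" for i in range(M)]
        coll = GeneSetCollection.from_sets({"t": genes[:K]}, universe=genes)
        for k in range(0, 11):
            query = genes[:k] + genes[K : K + (N - k)]
            row = enrich(query, coll)[0]
            assert row.p_value == pytest.approx(ps[k], abs=1e-12)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bh_adjustment_bounds(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        sets = {
            f"t{j}": [genes[i] for i in rng.choice(50, size=8, replace=False)]
            for j in range(12)
        }
        coll = GeneSetCollection.from_sets(sets, universe=genes)
        rows = enrich(genes[:10], coll, adjust=True)
        adj = [r.adjusted_p for r in rows]
        raw = [r.p_value for r in rows]
        assert all(a >= p - 1e-15 for a, p in zip(adj, raw))
        assert all(x <= y + 1e-15 for x, y in zip(adj, adj[1:]))  # rows are p-sorted


class TestCollections:
    def test_universe_defaults_to_union(self):
        coll = GeneSetCollection.from_sets({"a": ["g1", "g2"], "b": ["g2", "g3"]})
        assert coll.universe == {"g1", "g2", "g3"}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection.from_sets({"a": []})

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            GeneSetCollection.from_sets({"a": ["g1"]}, universe=["g2"])


class TestInterventionAndCoverage:
    def test_intersection_semantics(self):
        assert intervention_terms({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
        assert intervention_terms({"a"}, {"b"}) == frozenset()
        assert intervention_terms({"a"}, {"a"}) == {"a"}

    def test_proportion_half(self):
        rep = coverage_proportion({"a", "b"}, {"a", "b", "c", "d"})
        assert rep.proportion == 0.5 and rep.percent == 50.0

    def test_superset_numerator_full_coverage(self):
        assert coverage_proportion({"a", "b", "c"}, {"a", "b"}).percent == 100.0

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            coverage_proportion({"a"}, set())

    def test_invariant_under_term_renaming(self):
        num, den = {"a", "b"}, {"b", "c"}
        renamed = coverage_proportion({n + "_x" for n in num}, {d + "_x" for d in den})
        assert renamed.proportion == coverage_proportion(num, den).proportion


class TestCompareModels:
    def test_composite_beats_degree_on_planted_fixture(self, planted, planted_networks):
        df = compare_models(
            planted_networks["ctp"],
            ["composite", "degree", "clustering"],
            planted.gene_sets,
            {g.symbol for g in planted.disease_genes},
            {t for _, t in planted.associations},
        )
        by = df.set_index("method")["coverage_percent"]
        assert by["composite"] > by["degree"]
        assert by["composite"] > by["clustering"]

    def test_single_method_consistent_with_standalone(self, planted, planted_networks):
        df = compare_models(
            planted_networks["ctp"], ["composite"], planted.gene_sets,
            {g.symbol for g in planted.disease_genes},
            {t for _, t in planted.associations},
        )
        assert len(df) == 1 and df.loc[0, "method"] == "composite"
        assert len(
            compare_models(
                planted_networks["ctp"], [], planted.gene_sets,
                {g.symbol for g in planted.disease_genes},
                {t for _, t in planted.associations},
            )
        ) == 0

    def test_unknown_method_rejected(self, planted, planted_networks):
        with pytest.raises(ValueError, match="unknown methods"):
            compare_models(
                planted_networks["ctp"], ["pagerank"], planted.gene_sets,
                {g.symbol for g in planted.disease_genes},
                {t for _, t in planted.associations},
            )
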