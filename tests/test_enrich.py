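"""Fisher exact primitive, GO enrichment, and mirror enzyme-code tests."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import trajdeg as T
from trajdeg.enrich import records_to_frame
from trajdeg.simulate import toy_go_dag


def fisher_enumeration_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by full support enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    denom = math.comb(n, row1)
    probs = {
        k: Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherTwoSided:
    def test_symmetric_table_gives_one(self):
        assert T.fisher_two_sided(1, 1, 1, 1) == 1.0

    def test_row_and_column_swap_symmetry(self):
        p = T.fisher_two_sided(5, 100, 1, 165)
        assert T.fisher_two_sided(1, 165, 5, 100) == pytest.approx(p)
        assert T.fisher_two_sided(100, 5, 165, 1) == pytest.approx(p)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            T.fisher_two_sided(1, -1, 2, 3)

    @given(
        st.integers(0, 60), st.integers(0, 60),
        st.integers(0, 60), st.integers(0, 60),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        got = T.fisher_two_sided(a, b, c, d)
        assert got == pytest.approx(fisher_enumeration_oracle(a, b, c, d),
                                    rel=1e-9, abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 200, size=4)
            assert T.fisher_two_sided(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], rel=1e-6, abs=1e-12
            )


class TestPropagate:
    def chain(self):
        return T.GoDag.from_edges([("c", "b"), ("b", "a")])

    def test_root_only_annotation_unchanged(self):
        ann = T.AnnotationTable({"g1": {"a"}})
        out = T.propagate_annotations(ann, self.chain())
        assert out.terms_for("g1") == {"a"}

    def test_chain_closure(self):
        ann = T.AnnotationTable({"g1": {"c"}})
        out = T.propagate_annotations(ann, self.chain())
        assert out.terms_for("g1") == {"c", "b", "a"}

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        genes = {f"g{i}": {f"t{rng.integers(10)}"} for i in range(30)}
        dag = T.GoDag.from_edges(
            [(f"t{i}", f"t{rng.integers(i)}") for i in range(1, 10)]
        )
        ann = T.AnnotationTable(genes)
        once = T.propagate_annotations(ann, dag)
        twice = T.propagate_annotations(once, dag)
        assert once == twice

    def test_unknown_terms_kept(self):
        ann = T.AnnotationTable({"g1": {"zzz"}})
        out = T.propagate_annotations(ann, self.chain())
        assert out.terms_for("g1") == {"zzz"}


class TestEnrichCategory:
    def test_category_equal_to_universe_finds_nothing(self):
        genes = [f"g{i}" for i in range(20)]
        ann = T.AnnotationTable({g: {"t1"} for g in genes[:10]})
        recs = T.enrich_category(genes, genes, ann)
        assert recs == []

    def test_category_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            T.enrich_category(["x"], ["a", "b"], T.AnnotationTable())

    def test_planted_term_p_consistent_with_primitive(self):
        _, truth = T.simulate_counts(
            500, seed=20,
            category_weights={"ns_ns_ns": 0.7, "up_ns_ns": 0.3},
        )
        ann = T.simulate_annotations(
            truth, 5, planted=[("P1", "up_ns_ns", math.inf)], seed=3
        )
        universe = list(truth.genes.index)
        cat = list(truth.genes.index[truth.genes.category_ar == "up_ns_ns"])
        recs = {r.term: r for r in T.enrich_category(cat, universe, ann,
                                                     category="up_ns_ns")}
        assert "P1" in recs
        r = recs["P1"]
        assert r.p == pytest.approx(
            T.fisher_two_sided(r.k, r.n - r.k, r.K - r.k,
                               (r.N - r.n) - (r.K - r.k))
        )
        # contributing genes are exactly the annotated category genes
        assert set(r.contributing_genes) == set(cat) & ann.genes_with("P1")
        assert r.k == len(r.contributing_genes)

    def test_records_recompute_from_stored_counts(self):
        _, truth = T.simulate_counts(
            400, seed=21, category_weights={"ns_ns_ns": 0.6, "down_ns_ns": 0.4},
        )
        ann = T.simulate_annotations(
            truth, 8, planted=[("P1", "down_ns_ns", 20.0)], seed=4
        )
        universe = list(truth.genes.index)
        cat = list(truth.genes.index[truth.genes.category_ar == "down_ns_ns"])
        for r in T.enrich_category(cat, universe, ann, category="down_ns_ns"):
            assert r.p == pytest.approx(
                T.fisher_two_sided(r.k, r.n - r.k, r.K - r.k,
                                   (r.N - r.n) - (r.K - r.k))
            )
            assert 0 <= r.k <= min(r.n, r.K)
            assert r.fdr >= r.p

    def test_gene_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(100)]
        terms = {g: {f"t{rng.integers(5)}"} for g in genes}
        cat = genes[:30]
        ann = T.AnnotationTable(terms)
        recs1 = T.enrich_category(cat, genes, ann, fdr=1.0)
        relabel = {g: f"x{i}" for i, g in enumerate(genes)}
        ann2 = T.AnnotationTable({relabel[g]: ts for g, ts in terms.items()})
        recs2 = T.enrich_category(
            [relabel[g] for g in cat], list(relabel.values()), ann2, fdr=1.0
        )
        p1 = sorted(r.p for r in recs1)
        p2 = sorted(r.p for r in recs2)
        assert np.allclose(p1, p2)


class TestContributingPercentage:
    def test_no_enriched_terms_gives_zero(self):
        assert T.contributing_percentage(["a", "b"], []) == 0

    def test_all_genes_carry_single_term_gives_100(self):
        from trajdeg.enrich import EnrichmentRecord
        rec = EnrichmentRecord("c", "t", "", 2, 2, 2, 10, 0.01, 0.01,
                               contributing_genes=("a", "b"))
        assert T.contributing_percentage(["a", "b"], [rec]) == 100

    def test_matches_brute_force_union(self):
        from trajdeg.enrich import EnrichmentRecord
        rng = np.random.default_rng(11)
        cat = [f"g{i}" for i in range(40)]
        recs = [
            EnrichmentRecord("c", f"t{j}", "", 0, 40, 0, 100, 0.01, 0.01,
                             contributing_genes=tuple(
                                 rng.choice(cat, size=rng.integers(1, 15),
                                            replace=False)))
            for j in range(5)
        ]
        union = set().union(*(r.contributing_genes for r in recs))
        expect = round(100 * len(union) / 40)
        assert abs(T.contributing_percentage(cat, recs) - expect) <= 1

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            T.contributing_percentage([], [])


class TestCategorySummary:
    def test_counts_percentage_and_missing_marker(self):
        from trajdeg.enrich import EnrichmentRecord, category_summary

        rec = EnrichmentRecord("A", "t1", "", 3, 4, 5, 50, 0.01, 0.02,
                               contributing_genes=("a", "b", "c"))
        out = category_summary(
            {"A": ["a", "b", "c", "d"], "B": ["e", "f"]},
            {"A": [rec]},
        ).set_index("category")
        assert out.loc["A", "n_degs"] == 4
        assert out.loc["A", "pct_contributing"] == 75
        assert out.loc["A", "n_enriched_terms"] == 1
        assert out.loc["B", "pct_contributing"] is None or \
            np.isnan(out.loc["B", "pct_contributing"])
        assert out.loc["B", "n_enriched_terms"] == 0


class TestMostSpecific:
    def make_records(self, terms):
        from trajdeg.enrich import EnrichmentRecord
        return [EnrichmentRecord("c", t, "", 1, 1, 1, 2, 0.01, 0.01)
                for t in terms]

    def test_chain_keeps_leaf(self):
        dag = T.GoDag.from_edges([("c", "b"), ("b", "a")])
        out = T.most_specific_terms(self.make_records(["a", "b", "c"]), dag)
        assert [r.term for r in out] == ["c"]

    def test_siblings_both_kept(self):
        dag = T.GoDag.from_edges([("b", "a"), ("c", "a")])
        out = T.most_specific_terms(self.make_records(["b", "c"]), dag)
        assert sorted(r.term for r in out) == ["b", "c"]

    def test_matches_brute_force_descendant_scan(self):
        rng = np.random.default_rng(13)
        edges = [(f"t{i}", f"t{rng.integers(i)}") for i in range(1, 25)]
        dag = T.GoDag.from_edges(edges)
        enriched = [f"t{i}" for i in sorted(rng.choice(25, 10, replace=False))]
        out = {r.term for r in T.most_specific_terms(self.make_records(enriched), dag)}
        parent_of = {}
        for child, parent in edges:
            parent_of.setdefault(child, set()).add(parent)

        def descendants(t):
            return {c for c in (f"t{i}" for i in range(25))
                    if c != t and t in closure(c)}

        def closure(c):
            seen, stack = set(), list(parent_of.get(c, ()))
            while stack:
                p = stack.pop()
                if p not in seen:
                    seen.add(p)
                    stack.extend(parent_of.get(p, ()))
            return seen

        expect = {t for t in enriched
                  if not (descendants(t) & (set(enriched) - {t}))}
        assert out == expect


class TestMirrorKegg:
    def test_p_matches_primitive_and_alpha_screen(self):
        rng = np.random.default_rng(14)
        cats = {
            "up_ns_ns": [f"u{i}" for i in range(80)],
            "down_ns_ns": [f"d{i}" for i in range(120)],
        }
        ec = T.AnnotationTable({
            **{g: {"EC:1.1.1.1"} for g in cats["up_ns_ns"][:2]},
            **{g: {"EC:1.1.1.1"} for g in cats["down_ns_ns"][:30]},
            **{g: {"EC:2.2.2.2"} for g in cats["up_ns_ns"][2:6]},
            **{g: {"EC:2.2.2.2"} for g in cats["down_ns_ns"][30:36]},
        })
        out = T.mirror_kegg_tests(cats, ec, alpha=0.05)
        assert set(out.ec) == {"EC:1.1.1.1"}  # balanced code not significant
        row = out.iloc[0]
        assert row.category_1 == "up_ns_ns" and row.category_2 == "down_ns_ns"
        assert row.p == pytest.approx(
            T.fisher_two_sided(row.k1, row.n1 - row.k1, row.k2, row.n2 - row.k2)
        )
        assert row.p < 0.05

    def test_equal_proportions_not_reported(self):
        cats = {"up_ns_ns": [f"u{i}" for i in range(50)],
                "down_ns_ns": [f"d{i}" for i in range(50)]}
        ec = T.AnnotationTable({
            **{g: {"EC:9"} for g in cats["up_ns_ns"][:5]},
            **{g: {"EC:9"} for g in cats["down_ns_ns"][:5]},
        })
        out = T.mirror_kegg_tests(cats, ec, alpha=0.05)
        assert len(out) == 0

    def test_unpaired_category_skipped(self):
        cats = {"up_ns_ns": ["a", "b"]}
        ec = T.AnnotationTable({"a": {"EC:9"}})
        out = T.mirror_kegg_tests(cats, ec)
        assert len(out) == 0

    def test_records_frame_round_trip_columns(self):
        df = records_to_frame([])
        assert list(df.columns)[:4] == ["category", "term", "namespace", "k"]

    def test_toy_dag_builder(self):
        dag = toy_go_dag(["T1", "T2"])
        assert dag.ancestors("T1") == {"T:ROOT"}
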