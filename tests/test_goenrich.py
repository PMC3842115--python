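"""Annotation propagation, hypergeometric and rank tests, graph elimination."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hepaprot import goenrich, synthdata
from hepaprot.errors import AnnotationError, OntologyError, UndefinedTestError
from hepaprot.goenrich import OntologyDAG, propagate_annotations
from oracles import enumerate_abs_ranksum_tail, enumerate_hypergeom_tail


def chain_dag(*terms):
    """root <- terms[1] <- terms[2] <- ... (each child is_a its predecessor)."""
    g = nx.DiGraph()
    g.add_node(terms[0])
    for child, parent in zip(terms[1:], terms[:-1]):
        g.add_edge(child, parent)
    return OntologyDAG(g)


class TestOntologyDAG:
    def test_cycle_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(OntologyError):
            OntologyDAG(g)

    def test_multiple_roots_rejected(self):
        g = nx.DiGraph([("A", "root1"), ("B", "root2")])
        with pytest.raises(OntologyError):
            OntologyDAG(g)


class TestPropagateAnnotations:
    def test_transitive_closure(self):
        dag = chain_dag("root", "A", "B")
        ann = propagate_annotations({"p": {"B"}}, dag)
        assert "p" in ann.propagated["A"]
        assert "p" in ann.propagated["root"]

    def test_root_only_annotation(self):
        dag = chain_dag("root", "A")
        ann = propagate_annotations({"p": {"root"}}, dag)
        assert ann.propagated["A"] == frozenset()
        assert ann.propagated["root"] == frozenset({"p"})

    def test_parent_superset_invariant(self):
        dag, ann = synthdata.generate_ontology(25, 60, seed=5)
        for child, parent in dag.graph.edges:
            assert ann.propagated[child] <= ann.propagated[parent]

    def test_unknown_term_listed(self):
        dag = chain_dag("root", "A")
        with pytest.raises(AnnotationError, match="Z"):
            propagate_annotations({"p": {"Z"}}, dag)


class TestDetectionTest:
    def test_matches_exhaustive_enumeration(self, rng):
        universe = [f"P{i}" for i in range(10)]
        dag = chain_dag("root", "A")
        for _ in range(15):
            term_members = set(rng.choice(universe, size=rng.integers(3, 8), replace=False))
            fg = set(rng.choice(universe, size=rng.integers(3, 7), replace=False))
            direct = {p: {"A"} if p in term_members else {"root"} for p in universe}
            ann = propagate_annotations(direct, dag)
            records = goenrich.detection_test(fg, ann, dag, min_size=1)
            rec = next(r for r in records if r.term == "A")
            expected = enumerate_hypergeom_tail(universe, term_members, fg)
            assert rec.p_value == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        dag = chain_dag("root", "A")
        direct = {"p1": {"A"}, "p2": {"A"}, "p3": {"A"}, "q1": {"root"}, "q2": {"root"}}
        ann = propagate_annotations(direct, dag)
        records = goenrich.detection_test({"q1", "q2"}, ann, dag, min_size=3)
        rec = next(r for r in records if r.term == "A")
        assert rec.p_value == pytest.approx(1.0)

    def test_foreground_equal_background_gives_p_one(self):
        dag, ann = synthdata.generate_ontology(10, 30, seed=1)
        records = goenrich.detection_test(ann.proteins, ann, dag, min_size=3)
        assert all(r.p_value == pytest.approx(1.0) for r in records)


class TestPCScoreTest:
    def test_abswilcox_exact_top_ranks(self):
        """Annotated |scores| occupy the top 2 of 4 ranks: exactly 1 of the
        C(4,2)=6 label assignments is as extreme, so p = 1/6."""
        scores = pd.Series({"a": 2.0, "b": -1.8, "c": 0.1, "d": -0.2})
        p = goenrich.pc_score_test(scores, {"a", "b"}, "absWilcox")
        assert p == pytest.approx(1 / 6)

    def test_abswilcox_matches_enumeration(self, rng):
        for _ in range(15):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 8)
            vals = rng.normal(size=n1 + n2)
            names = [f"P{i}" for i in range(n1 + n2)]
            scores = pd.Series(vals, index=names)
            p = goenrich.pc_score_test(scores, set(names[:n1]), "absWilcox")
            expected = enumerate_abs_ranksum_tail(vals[:n1], vals[n1:])
            assert p == pytest.approx(expected, abs=1e-12)

    def test_ks_identical_distributions(self):
        vals = [1.0, 2.0, 3.0]
        scores = pd.Series(dict({f"a{i}": v for i, v in enumerate(vals)},
                                **{f"b{i}": v for i, v in enumerate(vals)}))
        p = goenrich.pc_score_test(scores, {f"a{i}" for i in range(3)}, "ks")
        assert p == pytest.approx(1.0)

    def test_wilcox_invariant_to_monotone_transform(self, rng):
        vals = rng.normal(size=12)
        names = [f"P{i}" for i in range(12)]
        annotated = set(names[:5])
        p_raw = goenrich.pc_score_test(pd.Series(vals, index=names), annotated, "wilcox")
        p_tr = goenrich.pc_score_test(pd.Series(np.exp(vals) + 7, index=names),
                                      annotated, "wilcox")
        assert p_raw == pytest.approx(p_tr)

    def test_annotated_everything_undefined(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(UndefinedTestError):
            goenrich.pc_score_test(scores, {"a", "b"}, "wilcox")

    def test_empty_annotated_undefined(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(UndefinedTestError):
            goenrich.pc_score_test(scores, set(), "absWilcox")


class TestElimEnrichment:
    def _two_level(self):
        """root <- A; A holds the extreme proteins, root adds only two more."""
        dag = chain_dag("root", "A")
        extremes = {f"e{i}": {"A"} for i in range(6)}
        fillers = {"f1": {"root"}, "f2": {"root"}}
        ann = propagate_annotations({**extremes, **fillers}, dag)
        scores = pd.Series(
            {**{f"e{i}": 5.0 + i * 0.01 for i in range(6)},
             "f1": 0.05, "f2": -0.02,
             **{f"bg{i}": (i - 10) * 0.01 for i in range(20)}}
        )
        return dag, ann, scores

    def test_hand_simulated_two_node_elimination(self):
        dag, ann, scores = self._two_level()
        recs = goenrich.elim_enrichment(scores, dag, ann, "absWilcox",
                                        elim_threshold=1e-3, report_threshold=1e-3,
                                        min_size=3)
        terms = [r.term for r in recs]
        assert terms == ["A"]  # root's set empties to 2 < min_size, never tested

    def test_elimination_records_removed_count(self):
        dag, ann, scores = self._two_level()
        recs = goenrich.elim_enrichment(scores, dag, ann, "absWilcox",
                                        elim_threshold=1e-3, report_threshold=0.999,
                                        min_size=2)
        by_term = {r.term: r for r in recs}
        assert by_term["A"].n_eliminated == 0
        # root was tested on {f1, f2} after losing A's six proteins
        if "root" in by_term:
            assert by_term["root"].n_annotated == 2
            assert by_term["root"].n_eliminated == 6

    def test_zero_elim_threshold_equals_flat_testing(self):
        dag, ann = synthdata.generate_ontology(20, 50, seed=6)
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=50), index=sorted(ann.proteins))
        flat = {
            t: goenrich.pc_score_test(scores, ps, "absWilcox")
            for t, ps in ann.propagated.items()
            if 3 <= len(ps) < len(scores)
        }
        recs = goenrich.elim_enrichment(scores, dag, ann, "absWilcox",
                                        elim_threshold=0.0, report_threshold=1.01,
                                        min_size=3)
        assert {r.term: r.p_value for r in recs} == pytest.approx(flat)

    def test_specific_before_generic_order(self):
        dag, ann = synthdata.generate_ontology(15, 30, seed=2)
        order = list(nx.lexicographical_topological_sort(dag.graph))
        for child, parent in dag.graph.edges:
            assert order.index(child) < order.index(parent)


class TestTermClustersAndViolin:
    def _records(self, sets):
        return [
            goenrich.EnrichmentRecord(t, t, "absWilcox", "PC1", 1e-4, len(ps), 0, 0.0,
                                      frozenset(ps))
            for t, ps in sets.items()
        ]

    def test_identical_sets_one_cluster(self):
        recs = self._records({"A": {"p1", "p2"}, "B": {"p1", "p2"}})
        clusters = goenrich.cluster_terms(recs, jaccard_min=0.5)
        assert len(clusters) == 1 and clusters[0]["terms"] == ["A", "B"]

    def test_disjoint_sets_singletons(self):
        recs = self._records({"A": {"p1"}, "B": {"p2"}})
        assert len(goenrich.cluster_terms(recs, jaccard_min=0.1)) == 2

    def test_single_linkage_chaining(self):
        recs = self._records({
            "A": {"p1", "p2", "p3"},
            "B": {"p2", "p3", "p4"},
            "C": {"p3", "p4", "p5"},
        })
        clusters = goenrich.cluster_terms(recs, jaccard_min=0.5)
        assert len(clusters) == 1 and clusters[0]["terms"] == ["A", "B", "C"]

    def test_violin_baseline_and_medians(self):
        scores = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 5.0})
        recs = self._records({"A": {"p1", "p2"}})
        table = goenrich.violin_table(recs, scores)
        base = table[table["label"] == goenrich.ALL_PROTEINS_LABEL]
        assert sorted(base["accession"]) == ["p1", "p2", "p3"]
        term_rows = table[table["label"] != goenrich.ALL_PROTEINS_LABEL]
        assert term_rows["median"].unique().tolist() == [1.5]
        assert np.median(term_rows["score"]) == 1.5


class TestEliminationInvariant:
    def test_ancestor_counts_never_increase(self):
        dag, ann = synthdata.generate_ontology(25, 80, seed=3)
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=80), index=sorted(ann.proteins))
        # plant one strong leaf term so elimination actually fires
        leaves = sorted(t for t in dag.graph.nodes
                        if dag.graph.in_degree(t) == 0 and len(ann.propagated[t]) >= 4)
        planted = leaves[0]
        scores.loc[sorted(ann.propagated[planted])] = 10.0 + np.arange(
            len(ann.propagated[planted]))
        recs = goenrich.elim_enrichment(scores, dag, ann, "absWilcox",
                                        elim_threshold=1e-3, report_threshold=1.01,
                                        min_size=3)
        by_term = {r.term: r for r in recs}
        for anc in dag.ancestors(planted):
            if anc in by_term:
                assert by_term[anc].n_annotated <= len(ann.propagated[anc])
                assert by_term[anc].n_eliminated >= len(ann.propagated[planted] & set(scores.index)) - 0
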