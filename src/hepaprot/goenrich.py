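"""GO-term enrichment: detection test and PC-score tests with graph elimination.

Two complementary enrichment strategies are implemented.  The *detection test*
asks whether a GO term is over-represented among a foreground protein set
(typically the proteins quantified in every sample) relative to an annotated
background universe, via the one-sided hypergeometric tail.  The *PC score
tests* ask whether a term's proteins carry unusually extreme scores on a
principal component, via rank statistics:

``absWilcox``
    one-sided Wilcoxon rank-sum on absolute scores (annotated more extreme);
``wilcox``
    two-sided rank-sum on raw scores;
``ks``
    two-sample two-sided Kolmogorov-Smirnov on raw scores.

The score tests run under a most-specific-first *elimination* over the is_a
DAG: terms are visited in reverse topological order, and whenever a term is
significant its proteins are removed from all of its ancestors' annotation
sets before those ancestors are tested.  This decorrelates the graph so that
a specific significant term does not drag every generic ancestor along.

Exact rank-test null enumeration is used when both group sizes are <= 8 and
there are no ties; a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats

from .errors import (
    AnnotationError,
    HepaprotError,
    OntologyError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)

SCORE_TEST_METHODS = ("absWilcox", "wilcox", "ks")


@dataclass
class OntologyDAG:
    """Rooted acyclic is_a graph; edges run child -> parent."""

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyError("is_a graph contains a cycle")
        roots = [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(f"expected a single root, found {sorted(roots)}")
        self.root = roots[0]

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via is_a edges (excluding ``term`` itself)."""
        return nx.descendants(self.graph, term)

    def name(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass
class AnnotationMap:
    """Direct and ancestry-propagated protein annotations.

    ``propagated`` is closed under the true-path rule: a protein annotated to
    a term belongs to the propagated set of every ancestor of that term.
    """

    direct: dict[str, frozenset[str]]  # protein -> terms
    propagated: dict[str, frozenset[str]]  # term -> proteins

    @property
    def proteins(self) -> frozenset[str]:
        """The annotated protein universe."""
        return frozenset(self.direct)


@dataclass
class EnrichmentRecord:
    term: str
    name: str
    test: str
    component: str | None
    p_value: float
    n_annotated: int
    n_eliminated: int
    median_score: float
    proteins: frozenset[str]


def read_obo(path: str | Path) -> OntologyDAG:
    """Parse a (possibly minimal) OBO file, keeping id, name and is_a only."""
    multigraph = obonet.read_obo(path)
    g = nx.DiGraph()
    names = {}
    for node, data in multigraph.nodes(data=True):
        g.add_node(node)
        if "name" in data:
            names[node] = data["name"]
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return OntologyDAG(g, names)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Write the term graph as a minimal OBO file (id/name/is_a stanzas)."""
    lines = ["format-version: 1.2", ""]
    for term in dag.terms:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.name(term)}")
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent} ! {dag.name(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (accession, term) TSV into a direct-annotation map."""
    raw = pd.read_csv(path, sep="\t", header=None, names=["accession", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for acc, term in raw.itertuples(index=False):
        out.setdefault(acc, set()).add(term)
    return {p: frozenset(ts) for p, ts in out.items()}


def write_annotations(direct: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(p, t) for p in sorted(direct) for t in sorted(direct[p])]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def propagate_annotations(
    direct: Mapping[str, Iterable[str]], dag: OntologyDAG
) -> AnnotationMap:
    """Close direct annotations under ancestry (true-path rule)."""
    unknown = sorted({t for ts in direct.values() for t in ts} - set(dag.graph.nodes))
    if unknown:
        raise AnnotationError(f"annotations reference unknown terms: {unknown}")
    # cache term -> ancestor closure once
    closure = {t: frozenset(dag.ancestors(t)) | {t} for t in dag.graph.nodes}
    propagated: dict[str, set[str]] = {t: set() for t in dag.graph.nodes}
    clean_direct: dict[str, frozenset[str]] = {}
    for protein, terms in direct.items():
        terms = frozenset(terms)
        if not terms:
            continue
        clean_direct[protein] = terms
        for term in terms:
            for anc in closure[term]:
                propagated[anc].add(protein)
    return AnnotationMap(clean_direct, {t: frozenset(ps) for t, ps in propagated.items()})


def detection_test(
    foreground: Iterable[str],
    ann: AnnotationMap,
    dag: OntologyDAG,
    min_size: int = 3,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each term in ``foreground``.

    For a background universe of N annotated proteins of which K carry the
    term, and a foreground of n proteins of which k carry it, the p-value is
    the upper hypergeometric tail P(X >= k).  Terms with fewer than
    ``min_size`` background annotations are skipped.  Records are sorted by
    p-value (term id breaking ties).
    """
    foreground = frozenset(foreground)
    if not foreground:
        raise HepaprotError("detection test: empty foreground")
    universe = ann.proteins
    extra = foreground - universe
    if extra:
        raise HepaprotError(
            f"detection test: foreground proteins outside the annotated universe: "
            f"{sorted(extra)[:5]}..."
        )
    N, n = len(universe), len(foreground)
    records = []
    for term in dag.terms:
        members = ann.propagated.get(term, frozenset())
        K = len(members)
        if K < min_size:
            continue
        hits = members & foreground
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(
            EnrichmentRecord(term, dag.name(term), "detection", None, p, K, 0,
                             float("nan"), hits)
        )
    records.sort(key=lambda r: (r.p_value, r.term))
    return records


def _exact_usable(x: np.ndarray, y: np.ndarray) -> bool:
    return len(x) <= 8 and len(y) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)


def pc_score_test(
    scores: pd.Series, annotated: Iterable[str], method: str = "absWilcox"
) -> float:
    """Rank-based association of a term's proteins with extreme PC scores.

    ``annotated`` must be a nonempty strict subset of the score domain; the
    complement is the comparison group.
    """
    if method not in SCORE_TEST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {SCORE_TEST_METHODS}")
    annotated = frozenset(annotated) & frozenset(scores.index)
    if not annotated:
        raise UndefinedTestError("score test: no annotated protein has a score")
    if len(annotated) == len(scores):
        raise UndefinedTestError("score test: annotated set equals the whole score domain")
    in_mask = scores.index.isin(annotated)
    x = scores.to_numpy(dtype=float)[in_mask]
    y = scores.to_numpy(dtype=float)[~in_mask]
    if method == "ks":
        return float(stats.ks_2samp(x, y, alternative="two-sided").pvalue)
    if method == "absWilcox":
        x, y = np.abs(x), np.abs(y)
        alternative = "greater"
    else:
        alternative = "two-sided"
    how = "exact" if _exact_usable(x, y) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=how).pvalue)


def elim_enrichment(
    scores: pd.Series,
    dag: OntologyDAG,
    ann: AnnotationMap,
    method: str = "absWilcox",
    elim_threshold: float = 1e-3,
    report_threshold: float = 1e-3,
    min_size: int = 3,
    component: str | None = None,
) -> list[EnrichmentRecord]:
    """Score-test every term most-specific-first with ancestor elimination.

    Terms are visited in reverse topological order of the is_a DAG (children
    before parents, ties by term id).  Each term is tested on its *current*
    annotation set — the propagated set minus proteins already claimed by
    significant descendants — provided that set has at least ``min_size``
    members with scores.  When a term's p-value falls below
    ``elim_threshold``, its current proteins are removed from every ancestor's
    set before those are tested.  The returned records are the tested terms
    with p below ``report_threshold``, sorted by p-value.

    ``elim_threshold = 0`` disables elimination, reducing to flat per-term
    testing.
    """
    scored = frozenset(scores.index)
    missing = sorted(ann.proteins - scored)
    current: dict[str, set[str]] = {
        t: set(ann.propagated.get(t, frozenset())) & scored for t in dag.graph.nodes
    }
    if missing:
        logger.info("elim enrichment: %d annotated proteins lack scores and are ignored",
                    len(missing))
    reported: list[EnrichmentRecord] = []
    for term in nx.lexicographical_topological_sort(dag.graph):
        members = current[term]
        if len(members) < min_size or len(members) >= len(scores):
            continue
        p = pc_score_test(scores, members, method)
        full = ann.propagated.get(term, frozenset()) & scored
        n_elim = len(full) - len(members)
        if p < report_threshold:
            reported.append(
                EnrichmentRecord(
                    term, dag.name(term), method, component, p,
                    len(members), n_elim,
                    float(scores.loc[sorted(members)].median()),
                    frozenset(members),
                )
            )
        if p < elim_threshold:
            claimed = frozenset(members)
            for anc in dag.ancestors(term):
                current[anc] -= claimed
    reported.sort(key=lambda r: (r.p_value, r.term))
    return reported


def cluster_terms(
    records: Sequence[EnrichmentRecord],
    jaccard_min: float = 0.5,
) -> list[dict]:
    """Single-linkage grouping of significant terms by annotation overlap.

    Two terms join the same cluster (directly or by chaining) when the Jaccard
    index of their post-elimination protein sets is >= ``jaccard_min``.  Each
    cluster is reported with its member terms and the union protein set.
    """
    if not records:
        raise HepaprotError("cluster_terms: no enrichment records given")
    g = nx.Graph()
    g.add_nodes_from(r.term for r in records)
    sets = {r.term: r.proteins for r in records}
    terms = sorted(sets)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            union = sets[a] | sets[b]
            if union and len(sets[a] & sets[b]) / len(union) >= jaccard_min:
                g.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        union: set[str] = set()
        for t in members:
            union |= sets[t]
        clusters.append({"terms": members, "proteins": sorted(union)})
    clusters.sort(key=lambda c: c["terms"][0])
    return clusters


ALL_PROTEINS_LABEL = "All Proteins"


def violin_table(records: Sequence[EnrichmentRecord], scores: pd.Series) -> pd.DataFrame:
    """Per-term score distributions for violin plotting.

    One row per (term, protein) score, plus an ``All Proteins`` baseline block
    holding every protein's score.  The ``median`` column repeats each term's
    median (the black dot of the plot).
    """
    blocks = []
    base = pd.DataFrame({
        "label": ALL_PROTEINS_LABEL,
        "accession": scores.index,
        "score": scores.to_numpy(dtype=float),
    })
    base["median"] = float(scores.median())
    blocks.append(base)
    for rec in records:
        members = sorted(rec.proteins)
        sub = pd.DataFrame({
            "label": f"{rec.term} {rec.name}" if rec.name != rec.term else rec.term,
            "accession": members,
            "score": scores.loc[members].to_numpy(dtype=float),
        })
        sub["median"] = float(scores.loc[members].median())
        blocks.append(sub)
    return pd.concat(blocks, ignore_index=True)


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate records; the ``q`` column is a Benjamini-Hochberg adjustment
    added for modern convenience (raw p-values remain the primary output)."""
    df = pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "test": r.test,
                "component": r.component if r.component is not None else "",
                "n_annotated": r.n_annotated,
                "n_eliminated": r.n_eliminated,
                "p": r.p_value,
                "median_score": r.median_score,
            }
            for r in records
        ]
    )
    if len(df):
        df["q"] = _bh_adjust(df["p"].to_numpy(dtype=float))
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
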