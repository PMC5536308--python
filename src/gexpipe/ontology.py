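"""Ontology-term enrichment with elim decorrelation.

Terms live in an acyclic child -> parent DAG (one root per ontology).
After evidence-code filtering and true-path propagation, each term is
tested with a two-tailed Fisher's exact test on its annotated genes versus
the rest of the universe.  The elim pass walks the DAG children-first:
whenever a term comes out significant, its genes are removed from all of
its ancestors' gene sets before those are tested, which decorrelates
parent p-values from signal that is really located in a child.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_NODE_SIZE = 10
DEFAULT_ELIM_CUTOFF = 0.01
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"ND", "IEA", "NR"})


@dataclass
class GODag:
    """Acyclic is-a term graph; edges point child -> parent."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_records(
        cls,
        terms: Iterable[tuple[str, str, str]],
        edges: Iterable[tuple[str, str]],
    ) -> "GODag":
        """Build from (term_id, name, ontology) triples and (child, parent) pairs."""
        g = nx.DiGraph()
        for tid, name, ont in terms:
            g.add_node(tid, name=name, ontology=ont)
        for child, parent in edges:
            if child not in g or parent not in g:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown term")
            if g.nodes[child]["ontology"] != g.nodes[parent]["ontology"]:
                raise ValueError("edges must stay within one ontology")
            g.add_edge(child, parent)
        dag = cls(g)
        dag.validate()
        return dag

    @classmethod
    def from_tables(cls, term_table: pd.DataFrame, edge_table: pd.DataFrame) -> "GODag":
        terms = list(
            term_table[["term", "name", "ontology"]].itertuples(index=False, name=None)
        )
        edges = list(edge_table[["child", "parent"]].itertuples(index=False, name=None))
        return cls.from_records(terms, edges)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("term graph contains a cycle")
        for ont in self.ontologies():
            roots = [
                n
                for n in self.graph
                if self.graph.nodes[n]["ontology"] == ont
                and self.graph.out_degree(n) == 0
            ]
            if len(roots) != 1:
                raise ValueError(f"ontology {ont!r} has {len(roots)} roots, expected 1")

    def ontologies(self) -> list[str]:
        return sorted({d["ontology"] for _, d in self.graph.nodes(data=True)})

    def terms(self, ontology: str | None = None) -> list[str]:
        if ontology is None:
            return sorted(self.graph)
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["ontology"] == ontology
        )

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child -> parent edges (excl. self)."""
        return nx.descendants(self.graph, term)

    def depths(self, ontology: str) -> dict[str, int]:
        """Longest-path distance to the ontology root, per term."""
        nodes = self.terms(ontology)
        sub = self.graph.subgraph(nodes)
        depth: dict[str, int] = {}
        # topological order of child->parent DAG puts children before parents
        for n in reversed(list(nx.topological_sort(sub))):
            parents = list(sub.successors(n))
            depth[n] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (c, p, self.graph.nodes[c]["ontology"]) for c, p in self.graph.edges
        ]
        return pd.DataFrame(rows, columns=["child", "parent", "ontology"])

    def term_table(self) -> pd.DataFrame:
        rows = [
            (n, d["name"], d["ontology"]) for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["term", "name", "ontology"])


def load_dag(term_path, edge_path) -> GODag:
    return GODag.from_tables(
        pd.read_csv(term_path, sep="\t"), pd.read_csv(edge_path, sep="\t")
    )


def filter_evidence(
    annotations: pd.DataFrame,
    excluded: Iterable[str] = DEFAULT_EXCLUDED_EVIDENCE,
) -> pd.DataFrame:
    """Drop (gene, term, evidence_code) triples with excluded evidence codes."""
    excluded = set(excluded)
    if not excluded:
        return annotations.copy()
    return annotations.loc[~annotations["evidence_code"].isin(excluded)].copy()


def propagate_annotations(
    dag: GODag, annotations: pd.DataFrame
) -> dict[str, set[str]]:
    """True-path closure: each gene inherits every ancestor of its terms.

    Returns gene -> set of terms.  Idempotent; unknown terms raise.
    """
    anc_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, term in annotations[["gene", "term"]].itertuples(index=False, name=None):
        if term not in dag.graph:
            raise ValueError(f"annotation references unknown term {term!r}")
        if term not in anc_cache:
            anc_cache[term] = dag.ancestors(term) | {term}
        out.setdefault(gene, set()).update(anc_cache[term])
    return out


def fisher_exact_p(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    ``two-sided`` sums hypergeometric outcomes whose probability does not
    exceed the observed table's (1e-7 relative tolerance for ties);
    ``greater``/``less`` are the one-sided enrichment/depletion tails of the
    top-left cell.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    if alternative == "two-sided":
        p_obs = pmf[a - lo]
        mask = pmf <= p_obs * (1 + 1e-7)
        p = 1.0 if mask.all() else pmf[mask].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, p))


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p (see :func:`fisher_exact_p`)."""
    return fisher_exact_p(a, b, c, d, alternative="two-sided")


def _term_genes(
    gene2terms: Mapping[str, set[str]], universe: set[str]
) -> dict[str, set[str]]:
    term2genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in gene2terms.get(gene, ()):
            term2genes.setdefault(term, set()).add(gene)
    return term2genes


def elim_enrichment(
    dag: GODag,
    gene2terms: Mapping[str, set[str]],
    universe: Iterable[str],
    interesting: Iterable[str],
    node_size: int = DEFAULT_NODE_SIZE,
    elim_cutoff: float = DEFAULT_ELIM_CUTOFF,
    ontology: str | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-term enrichment/depletion with elim decorrelation.

    Counts are always computed against the supplied universe.  Terms with
    fewer than ``node_size`` annotated universe genes are not testable.
    Processing order is decreasing depth (children before parents), ties in
    lexicographic term order; a term with p < ``elim_cutoff`` has its
    current gene set removed from every ancestor before the ancestor is
    tested.  ``elim_cutoff = 0`` disables elimination and reproduces the
    classic per-term Fisher test.  ``alternative`` selects the Fisher tail
    convention (two-sided default; "greater" for enrichment-only).
    """
    universe = set(universe)
    interesting = set(interesting)
    if not interesting <= universe:
        raise ValueError("interesting genes must be a subset of the universe")
    onts = [ontology] if ontology is not None else dag.ontologies()

    term2genes = _term_genes(gene2terms, universe)
    rows = []
    n_universe = len(universe)
    n_interesting = len(interesting)
    for ont in onts:
        depths = dag.depths(ont)
        order = sorted(depths, key=lambda t: (-depths[t], t))
        current = {
            t: set(term2genes.get(t, ())) for t in order
        }
        for term in order:
            genes = current[term]
            annotated = len(genes)
            if annotated < node_size:
                continue
            sig = len(genes & interesting)
            p = fisher_exact_p(
                sig,
                annotated - sig,
                n_interesting - sig,
                n_universe - annotated - (n_interesting - sig),
                alternative=alternative,
            )
            expected = n_interesting * annotated / n_universe
            rows.append(
                {
                    "term": term,
                    "name": dag.graph.nodes[term]["name"],
                    "ontology": ont,
                    "annotated_in_universe": annotated,
                    "significant_annotated": sig,
                    "expected": expected,
                    "p_fisher_two_tailed": p,
                    "direction": "enriched" if sig > expected else "depleted",
                }
            )
            if elim_cutoff > 0 and p < elim_cutoff:
                for anc in dag.ancestors(term):
                    if anc in current:
                        current[anc] -= genes
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "name",
            "ontology",
            "annotated_in_universe",
            "significant_annotated",
            "expected",
            "p_fisher_two_tailed",
            "direction",
        ],
    )
    return out.sort_values(
        ["ontology", "p_fisher_two_tailed", "term"]
    ).reset_index(drop=True)
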