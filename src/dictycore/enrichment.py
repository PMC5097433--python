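"""Hypergeometric GO-term enrichment with is_a annotation propagation.

Annotations are closed upward over the is_a DAG (true-path rule), then each
term with study annotations is tested with the upper-tail hypergeometric
distribution against the population background, BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError


@dataclass
class OntologyDAG:
    """Terms plus child -> parents is_a edges (must be acyclic)."""

    terms: frozenset[str]
    is_a: dict[str, frozenset[str]]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self.is_a.items():
            for parent in parents:
                if child not in self.terms or parent not in self.terms:
                    raise ValidationError(
                        f"OntologyDAG: edge {child} -> {parent} references unknown term"
                    )
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"OntologyDAG: is_a cycle detected: {cycle}")
        self._graph = g

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "OntologyDAG":
        terms = {t for e in edges for t in e}
        is_a: dict[str, set[str]] = {}
        for child, parent in edges:
            is_a.setdefault(child, set()).add(parent)
        return cls(
            terms=frozenset(terms),
            is_a={c: frozenset(p) for c, p in is_a.items()},
        )

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable by is_a edges (the term itself excluded)."""
        if term not in self.terms:
            return frozenset()
        return frozenset(nx.descendants(self._graph, term))


@dataclass
class EnrichmentResult:
    term_id: str
    k_study: int
    n_study: int
    k_pop: int
    n_pop: int
    p_value: float
    q_value: float


def propagate_annotations(
    dag: OntologyDAG,
    direct: dict[str, frozenset[str] | set[str]],
) -> dict[str, frozenset[str]]:
    """Close each gene's annotations upward over the DAG (idempotent)."""
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            closed.add(t)
            closed |= dag.ancestors(t)
        out[gene] = frozenset(closed)
    return out


def hypergeometric_enrichment(
    study: frozenset[str] | set[str],
    population: frozenset[str] | set[str],
    annotations: dict[str, frozenset[str]],
    fdr: float = 0.10,
    min_study_genes: int = 2,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of GO terms in a study set.

    ``annotations`` must already be propagated.  For each term annotated to
    at least ``min_study_genes`` study genes, the p-value is
    P(X >= k_study) for X ~ Hypergeom(n_pop, k_pop, n_study); BH correction
    runs across all tested terms.  Results are sorted by q then term id.
    """
    study = frozenset(study)
    population = frozenset(population)
    if not study <= population:
        raise ValidationError(
            "hypergeometric_enrichment: study set must be a subset of the population"
        )
    n_pop = len(population)
    n_study = len(study)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for t in annotations.get(gene, frozenset()):
            term_pop[t] = term_pop.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1

    tested = sorted(t for t, k in term_study.items() if k >= min_study_genes)
    if not tested:
        return []
    p_values = [
        float(stats.hypergeom.sf(term_study[t] - 1, n_pop, term_pop[t], n_study))
        for t in tested
    ]
    q_values = bh_adjust(p_values)
    results = [
        EnrichmentResult(
            term_id=t,
            k_study=term_study[t],
            n_study=n_study,
            k_pop=term_pop[t],
            n_pop=n_pop,
            p_value=p,
            q_value=float(q),
        )
        for t, p, q in zip(tested, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results
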