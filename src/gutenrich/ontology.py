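"""Gene Ontology handling: OBO parsing, DAG validation, annotation propagation.

The enrichment stage operates on a controlled vocabulary of functional terms
organised as a directed acyclic graph (the GO ``is_a`` hierarchy).  This
module loads an OBO 1.2 subset, validates the DAG, computes ancestor and
descendant closures, and applies the true-path rule (annotation to a term
implies annotation to all of its ancestors).

Only ``is_a`` edges are traversed; ``part_of`` and other relationship types
are ignored.  Obsolete terms are excluded at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


class OntologyError(ValueError):
    """Raised for structural defects: cycles, dangling is_a targets, unknown terms."""


@dataclass(frozen=True)
class Ontology:
    """An ``is_a`` DAG over functional terms.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point child -> parent,
    so graph-descendants of a node are its ontology *ancestors*.
    Node attributes: ``name`` and ``namespace``.
    """

    graph: nx.DiGraph

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def name(self, term: str) -> str:
        self._require(term)
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        self._require(term)
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> FrozenSet[str]:
        """Transitive ``is_a`` ancestors, excluding the term itself."""
        self._require(term)
        return frozenset(nx.descendants(self.graph, term))

    def descendants(self, term: str) -> FrozenSet[str]:
        """Transitive ``is_a`` descendants (more specific terms), excluding the term."""
        self._require(term)
        return frozenset(nx.ancestors(self.graph, term))

    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    def leaves(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.in_degree(t) == 0]

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`OntologyError` on failure."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"is_a graph contains a cycle: {cycle}")
        for term, attrs in self.graph.nodes(data=True):
            if "name" not in attrs:
                raise OntologyError(f"is_a target {term!r} is not a declared term")

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise OntologyError(f"unknown term id: {term!r}")


@dataclass
class AnnotationSet:
    """Contig -> term assignments, both direct and ancestor-closed.

    Invariants: ``propagated[c] >= direct[c]`` for every contig, and every
    propagated set is closed under the ``is_a`` ancestor relation.
    """

    direct: Dict[str, FrozenSet[str]]
    propagated: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def terms(self, propagated: bool = True) -> FrozenSet[str]:
        source = self.propagated if propagated else self.direct
        out: set[str] = set()
        for terms in source.values():
            out |= terms
        return frozenset(out)


def load_obo(path) -> Ontology:
    """Parse an OBO 1.2 file into a validated :class:`Ontology`.

    Reads ``id``, ``name``, ``namespace``, ``is_a`` and ``is_obsolete`` only;
    obsolete stanzas are dropped.  Fails on cycles and on ``is_a`` lines whose
    target is not a declared term.
    """
    multigraph = obonet.read_obo(path)  # obsolete terms already excluded
    graph = nx.DiGraph()
    graph.add_nodes_from(
        (t, {k: v for k, v in attrs.items() if k in ("name", "namespace")})
        for t, attrs in multigraph.nodes(data=True)
    )
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    ontology = Ontology(graph)
    ontology.validate()
    return ontology


def term_closure(ontology: Ontology, term: str, direction: str) -> FrozenSet[str]:
    """Transitive closure of a term in the given direction.

    ``direction`` is ``"ancestors"`` (more general terms) or ``"descendants"``
    (more specific terms).  The query term itself is excluded; the ancestors of
    a root form the empty set.
    """
    if direction == "ancestors":
        return ontology.ancestors(term)
    if direction == "descendants":
        return ontology.descendants(term)
    raise ValueError(f"direction must be 'ancestors' or 'descendants', got {direction!r}")


def propagate_annotations(
    direct: Mapping[str, Iterable[str]],
    ontology: Ontology,
    on_unknown: str = "warn",
) -> AnnotationSet:
    """Apply the true-path rule to direct annotations.

    Each contig's propagated set is its direct terms plus all of their
    ``is_a`` ancestors.  The operation is idempotent.  Annotations naming a
    term absent from the ontology are skipped with a warning (``on_unknown=
    "warn"``) or raise (``on_unknown="error"``).
    """
    if on_unknown not in ("warn", "error"):
        raise ValueError("on_unknown must be 'warn' or 'error'")
    # ancestor closures are shared across contigs; cache per term
    cache: Dict[str, FrozenSet[str]] = {}
    direct_out: Dict[str, FrozenSet[str]] = {}
    propagated: Dict[str, FrozenSet[str]] = {}
    for contig, terms in direct.items():
        kept: set[str] = set()
        closed: set[str] = set()
        for term in terms:
            if term not in ontology:
                if on_unknown == "error":
                    raise OntologyError(
                        f"contig {contig!r} annotated to unknown term {term!r}"
                    )
                logger.warning("contig %r annotated to unknown term %r; skipped", contig, term)
                continue
            kept.add(term)
            if term not in cache:
                cache[term] = ontology.ancestors(term)
            closed.add(term)
            closed |= cache[term]
        direct_out[contig] = frozenset(kept)
        propagated[contig] = frozenset(closed)
    return AnnotationSet(direct=direct_out, propagated=propagated)
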