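"""Gene Ontology DAG parsing and graph queries.

The ontology is held as a directed multigraph whose edges point from child
(more specific) to parent (more general) terms, each edge labelled with its
relation type (``is_a``, ``part_of``, ...).  Closure queries (ancestors,
descendants, depth, propagation) run over a configurable subset of relations;
the default ``{is_a, part_of}`` follows the convention of go-basic tooling.
"Depth" is the minimum number of edges needed to reach the namespace root.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import obonet

from .errors import (
    ConsistencyError,
    OboParseError,
    StructuralError,
    UnknownTermError,
)

logger = logging.getLogger("funcdeval")

#: Short namespace codes used throughout the package.
NAMESPACES = ("BP", "MF", "CC")

#: OBO namespace names <-> short codes.
OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
OBO_NAMESPACE_LONG = {v: k for k, v in OBO_NAMESPACE.items()}

#: Relations followed in closures unless the caller overrides them.
DEFAULT_TRAVERSAL_RELATIONS = frozenset({"is_a", "part_of"})

_TERM_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class TermSet:
    """A set of same-namespace GO terms (one protein's annotations or predictions)."""

    namespace: str
    members: frozenset[str]

    def __post_init__(self):
        if self.namespace not in NAMESPACES:
            raise ConsistencyError(f"unknown namespace {self.namespace!r}")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)


class OntologyGraph:
    """The GO DAG: terms, typed child->parent edges, alt-id and obsolete maps.

    Parameters
    ----------
    graph:
        Multigraph with one node per canonical term and one edge per
        ``(child, parent, relation)`` triple.
    traversal_relations:
        Relations followed by ``ancestors``/``descendants``/``depth``/
        ``propagate``.  Edges with other relations are kept but ignored by
        closures.
    """

    def __init__(
        self,
        graph: nx.MultiDiGraph,
        traversal_relations: Iterable[str] = DEFAULT_TRAVERSAL_RELATIONS,
        alt_ids: Mapping[str, str] | None = None,
        obsolete: Iterable[str] = (),
    ):
        self.graph = graph
        self.traversal_relations = frozenset(traversal_relations)
        if not self.traversal_relations:
            raise StructuralError("traversal_relations must be non-empty")
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.obsolete: frozenset[str] = frozenset(obsolete)

        for alt, canon in self.alt_ids.items():
            if canon not in graph:
                raise ConsistencyError(f"alt_id {alt} points at unknown term {canon}")

        # Traversal subgraph: plain DiGraph child -> parent, collapsing
        # parallel edges; per-pair relation recorded as the max-weight one
        # would be ambiguous, so keep the set of relations on each pair.
        dag = nx.DiGraph()
        dag.add_nodes_from(graph.nodes)
        for child, parent, rel in graph.edges(keys=True):
            if rel in self.traversal_relations:
                if dag.has_edge(child, parent):
                    dag[child][parent]["relations"].add(rel)
                else:
                    dag.add_edge(child, parent, relations={rel})
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise StructuralError(
                f"cycle over traversal relations involving {cycle[0][0]}"
            )
        self._dag = dag

        self.roots: dict[str, str] = {}
        for term in graph.nodes:
            if term in self.obsolete:
                continue
            if dag.out_degree(term) == 0:
                ns = self.namespace(term)
                if ns in self.roots:
                    raise StructuralError(
                        f"multiple roots in namespace {ns}: "
                        f"{self.roots[ns]} and {term}"
                    )
                self.roots[ns] = term

        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] = {}

    # -- basic lookups ----------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_ids

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map an alt-id to its canonical id; error on unknown ids."""
        if term in self.graph:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(term)

    def name(self, term: str) -> str:
        return self.graph.nodes[self.resolve(term)].get("name", "")

    def namespace(self, term: str) -> str:
        data = self.graph.nodes[self.resolve(term)]
        try:
            return OBO_NAMESPACE[data["namespace"]]
        except KeyError as exc:
            raise ConsistencyError(f"term {term} has no valid namespace") from exc

    def is_obsolete(self, term: str) -> bool:
        return self.resolve(term) in self.obsolete

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """All (child, parent, relation) triples, traversal or not."""
        return self.graph.edges(keys=True)

    # -- graph queries -----------------------------------------------------

    def parents(self, term: str) -> frozenset[str]:
        """Distance-1 more-general terms over traversal relations."""
        return frozenset(self._dag.successors(self.resolve(term)))

    def children(self, term: str) -> frozenset[str]:
        """Distance-1 more-specific terms over traversal relations."""
        return frozenset(self._dag.predecessors(self.resolve(term)))

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive closure of parents, excluding the term itself."""
        t = self.resolve(term)
        if t not in self._anc_cache:
            # edges point child->parent, so graph-theoretic descendants in
            # the traversal DiGraph are the ontological ancestors
            self._anc_cache[t] = frozenset(nx.descendants(self._dag, t))
        return self._anc_cache[t]

    def descendants(self, term: str) -> frozenset[str]:
        """Transitive closure of children, excluding the term itself."""
        t = self.resolve(term)
        if t not in self._desc_cache:
            self._desc_cache[t] = frozenset(nx.ancestors(self._dag, t))
        return self._desc_cache[t]

    def depth(self, term: str) -> int:
        """Minimum number of traversal edges from *term* to its namespace root."""
        t = self.resolve(term)
        if t not in self._depth_cache:
            ns = self.namespace(t)
            root = self.roots.get(ns)
            if root is None:
                raise StructuralError(f"namespace {ns} has no root")
            if t == root:
                self._depth_cache[t] = 0
            else:
                try:
                    self._depth_cache[t] = nx.shortest_path_length(self._dag, t, root)
                except nx.NetworkXNoPath as exc:
                    raise StructuralError(
                        f"term {t} cannot reach its namespace root {root}"
                    ) from exc
        return self._depth_cache[t]

    def relation(self, child: str, parent: str) -> frozenset[str]:
        """Traversal relation labels on the direct edge child -> parent."""
        data = self._dag.get_edge_data(self.resolve(child), self.resolve(parent))
        if data is None:
            return frozenset()
        return frozenset(data["relations"])

    def validate(self) -> None:
        """Check reachability invariants: every live term reaches its namespace root."""
        for term in self.graph.nodes:
            if term in self.obsolete:
                continue
            self.depth(term)  # raises StructuralError if unreachable

    def resolve_terms(
        self, terms: Iterable[str], namespace: str | None = None
    ) -> tuple[set[str], int]:
        """Resolve a collection of ids to live canonical terms.

        Unknown and obsolete ids are dropped (release skew between annotation
        files and the ontology is routine); the number dropped is returned and
        logged.  If *namespace* is given, terms from other namespaces raise
        :class:`ConsistencyError`.
        """
        resolved: set[str] = set()
        dropped = 0
        for term in terms:
            try:
                t = self.resolve(term)
            except UnknownTermError:
                dropped += 1
                continue
            if t in self.obsolete:
                dropped += 1
                continue
            if namespace is not None and self.namespace(t) != namespace:
                raise ConsistencyError(
                    f"term {t} ({self.namespace(t)}) in a {namespace} set"
                )
            resolved.add(t)
        if dropped:
            logger.info("dropped %d unknown/obsolete term ids", dropped)
        return resolved, dropped


# -- OBO I/O ---------------------------------------------------------------


def parse_obo(
    path,
    traversal_relations: Iterable[str] = DEFAULT_TRAVERSAL_RELATIONS,
) -> OntologyGraph:
    """Parse an OBO 1.2 file (go-basic dialect) into an :class:`OntologyGraph`.

    ``is_a:`` and ``relationship:`` lines are both captured with their
    relation type; ``alt_id:`` lines populate the alt-id map and
    ``is_obsolete:`` stanzas are flagged rather than dropped.
    """
    try:
        multi = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OboParseError(f"{path}: {exc}") from exc

    graph = nx.MultiDiGraph()
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    for term, data in multi.nodes(data=True):
        if not _TERM_RE.match(term):
            raise OboParseError(f"{path}: malformed term id {term!r}")
        graph.add_node(term, name=data.get("name", ""), namespace=data.get("namespace"))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
    for child, parent, rel in multi.edges(keys=True):
        graph.add_edge(child, parent, key=rel)
    return OntologyGraph(
        graph,
        traversal_relations=traversal_relations,
        alt_ids=alt_ids,
        obsolete=obsolete,
    )


def write_obo(graph: OntologyGraph, path, header_comments: Sequence[str] = ()) -> None:
    """Serialize an :class:`OntologyGraph` back to OBO 1.2.

    Round-trips through :func:`parse_obo`: re-parsing yields an equal graph.
    """
    alt_of: dict[str, list[str]] = {}
    for alt, canon in graph.alt_ids.items():
        alt_of.setdefault(canon, []).append(alt)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: go\n")
        for comment in header_comments:
            fh.write(f"remark: {comment}\n")
        for term in sorted(graph.graph.nodes):
            data = graph.graph.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', '')}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for alt in sorted(alt_of.get(term, [])):
                fh.write(f"alt_id: {alt}\n")
            for _, parent, rel in sorted(graph.graph.out_edges(term, keys=True)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            if term in graph.obsolete:
                fh.write("is_obsolete: true\n")


def graphs_equal(a: OntologyGraph, b: OntologyGraph) -> bool:
    """Structural equality: same terms, names, namespaces, typed edges, alt-ids, obsolete."""
    if set(a.graph.nodes) != set(b.graph.nodes):
        return False
    for t in a.graph.nodes:
        da, db = a.graph.nodes[t], b.graph.nodes[t]
        if (da.get("name", ""), da.get("namespace")) != (
            db.get("name", ""),
            db.get("namespace"),
        ):
            return False
    return (
        set(a.graph.edges(keys=True)) == set(b.graph.edges(keys=True))
        and a.alt_ids == b.alt_ids
        and a.obsolete == b.obsolete
    )


# -- Annotation containers -------------------------------------------------


@dataclass
class AnnotationSet:
    """Per-protein sets of GO terms, partitioned by namespace.

    ``terms[protein][namespace]`` is the set of term ids.  Used both for
    reference truth (GAF-derived) and for unscored prediction term sets.
    """

    terms: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, protein: str, namespace: str, term: str) -> None:
        if namespace not in NAMESPACES:
            raise ConsistencyError(f"unknown namespace {namespace!r}")
        self.terms.setdefault(protein, {}).setdefault(namespace, set()).add(term)

    def get(self, protein: str, namespace: str) -> set[str]:
        return self.terms.get(protein, {}).get(namespace, set())

    def term_set(self, protein: str, namespace: str) -> TermSet:
        return TermSet(namespace, frozenset(self.get(protein, namespace)))

    def proteins(self) -> list[str]:
        return sorted(self.terms)

    def items(self) -> Iterator[tuple[str, str, set[str]]]:
        """Yield (protein, namespace, terms) triples."""
        for protein in sorted(self.terms):
            for ns in sorted(self.terms[protein]):
                yield protein, ns, self.terms[protein][ns]

    def n_annotations(self) -> int:
        return sum(len(ts) for _, _, ts in self.items())

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(
            {p: {ns: set(ts) for ns, ts in by_ns.items()} for p, by_ns in self.terms.items()}
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self.terms == other.terms


def propagate(annotations: AnnotationSet, graph: OntologyGraph) -> AnnotationSet:
    """Close every protein's term set under ancestors (true-path rule).

    Idempotent; output is a superset of the input.  A term whose ontology
    namespace differs from the set it sits in raises :class:`ConsistencyError`.
    """
    out = AnnotationSet()
    for protein, ns, terms in annotations.items():
        closed: set[str] = set()
        for term in terms:
            t = graph.resolve(term)
            if graph.namespace(t) != ns:
                raise ConsistencyError(
                    f"term {t} ({graph.namespace(t)}) in the {ns} set of {protein}"
                )
            closed.add(t)
            closed |= graph.ancestors(t)
        out.terms.setdefault(protein, {})[ns] = closed
    return out


def filter_by_depth(records, graph: OntologyGraph, min_depth: int = 3):
    """Keep prediction records whose term sits at depth >= *min_depth*.

    Mirrors the treatment of predictors that emit near-root terms: terms
    fewer than three edges from the namespace root carry almost no
    information, so by default only records at depth >= 3 survive.  Order is
    preserved.
    """
    return [r for r in records if graph.depth(r.term) >= min_depth]
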