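"""Wang graph-based semantic similarity with best-match-average combination.

For a term A, every ancestor t receives an S-value: S_A(A) = 1 and
S_A(t) = max over children c of t (within A's ancestor DAG) of
w_e * S_A(c), where w_e is the contribution factor of the edge relation
(defaults: is_a 0.8, part_of 0.6).  Two terms are compared through their
shared ancestors,

    sim(A, B) = sum_{t in DAG_A ∩ DAG_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)),

and two term sets through the best-match average of the pairwise matrix:
the mean of all row maxima and all column maxima.  The similarity between a
non-empty and an empty set is undefined and reported as missing (``None``),
never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ConsistencyError, ValidationError
from .ontology import OntologyGraph, TermSet

#: Default contribution factors per relation type.
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


@dataclass(frozen=True)
class SValueMap:
    """S-values of a target term over its ancestor DAG, plus their sum SV."""

    target: str
    svalues: Mapping[str, float]
    sv_total: float


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise Wang similarities between two ordered term lists."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: np.ndarray  # shape (len(rows), len(cols)), entries in [0, 1]


def _edge_weight(graph: OntologyGraph, child: str, parent: str,
                 weights: Mapping[str, float]) -> float:
    best = None
    for rel in graph.relation(child, parent):
        try:
            w = weights[rel]
        except KeyError:
            raise ConfigurationError(f"no contribution factor for relation {rel!r}")
        if not (0 < w < 1):
            raise ConfigurationError(f"contribution factor for {rel!r} must be in (0,1)")
        best = w if best is None else max(best, w)
    if best is None:
        raise ConsistencyError(f"no traversal edge {child} -> {parent}")
    return best


def svalues(
    graph: OntologyGraph,
    term: str,
    weights: Mapping[str, float] | None = None,
) -> SValueMap:
    """Compute the Wang S-value map of *term* over its ancestor DAG."""
    if weights is None:
        weights = DEFAULT_WEIGHTS
    target = graph.resolve(term)
    dag_terms = {target} | set(graph.ancestors(target))
    svals: dict[str, float] = {target: 1.0}
    # process ancestors in increasing depth-from-target order: repeatedly
    # relax until fixpoint is unnecessary on a DAG if we sweep in
    # topological order of the ancestor subgraph
    order = _topo_order(graph, dag_terms, target)
    for t in order:
        if t == target:
            continue
        best = 0.0
        for c in graph.children(t):
            if c in dag_terms and c in svals:
                best = max(best, _edge_weight(graph, c, t, weights) * svals[c])
        svals[t] = best
    return SValueMap(target=target, svalues=svals, sv_total=float(sum(svals.values())))


def _topo_order(graph: OntologyGraph, dag_terms: set[str], target: str) -> list[str]:
    """Order dag_terms so every term comes after all its in-DAG children."""
    order: list[str] = []
    seen: set[str] = set()

    def visit(t: str) -> None:
        if t in seen:
            return
        seen.add(t)
        for c in graph.children(t):
            if c in dag_terms:
                visit(c)
        order.append(t)

    for t in sorted(dag_terms):
        visit(t)
    return order


def wang_sim(
    graph: OntologyGraph,
    a: str,
    b: str,
    weights: Mapping[str, float] | None = None,
    _cache: dict[str, SValueMap] | None = None,
) -> float:
    """Wang similarity of two same-namespace terms; symmetric, in [0, 1], sim(A,A)=1."""
    ra, rb = graph.resolve(a), graph.resolve(b)
    if graph.namespace(ra) != graph.namespace(rb):
        raise ConsistencyError(
            f"{ra} ({graph.namespace(ra)}) and {rb} ({graph.namespace(rb)}) "
            "are in different namespaces"
        )
    sa = _cached_svalues(graph, ra, weights, _cache)
    sb = _cached_svalues(graph, rb, weights, _cache)
    common = set(sa.svalues) & set(sb.svalues)
    num = sum(sa.svalues[t] + sb.svalues[t] for t in common)
    return num / (sa.sv_total + sb.sv_total)


def _cached_svalues(graph, term, weights, cache) -> SValueMap:
    if cache is None:
        return svalues(graph, term, weights)
    if term not in cache:
        cache[term] = svalues(graph, term, weights)
    return cache[term]


def sim_matrix(
    graph: OntologyGraph,
    set1: Sequence[str],
    set2: Sequence[str],
    weights: Mapping[str, float] | None = None,
    _cache: dict[str, SValueMap] | None = None,
) -> SimilarityMatrix:
    """Pairwise Wang similarity matrix between two term lists."""
    if _cache is None:
        _cache = {}
    rows = tuple(set1)
    cols = tuple(set2)
    values = np.empty((len(rows), len(cols)))
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            values[i, j] = wang_sim(graph, a, b, weights, _cache=_cache)
    return SimilarityMatrix(rows=rows, cols=cols, values=values)


def bma(matrix: SimilarityMatrix | np.ndarray) -> float:
    """Best-match average: mean of all row maxima and all column maxima."""
    values = matrix.values if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix)
    if values.size == 0:
        raise ValidationError("BMA of an empty matrix is undefined")
    n_rows, n_cols = values.shape
    return float(
        (values.max(axis=1).sum() + values.max(axis=0).sum()) / (n_rows + n_cols)
    )


def term_set_sim(
    graph: OntologyGraph,
    set1: Sequence[str],
    set2: Sequence[str],
    weights: Mapping[str, float] | None = None,
    _cache: dict[str, SValueMap] | None = None,
) -> float | None:
    """BMA-combined Wang similarity of two term collections; None if either is empty."""
    if len(set1) == 0 or len(set2) == 0:
        return None
    return bma(sim_matrix(graph, sorted(set(set1)), sorted(set(set2)), weights, _cache))


def protein_ss(
    graph: OntologyGraph,
    predicted: TermSet,
    annotated: TermSet,
    weights: Mapping[str, float] | None = None,
    _cache: dict[str, SValueMap] | None = None,
) -> float | None:
    """Per-protein semantic similarity between predicted and annotated term sets.

    1 means the two sets are semantically identical; ``None`` (undefined)
    when either side is empty.
    """
    if len(predicted) and len(annotated) and predicted.namespace != annotated.namespace:
        raise ConsistencyError("predicted and annotated sets are in different namespaces")
    return term_set_sim(
        graph, sorted(predicted.members), sorted(annotated.members), weights, _cache
    )
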