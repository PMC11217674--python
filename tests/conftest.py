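from __future__ import annotations

import networkx as nx
import pytest

from funcdeval.ontology import OBO_NAMESPACE_LONG, OntologyGraph


def make_graph(
    edges,
    namespace: str = "BP",
    extra_terms=(),
    alt_ids=None,
    obsolete=(),
    traversal_relations=("is_a", "part_of"),
) -> OntologyGraph:
    """Build an in-memory ontology from (child, parent[, relation]) triples."""
    g = nx.MultiDiGraph()
    long_ns = OBO_NAMESPACE_LONG[namespace]
    terms = set(extra_terms)
    norm = []
    for edge in edges:
        child, parent, rel = edge if len(edge) == 3 else (*edge, "is_a")
        terms.update((child, parent))
        norm.append((child, parent, rel))
    for t in sorted(terms):
        g.add_node(t, name=f"term {t}", namespace=long_ns)
    for child, parent, rel in norm:
        g.add_edge(child, parent, key=rel)
    return OntologyGraph(
        g,
        traversal_relations=traversal_relations,
        alt_ids=alt_ids or {},
        obsolete=obsolete,
    )


def edges_dict(graph: OntologyGraph) -> dict[str, set[str]]:
    """Child -> parents map over traversal edges, for the brute-force oracles."""
    out: dict[str, set[str]] = {}
    for child, parent, rel in graph.edges():
        if rel in graph.traversal_relations:
            out.setdefault(child, set()).add(parent)
    return out


def weighted_edges_dict(graph: OntologyGraph, weights=None) -> dict[str, dict[str, float]]:
    weights = weights or {"is_a": 0.8, "part_of": 0.6}
    out: dict[str, dict[str, float]] = {}
    for child, parent, rel in graph.edges():
        if rel in graph.traversal_relations:
            prev = out.setdefault(child, {}).get(parent, 0.0)
            out[child][parent] = max(prev, weights[rel])
    return out


@pytest.fixture
def chain_graph():
    """A -> B -> C -> D chain (A is the root)."""
    return make_graph([("B", "A"), ("C", "B"), ("D", "C")])


@pytest.fixture
def diamond_graph():
    """Root A; B and C both is_a A; D is_a both B and C."""
    return make_graph([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


#: Fixture reproducing the sulfite-reductase neighbourhood used in the
#: worked example: oxidoreductase activity GO:0016667 is the parent of
#: sulfite reductase activity GO:0016002, whose child is the NADPH form
#: GO:0004783.
SULFITE_OBO = """\
format-version: 1.2
ontology: go

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0016491
name: oxidoreductase activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0016667
name: oxidoreductase activity, acting on a sulfur group of donors
namespace: molecular_function
is_a: GO:0016491

[Term]
id: GO:0016002
name: sulfite reductase activity
namespace: molecular_function
is_a: GO:0016667

[Term]
id: GO:0004783
name: sulfite reductase (NADPH) activity
namespace: molecular_function
is_a: GO:0016002

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function
is_a: GO:0003674
"""


@pytest.fixture
def sulfite_graph(tmp_path):
    from funcdeval.ontology import parse_obo

    path = tmp_path / "sulfite.obo"
    path.write_text(SULFITE_OBO)
    return parse_obo(path)


@pytest.fixture
def small_synthetic():
    """A modest seeded synthetic instance shared by several test modules."""
    from funcdeval.synthetic import (
        CorpusConfig,
        DagConfig,
        PredictionConfig,
        SyntheticConfig,
        generate_all,
    )

    config = SyntheticConfig(
        seed=7,
        dag=DagConfig(n_terms=150, n_levels=5),
        corpus=CorpusConfig(n_proteins=120),
        predictions=PredictionConfig(n_records=1500),
    )
    return generate_all(config)
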