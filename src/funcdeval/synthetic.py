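"""Synthetic GO-like data with recorded ground truth.

Everything the evaluation pipeline consumes can be generated here: a
layered, acyclic, GO-like ontology; an annotation corpus over proteins with
an isoform (protein -> gene) structure; scored prediction sets whose terms
relate to the truth by a controlled mixture of exact / parent-child /
distant-branch / unrelated placements; and DEG lists with planted term
enrichment at a stated odds ratio.  Every draw comes from a single seeded
generator, ground truth is recorded alongside each artifact, and all
serialized files round-trip through the package's parsers.

Defaults reflect the regime the evaluation operates in: a 500-term DAG of
six levels, corpora of hundreds of proteins with a handful of leaf-biased
annotations each, a precision mixture of (0.4, 0.3, 0.2, 0.1) over
HIT/Close/Related/Unrelated with overlapping per-class Beta score
distributions (correct placements scoring higher on average), and planted
enrichment at odds ratio 9 for a term carried by ~10% of 1000 genes with
study lists of 50 genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .annotation_io import PredictionRecord
from .errors import ConfigurationError, ValidationError
from .ontology import (
    AnnotationSet,
    OntologyGraph,
    OBO_NAMESPACE_LONG,
)

#: Per-class Beta(a, b) score parameters; correct classes score higher on
#: average but the supports overlap, so stratification is non-degenerate.
DEFAULT_SCORE_PARAMS = {
    "HIT": (8.0, 2.0),
    "Close": (5.0, 3.0),
    "Related": (3.0, 3.0),
    "Unrelated": (2.0, 5.0),
}

CLASS_NAMES = ("HIT", "Close", "Related", "Unrelated")
#: When an intended placement is unavailable on the sampled term, fall
#: forward through this fixed order.
FALLBACK_ORDER = {"HIT": ("Close", "Related", "Unrelated"),
                  "Close": ("Related", "Unrelated"),
                  "Related": ("Unrelated",),
                  "Unrelated": ()}


@dataclass
class DagConfig:
    n_terms: int = 500
    n_levels: int = 6
    mean_children: float = 2.5
    multi_parent_prob: float = 0.2
    part_of_prob: float = 0.15
    namespaces: tuple[str, ...] = ("BP",)


@dataclass
class CorpusConfig:
    n_proteins: int = 500
    mean_terms_per_protein: float = 3.0
    depth_bias: float = 1.6  # term weight ~ depth_bias ** depth (leaf-biased)
    isoform_mean: float = 1.0  # mean proteins per gene


@dataclass
class PredictionConfig:
    n_records: int = 10_000
    mixture: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    score_params: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_PARAMS))
    method: str = "synthetic"

    def __post_init__(self):
        if abs(sum(self.mixture) - 1.0) > 1e-12:
            raise ConfigurationError("precision mixture must sum to 1")


@dataclass
class EnrichmentPlantConfig:
    odds_ratio: float = 9.0
    target_membership: float = 0.10
    study_size: int = 50

    def __post_init__(self):
        if self.odds_ratio < 1:
            raise ConfigurationError("odds ratio must be >= 1")


@dataclass
class SyntheticConfig:
    seed: int = 0
    dag: DagConfig = field(default_factory=DagConfig)
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    predictions: PredictionConfig = field(default_factory=PredictionConfig)
    enrichment: EnrichmentPlantConfig = field(default_factory=EnrichmentPlantConfig)

    def describe(self) -> str:
        return f"funcdeval synthetic data, config={dataclasses.asdict(self)}"


@dataclass
class PredictionTruth:
    """Ground truth for a generated prediction set.

    ``realized[i]`` is the precision class of ``records[i]`` evaluated
    against the protein's *full* annotation set (a term planted as Unrelated
    to one annotation can still be Close to another); ``intended[i]`` is the
    class drawn from the mixture before availability fallback.
    """

    records: list[PredictionRecord]
    intended: list[str]
    realized: list[str]
    true_term: list[str]


@dataclass
class DegTruth:
    """Planted-enrichment ground truth for one generated DEG list."""

    target_terms: set[str]
    target_genes: set[str]  # genes carrying a target term after propagation
    study_hits: int  # study genes that carry a target term


# -- DAG -------------------------------------------------------------------


def generate_dag(config: DagConfig, seed_or_rng) -> OntologyGraph:
    """Generate a layered single-root DAG per namespace.

    Terms are spread over ``n_levels`` levels with widths growing roughly by
    ``mean_children`` per level.  Each non-root term receives one primary
    parent from the previous level plus, with probability
    ``multi_parent_prob``, one extra parent from any strictly shallower
    level; edges are ``part_of`` with probability ``part_of_prob``, else
    ``is_a``.  Acyclic by construction.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, int) else seed_or_rng
    if config.n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    per_ns = config.n_terms // len(config.namespaces)
    if per_ns < config.n_levels:
        raise ValidationError(
            f"n_terms per namespace ({per_ns}) must be >= n_levels ({config.n_levels})"
        )

    graph = nx.MultiDiGraph()
    counter = 1
    for ns in config.namespaces:
        long_ns = OBO_NAMESPACE_LONG[ns]
        # level widths: geometric growth by mean_children, then adjusted so
        # every level holds >= 1 term and the total is exact
        raw = np.array([config.mean_children ** l for l in range(config.n_levels)])
        widths = np.maximum(1, np.round(raw / raw.sum() * per_ns).astype(int))
        widths[0] = 1
        while widths.sum() > per_ns:
            widths[int(np.argmax(widths))] -= 1
        while widths.sum() < per_ns:
            widths[int(np.argmax(raw))] += 1

        levels: list[list[str]] = []
        for level, width in enumerate(widths):
            terms = []
            for _ in range(width):
                term = f"GO:{counter:07d}"
                counter += 1
                graph.add_node(
                    term,
                    name=f"synthetic {ns} term {term[3:]}",
                    namespace=long_ns,
                )
                terms.append(term)
            levels.append(terms)

        shallower: list[str] = list(levels[0])
        for level in range(1, config.n_levels):
            prev = levels[level - 1]
            for term in levels[level]:
                parents = {prev[rng.integers(len(prev))]}
                if len(shallower) > 1 and rng.random() < config.multi_parent_prob:
                    extra = shallower[rng.integers(len(shallower))]
                    parents.add(extra)
                for parent in parents:
                    rel = "part_of" if rng.random() < config.part_of_prob else "is_a"
                    graph.add_edge(term, parent, key=rel)
            shallower.extend(levels[level])
    return OntologyGraph(graph)


# -- corpus ----------------------------------------------------------------


def generate_corpus(
    graph: OntologyGraph, config: CorpusConfig, seed_or_rng
) -> tuple[AnnotationSet, dict[str, str]]:
    """Annotate proteins with leaf-biased terms and group them into genes.

    Per protein the number of direct annotations is Poisson with mean
    ``mean_terms_per_protein``; each is a term drawn with weight
    ``depth_bias ** depth`` (deeper terms preferred) from a random
    namespace.  Genes collect ``1 + Poisson(isoform_mean - 1)`` proteins, so
    ``isoform_mean = 1`` yields a protein<->gene bijection.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, int) else seed_or_rng
    namespaces = sorted(graph.roots)
    if not namespaces:
        raise ValidationError("ontology has no namespace roots")
    terms_by_ns = {}
    weights_by_ns = {}
    for ns in namespaces:
        terms = sorted(
            t for t in graph.terms
            if not graph.is_obsolete(t) and graph.namespace(t) == ns
        )
        w = np.array([config.depth_bias ** graph.depth(t) for t in terms])
        terms_by_ns[ns] = terms
        weights_by_ns[ns] = w / w.sum()

    annotations = AnnotationSet()
    for i in range(config.n_proteins):
        protein = f"P{i:05d}"
        k = rng.poisson(config.mean_terms_per_protein)
        for _ in range(k):
            ns = namespaces[rng.integers(len(namespaces))]
            term = terms_by_ns[ns][
                rng.choice(len(terms_by_ns[ns]), p=weights_by_ns[ns])
            ]
            annotations.add(protein, ns, term)

    idmap: dict[str, str] = {}
    gene_idx = 0
    i = 0
    while i < config.n_proteins:
        size = 1 + rng.poisson(max(config.isoform_mean - 1.0, 0.0))
        gene = f"G{gene_idx:05d}"
        gene_idx += 1
        for _ in range(min(size, config.n_proteins - i)):
            idmap[f"P{i:05d}"] = gene
            i += 1
    return annotations, idmap


# -- predictions -----------------------------------------------------------


def _relation_pools(graph: OntologyGraph, term: str, ns_terms: list[str]):
    """Candidate placement pools per class for one true term."""
    parents = graph.parents(term)
    children = graph.children(term)
    close = sorted(parents | children)
    anc = graph.ancestors(term)
    desc = graph.descendants(term)
    related = sorted((anc | desc) - set(close))
    excluded = {term} | anc | desc | set(close)
    unrelated = [t for t in ns_terms if t not in excluded]
    return {"HIT": [term], "Close": close, "Related": related, "Unrelated": unrelated}


def _realized_class(graph: OntologyGraph, placed: str, annotated: set[str]) -> str:
    """Best precision class of a placed term against a full annotation set.

    Coded directly on the closure queries (not through the classifier
    module) so the classifier can be checked against recorded ground truth.
    """
    if placed in annotated:
        return "HIT"
    neigh = graph.parents(placed) | graph.children(placed)
    if annotated & neigh:
        return "Close"
    branch = graph.ancestors(placed) | graph.descendants(placed)
    if annotated & branch:
        return "Related"
    return "Unrelated"


def generate_predictions(
    graph: OntologyGraph,
    corpus: AnnotationSet,
    config: PredictionConfig,
    seed_or_rng,
) -> PredictionTruth:
    """Sample scored predictions with a controlled precision-class mixture.

    Each record picks an annotated (protein, namespace, term) triple, draws
    an intended class from the mixture, and places the predicted term
    accordingly (HIT: the term itself; Close: a uniform parent/child;
    Related: a uniform ancestor/descendant at distance >= 2; Unrelated: a
    uniform same-namespace term outside the branch).  If the intended pool
    is empty the next class in the fixed fallback order is used.  The
    realized class -- evaluated against the protein's full annotation set --
    is recorded, and the score is drawn from that class's Beta distribution.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, int) else seed_or_rng
    triples = [
        (protein, ns, term)
        for protein, ns, terms in corpus.items()
        for term in sorted(terms)
    ]
    if not triples:
        raise ValidationError("corpus has no annotations")
    ns_terms = {
        ns: sorted(
            t for t in graph.terms
            if not graph.is_obsolete(t) and graph.namespace(t) == ns
        )
        for ns in graph.roots
    }
    for ns, terms in ns_terms.items():
        if len(terms) < 5:
            raise ConfigurationError(f"namespace {ns} too small for Unrelated placement")

    pool_cache: dict[str, dict[str, list[str]]] = {}
    truth = PredictionTruth(records=[], intended=[], realized=[], true_term=[])
    mixture = np.asarray(config.mixture)
    class_draws = rng.choice(4, size=config.n_records, p=mixture)
    triple_draws = rng.integers(len(triples), size=config.n_records)
    for intended_idx, triple_idx in zip(class_draws, triple_draws):
        protein, ns, term = triples[triple_idx]
        intended = CLASS_NAMES[intended_idx]
        if term not in pool_cache:
            pool_cache[term] = _relation_pools(graph, term, ns_terms[ns])
        pools = pool_cache[term]
        # forward fallback first (Close -> Related -> Unrelated), then back
        # toward better classes for terms where nothing further out exists
        # (e.g. a root term has no Unrelated pool); HIT is always available
        candidates = [intended, *FALLBACK_ORDER[intended]]
        candidates += [c for c in ("Related", "Close", "HIT") if c not in candidates]
        placement_class = next(c for c in candidates if pools[c])
        pool = pools[placement_class]
        placed = pool[rng.integers(len(pool))]
        realized = _realized_class(graph, placed, corpus.get(protein, ns))
        a, b = config.score_params[realized]
        score = float(rng.beta(a, b))
        truth.records.append(
            PredictionRecord(protein, placed, score, config.method, ns)
        )
        truth.intended.append(intended)
        truth.realized.append(realized)
        truth.true_term.append(term)
    return truth


# -- planted enrichment ----------------------------------------------------


def plant_deg(
    gene2terms: dict[str, dict[str, set[str]]],
    graph: OntologyGraph,
    config: EnrichmentPlantConfig,
    seed_or_rng,
    namespace: str | None = None,
    target_terms: set[str] | None = None,
) -> tuple[set[str], set[str], DegTruth]:
    """Draw a study gene list enriched for carriers of a target term.

    Gene g is sampled (without replacement, to ``study_size``) with weight
    ``odds_ratio`` if its propagated annotation contains any target term,
    else 1.  When no target term is supplied, the term whose propagated
    carrier frequency is closest to ``target_membership`` is chosen.  The
    universe is every gene of *gene2terms*.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, int) else seed_or_rng
    if namespace is None:
        namespace = sorted(graph.roots)[0]
    universe = set(gene2terms)
    if config.study_size > len(universe):
        raise ValidationError("study_size exceeds universe size")

    propagated: dict[str, set[str]] = {}
    for gene, by_ns in gene2terms.items():
        closed: set[str] = set()
        for t in by_ns.get(namespace, set()):
            rt = graph.resolve(t)
            closed.add(rt)
            closed |= graph.ancestors(rt)
        propagated[gene] = closed

    if target_terms is None:
        freq: dict[str, float] = {}
        for terms in propagated.values():
            for t in terms:
                freq[t] = freq.get(t, 0.0) + 1.0 / len(universe)
        if not freq:
            raise ValidationError(f"no {namespace} annotations to plant enrichment in")
        target = min(freq, key=lambda t: (abs(freq[t] - config.target_membership), t))
        target_terms = {target}

    genes = sorted(universe)
    carriers = {g for g in genes if propagated[g] & target_terms}
    weights = np.array([config.odds_ratio if g in carriers else 1.0 for g in genes])
    weights /= weights.sum()
    study = set(
        np.array(genes)[
            rng.choice(len(genes), size=config.study_size, replace=False, p=weights)
        ]
    )
    truth = DegTruth(
        target_terms=set(target_terms),
        target_genes=carriers,
        study_hits=len(study & carriers),
    )
    return study, universe, truth


# -- one-call pipeline input -----------------------------------------------


def generate_all(config: SyntheticConfig):
    """Generate a complete, internally consistent pipeline input set.

    Returns (graph, corpus, idmap, prediction truth, study, universe, DEG
    truth); all randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    graph = generate_dag(config.dag, rng)
    corpus, idmap = generate_corpus(graph, config.corpus, rng)
    truth = generate_predictions(graph, corpus, config.predictions, rng)
    gene2terms: dict[str, dict[str, set[str]]] = {}
    for protein, ns, terms in corpus.items():
        gene = idmap[protein]
        gene2terms.setdefault(gene, {}).setdefault(ns, set()).update(terms)
    for gene in set(idmap.values()):
        gene2terms.setdefault(gene, {})
    study, universe, deg_truth = plant_deg(gene2terms, graph, config.enrichment, rng)
    return graph, corpus, idmap, truth, study, universe, deg_truth
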