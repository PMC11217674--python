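"""Information content of GO terms from child/ancestor annotation counts.

The specificity of a term t is measured as IC(t) = -log2(p(t)) with

    p(t) = 1 - child_count(t) / (child_count(t) + ancestor_count(t)),

where, under the default ``descendant_protein_counts`` strategy, child_count
counts the (protein, term) annotations of a propagated reference corpus lying
on t or any proper descendant, and ancestor_count those lying on any proper
ancestor.  An alternative ``term_graph_counts`` strategy uses pure DAG counts
(|descendants|, |ancestors|) and ignores the corpus.

Note the formula's direction: a namespace root has ancestor_count = 0, hence
p = 0 and IC = +inf (reported as an infinity sentinel and excluded from
averages), while a deep term with nothing annotated below it has
child_count = 0, p = 1 and IC = 0.  The formula is applied verbatim; see the
methods note for a discussion of this orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import PredictionRecord
from .errors import ConfigurationError
from .ontology import AnnotationSet, OntologyGraph, propagate

STRATEGIES = ("descendant_protein_counts", "term_graph_counts")


@dataclass
class ICModel:
    """Per-term probabilities and information content (bits) for one counting strategy.

    ``p[t]`` is None when the denominator child_count + ancestor_count is
    zero (no information at all about the term); ``ic[t]`` is then also None.
    ``ic[t]`` is ``math.inf`` exactly when ``p[t] == 0``.
    """

    strategy: str
    child_count: dict[str, int] = field(default_factory=dict)
    ancestor_count: dict[str, int] = field(default_factory=dict)
    p: dict[str, float | None] = field(default_factory=dict)
    ic: dict[str, float | None] = field(default_factory=dict)

    def ic_of(self, term: str) -> float | None:
        return self.ic.get(term)


def build_ic_model(
    graph: OntologyGraph,
    corpus: AnnotationSet | None = None,
    strategy: str = "descendant_protein_counts",
    smoothing: bool = False,
) -> ICModel:
    """Materialize p and IC for every live term of the ontology.

    With *smoothing* a pseudo-count of 1 is added to both the child and the
    ancestor count, removing the p = 0 and p = 1 boundary cases (off by
    default).  Deterministic: identical inputs give identical models.
    """
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown IC strategy {strategy!r}")
    model = ICModel(strategy=strategy)

    live_terms = [t for t in graph.terms if not graph.is_obsolete(t)]
    if strategy == "term_graph_counts":
        for t in live_terms:
            model.child_count[t] = len(graph.descendants(t))
            model.ancestor_count[t] = len(graph.ancestors(t))
    else:
        if corpus is None:
            raise ConfigurationError(
                "descendant_protein_counts requires a reference corpus"
            )
        propagated = propagate(corpus, graph)
        # annotations "on" each term: number of proteins carrying it after
        # true-path closure
        on_term: dict[str, int] = {}
        for _, _, terms in propagated.items():
            for t in terms:
                on_term[t] = on_term.get(t, 0) + 1
        for t in live_terms:
            below = on_term.get(t, 0) + sum(
                on_term.get(d, 0) for d in graph.descendants(t)
            )
            above = sum(on_term.get(a, 0) for a in graph.ancestors(t))
            model.child_count[t] = below
            model.ancestor_count[t] = above

    for t in live_terms:
        child = model.child_count[t] + (1 if smoothing else 0)
        anc = model.ancestor_count[t] + (1 if smoothing else 0)
        denom = child + anc
        if denom == 0:
            model.p[t] = None
            model.ic[t] = None
            continue
        p = 1.0 - child / denom
        model.p[t] = p
        model.ic[t] = math.inf if p == 0.0 else -math.log2(p)
    return model


def ic_summary(model: ICModel, records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """IC distribution per (method, namespace) over record terms, with multiplicity.

    Infinite and undefined IC values are excluded from the moments but
    reported in ``n_infinite`` / ``n_undefined``.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    n_inf: dict[tuple[str, str], int] = {}
    n_undef: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.method, r.namespace)
        groups.setdefault(key, [])
        n_inf.setdefault(key, 0)
        n_undef.setdefault(key, 0)
        value = model.ic.get(r.term)
        if value is None:
            n_undef[key] += 1
        elif math.isinf(value):
            n_inf[key] += 1
        else:
            groups[key].append(value)
    rows = []
    for (method, ns) in sorted(groups):
        finite = groups[(method, ns)]
        if finite:
            q1, med, q3 = np.quantile(finite, [0.25, 0.5, 0.75])
            mean = float(np.mean(finite))
        else:
            q1 = med = q3 = mean = float("nan")
        rows.append(
            {
                "method": method,
                "namespace": ns,
                "n": len(finite) + n_inf[(method, ns)] + n_undef[(method, ns)],
                "n_finite": len(finite),
                "n_infinite": n_inf[(method, ns)],
                "n_undefined": n_undef[(method, ns)],
                "mean_ic_bits": mean,
                "q1": q1,
                "median": med,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)
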