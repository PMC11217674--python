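"""Two-sided per-protein coverage at cumulative precision levels.

For each (protein, method, namespace) the report answers two questions at
three increasingly permissive levels (``guessed`` = HIT only,
``at_least_close`` = HIT or Close, ``at_least_related`` = HIT, Close or
Related):

* prediction side -- what fraction of the predicted terms achieves the
  level against the annotation set (are the predictions correct?);
* annotation side -- what fraction of the annotated terms is matched at the
  level by at least one prediction (is the annotation space recovered?).

Both sides use the same DAG relations, evaluated direction-symmetrically,
and are monotone non-decreasing across the levels.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .annotation_io import PredictionRecord
from .ontology import AnnotationSet, OntologyGraph
from .precision import PrecisionLabel, classify

#: Cumulative levels and the label sets they admit.
LEVELS = (
    ("guessed", frozenset({PrecisionLabel.HIT})),
    ("at_least_close", frozenset({PrecisionLabel.HIT, PrecisionLabel.CLOSE})),
    (
        "at_least_related",
        frozenset({PrecisionLabel.HIT, PrecisionLabel.CLOSE, PrecisionLabel.RELATED}),
    ),
)


def _best_relation(graph: OntologyGraph, term: str, others: frozenset[str]) -> PrecisionLabel:
    """Best precision relation of *term* against a set, via the shared classifier logic."""
    from .ontology import TermSet

    ns = graph.namespace(term)
    return classify(graph, term, TermSet(ns, others))


def coverage(
    graph: OntologyGraph,
    predictions: Sequence[PredictionRecord],
    reference: AnnotationSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein coverage report and per-(method, namespace) mean aggregate.

    Proteins with reference annotation but no predictions in a namespace get
    an undefined (NaN) prediction side and 0.0 on the annotation side.
    Proteins without reference annotation are skipped entirely (unevaluable).
    """
    predicted: dict[tuple[str, str, str], set[str]] = {}
    strata: set[tuple[str, str]] = set()
    for r in predictions:
        predicted.setdefault((r.protein, r.method, r.namespace), set()).add(
            graph.resolve(r.term)
        )
        strata.add((r.method, r.namespace))

    rows = []
    for method, ns in sorted(strata):
        proteins = sorted(
            {p for (p, m, n) in predicted if m == method and n == ns}
            | {p for p in reference.proteins() if reference.get(p, ns)}
        )
        for protein in proteins:
            annotated = frozenset(
                graph.resolve(t) for t in reference.get(protein, ns)
            )
            if not annotated:
                continue  # unevaluable: nothing to judge against
            pred_terms = predicted.get((protein, method, ns), set())
            row = {
                "protein": protein,
                "method": method,
                "namespace": ns,
                "predicted_total": len(pred_terms),
                "annotated_total": len(annotated),
            }
            if pred_terms:
                labels = {
                    t: _best_relation(graph, t, annotated) for t in pred_terms
                }
                for name, admitted in LEVELS:
                    n_ok = sum(1 for lab in labels.values() if lab in admitted)
                    row[f"prediction_{name}"] = n_ok / len(pred_terms)
                pred_fs = frozenset(pred_terms)
                for name, admitted in LEVELS:
                    n_cov = sum(
                        1
                        for t in annotated
                        if _best_relation(graph, t, pred_fs) in admitted
                    )
                    row[f"annotation_{name}"] = n_cov / len(annotated)
            else:
                for name, _ in LEVELS:
                    row[f"prediction_{name}"] = float("nan")
                    row[f"annotation_{name}"] = 0.0
            rows.append(row)

    per_protein = pd.DataFrame(rows)
    if len(per_protein):
        value_cols = [c for c in per_protein.columns
                      if c.startswith(("prediction_", "annotation_"))]
        aggregate = (
            per_protein.groupby(["method", "namespace"])[value_cols]
            .mean()
            .reset_index()
        )
    else:
        aggregate = pd.DataFrame(columns=["method", "namespace"])
    return per_protein, aggregate
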