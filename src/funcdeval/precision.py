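"""Four-class precision of predicted GO terms against reference annotations.

A predicted term is judged by where it sits in the DAG relative to the
protein's annotated terms:

* ``HIT``       -- the exact annotated term;
* ``Close``     -- a direct parent or child of an annotated term;
* ``Related``   -- an ancestor or descendant at graph distance >= 2;
* ``Unrelated`` -- none of the above (a different branch of the DAG).

When the annotation set contains several terms the most favourable relation
wins (HIT > Close > Related > Unrelated), so the classes partition the
predictions and per-stratum frequencies sum to one.  Proteins with no
reference annotation in a namespace cannot be judged and are counted
separately as "unevaluable".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import PredictionRecord
from .errors import ConsistencyError, ValidationError
from .ontology import AnnotationSet, OntologyGraph, TermSet


class PrecisionLabel(enum.Enum):
    """Precision class of one prediction; order encodes precedence (best first)."""

    HIT = "HIT"
    CLOSE = "Close"
    RELATED = "Related"
    UNRELATED = "Unrelated"

    def __str__(self) -> str:
        return self.value


LABEL_ORDER = tuple(PrecisionLabel)


def classify(graph: OntologyGraph, predicted: str, annotated: TermSet) -> PrecisionLabel:
    """Classify one predicted term against a non-empty same-namespace annotation set.

    The best relation over the set wins: HIT if the term itself is annotated;
    else Close if it is a direct parent/child of any annotated term; else
    Related if it is an ancestor/descendant (necessarily at distance >= 2,
    parents/children having been checked first); else Unrelated.
    """
    if len(annotated) == 0:
        raise ValidationError("empty annotation set: protein is unevaluable")
    pred = graph.resolve(predicted)
    if graph.namespace(pred) != annotated.namespace:
        raise ConsistencyError(
            f"predicted term {pred} is {graph.namespace(pred)}, "
            f"annotation set is {annotated.namespace}"
        )
    members = {graph.resolve(t) for t in annotated}
    for t in members:
        if graph.namespace(t) != annotated.namespace:
            raise ConsistencyError(f"annotated term {t} not in {annotated.namespace}")
    if pred in members:
        return PrecisionLabel.HIT
    pred_parents = graph.parents(pred)
    pred_children = graph.children(pred)
    if members & (pred_parents | pred_children):
        return PrecisionLabel.CLOSE
    pred_anc = graph.ancestors(pred)
    pred_desc = graph.descendants(pred)
    if members & (pred_anc | pred_desc):
        return PrecisionLabel.RELATED
    return PrecisionLabel.UNRELATED


@dataclass
class PrecisionTable:
    """Counts and frequencies of precision classes per (method, namespace)."""

    counts: dict[tuple[str, str, PrecisionLabel], int] = field(default_factory=dict)
    unevaluable: int = 0  # records whose protein lacks reference annotation

    def increment(self, method: str, namespace: str, label: PrecisionLabel) -> None:
        key = (method, namespace, label)
        self.counts[key] = self.counts.get(key, 0) + 1

    def total(self, method: str, namespace: str) -> int:
        return sum(
            n for (m, ns, _), n in self.counts.items() if m == method and ns == namespace
        )

    def frequency(self, method: str, namespace: str, label: PrecisionLabel) -> float:
        total = self.total(method, namespace)
        if total == 0:
            return float("nan")
        return self.counts.get((method, namespace, label), 0) / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        strata = sorted({(m, ns) for m, ns, _ in self.counts})
        for method, ns in strata:
            for label in LABEL_ORDER:
                rows.append(
                    {
                        "method": method,
                        "namespace": ns,
                        "label": label.value,
                        "count": self.counts.get((method, ns, label), 0),
                        "frequency": self.frequency(method, ns, label),
                    }
                )
        return pd.DataFrame(rows)


def classify_all(
    graph: OntologyGraph,
    predictions: Sequence[PredictionRecord],
    reference: AnnotationSet,
) -> tuple[PrecisionTable, list[PrecisionLabel | None]]:
    """Label every prediction record and tabulate class frequencies.

    Returns the table and a per-record label list aligned with *predictions*;
    records whose protein has no same-namespace reference annotation get
    ``None`` and are counted in ``table.unevaluable``.
    """
    table = PrecisionTable()
    labels: list[PrecisionLabel | None] = []
    for record in predictions:
        annotated = reference.term_set(record.protein, record.namespace)
        if len(annotated) == 0:
            table.unevaluable += 1
            labels.append(None)
            continue
        label = classify(graph, record.term, annotated)
        table.increment(record.method, record.namespace, label)
        labels.append(label)
    return table, labels


def scores_by_precision(
    records: Sequence[PredictionRecord],
    labels: Sequence[PrecisionLabel | None],
) -> pd.DataFrame:
    """Score distribution summary (n, quartiles) per (method, namespace, label).

    Strata with no records are reported with n = 0 and NaN quartiles, so the
    frame always carries all four classes for every (method, namespace) seen.
    """
    if len(records) != len(labels):
        raise ValidationError("records and labels must align")
    scores: dict[tuple[str, str, PrecisionLabel], list[float]] = {}
    strata: set[tuple[str, str]] = set()
    for record, label in zip(records, labels):
        if label is None:
            continue
        strata.add((record.method, record.namespace))
        scores.setdefault((record.method, record.namespace, label), []).append(record.score)
    rows = []
    for method, ns in sorted(strata):
        for label in LABEL_ORDER:
            vals = scores.get((method, ns, label), [])
            if vals:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            else:
                q1 = med = q3 = float("nan")
            rows.append(
                {
                    "method": method,
                    "namespace": ns,
                    "label": label.value,
                    "n": len(vals),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def iter_labelled(
    records: Iterable[PredictionRecord],
    labels: Iterable[PrecisionLabel | None],
):
    """Yield (record, label) pairs for records that received a label."""
    for record, label in zip(records, labels):
        if label is not None:
            yield record, label
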