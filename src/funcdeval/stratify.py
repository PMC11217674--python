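"""Cumulative score-quantile stratification of prediction sets.

Each method's scores are split at their empirical 25/50/75% quantiles
(linear interpolation of order statistics, the default of the R ``quantile``
function) into four *cumulative* groups: q = 0.00 keeps every record,
q = 0.25 drops the lowest-scoring quarter, q = 0.50 keeps the top half and
q = 0.75 only the top quarter.  Records exactly at a cutoff are retained
(>=), so under ties a group can slightly exceed its nominal fraction.
Groups are therefore nested, and per-group metrics (per-protein semantic
similarity, IC, protein counts) quantify how much usable signal survives as
the score threshold rises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import PredictionRecord
from .errors import ValidationError
from .ic import ICModel, ic_summary
from .ontology import AnnotationSet, OntologyGraph, TermSet
from .semsim import SValueMap, protein_ss

#: The four cumulative group thresholds.
QUANTILES = (0.00, 0.25, 0.50, 0.75)


@dataclass
class QuantileGrouping:
    """Cumulative score groups of one (method, namespace) prediction stratum.

    ``records`` holds the stratum's records; ``groups[q]`` indexes into it.
    Groups are nested: groups[0.00] >= groups[0.25] >= groups[0.50] >= groups[0.75].
    """

    method: str
    namespace: str
    records: tuple[PredictionRecord, ...]
    thresholds: dict[float, float]
    groups: dict[float, tuple[int, ...]]

    def group_records(self, q: float) -> list[PredictionRecord]:
        return [self.records[i] for i in self.groups[q]]


def build_grouping(
    records: Sequence[PredictionRecord], method: str, namespace: str
) -> QuantileGrouping:
    """Stratify one (method, namespace) record subset into the four score groups."""
    stratum = tuple(
        r for r in records if r.method == method and r.namespace == namespace
    )
    if not stratum:
        raise ValidationError(f"no records for {method}/{namespace}")
    scores = np.array([r.score for r in stratum])
    thresholds: dict[float, float] = {}
    groups: dict[float, tuple[int, ...]] = {}
    for q in QUANTILES:
        cutoff = float(np.quantile(scores, q, method="linear"))
        thresholds[q] = cutoff
        if q == 0.0:
            groups[q] = tuple(range(len(stratum)))
        else:
            groups[q] = tuple(i for i, r in enumerate(stratum) if r.score >= cutoff)
    return QuantileGrouping(
        method=method,
        namespace=namespace,
        records=stratum,
        thresholds=thresholds,
        groups=groups,
    )


def quantile_groups(
    records: Sequence[PredictionRecord],
) -> dict[tuple[str, str], QuantileGrouping]:
    """Build a :class:`QuantileGrouping` for every (method, namespace) stratum."""
    strata = sorted({(r.method, r.namespace) for r in records})
    return {key: build_grouping(records, *key) for key in strata}


def group_metrics(
    grouping: QuantileGrouping,
    graph: OntologyGraph,
    reference: AnnotationSet,
    ic_model: ICModel | None = None,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-group semantic similarity, IC summary and protein coverage.

    For each group: per-protein BMA Wang similarity between the retained
    predicted terms and the reference annotations (median over proteins with
    a defined value), the IC summary over retained records, and the number
    of distinct proteins still carrying predictions.
    """
    cache: dict[str, SValueMap] = {}
    rows = []
    for q in QUANTILES:
        retained = grouping.group_records(q)
        proteins = sorted({r.protein for r in retained})
        ss_values = []
        for protein in proteins:
            predicted = TermSet(
                grouping.namespace,
                frozenset(r.term for r in retained if r.protein == protein),
            )
            annotated = reference.term_set(protein, grouping.namespace)
            ss = protein_ss(graph, predicted, annotated, weights, _cache=cache)
            if ss is not None:
                ss_values.append(ss)
        row = {
            "method": grouping.method,
            "namespace": grouping.namespace,
            "quantile": q,
            "score_cutoff": grouping.thresholds[q],
            "n_records": len(retained),
            "n_proteins": len(proteins),
            "n_proteins_evaluable": len(ss_values),
            "median_ss": float(np.median(ss_values)) if ss_values else float("nan"),
        }
        if ic_model is not None:
            summary = ic_summary(ic_model, retained)
            if len(summary):
                row["mean_ic_bits"] = float(summary["mean_ic_bits"].iloc[0])
                row["median_ic_bits"] = float(summary["median"].iloc[0])
            else:
                row["mean_ic_bits"] = row["median_ic_bits"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
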