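"""GO term enrichment of gene lists and enrichment-recovery comparison.

Over-representation of each term in a study gene list against a universe is
tested with a one-sided Fisher's exact test (exact hypergeometric tail).
Alongside the classic per-term p-value, the ``elim`` procedure of the topGO
family is run: terms are processed bottom-up (decreasing DAG depth,
lexicographic tie-break) and whenever a term's current-set p-value falls
under the elimination cutoff its genes are removed from all of its
ancestors before those are tested, decoupling ancestor significance from
inherited signal.  A term is flagged significant when the *classic* p-value
is below alpha (default 0.05); no multiple-testing correction is applied by
default (an optional Benjamini-Hochberg flag exists).

The recovery stage compares enrichment run on prediction-derived gene
annotations (stratified by score quantile) with enrichment run on the
reference annotations, via BMA Wang similarity of the two significant-term
sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation_io import GeneScoreTable
from .errors import ValidationError
from .ontology import OntologyGraph
from .semsim import SValueMap, term_set_sim
from .stratify import QUANTILES


@dataclass
class EnrichmentResult:
    """One term's contingency counts and classic/elim p-values."""

    term: str
    study_hits: int
    study_size: int
    population_hits: int
    population_size: int
    p_classic: float
    p_elim: float
    significant: bool


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher's exact test on [[a, b], [c, d]].

    The table is [[study & term, study w/o term], [rest & term, rest w/o
    term]]; the p-value is the exact hypergeometric tail P(X >= a) with
    population a+b+c+d, a+c marked, and a+b drawn.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency cells must be non-negative")
    population = a + b + c + d
    marked = a + c
    drawn = a + b
    return float(hypergeom.sf(a - 1, population, marked, drawn))


def enrich(
    graph: OntologyGraph,
    study: set[str],
    universe: set[str],
    gene2terms: Mapping[str, set[str]],
    alpha: float = 0.05,
    elim_cutoff: float = 0.01,
    min_node_size: int = 1,
    propagate_terms: bool = True,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Classic + elim Fisher enrichment of every annotated term.

    *gene2terms* maps genes of one namespace to their term sets; true-path
    propagation is applied (idempotently) unless *propagate_terms* is False.
    Genes of the universe with no terms stay in the population denominator.
    Terms annotating fewer than *min_node_size* universe genes are skipped.
    With *bh_correction* the significance flag uses Benjamini-Hochberg
    adjusted classic p-values instead of raw ones.
    """
    if not study or not universe:
        raise ValidationError("study and universe must be non-empty")
    stray = study - universe
    if stray:
        raise ValidationError(f"study genes not in universe: {sorted(stray)[:10]}")

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        terms = gene2terms.get(gene, set())
        if not terms:
            continue
        closed: set[str] = set()
        for t in terms:
            rt = graph.resolve(t)
            closed.add(rt)
            if propagate_terms:
                closed |= graph.ancestors(rt)
        for t in closed:
            term_genes.setdefault(t, set()).add(gene)

    tested = [t for t, genes in term_genes.items() if len(genes) >= min_node_size]
    n_pop = len(universe)
    n_study = len(study)

    results: dict[str, EnrichmentResult] = {}
    for t in tested:
        genes = term_genes[t]
        k_pop = len(genes)
        k_study = len(genes & study)
        p = fisher_exact_greater(
            k_study, n_study - k_study, k_pop - k_study, n_pop - n_study - (k_pop - k_study)
        )
        results[t] = EnrichmentResult(
            term=t,
            study_hits=k_study,
            study_size=n_study,
            population_hits=k_pop,
            population_size=n_pop,
            p_classic=p,
            p_elim=p,  # overwritten by the elim pass below
            significant=False,
        )

    # elim pass: bottom-up on current (possibly reduced) gene sets
    order = sorted(tested, key=lambda t: (-graph.depth(t), t))
    current: dict[str, set[str]] = {t: set(term_genes[t]) for t in tested}
    for t in order:
        genes = current[t]
        k_pop = len(genes)
        k_study = len(genes & study)
        p_elim = fisher_exact_greater(
            k_study, n_study - k_study, k_pop - k_study, n_pop - n_study - (k_pop - k_study)
        )
        results[t].p_elim = p_elim
        if p_elim < elim_cutoff:
            for anc in graph.ancestors(t):
                if anc in current:
                    current[anc] -= genes

    out = sorted(results.values(), key=lambda r: (r.p_classic, r.term))
    if bh_correction:
        pvals = np.array([r.p_classic for r in out])
        m = len(pvals)
        adjusted = np.minimum.accumulate((pvals * m / np.arange(1, m + 1))[::-1])[::-1]
        for r, padj in zip(out, adjusted):
            r.significant = bool(padj < alpha)
    else:
        for r in out:
            r.significant = bool(r.p_classic < alpha)
    return out


def significant_terms(results: Sequence[EnrichmentResult]) -> set[str]:
    return {r.term for r in results if r.significant}


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "study_hits": r.study_hits,
                "study_size": r.study_size,
                "population_hits": r.population_hits,
                "population_size": r.population_size,
                "p_classic": r.p_classic,
                "p_elim": r.p_elim,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def recover(
    graph: OntologyGraph,
    deg_genes: set[str],
    universe: set[str],
    reference_gene2terms: Mapping[str, Mapping[str, set[str]]],
    predictions: GeneScoreTable,
    weights: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    elim_cutoff: float = 0.01,
    min_node_size: int = 1,
) -> pd.DataFrame:
    """Compare prediction-based enrichment with reference-based enrichment.

    *reference_gene2terms* maps gene -> namespace -> term set.  For every
    namespace present in *predictions* and every cumulative score quantile:
    the prediction-derived gene annotations restricted to that group are
    enriched on the DEG list, and the similarity between the resulting
    significant terms and the reference run's significant terms is reported
    as BMA Wang similarity (missing when either set is empty), together with
    the number of study genes still carrying a significant term.
    """
    cache: dict[str, SValueMap] = {}
    rows = []
    for ns in sorted(predictions.namespaces()):
        ref_g2t = {
            g: set(by_ns.get(ns, set()))
            for g, by_ns in reference_gene2terms.items()
            if by_ns.get(ns)
        }
        ref_results = enrich(
            graph, deg_genes, universe, ref_g2t,
            alpha=alpha, elim_cutoff=elim_cutoff, min_node_size=min_node_size,
        )
        ref_sig = significant_terms(ref_results)

        scores = np.array(predictions.scores(ns))
        for q in QUANTILES:
            cutoff = -np.inf if q == 0.0 else float(np.quantile(scores, q, method="linear"))
            pred_g2t = predictions.gene2terms(ns, min_score=cutoff)
            if pred_g2t:
                pred_results = enrich(
                    graph, deg_genes, universe, pred_g2t,
                    alpha=alpha, elim_cutoff=elim_cutoff, min_node_size=min_node_size,
                )
            else:
                pred_results = []
            pred_sig = significant_terms(pred_results)
            ss = (
                term_set_sim(graph, sorted(ref_sig), sorted(pred_sig), weights, _cache=cache)
                if ref_sig and pred_sig
                else None
            )
            # study genes annotated (propagated, within this score group)
            # with at least one significant predicted term
            n_genes_sig = 0
            for gene in deg_genes:
                terms = pred_g2t.get(gene)
                if not terms:
                    continue
                closed: set[str] = set()
                for t in terms:
                    rt = graph.resolve(t)
                    closed.add(rt)
                    closed |= graph.ancestors(rt)
                if closed & pred_sig:
                    n_genes_sig += 1
            rows.append(
                {
                    "namespace": ns,
                    "quantile": q,
                    "score_cutoff": cutoff,
                    "ss_vs_reference": float("nan") if ss is None else ss,
                    "n_enriched_reference": len(ref_sig),
                    "n_enriched_predicted": len(pred_sig),
                    "genes_with_significant_terms": n_genes_sig,
                }
            )
    return pd.DataFrame(rows)
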