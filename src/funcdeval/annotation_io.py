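"""Readers and writers for every external table the pipeline touches.

Formats handled here: GAF 2.x association files, the package's prediction
TSV dialect, HMMER3 ``--domtblout`` tables (via Bio.SearchIO), the pfam2go
``external2go`` mapping, protein->gene id-mapping TSVs and plain-text DEG
lists.  The module also implements the two data-reduction rules applied at
ingest time: conservative Pfam domain-hit filtering (i-Evalue and profile
coverage thresholds plus greedy non-overlap resolution) and max-score
protein->gene aggregation.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SearchIO

from .errors import TableParseError, ValidationError
from .ontology import NAMESPACES, AnnotationSet, OntologyGraph

logger = logging.getLogger("funcdeval")

GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}
ASPECT_FROM_NS = {v: k for k, v in GAF_ASPECT.items()}

#: Canonical prediction table header (tab-separated, UTF-8, "." decimals).
PREDICTION_COLUMNS = ("protein", "go_term", "score", "method", "ontology")


@dataclass(frozen=True)
class PredictionRecord:
    """One scored GO term prediction for one protein."""

    protein: str
    term: str
    score: float
    method: str
    namespace: str

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValidationError(f"non-finite score for {self.protein}/{self.term}")
        if self.namespace not in NAMESPACES:
            raise ValidationError(f"unknown namespace {self.namespace!r}")


@dataclass(frozen=True)
class DomainHit:
    """One HMMER domain alignment: protein region matched by a Pfam profile."""

    protein: str
    domain: str
    i_evalue: float
    ali_from: int  # 1-based inclusive, protein coordinates
    ali_to: int
    hmm_from: int  # 1-based inclusive, profile coordinates
    hmm_to: int
    hmm_len: int

    def __post_init__(self):
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValidationError(f"bad alignment coordinates on {self.protein}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_len):
            raise ValidationError(f"bad profile coordinates on {self.protein}")
        if self.i_evalue < 0:
            raise ValidationError("negative i-Evalue")

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1

    @property
    def profile_coverage(self) -> float:
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_len


@dataclass
class GeneScoreTable:
    """Best (max-over-isoforms) prediction score per (gene, term, namespace)."""

    entries: dict[tuple[str, str, str], float] = field(default_factory=dict)
    n_skipped: int = 0  # records whose protein had no gene mapping

    def genes(self) -> set[str]:
        return {g for g, _, _ in self.entries}

    def namespaces(self) -> set[str]:
        return {ns for _, _, ns in self.entries}

    def gene2terms(self, namespace: str, min_score: float = -math.inf) -> dict[str, set[str]]:
        """Per-gene term sets for one namespace, keeping scores >= *min_score*."""
        out: dict[str, set[str]] = {}
        for (gene, term, ns), score in self.entries.items():
            if ns == namespace and score >= min_score:
                out.setdefault(gene, set()).add(term)
        return out

    def scores(self, namespace: str) -> list[float]:
        return [s for (_, _, ns), s in self.entries.items() if ns == namespace]


# -- line-oriented parsers -------------------------------------------------


def _data_lines(path, comment_prefixes=("!", "#")):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(comment_prefixes):
                continue
            yield lineno, line


def parse_gaf(path, graph: OntologyGraph | None = None) -> AnnotationSet:
    """Read a GAF 2.x association file into an :class:`AnnotationSet`.

    Rows whose qualifier contains ``NOT`` are excluded, the aspect column is
    mapped P/F/C -> BP/MF/CC and duplicate (protein, term) rows collapse.
    When *graph* is given, term ids are resolved to canonical live terms and
    unknown/obsolete ids dropped with a logged count.
    """
    out = AnnotationSet()
    dropped = 0
    for lineno, line in _data_lines(path, comment_prefixes=("!",)):
        fields = line.split("\t")
        if len(fields) < 15:
            raise TableParseError(
                f"expected >=15 GAF columns, got {len(fields)}", path=path, line=lineno
            )
        protein = fields[1]
        qualifier = fields[3]
        term = fields[4]
        aspect = fields[8]
        if "NOT" in qualifier.split("|"):
            continue
        if aspect not in GAF_ASPECT:
            raise TableParseError(f"bad aspect {aspect!r}", path=path, line=lineno)
        if graph is not None:
            resolved, n_drop = graph.resolve_terms([term])
            dropped += n_drop
            if not resolved:
                continue
            term = next(iter(resolved))
            ns = graph.namespace(term)
        else:
            ns = GAF_ASPECT[aspect]
        out.add(protein, ns, term)
    if dropped:
        logger.info("parse_gaf: dropped %d unknown/obsolete terms", dropped)
    return out


def write_gaf(annotations: AnnotationSet, path, db: str = "synthetic",
              header_comments: Sequence[str] = ()) -> None:
    """Write a minimal (fixed evidence code) GAF 2.2 file that round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for comment in header_comments:
            fh.write(f"! {comment}\n")
        for protein, ns, terms in annotations.items():
            for term in sorted(terms):
                cols = [
                    db, protein, protein, "enables", term, "PMID:0", "IEA", "",
                    ASPECT_FROM_NS[ns], protein, "", "protein", "taxon:0",
                    "20240101", db, "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def parse_predictions(path) -> list[PredictionRecord]:
    """Read the canonical prediction TSV (header protein/go_term/score/method/ontology)."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise TableParseError(str(exc), path=path) from exc
    missing = set(PREDICTION_COLUMNS) - set(frame.columns)
    if missing:
        raise TableParseError(f"missing columns {sorted(missing)}", path=path)
    records = []
    for row in frame.itertuples(index=False):
        try:
            score = float(row.score)
        except (TypeError, ValueError) as exc:
            raise TableParseError(f"non-numeric score {row.score!r}", path=path) from exc
        records.append(
            PredictionRecord(row.protein, row.go_term, score, row.method, row.ontology)
        )
    return records


def write_predictions(records: Iterable[PredictionRecord], path,
                      header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.protein}\t{r.term}\t{r.score:.6g}\t{r.method}\t{r.namespace}\n")


def parse_deg_list(path) -> set[str]:
    """Read a DEG list, one gene id per line; empty lists are invalid."""
    genes = {line.strip() for _, line in _data_lines(path)}
    if not genes:
        raise ValidationError(f"{path}: empty DEG list")
    return genes


def write_gene_list(genes: Iterable[str], path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for g in sorted(genes):
            fh.write(g + "\n")


def parse_idmap(path) -> dict[str, str]:
    """Read a two-column protein->gene TSV (optional ``protein\\tgene`` header)."""
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise TableParseError(
                f"expected 2 columns, got {len(fields)}", path=path, line=lineno
            )
        if fields == ["protein", "gene"]:
            continue
        mapping[fields[0]] = fields[1]
    return mapping


def write_idmap(idmap: Mapping[str, str], path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("protein\tgene\n")
        for protein in sorted(idmap):
            fh.write(f"{protein}\t{idmap[protein]}\n")


def parse_pfam2go(path) -> dict[str, set[str]]:
    """Read a pfam2go external2go file into Pfam accession -> GO term sets.

    Lines look like ``Pfam:PF00001 7tm_1 > GO:G-protein ... ; GO:0004930``;
    accessions are stored without version suffixes.
    """
    mapping: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        if not line.startswith("Pfam:"):
            raise TableParseError("line does not start with 'Pfam:'", path=path, line=lineno)
        head, _, tail = line.partition(">")
        accession = head.split()[0][len("Pfam:"):].split(".")[0]
        term = tail.rsplit(";", 1)[-1].strip()
        if not term.startswith("GO:"):
            raise TableParseError(f"no GO id in {line!r}", path=path, line=lineno)
        mapping.setdefault(accession, set()).add(term)
    return mapping


# -- HMMER domtblout -------------------------------------------------------


def parse_domtblout(path, program: str = "hmmscan") -> list[DomainHit]:
    """Read a HMMER3 ``--domtblout`` table into :class:`DomainHit` rows.

    *program* selects the search direction: for ``hmmscan`` the query is the
    protein and the target the profile (profile length = tlen); for
    ``hmmsearch`` the roles are swapped (profile length = qlen).  The
    per-domain independent E-value ("i-Evalue") column and the "ali coord"
    from/to columns are used.
    """
    if program not in ("hmmscan", "hmmsearch"):
        raise ValidationError(f"program must be hmmscan or hmmsearch, not {program!r}")
    fmt = f"{program}3-domtab"
    hits: list[DomainHit] = []
    # strip comment lines up front: HMMER only writes them as header/footer,
    # but the tabular parser treats any later one as end-of-data
    with open(path, encoding="utf-8") as fh:
        stream = io.StringIO("".join(l for l in fh if not l.startswith("#")))
    try:
        for qresult in SearchIO.parse(stream, fmt):
            for hit in qresult:
                for hsp in hit.hsps:
                    if program == "hmmscan":
                        protein, domain = qresult.id, hit.id
                        hmm_len = hit.seq_len
                        hmm_start, hmm_end = hsp.hit_start, hsp.hit_end
                        ali_start, ali_end = hsp.query_start, hsp.query_end
                    else:
                        protein, domain = hit.id, qresult.id
                        hmm_len = qresult.seq_len
                        hmm_start, hmm_end = hsp.query_start, hsp.query_end
                        ali_start, ali_end = hsp.hit_start, hsp.hit_end
                    hits.append(
                        DomainHit(
                            protein=protein,
                            domain=domain,
                            i_evalue=hsp.evalue,
                            ali_from=ali_start + 1,  # SearchIO is 0-based half-open
                            ali_to=ali_end,
                            hmm_from=hmm_start + 1,
                            hmm_to=hmm_end,
                            hmm_len=hmm_len,
                        )
                    )
    except ValueError as exc:
        raise TableParseError(str(exc), path=path) from exc
    return hits


def filter_domain_hits(
    hits: Sequence[DomainHit],
    max_ievalue: float = 1e-3,
    min_coverage: float = 0.70,
) -> list[DomainHit]:
    """Conservative domain-hit filter: i-Evalue, profile coverage, non-overlap.

    Three passes: (1) drop hits with i-Evalue above *max_ievalue*; (2) drop
    hits whose aligned fraction of the profile is below *min_coverage*;
    (3) per protein, resolve overlaps on protein coordinates greedily --
    longest alignment first (ties: smaller i-Evalue, then domain accession),
    accepting a hit only if it shares no residue with an accepted one.
    Output is sorted by (protein, ali_from).
    """
    surviving = [
        h for h in hits
        if h.i_evalue <= max_ievalue and h.profile_coverage >= min_coverage
    ]
    by_protein: dict[str, list[DomainHit]] = {}
    for h in surviving:
        by_protein.setdefault(h.protein, []).append(h)

    accepted: list[DomainHit] = []
    for protein in by_protein:
        candidates = sorted(
            by_protein[protein],
            key=lambda h: (-h.ali_length, h.i_evalue, h.domain),
        )
        kept: list[DomainHit] = []
        for h in candidates:
            if all(h.ali_to < k.ali_from or h.ali_from > k.ali_to for k in kept):
                kept.append(h)
        accepted.extend(kept)
    return sorted(accepted, key=lambda h: (h.protein, h.ali_from))


def hits_to_annotations(
    hits: Sequence[DomainHit],
    pfam2go: Mapping[str, set[str]],
    graph: OntologyGraph,
    method: str = "profile-baseline",
) -> tuple[AnnotationSet, list[PredictionRecord], int]:
    """Transfer GO terms from filtered domain hits through pfam2go.

    Each hit contributes the union of its domain's mapped GO terms; the
    prediction score is -log10(i-Evalue) (capped for zero E-values).  Returns
    the annotation set, scored records, and the count of hits whose domain is
    absent from pfam2go.
    """
    annotations = AnnotationSet()
    records: list[PredictionRecord] = []
    unmapped = 0
    seen: set[tuple[str, str]] = set()
    for hit in hits:
        accession = hit.domain.split(".")[0]
        terms = pfam2go.get(accession)
        if not terms:
            unmapped += 1
            continue
        score = -math.log10(max(hit.i_evalue, 1e-300))
        resolved, _ = graph.resolve_terms(terms)
        for term in sorted(resolved):
            ns = graph.namespace(term)
            annotations.add(hit.protein, ns, term)
            if (hit.protein, term) not in seen:
                seen.add((hit.protein, term))
                records.append(PredictionRecord(hit.protein, term, score, method, ns))
    if unmapped:
        logger.info("hits_to_annotations: %d hits had no pfam2go mapping", unmapped)
    return annotations, records, unmapped


# -- gene-level aggregation ------------------------------------------------


def aggregate_gene_scores(
    records: Iterable[PredictionRecord], idmap: Mapping[str, str]
) -> GeneScoreTable:
    """Transfer protein predictions to genes, keeping the best score per term.

    When several proteins (isoforms) of the same gene predict the same term
    with different scores, the maximum is stored.  Records whose protein has
    no gene mapping are skipped and counted.
    """
    table = GeneScoreTable()
    for r in records:
        gene = idmap.get(r.protein)
        if gene is None:
            table.n_skipped += 1
            continue
        key = (gene, r.term, r.namespace)
        prev = table.entries.get(key)
        if prev is None or r.score > prev:
            table.entries[key] = r.score
    if table.n_skipped:
        logger.info("aggregate_gene_scores: skipped %d unmappable records", table.n_skipped)
    return table


def map_records_to_genes(
    records: Iterable[PredictionRecord], idmap: Mapping[str, str]
) -> tuple[list[PredictionRecord], int]:
    """Relabel records with gene ids; unmappable proteins are skipped and counted."""
    out: list[PredictionRecord] = []
    skipped = 0
    for r in records:
        gene = idmap.get(r.protein)
        if gene is None:
            skipped += 1
            continue
        out.append(replace(r, protein=gene))
    return out, skipped
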