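import math

import numpy as np
import pytest

from funcdeval.annotation_io import (
    DomainHit,
    PredictionRecord,
    aggregate_gene_scores,
    filter_domain_hits,
    hits_to_annotations,
    parse_deg_list,
    parse_domtblout,
    parse_gaf,
    parse_idmap,
    parse_pfam2go,
    parse_predictions,
    write_gaf,
    write_idmap,
    write_predictions,
)
from funcdeval.errors import TableParseError, ValidationError

from _oracles import max_nonoverlapping
from conftest import make_graph


def gaf_row(protein, term, aspect, qualifier="enables"):
    cols = ["UniProt", protein, protein, qualifier, term, "PMID:1", "IEA", "",
            aspect, protein, "", "protein", "taxon:9606", "20240101", "UniProt", "", ""]
    return "\t".join(cols)


def write_lines(path, *lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestGaf:
    def test_aspects_map_to_namespaces(self, tmp_path):
        path = write_lines(
            tmp_path / "a.gaf",
            "!gaf-version: 2.2",
            gaf_row("P1", "GO:0000010", "F"),
            gaf_row("P1", "GO:0000020", "P"),
        )
        ann = parse_gaf(path)
        assert ann.get("P1", "MF") == {"GO:0000010"}
        assert ann.get("P1", "BP") == {"GO:0000020"}

    def test_not_qualifier_excluded(self, tmp_path):
        path = write_lines(
            tmp_path / "n.gaf",
            gaf_row("P1", "GO:0000010", "F", qualifier="NOT|enables"),
        )
        assert parse_gaf(path).terms == {}

    def test_duplicates_collapse(self, tmp_path):
        rows = [gaf_row("P1", f"GO:000001{i}", "P") for i in range(7)]
        rows += rows[:3]  # 3 duplicate rows -> still 7 stored pairs
        path = write_lines(tmp_path / "d.gaf", *rows)
        ann = parse_gaf(path)
        assert ann.n_annotations() == 7

    def test_short_row_reports_line_number(self, tmp_path):
        path = write_lines(tmp_path / "bad.gaf", gaf_row("P1", "GO:1", "P"), "only\tthree\tcols")
        with pytest.raises(TableParseError, match="bad.gaf:2"):
            parse_gaf(path)

    def test_unknown_terms_dropped_against_graph(self, tmp_path):
        g = make_graph([("B", "A")])
        path = write_lines(
            tmp_path / "g.gaf", gaf_row("P1", "B", "P"), gaf_row("P1", "GO:9999999", "P")
        )
        ann = parse_gaf(path, graph=g)
        assert ann.get("P1", "BP") == {"B"}

    def test_round_trip(self, tmp_path, small_synthetic):
        _, corpus, *_ = small_synthetic
        path = tmp_path / "rt.gaf"
        write_gaf(corpus, path)
        assert parse_gaf(path) == corpus


class TestSimpleTables:
    def test_prediction_score_parsed(self, tmp_path):
        path = write_lines(
            tmp_path / "p.tsv",
            "protein\tgo_term\tscore\tmethod\tontology",
            "P1\tGO:0000001\t0.83\tm1\tBP",
        )
        (rec,) = parse_predictions(path)
        assert rec.score == pytest.approx(0.83)
        assert rec.namespace == "BP"

    def test_prediction_non_numeric_score(self, tmp_path):
        path = write_lines(
            tmp_path / "p.tsv",
            "protein\tgo_term\tscore\tmethod\tontology",
            "P1\tGO:0000001\thigh\tm1\tBP",
        )
        with pytest.raises(TableParseError, match="non-numeric"):
            parse_predictions(path)

    def test_prediction_round_trip(self, tmp_path, small_synthetic):
        records = small_synthetic[3].records[:200]
        path = tmp_path / "rt.tsv"
        write_predictions(records, path, header_comments=["provenance"])
        back = parse_predictions(path)
        assert [(r.protein, r.term, r.method, r.namespace) for r in back] == [
            (r.protein, r.term, r.method, r.namespace) for r in records
        ]
        assert all(a.score == pytest.approx(b.score, abs=1e-6) for a, b in zip(back, records))

    def test_deg_list_and_empty_error(self, tmp_path):
        path = write_lines(tmp_path / "deg.txt", "# comment", "g1", "g2")
        assert parse_deg_list(path) == {"g1", "g2"}
        empty = write_lines(tmp_path / "empty.txt", "# nothing")
        with pytest.raises(ValidationError):
            parse_deg_list(empty)

    def test_idmap_round_trip(self, tmp_path):
        idmap = {"P1": "G1", "P2": "G1", "P3": "G2"}
        path = tmp_path / "map.tsv"
        write_idmap(idmap, path)
        assert parse_idmap(path) == idmap

    def test_pfam2go_one_to_two(self, tmp_path):
        path = write_lines(
            tmp_path / "p2g.txt",
            "!version date: 2024/01/01",
            "Pfam:PF00001 7tm_1 > GO:G-protein coupled receptor activity ; GO:0004930",
            "Pfam:PF00001 7tm_1 > GO:signal transduction ; GO:0007165",
            "Pfam:PF00002 x > GO:whatever ; GO:0000002",
        )
        mapping = parse_pfam2go(path)
        assert mapping["PF00001"] == {"GO:0004930", "GO:0007165"}
        assert mapping["PF00002"] == {"GO:0000002"}


DOMTBL_HEADER = (
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target"
)


def domtbl_row(domain, acc, tlen, protein, ievalue, hmm_from, hmm_to, ali_from, ali_to):
    return (
        f"{domain} {acc} {tlen} {protein} - 400 1e-20 50.0 0.1 1 1 1e-21 {ievalue} "
        f"49.0 0.1 {hmm_from} {hmm_to} {ali_from} {ali_to} {ali_from} {ali_to} 0.9 desc"
    )


class TestDomtblout:
    def test_single_row_coordinates(self, tmp_path):
        path = write_lines(
            tmp_path / "one.domtblout",
            DOMTBL_HEADER,
            domtbl_row("Dom1", "PF00001.10", 100, "ProtA", "1.5e-30", 2, 95, 10, 120),
        )
        (hit,) = parse_domtblout(path)
        assert hit == DomainHit("ProtA", "Dom1", 1.5e-30, 10, 120, 2, 95, 100)
        assert hit.profile_coverage == pytest.approx(94 / 100)

    def test_comment_only_file(self, tmp_path):
        path = write_lines(tmp_path / "c.domtblout", DOMTBL_HEADER, "# another comment")
        assert parse_domtblout(path) == []

    def test_row_and_comment_count(self, tmp_path):
        rows = [
            domtbl_row("Dom1", "PF1.1", 100, "ProtA", "1e-10", 1, 90, 1, 100),
            domtbl_row("Dom2", "PF2.1", 100, "ProtA", "1e-09", 1, 80, 150, 260),
            domtbl_row("Dom1", "PF1.1", 100, "ProtB", "1e-08", 1, 95, 5, 100),
            domtbl_row("Dom3", "PF3.1", 50, "ProtC", "2e-04", 1, 50, 10, 60),
        ]
        path = write_lines(
            tmp_path / "m.domtblout", DOMTBL_HEADER, rows[0], rows[1],
            "# interleaved comment", rows[2], rows[3],
        )
        assert len(parse_domtblout(path)) == 4


def hit(protein="P", domain="PF1", ievalue=1e-5, ali=(1, 100), hmm=(1, 90), hmm_len=100):
    return DomainHit(protein, domain, ievalue, ali[0], ali[1], hmm[0], hmm[1], hmm_len)


class TestDomainFilter:
    def test_ievalue_threshold(self):
        assert filter_domain_hits([hit(ievalue=0.01)]) == []
        assert len(filter_domain_hits([hit(ievalue=1e-3)])) == 1  # <= is kept

    def test_coverage_threshold(self):
        assert filter_domain_hits([hit(hmm=(1, 50), hmm_len=100)]) == []
        assert len(filter_domain_hits([hit(hmm=(1, 70), hmm_len=100)])) == 1

    def test_longest_alignment_wins_overlap(self):
        long = hit(domain="PFlong", ali=(1, 120), hmm=(1, 120), hmm_len=130)
        short = hit(domain="PFshort", ali=(100, 179), hmm=(1, 80), hmm_len=90)
        kept = filter_domain_hits([short, long])
        assert [h.domain for h in kept] == ["PFlong"]
        # exhaustive search confirms only one hit can survive, and the greedy
        # pick is the longest of the feasible single-element optima
        optimum = max_nonoverlapping([(short.ali_from, short.ali_to), (long.ali_from, long.ali_to)])
        assert len(optimum) == len(kept) == 1 and kept[0].ali_length == 120

    def test_output_nonoverlapping_and_thresholds_randomized(self):
        rng = np.random.default_rng(17)
        hits = []
        for i in range(80):
            start = int(rng.integers(1, 300))
            length = int(rng.integers(20, 120))
            hmm_len = int(rng.integers(50, 150))
            hmm_to = int(rng.integers(1, hmm_len + 1))
            hits.append(
                DomainHit(
                    protein=f"P{int(rng.integers(4))}",
                    domain=f"PF{i:05d}",
                    i_evalue=float(10.0 ** rng.uniform(-30, 0)),
                    ali_from=start,
                    ali_to=start + length,
                    hmm_from=1,
                    hmm_to=hmm_to,
                    hmm_len=hmm_len,
                )
            )
        kept = filter_domain_hits(hits)
        assert all(h.i_evalue <= 1e-3 and h.profile_coverage >= 0.70 for h in kept)
        assert set(kept) <= set(hits)
        by_protein = {}
        for h in kept:
            by_protein.setdefault(h.protein, []).append(h)
        for group in by_protein.values():
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    assert a.ali_to < b.ali_from or a.ali_from > b.ali_to

    def test_tie_break_deterministic(self):
        a = hit(domain="PFB", ievalue=1e-5, ali=(1, 100))
        b = hit(domain="PFA", ievalue=1e-5, ali=(50, 149), hmm=(1, 90), hmm_len=100)
        kept = filter_domain_hits([a, b])
        # equal lengths and i-Evalues: lexicographically smaller accession wins
        assert [h.domain for h in kept] == ["PFA"]


class TestHitsToAnnotations:
    def test_domain_mapping_and_score(self):
        g = make_graph([("B", "A"), ("C", "A")])
        mapping = {"PF1": {"B", "C"}}
        ann, records, unmapped = hits_to_annotations([hit(domain="PF1.3", ievalue=1e-4)], mapping, g)
        assert ann.get("P", "BP") == {"B", "C"}
        assert unmapped == 0
        assert all(r.score == pytest.approx(4.0) for r in records)
        assert all(r.method == "profile-baseline" for r in records)

    def test_unmapped_domain_counted(self):
        g = make_graph([("B", "A")])
        ann, records, unmapped = hits_to_annotations([hit(domain="PFX")], {}, g)
        assert ann.terms == {} and records == [] and unmapped == 1

    def test_union_over_hits(self):
        g = make_graph([("B", "A"), ("C", "A"), ("D", "A")])
        mapping = {"PF1": {"B"}, "PF2": {"C", "D"}}
        hits = [
            hit(protein="P1", domain="PF1", ali=(1, 50)),
            hit(protein="P1", domain="PF2", ali=(60, 120)),
            hit(protein="P2", domain="PF2"),
        ]
        ann, _, _ = hits_to_annotations(hits, mapping, g)
        assert ann.get("P1", "BP") == {"B", "C", "D"}
        assert ann.get("P2", "BP") == {"C", "D"}


class TestAggregateGeneScores:
    def test_isoform_max(self):
        records = [
            PredictionRecord("P1", "GO:1", 0.4, "m", "BP"),
            PredictionRecord("P2", "GO:1", 0.9, "m", "BP"),
        ]
        table = aggregate_gene_scores(records, {"P1": "G1", "P2": "G1"})
        assert table.entries == {("G1", "GO:1", "BP"): pytest.approx(0.9)}

    def test_single_record_passthrough(self):
        records = [PredictionRecord("P1", "GO:1", 0.5, "m", "BP")]
        table = aggregate_gene_scores(records, {"P1": "G1"})
        assert table.entries == {("G1", "GO:1", "BP"): 0.5}

    def test_unmappable_skipped_and_counted(self):
        records = [PredictionRecord(f"P{i}", "GO:1", 0.1 * i, "m", "BP") for i in range(5)]
        idmap = {f"P{i}": f"G{i}" for i in range(4)}  # P4 unmappable
        table = aggregate_gene_scores(records, idmap)
        assert len(table.entries) == 4 and table.n_skipped == 1

    def test_matches_brute_force_group_max(self):
        rng = np.random.default_rng(23)
        records = [
            PredictionRecord(
                f"P{int(rng.integers(30))}", f"GO:{int(rng.integers(10))}",
                float(rng.random()), "m", str(rng.choice(["BP", "MF"])),
            )
            for _ in range(200)
        ]
        idmap = {f"P{i}": f"G{i // 3}" for i in range(30)}
        table = aggregate_gene_scores(records, idmap)
        expected = {}
        for r in records:
            key = (idmap[r.protein], r.term, r.namespace)
            expected[key] = max(expected.get(key, -math.inf), r.score)
        assert table.entries.keys() == expected.keys()
        for key in expected:
            assert table.entries[key] == pytest.approx(expected[key])
        # never below any contributing record
        for r in records:
            assert table.entries[(idmap[r.protein], r.term, r.namespace)] >= r.score
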