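"""Evidence, edge-list, regulon, GMT, and annotation I/O."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from tfdegrome import tables as tb
from tfdegrome.tables import (
    EvidenceEntry,
    EvidenceTable,
    GeneSet,
    Regulon,
    ScoredEdge,
    TFAnnotation,
)


def _write(path, text):
    path.write_text(text)
    return path


EVIDENCE_HEADER = "drug\ttarget\tlevel\teffect\tsystem\tsource_id\n"


class TestEvidenceTable:
    def test_parses_rows_and_canonicalizes_symbols(self, tmp_path):
        f = _write(
            tmp_path / "ev.tsv",
            EVIDENCE_HEADER
            + "thalidomide\t vegfa \tgene\tdownregulated\thESC\tS1\n"
            + "thalidomide\tCRBN\tprotein\tbound\thESC\tS2\n"
            + "lenalidomide\tVEGFA\tgene\tdownregulated\tHUVEC\tS3\n",
        )
        table = tb.read_evidence_table(f)
        assert len(table) == 3
        assert table.targets("gene") == {"VEGFA"}
        assert table.targets("protein") == {"CRBN"}

    def test_exact_duplicates_dropped_and_counted(self, tmp_path):
        row = "thalidomide\tVEGFA\tgene\tdownregulated\thESC\tS1\n"
        f = _write(tmp_path / "ev.tsv", EVIDENCE_HEADER + row * 2 + "thalidomide\tCRBN\tprotein\tbound\t\tS2\n")
        table = tb.read_evidence_table(f)
        assert len(table) == 2
        assert table.n_duplicates_dropped == 1

    def test_unknown_drug_is_a_row_error_with_line_number(self, tmp_path):
        f = _write(
            tmp_path / "ev.tsv",
            EVIDENCE_HEADER
            + "aspirin\tVEGFA\tgene\tdownregulated\t\tS1\n"
            + "thalidomide\tCRBN\tprotein\tbound\t\tS2\n",
        )
        table = tb.read_evidence_table(f)
        assert len(table) == 1
        assert len(table.row_errors) == 1
        assert table.row_errors[0].line == 2

    def test_missing_column_names_the_column(self, tmp_path):
        f = _write(tmp_path / "ev.tsv", "drug\ttarget\tlevel\teffect\tsystem\nx\ty\tz\tw\tv\n")
        with pytest.raises(tb.SchemaError, match="source_id"):
            tb.read_evidence_table(f)

    def test_round_trip(self, tmp_path, default_bundle):
        f = tmp_path / "ev.tsv"
        tb.write_evidence_table(default_bundle.evidence, f)
        again = tb.read_evidence_table(f)
        assert again.entries == default_bundle.evidence.entries


class TestSummarizeEvidence:
    def _table(self, n_thal, n_pom, n_len):
        entries = []
        i = 0
        for drug, n in (
            ("thalidomide", n_thal),
            ("pomalidomide", n_pom),
            ("lenalidomide", n_len),
        ):
            for _ in range(n):
                i += 1
                entries.append(
                    EvidenceEntry(drug, f"G{i}", "gene", "downregulated", "", f"S{i}")
                )
        return EvidenceTable(entries)

    def test_per_drug_counts_sum_to_total(self):
        summary = tb.summarize_evidence(self._table(339, 42, 26))
        assert summary.total == 407
        assert summary.by_drug == {
            "thalidomide": 339,
            "pomalidomide": 42,
            "lenalidomide": 26,
        }
        assert sum(summary.by_drug.values()) == summary.total
        assert sum(summary.by_level.values()) == summary.total

    def test_gene_share_rounds_half_even_to_one_decimal(self):
        # 253 gene entries of 407 -> 62.1621...% -> 62.2 under half-even
        entries = [
            EvidenceEntry("thalidomide", f"G{i}", "gene", "downregulated", "", f"S{i}")
            for i in range(253)
        ] + [
            EvidenceEntry("thalidomide", f"P{i}", "protein", "degraded", "", f"S{i}")
            for i in range(154)
        ]
        summary = tb.summarize_evidence(EvidenceTable(entries))
        assert summary.total == 407
        assert summary.level_pct["gene"] == 62.2

    def test_replication_requires_two_distinct_sources_at_same_level(self):
        entries = [
            EvidenceEntry("thalidomide", "VEGFA", "gene", "downregulated", "", "S1"),
            EvidenceEntry("lenalidomide", "VEGFA", "gene", "upregulated", "", "S2"),
            EvidenceEntry("thalidomide", "CRBN", "protein", "bound", "", "S1"),
            EvidenceEntry("thalidomide", "CRBN", "protein", "degraded", "", "S1"),
        ]
        summary = tb.summarize_evidence(EvidenceTable(entries))
        assert summary.replicated_targets == {"gene": 1, "protein": 0}

    def test_gene_protein_overlap(self):
        entries = [
            EvidenceEntry("thalidomide", "VEGFA", "gene", "downregulated", "", "S1"),
            EvidenceEntry("thalidomide", "VEGFA", "protein", "inhibited", "", "S2"),
            EvidenceEntry("thalidomide", "CRBN", "protein", "bound", "", "S3"),
        ]
        summary = tb.summarize_evidence(EvidenceTable(entries))
        assert summary.gene_protein_overlap == 1

    def test_empty_table_is_a_valid_empty_summary(self):
        summary = tb.summarize_evidence(EvidenceTable([]))
        assert summary.total == 0
        assert summary.gene_protein_overlap == 0


STRING_HEADER = "protein1\tprotein2\tscore\n"


class TestReadStringEdges:
    def test_strictly_greater_than_threshold(self, tmp_path):
        f = _write(
            tmp_path / "e.tsv",
            STRING_HEADER + "A\tB\t0.520\nA\tC\t0.400\nB\tC\t0.399\n",
        )
        edges = tb.read_string_edges(f, threshold=0.400)
        assert [(e.a, e.b) for e in edges] == [("A", "B")]
        assert edges[0].score == pytest.approx(0.520)

    def test_integer_dialect_normalized_by_1000(self, tmp_path):
        f = _write(tmp_path / "e.tsv", STRING_HEADER + "A\tB\t520\nA\tC\t400\n")
        edges = tb.read_string_edges(f, threshold=0.400)
        assert [(e.a, e.b, e.score) for e in edges] == [("A", "B", 0.520)]

    def test_duplicate_unordered_pairs_merged_keeping_max(self, tmp_path):
        f = _write(tmp_path / "e.tsv", STRING_HEADER + "A\tB\t0.5\nB\tA\t0.7\n")
        edges = tb.read_string_edges(f, threshold=0.400)
        assert len(edges) == 1
        assert edges[0].score == pytest.approx(0.7)

    def test_self_loops_dropped(self, tmp_path):
        f = _write(tmp_path / "e.tsv", STRING_HEADER + "A\tA\t0.9\nA\tB\t0.9\n")
        assert len(tb.read_string_edges(f)) == 1

    def test_result_is_function_of_unordered_pair_set(self, tmp_path):
        rows = ["A\tB\t0.6", "C\tD\t0.8", "B\tE\t0.5"]
        f1 = _write(tmp_path / "e1.tsv", STRING_HEADER + "\n".join(rows) + "\n")
        swapped = ["B\tA\t0.6", "B\tE\t0.5", "D\tC\t0.8"]
        f2 = _write(tmp_path / "e2.tsv", STRING_HEADER + "\n".join(swapped) + "\n")
        assert tb.read_string_edges(f1) == tb.read_string_edges(f2)

    def test_round_trip(self, tmp_path, default_bundle):
        f = tmp_path / "edges.tsv"
        tb.write_string_edges(default_bundle.edges, f)
        again = tb.read_string_edges(f, threshold=0.0)
        expected = {
            (e.a, e.b) if e.a < e.b else (e.b, e.a): e.score
            for e in default_bundle.edges
        }
        got = {(e.a, e.b): e.score for e in again}
        assert got == pytest.approx(expected)


class TestRegulonsGmtAnnotations:
    def test_regulon_grouping(self, tmp_path):
        f = _write(
            tmp_path / "r.tsv",
            "SP1\tVEGFA\tActivation\t123,456\nSP1\tCCL2\tUnknown\t7\n",
        )
        regs = tb.read_regulons(f)
        assert len(regs) == 1
        assert regs[0].tf == "SP1"
        assert regs[0].targets == {"VEGFA", "CCL2"}
        assert regs[0].modes["VEGFA"] == "activation"
        assert regs[0].references["VEGFA"] == 2

    def test_regulon_round_trip(self, tmp_path, default_bundle):
        f = tmp_path / "r.tsv"
        tb.write_regulons(default_bundle.regulons, f)
        again = tb.read_regulons(f)
        assert {r.tf: r.targets for r in again} == {
            r.tf: r.targets for r in default_bundle.regulons
        }

    def test_gmt_members(self, tmp_path):
        f = _write(tmp_path / "s.gmt", "GO:X\tdesc\tA\tB\tC\n")
        sets = tb.read_gmt(f)
        assert sets[0].members == {"A", "B", "C"}

    def test_short_gmt_line_skipped_with_warning(self, tmp_path, caplog):
        f = _write(tmp_path / "s.gmt", "GO:X\tdesc\n GO:Y\tdesc\tA\tB\n")
        with caplog.at_level(logging.WARNING):
            sets = tb.read_gmt(f)
        assert len(sets) == 1
        assert "line 1" in caplog.text

    def test_gmt_round_trip(self, tmp_path, default_bundle):
        f = tmp_path / "s.gmt"
        tb.write_gmt(default_bundle.dev_sets, f)
        assert tb.read_gmt(f) == default_bundle.dev_sets

    def test_annotation_c2h2_filter(self, tmp_path):
        f = _write(
            tmp_path / "a.tsv",
            "symbol\tis_tf\tdbd_class\nSALL4\ttrue\tC2H2\nCTNNB1\ttrue\tother\nALB\tfalse\tunknown\n",
        )
        annotations = tb.read_tf_annotations(f)
        assert tb.c2h2_symbols(annotations) == {"SALL4"}

    def test_c2h2_on_non_tf_rejected(self):
        with pytest.raises(ValueError):
            TFAnnotation(symbol="X", is_tf=False, dbd_class="C2H2")


class TestDomainTypeInvariants:
    def test_scored_edge_rejects_self_loop_and_bad_score(self):
        with pytest.raises(ValueError):
            ScoredEdge(a="A", b="A", score=0.5)
        with pytest.raises(ValueError):
            ScoredEdge(a="A", b="B", score=1.5)

    def test_empty_regulon_rejected(self):
        with pytest.raises(ValueError):
            Regulon(tf="SP1", targets=set())

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("X", "x", frozenset())

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(tb.DRUGS),
                st.text(alphabet="ABCDEF", min_size=1, max_size=3),
                st.sampled_from(tb.LEVELS),
                st.sampled_from(tb.EFFECTS),
            ),
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_summary_totals_consistent(self, rows):
        entries = [
            EvidenceEntry(drug, target, level, effect, "", f"S{i}")
            for i, (drug, target, level, effect) in enumerate(rows)
        ]
        summary = tb.summarize_evidence(EvidenceTable(entries))
        assert summary.total == len(entries)
        assert sum(summary.by_drug.values()) == summary.total
        assert sum(summary.by_level.values()) == summary.total
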