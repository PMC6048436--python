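"""Domain types and file-format round trips."""

import numpy as np
import pytest

from poolgea import PoolSeqMatrix, ValidationError
from poolgea.datamodel import AnnotationTable, chromosome_sort_key
from poolgea.io import (
    ParseError,
    read_gff3,
    read_pool_counts,
    read_scan_results,
    write_pool_counts,
    write_scan_results,
)
from poolgea.model.aux import AuxScanResult


class TestPoolSeqMatrix:
    def test_coverage_from_tsv_fixture(self, tiny_matrix, tmp_path):
        path = tmp_path / "counts.tsv"
        write_pool_counts(tiny_matrix, path)
        back = read_pool_counts(path)
        assert back.coverage.tolist() == [[20, 18], [25, 0]]
        assert back.pop_ids == ["popA", "popB"]

    @pytest.mark.parametrize("dialect", ["tsv", "genobaypass"])
    def test_round_trip_lossless(self, tiny_matrix, tmp_path, dialect):
        path = tmp_path / "counts"
        write_pool_counts(tiny_matrix, path, dialect=dialect)
        back = read_pool_counts(path, dialect=dialect, pop_ids=tiny_matrix.pop_ids)
        np.testing.assert_array_equal(back.ref_count, tiny_matrix.ref_count)
        np.testing.assert_array_equal(back.alt_count, tiny_matrix.alt_count)
        if dialect == "tsv":
            assert back.snp_ids.tolist() == tiny_matrix.snp_ids.tolist()
            assert back.pos.tolist() == tiny_matrix.pos.tolist()

    def test_genobaypass_pair_layout(self, tmp_path):
        path = tmp_path / "geno"
        path.write_text("12 8 30 0\n")
        m = read_pool_counts(path, dialect="genobaypass")
        assert m.ref_count.tolist() == [[12, 30]]
        assert m.alt_count.tolist() == [[8, 0]]

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "geno"
        path.write_text("12 8 30 0\n5 5 x 1\n")
        with pytest.raises(ParseError, match=":2"):
            read_pool_counts(path, dialect="genobaypass")

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "geno"
        path.write_text("12 -1 3 0\n")
        with pytest.raises(ValidationError):
            read_pool_counts(path, dialect="genobaypass")

    def test_zero_coverage_cells_are_masked(self, tiny_matrix):
        f = tiny_matrix.frequency()
        assert f.mask[1, 1]
        assert f[0, 0] == pytest.approx(0.6)

    def test_unsorted_rows_rejected(self):
        with pytest.raises(ValidationError):
            PoolSeqMatrix(
                snp_ids=["a", "b"],
                chrom=["1", "1"],
                pos=[200, 100],
                ref_count=[[1], [1]],
                alt_count=[[0], [0]],
                pop_ids=["p"],
            )

    def test_declared_chromosome_order_not_lexicographic(self):
        key = chromosome_sort_key(np.array(["10", "2"], dtype=object), ("2", "10"))
        assert key.tolist() == [1, 0]

    def test_sort_is_idempotent(self):
        m = PoolSeqMatrix.sorted_from_arrays(
            snp_ids=["a", "b", "c"],
            chrom=["2", "1", "1"],
            pos=[5, 9, 3],
            ref_count=[[1], [2], [3]],
            alt_count=[[0], [0], [0]],
            pop_ids=["p"],
        )
        assert m.snp_ids.tolist() == ["c", "b", "a"]
        m2 = PoolSeqMatrix.sorted_from_arrays(
            m.snp_ids, m.chrom, m.pos, m.ref_count, m.alt_count, m.pop_ids
        )
        assert m2.snp_ids.tolist() == m.snp_ids.tolist()


class TestScanResultsIO:
    def _result(self, n):
        return AuxScanResult(
            snp_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            chrom=np.array(["1"] * n, dtype=object),
            pos=np.arange(1, n + 1),
            beta=np.linspace(-0.1, 0.1, n) if n else np.array([]),
            bf_db=np.linspace(0, 30, n) if n else np.array([]),
            xtx=np.linspace(1, 9, n) if n else np.array([]),
            pip=np.linspace(0, 1, n) if n else np.array([]),
        )

    def test_empty_result_header_only(self, tmp_path):
        path = tmp_path / "scan.tsv"
        write_scan_results(self._result(0), path)
        assert path.read_text().count("\n") == 1

    def test_single_snp_two_lines(self, tmp_path):
        path = tmp_path / "scan.tsv"
        write_scan_results(self._result(1), path)
        assert path.read_text().count("\n") == 2

    def test_round_trip_to_1e12(self, tmp_path):
        path = tmp_path / "scan.tsv"
        res = self._result(7)
        write_scan_results(res, path)
        back = read_scan_results(path)
        np.testing.assert_allclose(back.bf_db, res.bf_db, atol=1e-12)
        np.testing.assert_allclose(back.beta, res.beta, atol=1e-12)


GFF = """\
##gff-version 3
1\ttair\tgene\t100\t200\t.\t+\t.\tID=AT1G01010;Name=NAC001
1\ttair\tmRNA\t100\t200\t.\t+\t.\tID=AT1G01010.1;Parent=AT1G01010
1\ttair\tmRNA\t100\t180\t.\t+\t.\tID=AT1G01010.2;Parent=AT1G01010
2\ttair\tgene\t500\t900\t.\t-\t.\tID=AT2G01008
2\ttair\tmRNA\t500\t900\t.\t-\t.\tID=AT2G01008.1;Parent=AT2G01008
3\ttair\tgene\t50\t60\t.\t+\t.\tID=AT3G00001
3\ttair\tmRNA\t50\t60\t.\t+\t.\tID=AT3G00001.1;Parent=AT3G00001
3\ttair\tmRNA\t50\t55\t.\t+\t.\tID=AT3G00001.2;Parent=AT3G00001
"""


class TestGff3:
    def test_gene_features_only(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        genes = read_gff3(path)
        assert len(genes) == 3
        assert genes.gene_id.tolist() == ["AT1G01010", "AT2G01008", "AT3G00001"]

    def test_one_based_inclusive_span(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        genes = read_gff3(path)
        assert (genes.start[0], genes.end[0]) == (100, 200)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text("")
        assert len(read_gff3(path)) == 0

    def test_missing_id_is_named_error(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text("1\tx\tgene\t1\t10\t.\t+\t.\tName=foo\n")
        with pytest.raises(ParseError, match="ID"):
            read_gff3(path)


def test_annotation_table_single_category_per_snp():
    with pytest.raises(ValidationError):
        AnnotationTable(
            snp_ids=np.array(["a", "a"], dtype=object),
            category=np.array(["intron", "UTR"], dtype=object),
        )
    with pytest.raises(ValidationError, match="unknown"):
        AnnotationTable(
            snp_ids=np.array(["a"], dtype=object),
            category=np.array(["exonish"], dtype=object),
        )
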