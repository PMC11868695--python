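"""File-dialect contracts: strict parsing, validation, round-trips."""

import pandas as pd
import pytest

from tetralink import formats_io
from tetralink.depth_abundance import DepthRecord
from tetralink.errors import ConsistencyError, ParseError, ValidationError
from tetralink.marker_concat import MagQuality
from tetralink.taxonomy_resolve import Lineage

B6_ROW = "mss\tscf1_3\t45.0\t300\t120\t4\t1\t300\t10\t310\t1e-40\t250.0\n"


class TestBlast6:
    def test_single_valid_row(self, tmp_path):
        path = tmp_path / "hits.b6"
        path.write_text(B6_ROW)
        hits = formats_io.read_blast6(path)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.scaffold_id, hit.protein_index) == ("scf1", 3)
        assert hit.evalue == 1e-40
        assert hit.pident == 45.0
        assert (hit.qstart, hit.qend) == (1, 300)  # 1-based inclusive kept

    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.b6"
        path.write_text("")
        assert formats_io.read_blast6(path) == []

    def test_short_row_names_line_number(self, tmp_path):
        path = tmp_path / "hits.b6"
        path.write_text("\t".join(B6_ROW.split("\t")[:11]) + "\n")
        with pytest.raises(ParseError, match="line 1"):
            formats_io.read_blast6(path)

    def test_bad_numeric_rejected(self, tmp_path):
        path = tmp_path / "hits.b6"
        path.write_text(B6_ROW.replace("1e-40", "abc"))
        with pytest.raises(ParseError, match="line 1"):
            formats_io.read_blast6(path)

    def test_query_to_family_mapping(self, tmp_path):
        path = tmp_path / "hits.b6"
        path.write_text(B6_ROW.replace("mss", "WP_0001.1"))
        hits = formats_io.read_blast6(path, query_to_family={"WP_0001.1": "mss"})
        assert hits[0].family == "mss"


class TestDepthTable:
    def test_roundtrip(self, tmp_path):
        records = [
            DepthRecord("scf1", "50", "50", 2.5, 1e8),
            DepthRecord("scf1", "50", "70", 0.25, 9.7e7),
        ]
        path = tmp_path / "depth.tsv"
        formats_io.write_depth_table(path, records)
        assert formats_io.read_depth_table(path) == records

    def test_negative_depth_rejected_with_row(self, tmp_path):
        path = tmp_path / "depth.tsv"
        path.write_text(
            "scaffold\tassembly_sample\tmapping_sample\tavg_depth\tmapping_total_reads\n"
            "scf1\t50\t50\t-1\t100\n"
        )
        with pytest.raises(ValidationError, match="line 2"):
            formats_io.read_depth_table(path)

    def test_header_only(self, tmp_path):
        path = tmp_path / "depth.tsv"
        path.write_text(
            "scaffold\tassembly_sample\tmapping_sample\tavg_depth\tmapping_total_reads\n"
        )
        assert formats_io.read_depth_table(path) == []


class TestLineageTable:
    def test_roundtrip(self, tmp_path):
        table = {
            "scf1": Lineage.parse("d__Bacteria;p__Planctomycetota"),
            "scf2": Lineage.unclassified(),
        }
        path = tmp_path / "cat.tsv"
        formats_io.write_lineage_table(path, table)
        assert formats_io.read_lineage_table(path) == table

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("scf1\td__Bacteria\nscf1\td__Archaea\n")
        with pytest.raises(ValidationError, match="scf1"):
            formats_io.read_lineage_table(path)

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("# comment\nscf1\td__Bacteria\n")
        assert len(formats_io.read_lineage_table(path)) == 1


class TestBinTable:
    def test_scaffold_in_two_bins_rejected(self, tmp_path):
        path = tmp_path / "bins.tsv"
        path.write_text("scf1\tbin1\nscf1\tbin2\n")
        with pytest.raises(ConsistencyError, match="scf1"):
            formats_io.read_bin_table(path)

    def test_roundtrip(self, tmp_path):
        bins = {"scf1": "bin1", "scf2": "bin1", "scf3": "bin2"}
        path = tmp_path / "bins.tsv"
        formats_io.write_bin_table(path, bins)
        assert formats_io.read_bin_table(path) == bins


class TestPeakTable:
    HEADER = "lipid\tsample_depth_m\tadduct\tarea\tis_area\tlitres\n"

    def test_three_adducts_one_cell(self, tmp_path):
        path = tmp_path / "peaks.tsv"
        path.write_text(
            self.HEADER
            + "L\t50\tM+H\t100\t200\t1\n"
            + "L\t50\tM+NH4\t40\t200\t1\n"
            + "L\t50\tM+Na\t10\t200\t1\n"
        )
        df = formats_io.read_peak_table(path)
        assert len(df) == 3
        assert set(df["adduct"]) == {"M+H", "M+NH4", "M+Na"}

    def test_unknown_adduct_rejected(self, tmp_path):
        path = tmp_path / "peaks.tsv"
        path.write_text(self.HEADER + "L\t50\tM+K\t100\t200\t1\n")
        with pytest.raises(ValidationError, match="M\\+K"):
            formats_io.read_peak_table(path)

    def test_nonpositive_internal_standard_rejected(self, tmp_path):
        # IS normalization requires a positive standard response
        path = tmp_path / "peaks.tsv"
        path.write_text(self.HEADER + "L\t50\tM+H\t100\t0\t1\n")
        with pytest.raises(ValidationError):
            formats_io.read_peak_table(path)

    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            [("L", "50", "M+H", 100.0, 200.0, 1.5)],
            columns=list(formats_io.PEAK_HEADER),
        )
        path = tmp_path / "peaks.tsv"
        formats_io.write_peak_table(path, df)
        back = formats_io.read_peak_table(path)
        pd.testing.assert_frame_equal(back, df)


class TestInternalTables:
    def test_presence_roundtrip(self, tmp_path):
        presence = {("mss", "bin1"): ["scf1", "scf2"], ("ger", "unbinned:scf3"): ["scf3"]}
        path = tmp_path / "presence.tsv"
        formats_io.write_presence_table(path, presence)
        assert formats_io.read_presence_table(path) == presence

    def test_quality_roundtrip(self, tmp_path):
        rows = [MagQuality("m1", 90.0, 4.0), MagQuality("m2", 55.5, 0.0)]
        path = tmp_path / "quality.tsv"
        formats_io.write_quality_table(path, rows)
        assert formats_io.read_quality_table(path) == rows

    def test_lipid_profile_roundtrip(self, tmp_path):
        profiles = {"brGDGT-1a": {"50": 0.5, "2000": 1.25}}
        path = tmp_path / "lipids.tsv"
        formats_io.write_lipid_profile_table(path, profiles)
        assert formats_io.read_lipid_profile_table(path) == profiles

    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"p1": "MKLV", "p2": "ACDEFGH"}
        path = tmp_path / "prot.faa"
        formats_io.write_fasta(path, seqs)
        assert formats_io.read_fasta(path) == seqs
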