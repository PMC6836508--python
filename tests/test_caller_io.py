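"""Caller VCF dialect parsing and BEDPE round-trips."""

import gzip

import pytest

from cnvpost.caller_io import (
    DIALECTS,
    read_bedpe,
    read_caller_vcf,
    read_caller_vcf_with_stats,
    write_adjacency_vcf,
    write_bedpe,
)
from cnvpost.model import (
    LEFT,
    RIGHT,
    UNKNOWN,
    Breakend,
    CNVCall,
    CNVType,
    GenomicInterval,
    Locus,
    ValidationError,
)
from cnvpost.reclassify import reclassify
from cnvpost.simulate import CallerProfile, emulate_caller, simulate_truth
from conftest import del_adj, make_adj, tdup_adj

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr5,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=PE,Number=1,Type=Integer,Description="x">
##INFO=<ID=SR,Number=1,Type=Integer,Description="x">
##INFO=<ID=RP,Number=1,Type=Integer,Description="x">
##INFO=<ID=MATEID,Number=1,Type=String,Description="x">
##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=RV,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=PE,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=SR,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=PR,Number=.,Type=Integer,Description="x">
##ALT=<ID=DEL,Description="x">
##ALT=<ID=DUP,Description="x">
##ALT=<ID=INS,Description="x">
##ALT=<ID=INV,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(tmp_path, body, name="toy.vcf"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestSymbolicDialects:
    def test_delly_del_coordinates_and_format_support(self, tmp_path):
        # 1-based POS 100 = base before the deleted segment 101..5000
        body = "chr1\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5000;PE=9;SR=9\tGT:DV:RV\t0/1:7:3\n"
        adjs = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["DELLY"])
        (adj,) = adjs
        assert adj.bnd1 == Breakend("chr1", 100, RIGHT)
        assert adj.bnd2 == Breakend("chr1", 5000, LEFT)
        # sample-level DV/RV preferred over site-level PE/SR
        assert (adj.pe_support, adj.sr_support) == (7, 3)
        assert adj.source_tool == "DELLY"

    def test_lumpy_dup_orientation(self, tmp_path):
        body = "chr1\t2000\tu1\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=9000\tGT:PE:SR\t0/1:4:6\n"
        (adj,) = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["LUMPY"])
        assert adj.orientations == (LEFT, RIGHT)
        assert (adj.bnd1.pos, adj.bnd2.pos) == (2000, 9000)
        assert (adj.pe_support, adj.sr_support) == (4, 6)

    def test_manta_tuple_valued_pr_takes_alt_count(self, tmp_path):
        body = "chr1\t2000\tm1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=3000\tGT:PR:SR\t0/1:12,5:9,2\n"
        (adj,) = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["MANTA"])
        assert (adj.pe_support, adj.sr_support) == (5, 2)

    def test_insertion_with_and_without_sequence(self, tmp_path):
        body = (
            "chr1\t500\ti1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=500;SVINSSEQ=ACGTACGT;PE=1;SR=1\tGT\t0/1\n"
            "chr1\t900\ti2\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=900;PE=1;SR=1\tGT\t0/1\n"
        )
        a1, a2 = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["SIM"])
        assert a1.inserted_seq == "ACGTACGT"
        assert a1.bnd1.pos == a1.bnd2.pos == 500
        assert a2.inserted_seq is UNKNOWN

    def test_inversion_kept_with_encoded_orientations(self, tmp_path):
        body = "chr1\t100\tv1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=5000;PE=1;SR=1\tGT\t0/1\n"
        (adj,) = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["SIM"])
        assert adj.orientations[0] == adj.orientations[1]

    def test_missing_support_defaults_to_zero(self, tmp_path):
        body = "chr1\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5000\tGT\t0/1\n"
        adjs, stats = read_caller_vcf_with_stats(write_vcf(tmp_path, body), DIALECTS["SIM"])
        assert adjs[0].pe_support == 0 and adjs[0].sr_support == 0
        assert stats.n_missing_support == 2

    def test_empty_vcf(self, tmp_path):
        assert read_caller_vcf(write_vcf(tmp_path, ""), DIALECTS["DELLY"]) == []

    def test_one_adjacency_per_symbolic_record(self, tmp_path):
        body = "".join(
            f"chr1\t{1000 * (i + 1)}\tr{i}\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END={1000 * (i + 1) + 500};PE=1;SR=1\tGT\t0/1\n"
            for i in range(7)
        )
        assert len(read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["SIM"])) == 7


class TestBreakendDialect:
    def test_mate_pair_yields_single_adjacency(self, tmp_path):
        body = (
            "chr1\t200\tb1\tN\tN[chr5:7000[\t.\tPASS\tSVTYPE=BND;MATEID=b2;RP=8;SR=4\tGT\t0/1\n"
            "chr5\t7001\tb2\tN\t]chr1:200]N\t.\tPASS\tSVTYPE=BND;MATEID=b1;RP=8;SR=4\tGT\t0/1\n"
        )
        adjs = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["GRIDSS"])
        (adj,) = adjs
        assert adj.bnd1 == Breakend("chr1", 200, RIGHT)
        assert adj.bnd2 == Breakend("chr5", 7000, LEFT)
        assert (adj.pe_support, adj.sr_support) == (8, 4)

    def test_unmatched_mate_skipped_and_counted(self, tmp_path):
        body = "chr1\t200\tb1\tN\tN[chr5:7000[\t.\tPASS\tSVTYPE=BND;MATEID=zz;RP=1;SR=1\tGT\t0/1\n"
        adjs, stats = read_caller_vcf_with_stats(write_vcf(tmp_path, body), DIALECTS["GRIDSS"])
        assert adjs == []
        assert stats.n_unmatched_bnd == 1

    def test_bnd_records_yield_half_the_adjacencies(self, tmp_path):
        truth = simulate_truth(2_000_000, {"DEL": 5, "TDUP": 5}, seed=9)
        adjs = emulate_caller(truth, CallerProfile(tool="GRIDSS"), seed=9)
        path = tmp_path / "bnd.vcf"
        write_adjacency_vcf(adjs, path, truth.chrom_lengths, style="BREAKEND_ONLY")
        n_records = sum(
            1 for line in path.read_text().splitlines() if not line.startswith("#")
        )
        back = read_caller_vcf(path, DIALECTS["GRIDSS"])
        assert n_records == 2 * len(back) == 2 * len(adjs)


class TestVcfCoordinateRoundTrip:
    @pytest.mark.parametrize("style", ["SYMBOLIC", "BREAKEND_ONLY"])
    def test_internal_to_vcf_to_internal_identity(self, tmp_path, style):
        truth = simulate_truth(
            {"chr1": 2_000_000, "chr2": 2_000_000},
            {"DEL": 6, "INS": 4, "TDUP": 5, "DDUP": 6},
            seed=11, ddup_inter_fraction=0.5,
        )
        adjs = emulate_caller(truth, CallerProfile(tool="SIM", jitter_sd=1.5), seed=12)
        path = tmp_path / "rt.vcf"
        write_adjacency_vcf(adjs, path, truth.chrom_lengths, style=style)
        back = read_caller_vcf(path, DIALECTS["SIM"] if style == "SYMBOLIC" else DIALECTS["GRIDSS"])
        key = lambda a: a.sort_key()
        assert [
            (a.bnd1, a.bnd2, a.pe_support, a.sr_support, a.inserted_seq)
            for a in sorted(adjs, key=key)
        ] == [
            (a.bnd1, a.bnd2, a.pe_support, a.sr_support, a.inserted_seq)
            for a in sorted(back, key=key)
        ]


def _mixed_call_set():
    seq = "ACGT" * 20
    return [
        CNVCall(CNVType.DEL, GenomicInterval("chr1", 100, 5000),
                [del_adj("chr1", 100, 5000, id="a")], pe_support=3, sr_support=4,
                source_tools=frozenset({"DELLY"}), name="c1"),
        CNVCall(CNVType.TDUP, GenomicInterval("chr1", 8000, 9000),
                [tdup_adj("chr1", 8000, 9000, id="b")], pe_support=2, sr_support=2,
                source_tools=frozenset({"MANTA"}), name="c2", score=0.25),
        CNVCall(CNVType.INS, GenomicInterval("chr1", 12000, 12000),
                [make_adj("chr1", 12000, RIGHT, "chr1", 12000, LEFT, ins=seq, id="c")],
                insertion_point=Locus("chr1", 12000), inserted_seq=seq,
                source_tools=frozenset({"LUMPY"}), name="c3"),
        CNVCall(CNVType.DDUP, GenomicInterval("chr2", 10000, 12000),
                [tdup_adj("chr2", 10000, 50000, id="d1"),
                 del_adj("chr2", 12000, 50000, id="d2")],
                insertion_point=Locus("chr2", 50000), pe_support=5, sr_support=6,
                source_tools=frozenset({"DELLY", "GRIDSS"}), name="c4"),
    ]


class TestBedpe:
    def test_mixed_round_trip_identity(self, tmp_path):
        calls = _mixed_call_set()
        path = tmp_path / "calls.bedpe"
        write_bedpe(calls, path)
        assert read_bedpe(path) == calls

    def test_gzip_round_trip(self, tmp_path):
        calls = _mixed_call_set()
        path = tmp_path / "calls.bedpe.gz"
        write_bedpe(calls, path)
        with gzip.open(path, "rt") as fh:
            assert fh.readline().startswith("#chrom1")
        assert read_bedpe(path) == calls

    def test_del_breakend_intervals_and_strands(self, tmp_path):
        path = tmp_path / "one.bedpe"
        write_bedpe(_mixed_call_set()[:1], path)
        row = path.read_text().splitlines()[1].split("\t")
        assert row[:6] == ["chr1", "99", "100", "chr1", "5000", "5001"]
        assert (row[8], row[9]) == ("+", "-")

    def test_ddup_line_carries_insertion_point(self, tmp_path):
        path = tmp_path / "dd.bedpe"
        write_bedpe([_mixed_call_set()[3]], path)
        row = path.read_text().splitlines()[1].split("\t")
        assert row[10] == "DDUP"
        assert row[15] == "chr2:50000"
        (call,) = read_bedpe(path)
        assert len(call.adjacencies) == 2
        assert call.region == GenomicInterval("chr2", 10000, 12000)

    def test_empty_call_list(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        write_bedpe([], path)
        assert read_bedpe(path) == []
        assert path.read_text().startswith("#")

    def test_truncated_line_error_names_line(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        write_bedpe(_mixed_call_set(), path)
        lines = path.read_text().splitlines()
        lines[2] = "\t".join(lines[2].split("\t")[:5])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="line 3"):
            read_bedpe(path)

    def test_documented_columns_without_detail_blob(self, tmp_path):
        path = tmp_path / "hand.bedpe"
        path.write_text(
            "chr1\t99\t100\tchr1\t5000\t5001\tx1\t.\t+\t-\tDEL\t4900\t3.0\t4.0\tDELLY\t.\t.\n"
        )
        (call,) = read_bedpe(path)
        assert call.cnv_type is CNVType.DEL
        assert call.region == GenomicInterval("chr1", 100, 5000)
        assert call.source_tools == frozenset({"DELLY"})

    def test_unwritable_path_raises_oserror(self):
        with pytest.raises(OSError):
            write_bedpe([], "/nonexistent-dir/x.bedpe")


def test_dialect_to_classified_calls_end_to_end(tmp_path):
    """A symbolic DEL record survives VCF -> adjacency -> call intact."""
    body = "chr1\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5000;PE=9;SR=2\tGT\t0/1\n"
    adjs = read_caller_vcf(write_vcf(tmp_path, body), DIALECTS["SIM"])
    (call,) = reclassify(adjs).calls
    assert call.cnv_type is CNVType.DEL
    assert call.region == GenomicInterval("chr1", 100, 5000)
    assert call.size == 4900
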