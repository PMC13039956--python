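"""VCF parsing, the callset filters, and round-tripping."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svfold import (
    StructuralVariant,
    filter_variants,
    read_sample_metadata,
    read_sv_vcf,
    sv_length,
    write_sv_vcf,
)
from svfold.sv_io import parse_bracket_alt

HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="t">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="t">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="t">
##INFO=<ID=CIEND,Number=2,Type=Integer,Description="t">
##INFO=<ID=MATEID,Number=1,Type=String,Description="t">
##ALT=<ID=DEL,Description="t">
##ALT=<ID=DUP,Description="t">
##ALT=<ID=INV,Description="t">
##contig=<ID=chr1,length=250000000>
##contig=<ID=chr4,length=200000000>
##contig=<ID=chrX,length=160000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_vcf(tmp_path, body, name="test.vcf"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


def test_del_coordinates_are_zero_based_half_open(tmp_path):
    """A 1-based VCF DEL record maps to 0-based half-open coordinates."""
    p = _write_vcf(
        tmp_path, "chr4\t6948840\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=6949029\n"
    )
    (sv,) = read_sv_vcf(p, "s1")
    assert (sv.chrom, sv.start, sv.end, sv.svtype) == ("chr4", 6948839, 6949029, "DEL")
    assert sv_length(sv) == 190


def test_bnd_mate_pair_joined_into_one_record(tmp_path):
    """A BND mate pair yields a single variant carrying the partner locus."""
    body = (
        "chr1\t45703450\tb1\tN\tN[chrX:112696292[\t.\tPASS\tSVTYPE=BND;MATEID=b2\n"
        "chrX\t112696292\tb2\tN\t]chr1:45703450]N\t.\tPASS\tSVTYPE=BND;MATEID=b1\n"
    )
    svs = read_sv_vcf(_write_vcf(tmp_path, body), "s1")
    assert len(svs) == 1
    sv = svs[0]
    assert sv.svtype == "BND" and sv.mate_resolved
    assert sv.chrom == "chr1" and sv.start == 45703449
    assert sv.mate_chrom == "chrX" and sv.mate_pos == 112696291
    assert sv.junction_orientation == "t[p["
    assert sv_length(sv) is None


def test_empty_vcf_yields_empty_list(tmp_path):
    assert read_sv_vcf(_write_vcf(tmp_path, ""), "s1") == []


def test_malformed_bracket_alt_collected_not_fatal(tmp_path):
    body = (
        "chr1\t100\tb1\tN\tN[chrX:bad\t.\tPASS\tSVTYPE=BND;MATEID=b2\n"
        "chr1\t500000\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=500600\n"
    )
    errors: list[str] = []
    svs = read_sv_vcf(_write_vcf(tmp_path, body), "s1", errors=errors)
    assert [sv.svtype for sv in svs] == ["DEL"]
    assert len(errors) == 1 and "b1" in errors[0]


@pytest.mark.parametrize(
    "alt,expected",
    [
        ("N[chrX:101[", ("chrX", 100, "t[p[")),
        ("N]chrX:101]", ("chrX", 100, "t]p]")),
        ("]chrX:101]N", ("chrX", 100, "]p]t")),
        ("[chrX:101[N", ("chrX", 100, "[p[t")),
    ],
)
def test_bracket_alt_orientations(alt, expected):
    chrom, pos, orient, _ = parse_bracket_alt(alt)
    assert (chrom, pos, orient) == expected


def test_symbolic_ins_uses_svlen(tmp_path):
    body = (
        "chr1\t1000\ti1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=50\n"
        "chr1\t2000\ti2\tN\t<INS>\t.\tPASS\tSVTYPE=INS\n"  # no SVLEN: rejected
        "chr1\t3000\ti3\tN\tNACGTACGTA\t.\tPASS\tSVTYPE=INS\n"
    )
    errors: list[str] = []
    svs = read_sv_vcf(_write_vcf(tmp_path, body), "s1", errors=errors)
    assert [sv.id for sv in svs] == ["i1", "i3"]
    assert sv_length(svs[0]) == 50
    assert svs[1].inserted_seq == "ACGTACGTA"
    assert len(errors) == 1


FIXTURE_12 = (
    # 2 non-PASS
    "chr1\t1000\tv1\tN\t<DEL>\t.\tMinSomaticScore\tSVTYPE=DEL;END=2000\n"
    "chr1\t3000\tv2\tN\t<DUP>\t.\tLowQual\tSVTYPE=DUP;END=4000\n"
    # 1 over-length (600,001 bp)
    "chr1\t10000\tv3\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=610001\n"
    # 2 sharing identical breakpoints (both removed)
    "chr1\t20000\tv4\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=21000\n"
    "chr1\t20000\tv5\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=21000\n"
    # 1 unmated BND
    "chr1\t30000\tv6\tN\tN[chrX:500[\t.\tPASS\tSVTYPE=BND;MATEID=missing\n"
    # 6 clean records, one variant each
    "chr1\t40000\tv7\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=41000;CIPOS=-10,10;CIEND=-5,5\n"
    "chr1\t50000\tv8\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=52000\n"
    "chr1\t60000\tv9\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=63000\n"
    "chr1\t70000\tv10\tN\tNACGT\t.\tPASS\tSVTYPE=INS\n"
    "chr1\t80000\tv11\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=80500\n"
    "chr1\t90000\tv12\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=95000\n"
)


def test_filter_fixture_retains_six_with_conserved_report(tmp_path):
    """12-record fixture: 2 non-PASS + 1 over-length + 2 duplicate + 1
    unmated BND are excluded, leaving 6 variants and a conserved report."""
    svs = read_sv_vcf(_write_vcf(tmp_path, FIXTURE_12), "s1")
    assert len(svs) == 12  # the clean BND pair collapses to one variant
    retained, report = filter_variants(svs)
    assert len(retained) == 6
    assert report.non_pass == 2
    assert report.over_length == 1
    assert report.duplicate_breakpoints == 2
    assert report.unresolved_mate == 1
    assert report.retained == 6
    assert report.check_conserved()


def test_filter_is_idempotent(tmp_path):
    svs = read_sv_vcf(_write_vcf(tmp_path, FIXTURE_12), "s1")
    retained, _ = filter_variants(svs)
    again, report = filter_variants(retained)
    assert [sv.id for sv in again] == [sv.id for sv in retained]
    assert report.retained == report.input_count


def test_duplicate_keep_one_mode(tmp_path):
    svs = read_sv_vcf(_write_vcf(tmp_path, FIXTURE_12), "s1")
    retained, report = filter_variants(svs, duplicate_mode="keep_one")
    assert report.duplicate_breakpoints == 1
    assert len(retained) == 7


def test_over_length_boundary_exact():
    """A 500,000 bp DEL passes; 500,001 bp is removed."""
    keep = StructuralVariant("a", "chr1", 0, 500_000, "DEL", sample_id="s")
    drop = StructuralVariant("b", "chr1", 0, 500_001, "DEL", sample_id="s")
    retained, report = filter_variants([keep, drop])
    assert [sv.id for sv in retained] == ["a"]
    assert report.over_length == 1


def test_roundtrip_through_vcf(tmp_path):
    """Writing retained variants and re-reading reproduces them exactly."""
    svs = read_sv_vcf(_write_vcf(tmp_path, FIXTURE_12), "s1")
    retained, _ = filter_variants(svs)
    out = tmp_path / "out.vcf"
    write_sv_vcf(retained, out, {"chr1": 250_000_000, "chrX": 160_000_000})
    back = read_sv_vcf(out, "s1")
    key = lambda sv: (sv.chrom, sv.start, sv.svtype)
    for a, b in zip(sorted(retained, key=key), sorted(back, key=key)):
        assert (a.chrom, a.start, a.end, a.svtype) == (b.chrom, b.start, b.end, b.svtype)
        assert a.ci_pos == b.ci_pos and a.ci_end == b.ci_end
        assert a.inserted_seq == b.inserted_seq
        if a.svtype == "BND":
            assert (a.mate_chrom, a.mate_pos) == (b.mate_chrom, b.mate_pos)
            assert a.junction_orientation == b.junction_orientation


@st.composite
def _variants(draw):
    svtype = draw(st.sampled_from(["DEL", "DUP", "INV", "INS"]))
    start = draw(st.integers(0, 10_000))
    if svtype == "INS":
        end = start + 1
    else:
        end = start + draw(st.integers(1, 600_000))
    status = draw(st.sampled_from(["PASS", "PASS", "PASS", "LowQual"]))
    return StructuralVariant(
        id=f"v{draw(st.integers(0, 10**6))}",
        chrom="chr1",
        start=start,
        end=end,
        svtype=svtype,
        inserted_seq="ACGT" if svtype == "INS" else "",
        filter_status=status,
        sample_id="s1",
    )


@settings(max_examples=50, deadline=None)
@given(st.lists(_variants(), max_size=30))
def test_filter_report_conserved_on_any_input(svs):
    """Exclusion counts plus retained always sum to the input size, and
    filtering the retained set again removes nothing."""
    retained, report = filter_variants(svs)
    assert report.check_conserved()
    again, report2 = filter_variants(retained)
    assert len(again) == len(retained)
    assert report2.retained == report2.input_count


@pytest.mark.parametrize("orient", ["t[p[", "t]p]", "]p]t", "[p[t"])
def test_bnd_roundtrip_all_orientations(tmp_path, orient):
    """Each bracket orientation survives a write/read cycle intact."""
    sv = StructuralVariant(
        id="b", chrom="chr1", start=1_000, end=1_001, svtype="BND",
        mate_chrom="chrX", mate_pos=5_000, junction_orientation=orient,
        ci_pos=(-3, 3), ci_end=(-2, 2), sample_id="s1",
    )
    out = tmp_path / "bnd.vcf"
    write_sv_vcf([sv], out, {"chr1": 10_000_000, "chrX": 10_000_000})
    (back,) = read_sv_vcf(out, "s1")
    assert back.mate_resolved
    assert (back.chrom, back.start) == ("chr1", 1_000)
    assert (back.mate_chrom, back.mate_pos) == ("chrX", 5_000)
    assert back.junction_orientation == orient


def test_metadata_loader_validates(tmp_path):
    good = tmp_path / "meta.tsv"
    good.write_text(
        "sample_id\tparticipant_id\ttumor_type\ttumor_category\tstage\tpurity\n"
        "S1\tP1\tT1\tC1\tinitial\t0.8\n"
        "S2\tP1\tT1\tC1\tprogressive\t\n"
    )
    meta = read_sample_metadata(good)
    assert list(meta.sample_id) == ["S1", "S2"]
    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "sample_id\tparticipant_id\ttumor_type\ttumor_category\tstage\tpurity\n"
        "S1\tP1\tT1\tC1\trelapse\t0.8\n"
    )
    with pytest.raises(ValueError, match="stage"):
        read_sample_metadata(bad)
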