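"""SV notation parsing, derivative reconstruction and coordinate algebra."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neotad.errors import CoordinateRangeError, ModelError, NotationError, UsageError
from neotad.intervals import GenomicInterval, from_1based, merge_intervals
from neotad.locus_model import (
    FORWARD,
    REVERSE,
    SVDefinition,
    Segment,
    build_derivative,
    common_core,
    copy_number,
    format_sv,
    identity_derivative,
    parse_sv,
)

EXT = GenomicInterval("chrT", 0, 10_000)


def _identity_sv(ext, sv_id="ID"):
    return SVDefinition(sv_id=sv_id, sv_class="composite", edits=(),
                        source_notation="identity", reference_extent=ext)


# ---------------------------------------------------------------------------
# parse_sv
# ---------------------------------------------------------------------------


class TestParseSV:
    def test_printed_duplication_span(self, ext17, nl_sv1):
        # 1-based inclusive span 57,291,905..57,518,137 covers 226,233 bp
        assert nl_sv1.sv_class == "tandem_duplication"
        assert nl_sv1.edits[0].interval.length == 226_233
        assert nl_sv1.source_notation == "chr17:57,291,905_57,518,137dup"

    def test_minimal_inclusive_span(self):
        sv = parse_sv("chrT:100_200dup", EXT)
        assert sv.sv_class == "tandem_duplication"
        assert sv.edits[0].interval.length == 101  # 1-based inclusive

    def test_delins_inversion_spans(self, uk_sv2):
        e = uk_sv2.edits[0]
        assert uk_sv2.sv_class == "delins_inversion"
        assert e.interval.length == 12_863
        assert e.insert.length == 283_276

    @pytest.mark.parametrize(
        "notation,sv_class,multiplicity,inverted",
        [
            ("chrT:100_200trip", "triplication", 3, False),
            ("chrT:100_200dupinv", "inverted_duplication", 2, True),
            ("chrT:100_200inv", "inversion", None, None),
            ("chrT:100_200del", "deletion", None, None),
        ],
    )
    def test_suffix_classes(self, notation, sv_class, multiplicity, inverted):
        sv = parse_sv(notation, EXT)
        assert sv.sv_class == sv_class
        if multiplicity is not None:
            assert sv.edits[0].multiplicity == multiplicity
            assert sv.edits[0].inverted_copy == inverted

    @pytest.mark.parametrize(
        "separator", ["_", "-", "–", "—"], ids=["underscore", "hyphen", "endash", "emdash"]
    )
    def test_separator_variants(self, separator):
        sv = parse_sv(f"chrT:1,000{separator}2,000dup", EXT)
        assert sv.edits[0].interval == GenomicInterval("chrT", 999, 2000)

    @pytest.mark.parametrize(
        "bad",
        ["chrT:100dup", "chrT:100_200flip", "100_200dup", "chrT:100_200delins300_400",
         "chrT:1,00_200dup", ""],
    )
    def test_malformed_notation(self, bad):
        with pytest.raises(NotationError):
            parse_sv(bad, EXT)

    def test_out_of_extent_is_range_error(self):
        with pytest.raises(CoordinateRangeError):
            parse_sv("chrT:100_20000dup", EXT)
        with pytest.raises(CoordinateRangeError):
            parse_sv("chr9:100_200dup", EXT)

    def test_reversed_coordinates_rejected(self):
        with pytest.raises(NotationError):
            parse_sv("chrT:200_100dup", EXT)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.integers(1, 9_000),
    st.integers(1, 999),
    st.sampled_from(["dup", "trip", "inv", "del", "dupinv"]),
)
def test_parse_format_roundtrip(start, span, suffix):
    """parse_sv followed by format_sv is the identity on canonical notations."""
    notation = f"chrT:{start:,}_{min(start + span, 10_000):,}{suffix}"
    sv = parse_sv(notation, EXT)
    assert format_sv(sv) == notation
    assert parse_sv(format_sv(sv), EXT).edits == sv.edits


def test_delins_format_roundtrip():
    notation = "chrT:1,000_2,000delins5,000_7,500inv"
    assert format_sv(parse_sv(notation, EXT)) == notation


# ---------------------------------------------------------------------------
# build_derivative
# ---------------------------------------------------------------------------


class TestBuildDerivative:
    def test_tandem_duplication_junction(self, ext17, nl_sv1):
        """Head-to-tail orientation: junction joins dup end to dup start."""
        d = build_derivative(nl_sv1)
        assert len(d.segments) == 3
        assert [s.orientation for s in d.segments] == [FORWARD] * 3
        assert d.length == ext17.length + 226_233
        novel = d.novel_junctions
        assert len(novel) == 1
        assert novel[0].as_1based() == (57_518_137, 57_291_905)

    def test_identity_is_single_forward_segment(self, ext17):
        d = build_derivative(_identity_sv(ext17))
        assert len(d.segments) == 1
        assert d.segments[0].source == ext17
        assert d.segments[0].orientation == FORWARD
        assert d.junctions == ()

    def test_delins_inversion_length(self, ext17, uk_sv2):
        d = build_derivative(uk_sv2)
        assert d.length == ext17.length - 12_863 + 283_276
        # middle segment is the reverse-oriented insert copy
        assert d.segments[1].orientation == REVERSE
        assert d.segments[1].source == from_1based("chr17", 57_275_839, 57_559_114)

    def test_segment_lengths_sum_to_total(self, uk_sv2, nl_sv1):
        for sv in (uk_sv2, nl_sv1):
            d = build_derivative(sv)
            assert sum(s.length for s in d.segments) == d.length
            assert len(d.junctions) == len(d.segments) - 1

    def test_inversion_segments(self):
        d = build_derivative(parse_sv("chrT:2,001_4,000inv", EXT))
        assert [(s.source.start, s.source.end, s.orientation) for s in d.segments] == [
            (0, 2000, FORWARD), (2000, 4000, REVERSE), (4000, 10_000, FORWARD)
        ]
        assert all(not j.novel for j in []) or len(d.novel_junctions) == 2

    def test_triplication_copy_indices(self):
        d = build_derivative(parse_sv("chrT:1,001_2,000trip", EXT))
        dup_copies = [s for s in d.segments if (s.source.start, s.source.end) == (1000, 2000)]
        assert [s.copy_index for s in dup_copies] == [1, 2]  # plus the run-through copy

    def test_overlapping_edits_rejected(self):
        from neotad.locus_model import Edit
        sv = SVDefinition(
            sv_id="bad", sv_class="composite",
            edits=(Edit("invert", GenomicInterval("chrT", 100, 500)),
                   Edit("delete", GenomicInterval("chrT", 400, 600))),
            source_notation="synthetic", reference_extent=EXT,
        )
        with pytest.raises(ModelError):
            build_derivative(sv)

    def test_explicit_segments_bypass_edits(self):
        sv = SVDefinition(
            sv_id="X", sv_class="composite", edits=(), source_notation="explicit",
            reference_extent=EXT,
            explicit_segments=(Segment(GenomicInterval("chrT", 0, 5000)),
                               Segment(GenomicInterval("chrT", 2000, 3000), REVERSE),
                               Segment(GenomicInterval("chrT", 5000, 10_000))),
        )
        d = build_derivative(sv)
        assert d.length == 11_000
        assert d.segments[1].orientation == REVERSE


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------


class TestLiftover:
    def test_duplicated_position_maps_twice(self, nl_sv1):
        d = build_derivative(nl_sv1)
        hits = d.liftover(57_400_000)
        assert len(hits) == 2
        assert all(ori == FORWARD for _, ori in hits)

    def test_identity_maps_once_at_same_offset(self, ext17):
        d = identity_derivative(ext17)
        assert d.liftover(57_123_456) == [(123_456, FORWARD)]

    def test_triplicated_position_maps_three_times(self):
        d = build_derivative(parse_sv("chrT:1,001_2,000trip", EXT))
        assert len(d.liftover(1500)) == 3

    def test_deleted_position_maps_nowhere(self):
        d = build_derivative(parse_sv("chrT:1,001_2,000del", EXT))
        assert d.liftover(1500) == []

    def test_reverse_segment_orientation(self):
        d = build_derivative(parse_sv("chrT:2,001_4,000inv", EXT))
        (pos, ori), = d.liftover(2000)  # first base of the inverted span
        assert ori == REVERSE
        assert pos == 3999  # lands at the far end of the inverted block

    def test_out_of_extent_raises(self, ext17):
        with pytest.raises(CoordinateRangeError):
            identity_derivative(ext17).liftover(10)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 9_999), st.sampled_from(["dup", "trip", "inv", "del", "dupinv"]))
    def test_roundtrip_through_reference(self, pos, suffix):
        """Derivative -> reference -> derivative recovers the position."""
        d = build_derivative(parse_sv(f"chrT:3,001_6,000{suffix}", EXT))
        for dpos, _ in d.liftover(pos) if d.liftover(pos) else []:
            rpos, _ = d.to_reference(dpos)
            assert rpos == pos
        # and the reverse walk: every derivative base lifts back to a hit set
        # containing itself
        dpos = min(pos, d.length - 1)
        rpos, _ = d.to_reference(dpos)
        assert dpos in [p for p, _ in d.liftover(rpos)]


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


def brute_force_cn(d, lo, hi):
    """Independent per-base counter over liftover hits."""
    return [len(d.liftover(p)) for p in range(lo, hi)]


class TestCopyNumber:
    def test_nl_sv1_profile(self, nl_sv1):
        cn = copy_number(build_derivative(nl_sv1))
        dup = from_1based("chr17", 57_291_905, 57_518_137)
        assert cn.regions_with_cn_at_least(2) == [GenomicInterval("chr17", dup.start, dup.end)]
        assert cn.at(dup.start - 1) == 1 and cn.at(dup.start) == 2
        assert cn.at(dup.end - 1) == 2 and cn.at(dup.end) == 1

    def test_uk_sv2_profile(self, uk_sv2):
        """Deleted span retains one copy carried inside the inverted insert."""
        cn = copy_number(build_derivative(uk_sv2))
        expect = {
            (57_275_838, 57_456_097): 2,
            (57_456_097, 57_468_960): 1,
            (57_468_960, 57_559_114): 2,
        }
        for (s, e), want in expect.items():
            for p in (s, e - 1):
                assert cn.at(p) == want, (p, want)

    def test_identity_single_piece(self, ext17):
        cn = copy_number(identity_derivative(ext17))
        assert len(cn.pieces) == 1
        assert cn.pieces[0][1] == 1

    def test_pieces_tile_extent(self, uk_sv2, ext17):
        cn = copy_number(build_derivative(uk_sv2))
        assert cn.pieces[0][0].start == ext17.start
        assert cn.pieces[-1][0].end == ext17.end
        for (a, _), (b, _) in zip(cn.pieces, cn.pieces[1:]):
            assert a.end == b.start

    @pytest.mark.parametrize(
        "notation", ["chrT:2,001_4,000dup", "chrT:2,001_4,000trip",
                     "chrT:2,001_4,000inv", "chrT:2,001_4,000del",
                     "chrT:2,001_4,000dupinv",
                     "chrT:3,001_3,500delins1,001_5,000inv"]
    )
    def test_agrees_with_brute_force_counter(self, notation):
        d = build_derivative(parse_sv(notation, EXT))
        cn = copy_number(d)
        brute = brute_force_cn(d, 0, 10_000)
        for iv, c in cn.pieces:
            assert all(brute[p] == c for p in range(iv.start, iv.end))

    def test_conservation_of_bases(self):
        """Sum of piece length x CN equals derivative length (no novel bases)."""
        for notation in ("chrT:2,001_4,000dup", "chrT:2,001_4,000trip",
                         "chrT:3,001_3,500delins1,001_5,000inv"):
            d = build_derivative(parse_sv(notation, EXT))
            assert copy_number(d).total_bases == d.length


# ---------------------------------------------------------------------------
# common core
# ---------------------------------------------------------------------------


class TestCommonCore:
    def test_printed_core_contained(self, nl_sv1, uk_sv2):
        core = common_core([nl_sv1, uk_sv2])
        assert len(core) == 2
        printed = from_1based("chr17", *[57_499_214, 57_510_765])
        assert any(iv.contains_interval(printed) for iv in core)

    def test_single_sv_returns_own_region(self, nl_sv1):
        d = build_derivative(nl_sv1)
        assert common_core([nl_sv1]) == copy_number(d).regions_with_cn_at_least(2)

    def test_disjoint_duplications_empty(self):
        a = parse_sv("chrT:1,001_2,000dup", EXT, sv_id="A")
        b = parse_sv("chrT:5,001_6,000dup", EXT, sv_id="B")
        assert common_core([a, b]) == []

    def test_order_independent_and_idempotent(self, nl_sv1, uk_sv2):
        fwd = common_core([nl_sv1, uk_sv2])
        assert common_core([uk_sv2, nl_sv1]) == fwd
        assert common_core([nl_sv1, uk_sv2, nl_sv1]) == fwd

    def test_min_cn_three_selects_triplication_only(self):
        trip = parse_sv("chrT:1,001_3,000trip", EXT)
        assert common_core([trip], min_cn=3) == [GenomicInterval("chrT", 1000, 3000)]
        dup = parse_sv("chrT:1,001_3,000dup", EXT)
        assert common_core([dup], min_cn=3) == []

    def test_empty_cohort_is_usage_error(self):
        with pytest.raises(UsageError):
            common_core([])


def test_merge_intervals_bookended():
    out = merge_intervals([GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20),
                           GenomicInterval("c", 30, 40)])
    assert [(iv.start, iv.end) for iv in out] == [(0, 20), (30, 40)]
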