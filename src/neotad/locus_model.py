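"""Structural-variant notation parsing and derivative-allele reconstruction.

A complex rearrangement is described in an HGVS-like text notation with
1-based inclusive coordinates (``chr17:57,291,905_57,518,137dup``).  The
module parses such notations into :class:`SVDefinition` objects, compiles
them into :class:`DerivativeAllele` structures (ordered, oriented reference
segments with breakpoint junctions), and provides the coordinate algebra
used downstream: wild-type-to-derivative liftover, per-base copy-number
profiles, and the cohort intersection of amplified regions.

Supported notation suffixes
---------------------------
``dup``      tandem duplication, extra copy head-to-tail after the span
``trip``     triplication, two extra head-to-tail copies
``dupinv``   inverted duplication, extra copy reversed (head-to-head)
``inv``      inversion in place
``del``      deletion
``<del-span>delins<ins-span>inv``
             deletion replaced by a reverse-oriented copy of another span

Coordinate separators may be ``_``, ``-`` or the en/em dashes used in
print; thousands commas are optional.  Internally everything is 0-based
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import CoordinateRangeError, ModelError, NotationError, UsageError
from .intervals import GenomicInterval, from_1based, intersect_sets, merge_intervals

FORWARD = "forward"
REVERSE = "reverse"

SV_CLASSES = {
    "tandem_duplication",
    "inverted_duplication",
    "delins_inversion",
    "triplication",
    "inversion",
    "deletion",
    "composite",
}

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """One reference-relative edit of a rearrangement.

    ``op`` is one of ``duplicate`` (multiplicity extra head-to-tail or
    inverted copies), ``invert``, ``delete`` or ``delins_inverted`` (delete
    ``interval`` and insert a reverse-oriented copy of ``insert``).
    """

    op: str
    interval: GenomicInterval
    insert: GenomicInterval | None = None
    multiplicity: int = 2  # total copy count for duplicate ops
    inverted_copy: bool = False

    def __post_init__(self) -> None:
        if self.op not in {"duplicate", "invert", "delete", "delins_inverted"}:
            raise UsageError(f"unknown edit op {self.op!r}")
        if self.op == "delins_inverted" and self.insert is None:
            raise UsageError("delins_inverted requires an insert interval")
        if self.op == "duplicate" and self.multiplicity < 2:
            raise UsageError("duplicate multiplicity must be >= 2")


@dataclass(frozen=True)
class SVDefinition:
    """A parsed complex rearrangement as ordered reference-relative edits."""

    sv_id: str
    sv_class: str
    edits: tuple[Edit, ...]
    source_notation: str
    reference_extent: GenomicInterval
    explicit_segments: tuple["Segment", ...] | None = None

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise UsageError(f"unknown sv_class {self.sv_class!r}")
        if not self.edits and self.sv_class != "composite" and self.explicit_segments is None:
            # the identity SV is modelled as class "composite" with no edits
            raise UsageError("edits must be non-empty for non-composite SVs")
        for e in self.edits:
            for iv in filter(None, (e.interval, e.insert)):
                if iv.chrom != self.reference_extent.chrom:
                    raise UsageError(
                        f"edit on {iv.chrom} but reference extent on "
                        f"{self.reference_extent.chrom}"
                    )
                if not self.reference_extent.contains_interval(iv):
                    raise CoordinateRangeError(
                        f"{iv} outside reference extent {self.reference_extent}"
                    )

    @property
    def is_identity(self) -> bool:
        return not self.edits and self.explicit_segments is None


@dataclass(frozen=True)
class Segment:
    """An oriented reference segment of a derivative allele."""

    source: GenomicInterval
    orientation: str = FORWARD
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise UsageError(f"bad orientation {self.orientation!r}")
        if self.copy_index < 1:
            raise UsageError("copy_index must be >= 1")

    @property
    def length(self) -> int:
        return self.source.length


@dataclass(frozen=True)
class Junction:
    """Adjacency between two consecutive derivative segments.

    ``left_ref`` / ``right_ref`` are the 0-based reference coordinates of
    the last base of the left segment and the first base of the right
    segment (in derivative order).  ``novel`` is False for adjacencies that
    simply restore the reference sequence.
    """

    left_ref: int
    right_ref: int
    left_orientation: str
    right_orientation: str
    derivative_pos: int  # derivative coordinate of the first base right of the junction
    novel: bool

    def as_1based(self) -> tuple[int, int]:
        return self.left_ref + 1, self.right_ref + 1


@dataclass(frozen=True)
class DerivativeAllele:
    """Ordered, oriented reference segments making up a rearranged allele."""

    segments: tuple[Segment, ...]
    reference_extent: GenomicInterval

    def __post_init__(self) -> None:
        if not self.segments:
            raise UsageError("derivative must contain at least one segment")
        for s in self.segments:
            if not self.reference_extent.contains_interval(s.source):
                raise CoordinateRangeError(
                    f"segment {s.source} outside extent {self.reference_extent}"
                )

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def offsets(self) -> tuple[int, ...]:
        """Derivative start coordinate of each segment."""
        out, pos = [], 0
        for s in self.segments:
            out.append(pos)
            pos += s.length
        return tuple(out)

    @property
    def junctions(self) -> tuple[Junction, ...]:
        out = []
        offs = self.offsets
        for i in range(len(self.segments) - 1):
            left, right = self.segments[i], self.segments[i + 1]
            lref = left.source.end - 1 if left.orientation == FORWARD else left.source.start
            rref = right.source.start if right.orientation == FORWARD else right.source.end - 1
            novel = not (
                (
                    left.orientation == FORWARD
                    and right.orientation == FORWARD
                    and left.source.end == right.source.start
                )
                or (
                    left.orientation == REVERSE
                    and right.orientation == REVERSE
                    and right.source.end == left.source.start
                )
            )
            out.append(
                Junction(
                    left_ref=lref,
                    right_ref=rref,
                    left_orientation=left.orientation,
                    right_orientation=right.orientation,
                    derivative_pos=offs[i + 1],
                    novel=novel,
                )
            )
        return tuple(out)

    @property
    def novel_junctions(self) -> tuple[Junction, ...]:
        return tuple(j for j in self.junctions if j.novel)

    # -- coordinate algebra -------------------------------------------------

    def liftover(self, pos: int) -> list[tuple[int, str]]:
        """Map a reference position to every derivative copy.

        Returns one ``(derivative position, orientation)`` hit per copy of
        ``pos`` present on the derivative, ordered along the derivative.
        Positions that were deleted return the empty list.
        """
        if not self.reference_extent.contains(pos):
            raise CoordinateRangeError(
                f"position {pos} outside extent {self.reference_extent}"
            )
        hits: list[tuple[int, str]] = []
        for off, seg in zip(self.offsets, self.segments):
            if seg.source.contains(pos):
                if seg.orientation == FORWARD:
                    hits.append((off + pos - seg.source.start, FORWARD))
                else:
                    hits.append((off + seg.source.end - 1 - pos, REVERSE))
        return hits

    def liftover_interval(self, iv: GenomicInterval) -> list[tuple[GenomicInterval, str, int]]:
        """Map a reference interval to its (possibly partial) derivative copies.

        Returns ``(derivative interval, orientation, copy_index)`` triples
        where ``copy_index`` numbers hits 1..k in derivative order.  Copies
        truncated by a breakpoint are returned as the overlapping part.
        """
        out = []
        for off, seg in zip(self.offsets, self.segments):
            ov = seg.source.intersect(iv)
            if ov is None:
                continue
            if seg.orientation == FORWARD:
                d0 = off + ov.start - seg.source.start
                d1 = off + ov.end - seg.source.start
            else:
                d0 = off + seg.source.end - ov.end
                d1 = off + seg.source.end - ov.start
            out.append((GenomicInterval("derivative", d0, d1, label=iv.label), seg.orientation))
        out.sort(key=lambda t: t[0].start)
        return [(iv_d, ori, i + 1) for i, (iv_d, ori) in enumerate(out)]

    def to_reference(self, dpos: int) -> tuple[int, str]:
        """Map a derivative position back to its reference source base."""
        if not 0 <= dpos < self.length:
            raise CoordinateRangeError(f"derivative position {dpos} out of range")
        for off, seg in zip(self.offsets, self.segments):
            if off <= dpos < off + seg.length:
                if seg.orientation == FORWARD:
                    return seg.source.start + (dpos - off), FORWARD
                return seg.source.end - 1 - (dpos - off), REVERSE
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class CopyNumberProfile:
    """Per-base copy number over the reference extent, as maximal constant runs."""

    pieces: tuple[tuple[GenomicInterval, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for iv, cn in self.pieces:
            if cn < 0:
                raise UsageError("copy number must be >= 0")
            if prev_end is not None and iv.start != prev_end:
                raise UsageError("pieces must tile the extent without gaps")
            prev_end = iv.end

    def at(self, pos: int) -> int:
        for iv, cn in self.pieces:
            if iv.contains(pos):
                return cn
        raise CoordinateRangeError(f"position {pos} outside profile")

    def regions_with_cn_at_least(self, min_cn: int) -> list[GenomicInterval]:
        return merge_intervals([iv for iv, cn in self.pieces if cn >= min_cn])

    @property
    def total_bases(self) -> int:
        """Sum of piece length x copy number (derivative bases of reference origin)."""
        return sum(iv.length * cn for iv, cn in self.pieces)


# ---------------------------------------------------------------------------
# Notation parsing
# ---------------------------------------------------------------------------

_NUM = r"\d{1,3}(?:,\d{3})+|\d+"
_SEP = r"[_\-–—]"


def _span(a: str, b: str) -> str:
    return rf"(?P<{a}>{_NUM})\s*{_SEP}\s*(?P<{b}>{_NUM})"


_NOTATION_RE = re.compile(
    r"^\s*(?P<chrom>[A-Za-z0-9_.]+)\s*:\s*"
    + _span("s1", "e1")
    + r"(?P<kind>dupinv|dup|trip|inv|del(?:ins)?)"
    + r"(?:(?P<ins>"
    + _span("s2", "e2")
    + r"inv))?\s*$"
)


def _to_int(token: str) -> int:
    return int(token.replace(",", ""))


def parse_sv(
    notation: str,
    reference_extent: GenomicInterval,
    sv_id: str = "SV",
) -> SVDefinition:
    """Parse an HGVS-like SV notation into an :class:`SVDefinition`.

    Coordinates in the notation are 1-based inclusive and are converted to
    the internal 0-based half-open convention; ``source_notation`` keeps the
    verbatim input.
    """
    m = _NOTATION_RE.match(notation)
    if m is None:
        # best-effort identification of the offending token for the message
        token = notation.strip().split(":")[-1] if ":" in notation else notation.strip()
        raise NotationError(f"cannot parse SV notation {notation!r}", token=token or None)
    chrom = m.group("chrom")
    if chrom != reference_extent.chrom:
        raise CoordinateRangeError(
            f"notation chromosome {chrom!r} does not match extent "
            f"{reference_extent.chrom!r}"
        )
    s1, e1 = _to_int(m.group("s1")), _to_int(m.group("e1"))
    if s1 > e1:
        raise NotationError(f"start {s1:,} exceeds end {e1:,}", token=m.group("s1"))
    span = from_1based(chrom, s1, e1)
    if not reference_extent.contains_interval(span):
        raise CoordinateRangeError(f"{span} outside reference extent {reference_extent}")

    kind = m.group("kind")
    if kind == "delins":
        if m.group("ins") is None:
            raise NotationError("delins requires an inserted span ending in 'inv'", token=kind)
        s2, e2 = _to_int(m.group("s2")), _to_int(m.group("e2"))
        if s2 > e2:
            raise NotationError(f"start {s2:,} exceeds end {e2:,}", token=m.group("s2"))
        ins = from_1based(chrom, s2, e2)
        if not reference_extent.contains_interval(ins):
            raise CoordinateRangeError(f"{ins} outside reference extent {reference_extent}")
        edits = (Edit("delins_inverted", span, insert=ins),)
        sv_class = "delins_inversion"
    elif m.group("ins") is not None:
        raise NotationError("inserted span only valid after 'delins'", token=m.group("ins"))
    elif kind == "dup":
        edits = (Edit("duplicate", span, multiplicity=2),)
        sv_class = "tandem_duplication"
    elif kind == "trip":
        edits = (Edit("duplicate", span, multiplicity=3),)
        sv_class = "triplication"
    elif kind == "dupinv":
        edits = (Edit("duplicate", span, multiplicity=2, inverted_copy=True),)
        sv_class = "inverted_duplication"
    elif kind == "inv":
        edits = (Edit("invert", span),)
        sv_class = "inversion"
    elif kind == "del":
        edits = (Edit("delete", span),)
        sv_class = "deletion"
    else:  # pragma: no cover - regex restricts kinds
        raise NotationError(f"unknown suffix {kind!r}", token=kind)

    return SVDefinition(
        sv_id=sv_id,
        sv_class=sv_class,
        edits=edits,
        source_notation=notation,
        reference_extent=reference_extent,
    )


def format_sv(sv: SVDefinition) -> str:
    """Render a single-edit SVDefinition back to canonical notation.

    Inverse of :func:`parse_sv` on canonical strings (commas, ``_``
    separator).  Composite SVs with explicit segment lists have no
    single-line notation and raise :class:`UsageError`.
    """
    if len(sv.edits) != 1:
        raise UsageError("only single-edit SVs have a canonical notation")
    e = sv.edits[0]
    chrom = sv.reference_extent.chrom
    s1, e1 = e.interval.to_1based()
    head = f"{chrom}:{s1:,}_{e1:,}"
    if e.op == "duplicate":
        if e.inverted_copy:
            return head + "dupinv"
        return head + ("trip" if e.multiplicity == 3 else "dup")
    if e.op == "invert":
        return head + "inv"
    if e.op == "delete":
        return head + "del"
    s2, e2 = e.insert.to_1based()
    return head + f"delins{s2:,}_{e2:,}inv"


# ---------------------------------------------------------------------------
# Derivative construction
# ---------------------------------------------------------------------------


def _assign_copy_indices(segments: list[Segment]) -> tuple[Segment, ...]:
    seen: dict[tuple[int, int], int] = {}
    out = []
    for s in segments:
        key = (s.source.start, s.source.end)
        seen[key] = seen.get(key, 0) + 1
        out.append(replace(s, copy_index=seen[key]))
    return tuple(out)


def build_derivative(
    sv: SVDefinition, reference_extent: GenomicInterval | None = None
) -> DerivativeAllele:
    """Compile an SV definition into the derivative allele.

    Edits are applied left-to-right along the reference; tandem duplications
    are head-to-tail (the extra copy follows the original, creating the
    junction dup-end | dup-start), inverted-duplication copies are reversed,
    and delins inversions replace the deleted span with the reverse-oriented
    insert copy.  Edits whose intervals overlap are rejected.

    SVs carrying an explicit segment list (supplementary-defined internal
    structure) bypass edit compilation entirely.
    """
    extent = reference_extent or sv.reference_extent
    chrom = extent.chrom
    if sv.explicit_segments is not None:
        return DerivativeAllele(
            segments=_assign_copy_indices(list(sv.explicit_segments)),
            reference_extent=extent,
        )

    edits = sorted(sv.edits, key=lambda e: e.interval.start)
    for a, b in zip(edits, edits[1:]):
        if a.interval.end > b.interval.start:
            raise ModelError(
                f"overlapping incompatible edits: {a.interval} and {b.interval}"
            )

    segs: list[Segment] = []
    cursor = extent.start

    def emit(start: int, end: int, orientation: str = FORWARD) -> None:
        if end > start:
            segs.append(Segment(GenomicInterval(chrom, start, end), orientation))

    for e in edits:
        a, b = e.interval.start, e.interval.end
        if e.op == "duplicate":
            emit(cursor, b)  # reference through the end of the duplicated span
            for _ in range(e.multiplicity - 1):
                emit(a, b, REVERSE if e.inverted_copy else FORWARD)
            cursor = b
        elif e.op == "invert":
            emit(cursor, a)
            emit(a, b, REVERSE)
            cursor = b
        elif e.op == "delete":
            emit(cursor, a)
            cursor = b
        elif e.op == "delins_inverted":
            emit(cursor, a)
            emit(e.insert.start, e.insert.end, REVERSE)
            cursor = b
    emit(cursor, extent.end)
    if not segs:
        raise ModelError("edits delete the entire reference extent")
    return DerivativeAllele(
        segments=_assign_copy_indices(segs), reference_extent=extent
    )


def identity_derivative(reference_extent: GenomicInterval) -> DerivativeAllele:
    """The trivial derivative: one forward segment equal to the extent."""
    return DerivativeAllele(
        segments=(Segment(reference_extent),), reference_extent=reference_extent
    )


# ---------------------------------------------------------------------------
# Copy number and cohort intersection
# ---------------------------------------------------------------------------


def copy_number(d: DerivativeAllele) -> CopyNumberProfile:
    """Per-base copy number of the reference extent on the derivative.

    Pieces are maximal runs of constant copy number and tile the extent,
    including copy-number-zero (deleted) runs.
    """
    ext = d.reference_extent
    cuts = {ext.start, ext.end}
    for s in d.segments:
        cuts.add(s.source.start)
        cuts.add(s.source.end)
    bounds = sorted(cuts)
    pieces: list[tuple[GenomicInterval, int]] = []
    for lo, hi in zip(bounds, bounds[1:]):
        cn = sum(1 for s in d.segments if s.source.start <= lo and hi <= s.source.end)
        if pieces and pieces[-1][1] == cn:
            prev_iv, _ = pieces[-1]
            pieces[-1] = (GenomicInterval(ext.chrom, prev_iv.start, hi), cn)
        else:
            pieces.append((GenomicInterval(ext.chrom, lo, hi), cn))
    return CopyNumberProfile(pieces=tuple(pieces))


def common_core(svs: list[SVDefinition], min_cn: int = 2) -> list[GenomicInterval]:
    """Intersection over a cohort of the regions amplified to >= ``min_cn``.

    Returns the sorted, merged intervals present at copy number >= min_cn
    in *every* SV of the cohort; an empty intersection yields an empty list.
    """
    if not svs:
        raise UsageError("common_core requires at least one SV")
    chroms = {sv.reference_extent.chrom for sv in svs}
    if len(chroms) > 1:
        raise UsageError(f"SVs span multiple chromosomes: {sorted(chroms)}")
    result: list[GenomicInterval] | None = None
    for sv in svs:
        regions = copy_number(build_derivative(sv)).regions_with_cn_at_least(min_cn)
        result = regions if result is None else intersect_sets(result, regions)
        if not result:
            return []
    return result
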