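"""Breakpoint-junction characterization.

Given the two reference flanks of a breakpoint and a junction-spanning
sequence from the derivative allele (Sanger-validated in practice), the
module measures exact-match microhomology between the flanks, detects
untemplated inserted bases, classifies the likely repair mechanism, and
reports repeat annotations near a breakpoint.

Microhomology here is exact-match only (no mismatches) and case-insensitive;
``N`` never matches.  The mechanism classes follow the usual DNA-repair
reading: blunt joins point to non-homologous end joining (NHEJ), short
shared stretches to microhomology-mediated events (MMEJ / fork stalling and
template switching), long shared stretches to homology-mediated unequal
crossover, and untemplated insertions to NHEJ with fill-in synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateInputError, UsageError
from .intervals import GenomicInterval

BLUNT_NHEJ = "blunt_NHEJ"
MICROHOMOLOGY = "microhomology_mediated"
HOMOLOGY = "homology_mediated"
INSERTION_NHEJ = "insertion_NHEJ"

_VALID = set("ACGTN")


def _clean(seq: str, name: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise UsageError(f"{name} contains non-ACGTN characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class JunctionSequences:
    """Reference flanks and observed derivative sequence of one junction.

    ``left_ref`` ends at the left breakpoint (its final base is the last
    reference base retained on the derivative); ``right_ref`` starts at the
    right breakpoint.  ``observed`` spans the junction on the derivative.
    """

    left_ref: str
    right_ref: str
    observed: str
    junction_id: str = "junction"

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_ref", _clean(self.left_ref, "left_ref"))
        object.__setattr__(self, "right_ref", _clean(self.right_ref, "right_ref"))
        object.__setattr__(self, "observed", _clean(self.observed, "observed"))
        if len(self.observed) < 1:
            raise UsageError("observed sequence must be non-empty")


@dataclass(frozen=True)
class JunctionCall:
    """Microhomology / insertion call for one junction."""

    microhomology_len: int
    microhomology_seq: str
    inserted_seq: str
    mechanism_class: str
    junction_id: str = "junction"

    def __post_init__(self) -> None:
        if self.microhomology_len != len(self.microhomology_seq):
            raise UsageError("microhomology_len must equal len(microhomology_seq)")
        if self.microhomology_seq and self.inserted_seq:
            raise UsageError("microhomology and insertion are mutually exclusive")


def _match_len(a: str, b: str) -> bool:
    """Exact equality with N never matching."""
    return len(a) == len(b) and all(x == y and x != "N" for x, y in zip(a, b))


def _flank_microhomology(left: str, right: str, max_mh: int) -> int:
    """Longest k <= max_mh with suffix(left, k) == prefix(right, k)."""
    for k in range(min(max_mh, len(left), len(right)), 0, -1):
        if _match_len(left[-k:], right[:k]):
            return k
    return 0


def _max_left_anchor(observed: str, left: str) -> int:
    """Longest prefix of observed that is a suffix of left."""
    for a in range(min(len(observed), len(left)), 0, -1):
        if _match_len(observed[:a], left[-a:]):
            return a
    return 0


def _max_right_anchor(observed: str, right: str) -> int:
    """Longest suffix of observed that is a prefix of right."""
    for b in range(min(len(observed), len(right)), 0, -1):
        if _match_len(observed[-b:], right[:b]):
            return b
    return 0


def detect_microhomology(
    j: JunctionSequences,
    max_mh: int = 50,
    mh_threshold: int = 2,
    homology_threshold: int = 70,
) -> JunctionCall:
    """Call microhomology or untemplated insertion at one junction.

    The observed sequence is anchored to the flanks by its longest
    left/right exact overlaps.  If the anchors cover the observed sequence
    the junction is templated and the microhomology is the longest suffix
    of ``left_ref`` equal to a prefix of ``right_ref`` (single maximal
    value, so ties cannot arise); any observed bases matching neither flank
    are reported as an untemplated insertion instead.
    """
    if len(j.left_ref) < max_mh or len(j.right_ref) < max_mh:
        raise UsageError(
            f"flanks must each be at least max_mh={max_mh} bp "
            f"(got {len(j.left_ref)} / {len(j.right_ref)})"
        )
    if set(j.left_ref) <= {"N"} or set(j.right_ref) <= {"N"}:
        raise DegenerateInputError("flank consists only of N bases")

    a = _max_left_anchor(j.observed, j.left_ref)
    b = _max_right_anchor(j.observed, j.right_ref)

    if a + b >= len(j.observed):
        k = _flank_microhomology(j.left_ref, j.right_ref, max_mh)
        call = JunctionCall(
            microhomology_len=k,
            microhomology_seq=j.right_ref[:k],
            inserted_seq="",
            mechanism_class="",
            junction_id=j.junction_id,
        )
    else:
        call = JunctionCall(
            microhomology_len=0,
            microhomology_seq="",
            inserted_seq=j.observed[a : len(j.observed) - b],
            mechanism_class="",
            junction_id=j.junction_id,
        )
    return JunctionCall(
        microhomology_len=call.microhomology_len,
        microhomology_seq=call.microhomology_seq,
        inserted_seq=call.inserted_seq,
        mechanism_class=classify_mechanism(call, mh_threshold, homology_threshold),
        junction_id=j.junction_id,
    )


def classify_mechanism(
    call: JunctionCall, mh_threshold: int = 2, homology_threshold: int = 70
) -> str:
    """Map a junction call to a repair-mechanism class.

    Untemplated insertion -> insertion_NHEJ; shared stretch >=
    ``homology_threshold`` -> homology_mediated; shared stretch >=
    ``mh_threshold`` -> microhomology_mediated; anything shorter (including
    a single coincidental base) -> blunt_NHEJ.
    """
    if call.inserted_seq:
        return INSERTION_NHEJ
    if call.microhomology_len >= homology_threshold:
        return HOMOLOGY
    if call.microhomology_len >= mh_threshold:
        return MICROHOMOLOGY
    return BLUNT_NHEJ


def repeat_context(
    junction_pos: int,
    repeats: list[GenomicInterval],
    window: int = 500,
) -> list[str]:
    """Labels of repeat intervals within +/- ``window`` bp of a breakpoint.

    A repeat is reported when the gap between the breakpoint position and
    the interval is at most ``window`` (zero when the breakpoint falls
    inside the repeat).  Returns an empty list when nothing is nearby.
    """
    out = []
    for iv in sorted(repeats, key=lambda r: (r.start, r.end)):
        if iv.contains(junction_pos):
            gap = 0
        elif junction_pos < iv.start:
            gap = iv.start - junction_pos
        else:
            gap = junction_pos - (iv.end - 1)
        if gap <= window:
            out.append(iv.label if iv.label is not None else str(iv))
    return out
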