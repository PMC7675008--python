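"""Synthetic locus, contact-matrix, SV-suite and junction generators.

Every stage of the pipeline is testable without external data: the
generators emulate a ~1 Mb locus with the topology of the disease locus
under study — a single structured TAD containing a retina-expressed gene
(*YPEL2*-like) and clusters of retinal enhancers (NRL/CRX/OTX2 motifs),
flanked by boundary CTCF sites and by insulated neighbor genes
(*GDPD1*-like and *SMG8*-like) on the 5' side — together with a wild-type
contact matrix (power-law distance decay, TAD boost, boundary insulation,
Poisson counting noise) and a suite of eight rearrangement scenarios
mirroring the allele classes seen at the locus, each annotated with its
ground-truth ectopic enhancer-gene pairs.

Scenario geometry is parameterized on the locus landmarks, so the same
constructions remain valid under the seed-dependent coordinate jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotations import CTCFSite, Enhancer, Gene, LocusAnnotation
from .errors import UsageError
from .hic_rearrangement import ContactMatrix
from .intervals import GenomicInterval
from .junction_analysis import JunctionSequences, detect_microhomology
from .locus_model import (
    REVERSE,
    Segment,
    SVDefinition,
    build_derivative,
    parse_sv,
)

CHROM = "chrT"
_KB = 1000


@dataclass(frozen=True)
class LocusSpec:
    """A toy locus with one structured TAD and insulated neighbors."""

    extent: GenomicInterval
    tad: GenomicInterval
    annotation: LocusAnnotation
    seed: int = 0

    def __post_init__(self) -> None:
        for e in self.annotation.enhancers:
            if not self.tad.contains_interval(e.interval):
                raise UsageError(f"enhancer {e.enhancer_id} must lie inside the TAD")
        gdpd1 = self.annotation.gene("GDPD1L")
        if self.tad.overlaps(gdpd1.interval):
            raise UsageError("GDPD1-like gene must be insulated outside the TAD")
        bpos = {s.position for s in self.annotation.boundary_sites}
        if self.tad.start not in bpos or self.tad.end not in bpos:
            raise UsageError("boundary CTCF sites must sit at the TAD edges")


@dataclass(frozen=True)
class MatrixGenParams:
    """Parameters of the wild-type contact-matrix generator.

    ``depth`` scales the count level; ``alpha`` is the power-law decay
    exponent; ``beta`` multiplies pairs inside the TAD; ``gamma``
    attenuates pairs once per crossed boundary.  ``beta=1``/``gamma=1``
    are accepted to generate structure-free power-law controls.
    """

    bin_size: int = 5000
    alpha: float = -1.0
    beta: float = 3.0
    gamma: float = 0.3
    depth: float = 500.0
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise UsageError("decay exponent alpha must be negative")
        if self.beta < 1:
            raise UsageError("TAD boost beta must be >= 1")
        if not 0 < self.gamma <= 1:
            raise UsageError("boundary insulation gamma must be in (0, 1]")
        if self.noise not in ("poisson", "none"):
            raise UsageError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class SVScenario:
    """One rearrangement scenario with its designed ground truth."""

    sv_id: str
    definition: SVDefinition
    expected_ectopic: frozenset[tuple[str, str]]  # (enhancer id, gene id)
    expected_hijacked_copies: tuple[tuple[str, int], ...]  # gene id -> copy count
    description: str = ""

    @property
    def is_identity(self) -> bool:
        return self.definition.is_identity


# ---------------------------------------------------------------------------
# Locus
# ---------------------------------------------------------------------------


def gen_locus(seed: int = 0, extent_bp: int = 1_000_000, jitter_bp: int = 2000) -> LocusSpec:
    """Deterministic toy locus with seed-dependent coordinate jitter.

    The canonical layout (kb): SMG8-like [230,270) on '-', GDPD1-like
    [300,340) on '+', 5' boundary CTCF at 400, YPEL2-like [430,470) on '+',
    a non-boundary CTCF at 520, enhancers NRL [550,560), CRX [620,630),
    OTX2 [630,640), 3' boundary CTCF at 700.  Each landmark is shifted by
    an independent uniform offset in +/- ``jitter_bp``; the margins between
    landmarks exceed the jitter so topology (and therefore scenario ground
    truth) is seed-invariant.
    """
    rng = np.random.default_rng(seed)

    def j() -> int:
        return int(rng.integers(-jitter_bp, jitter_bp + 1))

    smg8 = 230 * _KB + j()
    gdpd1 = 300 * _KB + j()
    b5 = 400 * _KB + j()
    ypel2 = 430 * _KB + j()
    ctcf_mid = 520 * _KB + j()
    e_nrl = 550 * _KB + j()
    e_crx = 620 * _KB + j()
    b3 = 700 * _KB + j()

    def ctcf(site_id: str, pos: int, motif: str, boundary: bool) -> CTCFSite:
        return CTCFSite(
            site_id, GenomicInterval(CHROM, pos - 100, pos + 100, label=site_id),
            motif, boundary=boundary,
        )

    ann = LocusAnnotation(
        genes=(
            Gene("SMG8L", GenomicInterval(CHROM, smg8, smg8 + 40 * _KB, label="SMG8L"), "-"),
            Gene("GDPD1L", GenomicInterval(CHROM, gdpd1, gdpd1 + 40 * _KB, label="GDPD1L"), "+"),
            Gene("YPEL2L", GenomicInterval(CHROM, ypel2, ypel2 + 40 * _KB, label="YPEL2L"), "+"),
        ),
        enhancers=(
            Enhancer("ENH_NRL", GenomicInterval(CHROM, e_nrl, e_nrl + 10 * _KB), "NRL"),
            Enhancer("ENH_CRX", GenomicInterval(CHROM, e_crx, e_crx + 10 * _KB), "CRX"),
            Enhancer("ENH_OTX2", GenomicInterval(CHROM, e_crx + 10 * _KB, e_crx + 20 * _KB), "OTX2"),
        ),
        ctcf_sites=(
            ctcf("CTCF_5p", b5, "+", boundary=True),
            ctcf("CTCF_mid", ctcf_mid, "+", boundary=False),
            ctcf("CTCF_3p", b3, "-", boundary=True),
        ),
    )
    return LocusSpec(
        extent=GenomicInterval(CHROM, 0, extent_bp),
        tad=GenomicInterval(CHROM, b5, b3, label="YPEL2L_TAD"),
        annotation=ann,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Wild-type matrix
# ---------------------------------------------------------------------------


def expected_wt_matrix(spec: LocusSpec, p: MatrixGenParams) -> np.ndarray:
    """Noise-free expectation: power-law decay x TAD boost x insulation."""
    n = spec.extent.length // p.bin_size
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    expected = p.depth * np.power(1.0 + sep, p.alpha)

    t0, t1 = spec.tad.start // p.bin_size, spec.tad.end // p.bin_size
    in_tad = (idx >= t0) & (idx < t1)
    expected[np.ix_(in_tad, in_tad)] *= p.beta

    lo = np.minimum(idx[:, None], idx[None, :])
    hi = np.maximum(idx[:, None], idx[None, :])
    for site in spec.annotation.boundary_sites:
        b = site.position // p.bin_size
        expected[(lo < b) & (b <= hi)] *= p.gamma
    return expected


def gen_wt_matrix(spec: LocusSpec, p: MatrixGenParams) -> ContactMatrix:
    """Sample the wild-type contact matrix (symmetric by construction)."""
    expected = expected_wt_matrix(spec, p)
    if p.noise == "poisson":
        rng = np.random.default_rng(p.seed)
        n = expected.shape[0]
        upper = np.triu(rng.poisson(np.triu(expected)).astype(float))
        counts = upper + np.triu(upper, 1).T
    else:
        counts = expected
    return ContactMatrix(
        counts=counts,
        bin_size=p.bin_size,
        anchor=GenomicInterval(spec.extent.chrom, spec.extent.start,
                               spec.extent.start + p.bin_size),
        coordinate_space="reference",
    )


# ---------------------------------------------------------------------------
# SV scenario suite
# ---------------------------------------------------------------------------


def _notation(chrom: str, s0: int, e0: int, suffix: str,
              ins: tuple[int, int] | None = None) -> str:
    head = f"{chrom}:{s0 + 1:,}_{e0:,}"
    if ins is None:
        return head + suffix
    return head + f"delins{ins[0] + 1:,}_{ins[1]:,}inv"


def gen_sv_suite(spec: LocusSpec, include_identity: bool = True) -> list[SVScenario]:
    """Eight rearrangement scenarios plus an identity control.

    The constructions are anchored on the locus landmarks so that in every
    scenario the GDPD1-like gene (and in some the SMG8-like gene) acquires
    a copy co-domained with the retinal enhancers — the convergent
    enhancer-hijacking outcome — while the identity control changes
    nothing.  The triplication places two GDPD1-like copies into active
    neo-TADs.
    """
    ann = spec.annotation
    chrom = spec.extent.chrom
    G = ann.gene("GDPD1L").interval
    b5 = spec.tad.start
    e_nrl = ann.enhancers[0].interval.start
    e_end = max(e.interval.end for e in ann.enhancers)
    ext = spec.extent

    enh_ids = tuple(e.enhancer_id for e in ann.enhancers)

    def pairs(*genes: str) -> frozenset[tuple[str, str]]:
        return frozenset((e, g) for e in enh_ids for g in genes)

    dup_lo, dup_hi = G.start - 20 * _KB, e_end + 20 * _KB
    scenarios = [
        SVScenario(
            "NL-SV1-like",
            parse_sv(_notation(chrom, dup_lo, dup_hi, "dup"), ext, sv_id="NL-SV1-like"),
            pairs("GDPD1L"),
            (("GDPD1L", 1),),
            "tandem duplication spanning neighbor gene, 5' boundary and enhancers",
        ),
        SVScenario(
            "UK-SV2-like",
            parse_sv(
                _notation(chrom, b5 - 40 * _KB, b5 - 20 * _KB, "delins",
                          ins=(G.start - 10 * _KB, e_end + 40 * _KB)),
                ext, sv_id="UK-SV2-like",
            ),
            pairs("GDPD1L", "SMG8L"),
            (("GDPD1L", 1), ("SMG8L", 1)),
            "duplicated inversion: deletion replaced by large inverted copy",
        ),
        SVScenario(
            "SA-SV3-like",
            replace(
                parse_sv(
                    _notation(chrom, b5 - 46 * _KB, b5 - 44 * _KB, "delins",
                              ins=(G.start - 5 * _KB, e_end + 25 * _KB)),
                    ext, sv_id="SA-SV3-like",
                ),
                sv_class="inverted_duplication",
            ),
            pairs("GDPD1L", "SMG8L"),
            (("GDPD1L", 1), ("SMG8L", 1)),
            "inversion-duplication founder allele",
        ),
        SVScenario(
            "CA-SV4-like",
            replace(
                parse_sv(
                    _notation(chrom, b5 - 30 * _KB, b5 - 26 * _KB, "delins",
                              ins=(G.start - 2 * _KB, e_end + 15 * _KB)),
                    ext, sv_id="CA-SV4-like",
                ),
                sv_class="inverted_duplication",
            ),
            pairs("GDPD1L", "SMG8L"),
            (("GDPD1L", 1), ("SMG8L", 1)),
            "second, independent inversion-duplication",
        ),
        SVScenario(
            "NL-SV5-like",
            SVDefinition(
                sv_id="NL-SV5-like",
                sv_class="composite",
                edits=(),
                source_notation="composite(explicit segments)",
                reference_extent=ext,
                explicit_segments=(
                    Segment(GenomicInterval(chrom, ext.start, dup_hi)),
                    Segment(GenomicInterval(chrom, e_nrl - 50 * _KB, dup_hi), REVERSE),
                    Segment(GenomicInterval(chrom, dup_lo, e_nrl - 50 * _KB)),
                    Segment(GenomicInterval(chrom, dup_hi, ext.end)),
                ),
            ),
            pairs("GDPD1L"),
            (("GDPD1L", 1),),
            "composite duplication with internally inverted copy",
        ),
        SVScenario(
            "UK-SV6-like",
            parse_sv(_notation(chrom, dup_lo, dup_hi, "trip"), ext, sv_id="UK-SV6-like"),
            pairs("GDPD1L"),
            (("GDPD1L", 2),),
            "triplication: two extra copies, two hijacked gene copies",
        ),
        SVScenario(
            "UK-SV7-like",
            parse_sv(
                _notation(chrom, b5 - 39 * _KB, b5 - 21 * _KB, "delins",
                          ins=(G.start - 9 * _KB, e_end + 39 * _KB)),
                ext, sv_id="UK-SV7-like",
            ),
            pairs("GDPD1L", "SMG8L"),
            (("GDPD1L", 1), ("SMG8L", 1)),
            "duplicated inversion with breakpoints shifted ~1 kb from UK-SV2-like",
        ),
        SVScenario(
            "UK-SV8-like",
            SVDefinition(
                sv_id="UK-SV8-like",
                sv_class="composite",
                edits=(),
                source_notation="composite(explicit segments)",
                reference_extent=ext,
                explicit_segments=(
                    Segment(GenomicInterval(chrom, ext.start, G.end + 5 * _KB)),
                    Segment(GenomicInterval(chrom, e_nrl - 5 * _KB, e_end + 25 * _KB)),
                    Segment(GenomicInterval(chrom, G.end + 5 * _KB, ext.end)),
                ),
            ),
            pairs("GDPD1L", "SMG8L"),
            (("GDPD1L", 1), ("SMG8L", 1)),
            "composite: forward enhancer-block copy inserted next to the neighbor gene",
        ),
    ]
    if include_identity:
        scenarios.append(
            SVScenario(
                "WT-CTRL",
                SVDefinition(
                    sv_id="WT-CTRL",
                    sv_class="composite",
                    edits=(),
                    source_notation="identity",
                    reference_extent=ext,
                ),
                frozenset(),
                (),
                "identity control: unrearranged allele",
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# Junction fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionFixture:
    junction_id: str
    sequences: JunctionSequences
    planted_mh: int
    planted_insert: int


DEFAULT_PLANT_CYCLE = (4, 0, 7, -5, 2, 12, 18, 1, 15, -3, 6, 20)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def gen_junctions(
    svs: list[SVDefinition] | list[SVScenario],
    seed: int,
    mh_lengths: list[int] | None = None,
    flank_len: int = 120,
    max_mh: int = 50,
) -> list[JunctionFixture]:
    """Junction-sequence fixtures with planted microhomology or insertions.

    One fixture is generated per novel junction of each SV, identified as
    ``<sv_id>:<junction_index>``.  Entries of ``mh_lengths`` are planted
    microhomology lengths; a negative entry ``-m`` plants an untemplated
    insertion of ``m`` bases instead.  When omitted, a fixed cycle covering
    blunt joins, short and long homology and insertions is used.  Flanks
    are rejection-sampled until exact recovery of the planted value is the
    unique maximal call, so fixtures carry unambiguous ground truth.
    """
    rng = np.random.default_rng(seed)
    jids: list[str] = []
    for sv in svs:
        definition = sv.definition if isinstance(sv, SVScenario) else sv
        d = build_derivative(definition)
        for i, _ in enumerate(d.novel_junctions, start=1):
            jids.append(f"{definition.sv_id}:{i}")
    plan = list(mh_lengths) if mh_lengths is not None else [
        DEFAULT_PLANT_CYCLE[i % len(DEFAULT_PLANT_CYCLE)] for i in range(len(jids))
    ]
    if len(plan) != len(jids):
        raise UsageError(
            f"mh_lengths has {len(plan)} entries for {len(jids)} junctions"
        )

    fixtures = []
    for jid, want in zip(jids, plan):
        mh = max(want, 0)
        ins = -want if want < 0 else 0
        if mh > max_mh:
            raise UsageError(f"planted microhomology {mh} exceeds max_mh={max_mh}")
        for _ in range(1000):
            core = _random_seq(rng, mh)
            left = _random_seq(rng, flank_len - mh) + core
            right = core + _random_seq(rng, flank_len - mh)
            insert = _random_seq(rng, ins)
            span = min(40, flank_len)
            observed = left[-span:] + insert + right[mh : mh + span]
            seqs = JunctionSequences(left, right, observed, junction_id=jid)
            call = detect_microhomology(seqs, max_mh=max_mh)
            ok_mh = ins == 0 and call.microhomology_len == mh and not call.inserted_seq
            ok_ins = ins > 0 and call.inserted_seq == insert
            if ok_mh or ok_ins:
                fixtures.append(JunctionFixture(jid, seqs, mh, ins))
                break
        else:  # pragma: no cover - rejection sampling virtually always succeeds
            raise RuntimeError(f"could not realize planted junction for {jid}")
    return fixtures


def write_junction_fasta(fixtures: list[JunctionFixture], fasta_path, truth_path=None) -> None:
    """Write fixtures as FASTA (ids ``<sv>:<idx>:<role>``) + truth TSV."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for f in fixtures:
        for role, seq in (
            ("left", f.sequences.left_ref),
            ("right", f.sequences.right_ref),
            ("observed", f.sequences.observed),
        ):
            records.append(SeqRecord(Seq(seq), id=f"{f.junction_id}:{role}", description=""))
    seqio_write(records, str(fasta_path), "fasta")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("junction_id\tplanted_mh\tplanted_insert\n")
            for f in fixtures:
                fh.write(f"{f.junction_id}\t{f.planted_mh}\t{f.planted_insert}\n")


def read_junction_fasta(fasta_path) -> list[JunctionSequences]:
    """Read ``<sv>:<idx>:<role>`` FASTA records back into junction triples."""
    from Bio.SeqIO import parse as seqio_parse

    groups: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in seqio_parse(str(fasta_path), "fasta"):
        jid, _, role = rec.id.rpartition(":")
        if jid not in groups:
            groups[jid] = {}
            order.append(jid)
        groups[jid][role] = str(rec.seq)
    out = []
    for jid in order:
        g = groups[jid]
        missing = {"left", "right", "observed"} - set(g)
        if missing:
            raise UsageError(f"junction {jid}: missing FASTA roles {sorted(missing)}")
        out.append(JunctionSequences(g["left"], g["right"], g["observed"], junction_id=jid))
    return out
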