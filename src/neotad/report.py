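"""End-to-end pipeline driver, run configuration and report assembly.

``run_pipeline`` executes parse -> derivative -> copy number -> cohort core
-> matrix rearrangement -> partitions -> neo-TAD report for every SV of a
scenario suite, either on simulated inputs (the built-in locus generator)
or on user-supplied BED/TSV/YAML/FASTA files, and assembles a single JSON
report.  Reports echo coordinates in both conventions (0-based half-open
and 1-based inclusive) to prevent off-by-one disputes, and are
byte-identical for a fixed configuration and seed once the timestamp is
set aside.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotations import read_annotation_beds, write_annotation_beds
from .errors import DataFormatError, UsageError
from .hic_rearrangement import (
    build_bin_map,
    fit_decay,
    read_matrix,
    rearrange_matrix,
    write_matrix,
)
from .intervals import GenomicInterval
from .junction_analysis import detect_microhomology
from .locus_model import (
    Segment,
    SVDefinition,
    build_derivative,
    common_core,
    copy_number,
    identity_derivative,
    parse_sv,
)
from .synthetic_data import (
    LocusSpec,
    MatrixGenParams,
    SVScenario,
    gen_junctions,
    gen_locus,
    gen_sv_suite,
    gen_wt_matrix,
    read_junction_fasta,
    write_junction_fasta,
)
from .tad_analysis import (
    call_boundaries,
    ctcf_partition,
    insulation_score,
    neo_tad_report,
    place_features,
)


def format_size(bp: int, unit: str = "kb", decimals: int = 1) -> str:
    """Format a base-pair size in kb/Mb, truncated (floor) to ``decimals``.

    Truncation (rather than rounding) matches the convention of quoting an
    11,552 bp interval as "11.5 kb"; sizes whose truncated decimal part is
    zero print as integers ("226 kb").
    """
    if bp < 0:
        raise UsageError("size must be non-negative")
    scale = {"kb": 1_000, "Mb": 1_000_000}.get(unit)
    if scale is None:
        raise UsageError(f"unknown unit {unit!r}")
    factor = 10**decimals
    value = math.floor(bp / scale * factor) / factor
    if value == int(value):
        return f"{int(value)} {unit}"
    return f"{value:.{decimals}f} {unit}"


# ---------------------------------------------------------------------------
# Configuration and scenario files
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    bin_size: int = 5000
    mode: str = "distance_adjusted"
    insulation_window: int = 5
    insulation_depth: float = 0.2
    promoter_bp: int = 2000
    min_cn: int = 2
    simulate: bool = True
    outdir: str | None = None
    write_matrices: bool = False
    # external inputs (used when simulate is False)
    reference: dict | None = None  # {chrom, start, end} 0-based half-open
    genes_bed: str | None = None
    enhancers_bed: str | None = None
    ctcf_bed: str | None = None
    wt_matrix: str | None = None
    sv_yaml: str | None = None
    junction_fasta: str | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise UsageError("bin_size must be positive")
        if self.mode not in ("locus_copy", "distance_adjusted"):
            raise UsageError(f"unknown mode {self.mode!r}")
        if self.insulation_window < 1:
            raise UsageError("insulation_window must be >= 1")
        if not self.simulate:
            needed = ["reference", "genes_bed", "enhancers_bed", "ctcf_bed",
                      "wt_matrix", "sv_yaml"]
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise UsageError(f"non-simulated run requires: {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise DataFormatError(f"{path}: config must be a mapping")
        data.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def dump_scenarios(scenarios: list[SVScenario], extent: GenomicInterval,
                   path: str | Path) -> None:
    """Serialize a scenario suite (with ground truth) as YAML."""
    doc = {
        "reference": {"chrom": extent.chrom, "start": extent.start, "end": extent.end},
        "svs": [],
    }
    for sc in scenarios:
        d: dict = {"sv_id": sc.sv_id, "class": sc.definition.sv_class,
                   "description": sc.description}
        if sc.definition.explicit_segments is not None:
            d["segments"] = [
                [s.source.start, s.source.end, s.orientation]
                for s in sc.definition.explicit_segments
            ]
        elif sc.definition.edits:
            d["notation"] = sc.definition.source_notation
        else:
            d["identity"] = True
        if sc.expected_ectopic:
            d["expected_ectopic"] = sorted([list(p) for p in sc.expected_ectopic])
        if sc.expected_hijacked_copies:
            d["expected_hijacked_copies"] = {g: c for g, c in sc.expected_hijacked_copies}
        doc["svs"].append(d)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenarios(path: str | Path) -> tuple[list[SVScenario], GenomicInterval]:
    """Load a scenario suite from YAML (inverse of :func:`dump_scenarios`)."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        ref = doc["reference"]
        extent = GenomicInterval(ref["chrom"], int(ref["start"]), int(ref["end"]))
        entries = doc["svs"]
    except (KeyError, TypeError) as exc:
        raise DataFormatError(f"{path}: malformed scenario file ({exc})") from exc
    scenarios = []
    for d in entries:
        sv_id = d["sv_id"]
        sv_class = d.get("class", "composite")
        if "segments" in d:
            definition = SVDefinition(
                sv_id=sv_id, sv_class=sv_class, edits=(),
                source_notation=d.get("notation", "composite(explicit segments)"),
                reference_extent=extent,
                explicit_segments=tuple(
                    Segment(GenomicInterval(extent.chrom, int(s), int(e)), ori)
                    for s, e, ori in d["segments"]
                ),
            )
        elif "notation" in d:
            definition = parse_sv(d["notation"], extent, sv_id=sv_id)
            if sv_class != definition.sv_class:
                from dataclasses import replace
                definition = replace(definition, sv_class=sv_class)
        elif d.get("identity"):
            definition = SVDefinition(
                sv_id=sv_id, sv_class="composite", edits=(),
                source_notation="identity", reference_extent=extent,
            )
        else:
            raise DataFormatError(f"{path}: SV {sv_id} has no notation or segments")
        scenarios.append(
            SVScenario(
                sv_id=sv_id,
                definition=definition,
                expected_ectopic=frozenset(
                    tuple(p) for p in d.get("expected_ectopic", [])
                ),
                expected_hijacked_copies=tuple(
                    sorted(d.get("expected_hijacked_copies", {}).items())
                ),
                description=d.get("description", ""),
            )
        )
    return scenarios, extent


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineReport:
    """Assembled pipeline output with provenance."""

    payload: dict
    output_files: list[str] = field(default_factory=list)

    def deterministic_payload(self) -> dict:
        """Payload with run timestamps stripped, for reproducibility checks."""
        out = json.loads(json.dumps(self.payload))
        out.get("provenance", {}).pop("timestamp", None)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=2, sort_keys=True))


def _interval_dict(iv: GenomicInterval) -> dict:
    s1, e1 = iv.to_1based()
    return {
        "chrom": iv.chrom,
        "start0": iv.start,
        "end0": iv.end,
        "start1": s1,
        "end1": e1,
        "size": format_size(iv.length),
    }


def simulate_workspace(outdir: str | Path, seed: int = 0,
                       bin_size: int = 5000) -> dict[str, Path]:
    """Write a full simulated input set (BEDs, matrix, SV YAML, junctions)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = gen_locus(seed)
    paths = write_annotation_beds(spec.annotation, outdir)
    wt = gen_wt_matrix(spec, MatrixGenParams(bin_size=bin_size, seed=seed))
    paths["wt_matrix"] = outdir / "wt_matrix.tsv"
    write_matrix(wt, paths["wt_matrix"], dialect="dense_tsv")
    scenarios = gen_sv_suite(spec)
    paths["sv_yaml"] = outdir / "sv_suite.yaml"
    dump_scenarios(scenarios, spec.extent, paths["sv_yaml"])
    fixtures = gen_junctions([s for s in scenarios if not s.is_identity], seed=seed)
    paths["junctions"] = outdir / "junctions.fa"
    paths["junction_truth"] = outdir / "junction_truth.tsv"
    write_junction_fasta(fixtures, paths["junctions"], paths["junction_truth"])
    tad_bed = outdir / "tad.bed"
    tad_bed.write_text(
        f"{spec.tad.chrom}\t{spec.tad.start}\t{spec.tad.end}\tYPEL2L_TAD\t0\t.\n"
    )
    paths["tad"] = tad_bed
    return paths


def _load_inputs(config: RunConfig):
    if config.simulate:
        spec: LocusSpec = gen_locus(config.seed)
        ann = spec.annotation
        extent = spec.extent
        wt = gen_wt_matrix(spec, MatrixGenParams(bin_size=config.bin_size,
                                                 seed=config.seed))
        scenarios = gen_sv_suite(spec)
        fixtures = gen_junctions(
            [s for s in scenarios if not s.is_identity], seed=config.seed
        )
        junctions = [f.sequences for f in fixtures]
    else:
        ann = read_annotation_beds(config.genes_bed, config.enhancers_bed,
                                   config.ctcf_bed)
        scenarios, extent = load_scenarios(config.sv_yaml)
        wt = read_matrix(config.wt_matrix)
        if wt.bin_size != config.bin_size:
            raise DataFormatError(
                f"matrix bin size {wt.bin_size} != configured {config.bin_size}"
            )
        junctions = (
            read_junction_fasta(config.junction_fasta)
            if config.junction_fasta
            else []
        )
    return ann, extent, wt, scenarios, junctions


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis for every SV of the configured suite."""
    ann, extent, wt, scenarios, junctions = _load_inputs(config)
    bs = config.bin_size
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    # wild-type references shared by all scenarios
    wt_deriv = identity_derivative(extent)
    wt_part = ctcf_partition(ann, wt_deriv, bs)
    wt_place = place_features(ann, wt_deriv, wt_part, bs, config.promoter_bp)
    wt_decay = fit_decay(wt)
    wt_insulation = call_boundaries(
        insulation_score(wt, config.insulation_window), config.insulation_depth
    )

    junction_calls = []
    for seqs in junctions:
        call = detect_microhomology(seqs)
        junction_calls.append(
            {
                "junction_id": seqs.junction_id,
                "microhomology_len": call.microhomology_len,
                "microhomology_seq": call.microhomology_seq,
                "inserted_seq": call.inserted_seq,
                "mechanism_class": call.mechanism_class,
            }
        )

    sv_entries = []
    for sc in scenarios:
        sv = sc.definition
        d = build_derivative(sv)
        cn = copy_number(d)
        mut = rearrange_matrix(wt, build_bin_map(d, bs), mode=config.mode,
                               decay=wt_decay)
        mut_part = ctcf_partition(ann, d, bs)
        mut_place = place_features(ann, d, mut_part, bs, config.promoter_bp)
        mut_insulation = call_boundaries(
            insulation_score(mut, config.insulation_window), config.insulation_depth
        )
        rep = neo_tad_report(
            wt_part, mut_part, wt_place, mut_place, wt, mut,
            derivative=d, sv_id=sv.sv_id, wt_decay=wt_decay,
        )
        entry = {
            "sv_id": sv.sv_id,
            "sv_class": sv.sv_class,
            "notation": sv.source_notation,
            "is_identity": sv.is_identity,
            "derivative_length_bp": d.length,
            "derivative_size": format_size(d.length),
            "segments": [
                {
                    "source": _interval_dict(s.source),
                    "orientation": s.orientation,
                    "copy_index": s.copy_index,
                }
                for s in d.segments
            ],
            "junctions": [
                {
                    "left_ref1": j.left_ref + 1,
                    "right_ref1": j.right_ref + 1,
                    "novel": j.novel,
                }
                for j in d.junctions
            ],
            "copy_number": [
                {"interval": _interval_dict(iv), "cn": cn_}
                for iv, cn_ in cn.pieces
            ],
            "ctcf_boundaries_bins": list(mut_part.boundaries),
            "insulation_boundaries_bins": list(mut_insulation.boundaries),
            "neo_tad": rep.to_dict(),
        }
        sv_entries.append(entry)

        if outdir:
            seg_bed = outdir / f"{sv.sv_id}.segments.bed"
            with seg_bed.open("w") as fh:
                for off, s in zip(d.offsets, d.segments):
                    strand = "+" if s.orientation == "forward" else "-"
                    fh.write(
                        f"derivative\t{off}\t{off + s.length}\t"
                        f"{s.source.chrom}:{s.source.start}-{s.source.end}/"
                        f"{s.copy_index}\t0\t{strand}\n"
                    )
            written.append(str(seg_bed))
            dom_bed = outdir / f"{sv.sv_id}.domains.bed"
            with dom_bed.open("w") as fh:
                for k, (a, b) in enumerate(mut_part.domains):
                    neo = "neo" if k in rep.neo_domain_indices else "domain"
                    fh.write(f"derivative\t{a * bs}\t{min(b * bs, d.length)}\t"
                             f"{sv.sv_id}_{neo}_{k}\t0\t.\n")
            written.append(str(dom_bed))
            if d.novel_junctions:
                bedpe = outdir / f"{sv.sv_id}.junctions.bedpe"
                with bedpe.open("w") as fh:
                    for j in d.novel_junctions:
                        fh.write(
                            f"{extent.chrom}\t{j.left_ref}\t{j.left_ref + 1}\t"
                            f"{extent.chrom}\t{j.right_ref}\t{j.right_ref + 1}\t"
                            f"{sv.sv_id}\t0\t"
                            f"{'+' if j.left_orientation == 'forward' else '-'}\t"
                            f"{'+' if j.right_orientation == 'forward' else '-'}\n"
                        )
                written.append(str(bedpe))
            if config.write_matrices:
                mpath = outdir / f"{sv.sv_id}.matrix.tsv"
                write_matrix(mut, mpath)
                written.append(str(mpath))

    real_svs = [sc.definition for sc in scenarios if not sc.is_identity]
    core = common_core(real_svs, min_cn=config.min_cn) if real_svs else []

    payload = {
        "config": {k: v for k, v in asdict(config).items()},
        "reference_extent": _interval_dict(extent),
        "wild_type": {
            "ctcf_boundaries_bins": list(wt_part.boundaries),
            "insulation_boundaries_bins": list(wt_insulation.boundaries),
            "n_bins": wt.n,
        },
        "svs": sv_entries,
        "n_sv_alleles": len(real_svs),
        "common_core": [_interval_dict(iv) for iv in core],
        "junction_calls": junction_calls,
        "provenance": {
            "package": "neotad",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    }
    report = PipelineReport(payload=payload, output_files=written)
    if outdir:
        report_path = outdir / "report.json"
        report.save(report_path)
        report.output_files.append(str(report_path))
        calls_tsv = outdir / "junction_calls.tsv"
        with calls_tsv.open("w") as fh:
            fh.write("junction_id\tmicrohomology_len\tmicrohomology_seq\t"
                     "inserted_seq\tmechanism_class\n")
            for c in junction_calls:
                fh.write(
                    f"{c['junction_id']}\t{c['microhomology_len']}\t"
                    f"{c['microhomology_seq']}\t{c['inserted_seq']}\t"
                    f"{c['mechanism_class']}\n"
                )
        report.output_files.append(str(calls_tsv))
    return report
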