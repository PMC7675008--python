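"""Locus annotations: genes, enhancers and CTCF sites, with BED6 I/O.

All coordinates are 0-based half-open, matching emitted BED.  CTCF motif
orientation is carried in the BED strand column; boundary-flagged sites
(those anchoring a domain boundary) use score 1000, others 0.  Enhancers
carry their transcription-factor label (e.g. NRL, CRX, OTX2) after a ``|``
in the name column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import DataFormatError
from .intervals import GenomicInterval


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    strand: str  # '+' or '-'

    @property
    def tss(self) -> int:
        """Transcription start site: strand-aware end of the interval."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def promoter(self, upstream_bp: int = 2000) -> GenomicInterval:
        """Promoter interval upstream of the TSS (strand-aware)."""
        if self.strand == "+":
            return GenomicInterval(
                self.interval.chrom,
                self.interval.start - upstream_bp,
                self.interval.start,
                label=f"{self.gene_id}:promoter",
            )
        return GenomicInterval(
            self.interval.chrom,
            self.interval.end,
            self.interval.end + upstream_bp,
            label=f"{self.gene_id}:promoter",
        )


@dataclass(frozen=True)
class Enhancer:
    enhancer_id: str
    interval: GenomicInterval
    tf_label: str = ""


@dataclass(frozen=True)
class CTCFSite:
    site_id: str
    interval: GenomicInterval
    motif_orientation: str  # '+' or '-'
    boundary: bool = False

    @property
    def position(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class LocusAnnotation:
    """All regulatory annotations of the configured locus."""

    genes: tuple[Gene, ...]
    enhancers: tuple[Enhancer, ...]
    ctcf_sites: tuple[CTCFSite, ...]

    @property
    def boundary_sites(self) -> tuple[CTCFSite, ...]:
        return tuple(s for s in self.ctcf_sites if s.boundary)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# BED6 round trip
# ---------------------------------------------------------------------------


def _bed_rows(path: Path) -> list[list[str]]:
    rows = []
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 6:
            raise DataFormatError(f"{path}: expected BED6, got {len(parts)} columns")
        rows.append(parts)
    return rows


def write_annotation_beds(ann: LocusAnnotation, outdir: str | Path) -> dict[str, Path]:
    """Write genes.bed / enhancers.bed / ctcf.bed under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    genes = outdir / "genes.bed"
    with genes.open("w") as fh:
        for g in ann.genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
                f"\t{g.gene_id}\t0\t{g.strand}\n"
            )
    paths["genes"] = genes

    enh = outdir / "enhancers.bed"
    with enh.open("w") as fh:
        for e in ann.enhancers:
            name = f"{e.enhancer_id}|{e.tf_label}" if e.tf_label else e.enhancer_id
            fh.write(
                f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}"
                f"\t{name}\t0\t.\n"
            )
    paths["enhancers"] = enh

    ctcf = outdir / "ctcf.bed"
    with ctcf.open("w") as fh:
        for s in ann.ctcf_sites:
            score = 1000 if s.boundary else 0
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.site_id}\t{score}\t{s.motif_orientation}\n"
            )
    paths["ctcf"] = ctcf
    return paths


def read_annotation_beds(
    genes_bed: str | Path, enhancers_bed: str | Path, ctcf_bed: str | Path
) -> LocusAnnotation:
    genes = []
    for c, s, e, name, _score, strand in _bed_rows(Path(genes_bed)):
        if strand not in "+-":
            raise DataFormatError(f"gene {name}: strand must be + or -")
        genes.append(Gene(name, GenomicInterval(c, int(s), int(e), label=name), strand))
    enhancers = []
    for c, s, e, name, _score, _strand in _bed_rows(Path(enhancers_bed)):
        eid, _, tf = name.partition("|")
        enhancers.append(Enhancer(eid, GenomicInterval(c, int(s), int(e), label=eid), tf))
    ctcf = []
    for c, s, e, name, score, strand in _bed_rows(Path(ctcf_bed)):
        if strand not in "+-":
            raise DataFormatError(f"CTCF site {name}: motif orientation must be + or -")
        ctcf.append(
            CTCFSite(
                name,
                GenomicInterval(c, int(s), int(e), label=name),
                strand,
                boundary=int(float(score)) >= 1000,
            )
        )
    return LocusAnnotation(tuple(genes), tuple(enhancers), tuple(ctcf))
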