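"""Binned contact matrices and in-silico rearrangement.

The central operation turns a wild-type Hi-C matrix into the predicted
matrix of a derivative allele: every derivative bin is mapped to its source
reference bin(s) through a :class:`BinMap`, and the mutant entry for a bin
pair is assembled from the corresponding wild-type entries.  In
``distance_adjusted`` mode (the default), pairs whose genomic separation
changed on the derivative are rescaled by the ratio of the expected
contact-by-distance curve at the new versus the old separation, so that
contacts across novel junctions follow the distance decay of the map
instead of retaining their (much weaker) long-range reference values.
``locus_copy`` mode copies values unscaled and is kept as an exactly
checkable oracle.

Matrices live in small plain-text files: a dense TSV with a metadata
comment line, or a 0-based ``bin_i bin_j count`` triplet text compatible
with standard cooler-style loaders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataFormatError, ModelError, UsageError
from .intervals import GenomicInterval
from .locus_model import FORWARD, DerivativeAllele

EXPECTED_FLOOR_FRACTION = 1e-6  # floor for the decay curve, relative to its max


@dataclass
class ContactMatrix:
    """A symmetric binned contact map anchored on the genome.

    ``anchor`` is the genomic interval of bin 0; bin ``i`` covers
    ``[anchor.start + i*bin_size, anchor.start + (i+1)*bin_size)`` on the
    chromosome (or on the derivative allele when ``coordinate_space`` is
    ``"derivative"``).
    """

    counts: np.ndarray
    bin_size: int
    anchor: GenomicInterval
    coordinate_space: str = "reference"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataFormatError(f"counts must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise DataFormatError("contact counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise DataFormatError("contact matrix must be symmetric")
        if self.bin_size <= 0:
            raise UsageError("bin_size must be positive")
        if self.coordinate_space not in ("reference", "derivative"):
            raise UsageError(f"bad coordinate_space {self.coordinate_space!r}")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int) -> int:
        b = (pos - self.anchor.start) // self.bin_size
        if not 0 <= b < self.n:
            raise UsageError(f"position {pos} outside matrix extent")
        return int(b)

    @property
    def extent(self) -> GenomicInterval:
        return GenomicInterval(
            self.anchor.chrom,
            self.anchor.start,
            self.anchor.start + self.n * self.bin_size,
        )


@dataclass(frozen=True)
class DecayCurve:
    """Expected contact as a function of bin separation.

    ``expected[s]`` is the mean observed contact at separation ``s`` in
    bins; separations beyond the fitted range are extrapolated with a
    power law fitted to the curve in log-log space.  Values are floored at
    a small positive fraction of the maximum so that observed/expected
    ratios stay finite at unsampled separations.
    """

    separations: np.ndarray
    expected: np.ndarray
    _powerlaw: tuple[float, float] = field(default=(0.0, 0.0), repr=False)

    @property
    def floor(self) -> float:
        mx = float(self.expected.max(initial=0.0))
        return EXPECTED_FLOOR_FRACTION * mx if mx > 0 else EXPECTED_FLOOR_FRACTION

    def value_at(self, s: np.ndarray | int) -> np.ndarray:
        """Expected contact at separation(s) ``s``, floored, extrapolated."""
        s = np.atleast_1d(np.asarray(s, dtype=int))
        n = len(self.expected)
        out = np.empty(s.shape, dtype=float)
        inside = s < n
        out[inside] = self.expected[s[inside]]
        if (~inside).any():
            log_c, alpha = self._powerlaw
            out[~inside] = np.exp(log_c + alpha * np.log1p(s[~inside]))
        return np.maximum(out, self.floor)


def fit_decay(m: ContactMatrix, monotone: bool = False) -> DecayCurve:
    """Expected-by-distance curve: mean of each diagonal of the matrix.

    ``monotone=True`` additionally enforces a non-increasing curve via a
    running minimum (off by default).
    """
    if m.n < 2:
        raise UsageError("need at least 2 bins to fit a decay curve")
    expected = np.array(
        [float(np.mean(np.diagonal(m.counts, offset=s))) for s in range(m.n)]
    )
    if monotone:
        expected = np.minimum.accumulate(expected)
    pos = expected > 0
    if pos.sum() >= 2:
        x = np.log1p(np.nonzero(pos)[0].astype(float))
        y = np.log(expected[pos])
        alpha, log_c = np.polyfit(x, y, 1)
    else:
        alpha, log_c = 0.0, np.log(max(expected.max(initial=0.0), 1e-12))
    return DecayCurve(
        separations=np.arange(m.n),
        expected=expected,
        _powerlaw=(float(log_c), float(alpha)),
    )


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------


def _meta_line(m: ContactMatrix) -> str:
    return (
        f"#neotad chrom={m.anchor.chrom} start={m.anchor.start} "
        f"bin_size={m.bin_size} n={m.n} space={m.coordinate_space}"
    )


def _parse_meta(line: str) -> dict:
    fields = dict(tok.split("=", 1) for tok in line.lstrip("#").split()[1:])
    return {
        "chrom": fields.get("chrom", "chr"),
        "start": int(fields.get("start", 0)),
        "bin_size": int(fields.get("bin_size", 10_000)),
        "n": int(fields["n"]) if "n" in fields else None,
        "space": fields.get("space", "reference"),
    }


def write_matrix(m: ContactMatrix, path: str | Path, dialect: str = "dense_tsv") -> None:
    """Write a matrix as dense TSV (header of bin starts) or triplet text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_meta_line(m) + "\n")
        if dialect == "dense_tsv":
            starts = [str(m.anchor.start + i * m.bin_size) for i in range(m.n)]
            fh.write("\t".join(starts) + "\n")
            for row in m.counts:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
        elif dialect == "triplet":
            for i in range(m.n):
                for jj in range(i, m.n):
                    v = m.counts[i, jj]
                    if v != 0:
                        fh.write(f"{i}\t{jj}\t{v:.6g}\n")
        else:
            raise UsageError(f"unknown dialect {dialect!r}")


def read_matrix(path: str | Path, dialect: str | None = None) -> ContactMatrix:
    """Read a dense TSV or triplet matrix; triplet input is symmetrized.

    When ``dialect`` is None it is inferred from the file shape.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise DataFormatError(f"{path}: empty matrix file")
    meta = {"chrom": "chr", "start": 0, "bin_size": 10_000, "n": None, "space": "reference"}
    if lines[0].startswith("#"):
        meta.update(_parse_meta(lines[0]))
        lines = lines[1:]
    if dialect is None:
        ncols0 = len(lines[0].split("\t"))
        square_shape = len(lines) == ncols0 + 1 and all(
            len(ln.split("\t")) == ncols0 for ln in lines
        )
        if meta["n"] is not None:
            dialect = "dense_tsv" if (ncols0 == meta["n"] and square_shape) else "triplet"
        elif square_shape:
            dialect = "dense_tsv"  # header row of bin starts + n rows
        elif all(len(ln.split("\t")) == 3 for ln in lines):
            dialect = "triplet"
        else:
            dialect = "dense_tsv"

    if dialect == "dense_tsv":
        header = lines[0].split("\t")
        n = len(header)
        rows = [ln.split("\t") for ln in lines[1:]]
        if len(rows) != n or any(len(r) != n for r in rows):
            raise DataFormatError(f"{path}: dense matrix is not square ({n} columns)")
        counts = np.array([[float(v) for v in r] for r in rows])
        try:
            start = int(header[0])
        except ValueError:
            start = meta["start"]
        anchor_start = start
    elif dialect == "triplet":
        n = meta["n"]
        triplets = []
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) != 3:
                raise DataFormatError(f"{path}: malformed triplet row {ln!r}")
            i, jj, v = int(parts[0]), int(parts[1]), float(parts[2])
            triplets.append((i, jj, v))
        if n is None:
            n = max(max(i, jj) for i, jj, _ in triplets) + 1
        counts = np.zeros((n, n))
        for i, jj, v in triplets:
            if not (0 <= i < n and 0 <= jj < n):
                raise DataFormatError(f"{path}: bin index ({i},{jj}) out of range for n={n}")
            if v < 0:
                raise DataFormatError(f"{path}: negative count at ({i},{jj})")
            counts[i, jj] = v
            counts[jj, i] = v
        anchor_start = meta["start"]
    else:
        raise UsageError(f"unknown dialect {dialect!r}")

    if (counts < 0).any():
        raise DataFormatError(f"{path}: negative counts")
    return ContactMatrix(
        counts=counts,
        bin_size=meta["bin_size"],
        anchor=GenomicInterval(meta["chrom"], anchor_start, anchor_start + meta["bin_size"]),
        coordinate_space=meta["space"],
    )


# ---------------------------------------------------------------------------
# Bin maps and rearrangement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinSource:
    """One source contribution to a derivative bin."""

    ref_bin: int
    orientation: str
    fraction: float


@dataclass(frozen=True)
class BinMap:
    """Per-derivative-bin source assignment into reference bins.

    Every derivative bin has at least one entry; fractions within a bin sum
    to 1.  Bins that straddle a breakpoint junction carry multiple
    fractional entries (majority-weighted averaging rather than dropping),
    which keeps matrix dimensions a deterministic function of derivative
    length.
    """

    entries: tuple[tuple[BinSource, ...], ...]
    bin_size: int
    n_ref_bins: int

    @property
    def n_bins(self) -> int:
        return len(self.entries)


def build_bin_map(d: DerivativeAllele, bin_size: int) -> BinMap:
    """Assign each derivative bin to reference bin(s) by overlap fraction.

    Reverse segments carry reverse orientation.  The trailing derivative
    bin may be shorter than ``bin_size``; its fractions are normalized over
    the covered length so they still sum to 1.
    """
    if bin_size <= 0:
        raise UsageError("bin_size must be positive")
    ext = d.reference_extent
    n_ref = -(-ext.length // bin_size)
    n_bins = -(-d.length // bin_size)
    acc: list[dict[tuple[int, str], float]] = [dict() for _ in range(n_bins)]

    for off, seg in zip(d.offsets, d.segments):
        # walk the segment in derivative coordinates, bin by bin
        dpos = off
        dend = off + seg.length
        while dpos < dend:
            b = dpos // bin_size
            chunk_end = min((b + 1) * bin_size, dend)
            lo, hi = dpos, chunk_end  # derivative sub-interval inside one bin
            if seg.orientation == FORWARD:
                r0 = seg.source.start + (lo - off)
                r1 = seg.source.start + (hi - off)
            else:
                r0 = seg.source.end - (hi - off)
                r1 = seg.source.end - (lo - off)
            # split [r0, r1) across reference bins
            rpos = r0
            while rpos < r1:
                rb = (rpos - ext.start) // bin_size
                rchunk = min(ext.start + (rb + 1) * bin_size, r1)
                key = (int(rb), seg.orientation)
                acc[b][key] = acc[b].get(key, 0.0) + (rchunk - rpos)
                rpos = rchunk
            dpos = chunk_end

    entries = []
    for b, sources in enumerate(acc):
        total = sum(sources.values())
        if total <= 0:
            raise ModelError(f"derivative bin {b} received no source coverage")
        entries.append(
            tuple(
                BinSource(ref_bin=rb, orientation=ori, fraction=bp / total)
                for (rb, ori), bp in sorted(sources.items())
            )
        )
    return BinMap(entries=tuple(entries), bin_size=bin_size, n_ref_bins=n_ref)


def rearrange_matrix(
    wt: ContactMatrix,
    bm: BinMap,
    mode: str = "distance_adjusted",
    decay: DecayCurve | None = None,
) -> ContactMatrix:
    """Predict the derivative-allele contact matrix from the wild type.

    ``mutant[i, j]`` is the fraction-weighted sum of ``wt[u, v]`` over the
    source entries of bins ``i`` and ``j``.  In ``distance_adjusted`` mode
    each contribution is additionally rescaled by
    ``expected(|i-j|) / expected(|u-v|)`` using the wild-type decay curve,
    so only pairs whose separation changed are modified.  The output is
    symmetric and lives in derivative space.
    """
    if mode not in ("locus_copy", "distance_adjusted"):
        raise UsageError(f"unknown mode {mode!r}")
    if wt.coordinate_space != "reference":
        raise ModelError("wild-type matrix must be in reference space")
    if bm.n_ref_bins != wt.n:
        raise ModelError(
            f"bin map expects {bm.n_ref_bins} reference bins, matrix has {wt.n}"
        )
    n = bm.n_bins
    if mode == "distance_adjusted" and decay is None:
        decay = fit_decay(wt)

    # decompose entries into padded layers for vectorized gathering
    max_entries = max(len(e) for e in bm.entries)
    src = np.zeros((max_entries, n), dtype=int)
    frac = np.zeros((max_entries, n), dtype=float)
    for i, sources in enumerate(bm.entries):
        for k, s in enumerate(sources):
            src[k, i] = s.ref_bin
            frac[k, i] = s.fraction

    if mode == "distance_adjusted":
        etab = decay.value_at(np.arange(max(n, wt.n)))  # lookup incl. extrapolation
        d_new = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        e_new = etab[d_new]

    mut = np.zeros((n, n))
    for k in range(max_entries):
        for l_ in range(max_entries):
            w = frac[k][:, None] * frac[l_][None, :]
            if not w.any():
                continue
            block = wt.counts[np.ix_(src[k], src[l_])]
            if mode == "distance_adjusted":
                d_ref = np.abs(src[k][:, None] - src[l_][None, :])
                block = block * (e_new / etab[d_ref])
            mut += w * block

    mut = (mut + mut.T) / 2.0  # exact symmetry despite float summation order
    return ContactMatrix(
        counts=mut,
        bin_size=bm.bin_size,
        anchor=GenomicInterval("derivative", 0, bm.bin_size),
        coordinate_space="derivative",
    )


def matrix_for_derivative(
    wt: ContactMatrix, d: DerivativeAllele, mode: str = "distance_adjusted"
) -> ContactMatrix:
    """Convenience wrapper: build the bin map and rearrange in one step."""
    if wt.extent.start != d.reference_extent.start or wt.extent.chrom != d.reference_extent.chrom:
        raise ModelError("matrix anchor does not match derivative reference extent")
    return rearrange_matrix(wt, build_bin_map(d, wt.bin_size), mode=mode)
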