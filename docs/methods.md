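# Methods

This note documents the models behind `neotad`, the parameters that matter,
what the synthetic generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Coordinate conventions

Printed breakpoint notations use 1-based inclusive coordinates with
optional thousands commas and `_`/`-`/en-dash separators; everything
internal is 0-based half-open, and emitted BED/BEDPE is 0-based half-open.
Reports echo both conventions (`start0/end0` and `start1/end1`) so that a
span like 57,291,905–57,518,137 is unambiguously 226,233 bp. Sizes are
formatted by *truncating* (floor) to the requested number of decimals —
an 11,552 bp interval prints as "11.5 kb", a 226,233 bp span as "226 kb"
at integer precision — because that is the convention the cohort's
printed sizes follow.

## Derivative alleles

An SV is an ordered list of reference-relative edits (`duplicate` with
multiplicity, `invert`, `delete`, `delins_inverted`). Compilation walks
the reference left to right, emitting oriented segments:

- tandem duplication: the extra copy follows the original head-to-tail,
  so the novel junction joins the duplication end to the duplication
  start — fixed by the validated junction of the index duplication
  allele;
- inverted duplication (`dupinv`): the extra copy is reversed
  (head-to-head junction);
- triplication: a duplicate edit with multiplicity 3, head-to-tail by
  default;
- `delins…inv`: the deleted span is replaced by a reverse-oriented copy
  of the inserted span.

Edits must not overlap (a `ModelError` otherwise). Alleles whose internal
segment order is known only from supplementary material are given as
explicit segment lists in the scenario YAML, bypassing edit compilation;
this is deliberately the extension point for arbitrary composites.

Copy number is computed by cutting the extent at all segment endpoints and
counting covering segments per elementary interval — not by "duplicated
minus deleted" arithmetic. This matters for duplicated inversions, where
the natively deleted span retains exactly one copy carried inside the
inverted insert. The cohort core is the intersection over alleles of the
regions at copy number ≥ 2 (configurable), merged and sorted; it is
order-independent and idempotent by construction.

## Contact-map rearrangement

Matrices are symmetric binned counts (default 5 kb bins on the synthetic
locus; 10 kb is typical for real maps) in dense-TSV or 0-based triplet
text. The expected-by-distance curve `E(s)` is the mean of diagonal `s`;
beyond the observed range it is extrapolated by a power law fitted in
log-log space, and all evaluations are floored at `1e-6 · max E` so
observed/expected ratios stay finite. Optional monotone smoothing (running
minimum) is off by default.

A `BinMap` assigns every derivative bin its source reference bin(s) with
overlap fractions summing to 1; bins straddling a junction carry multiple
fractional entries (averaging, not dropping, keeps the matrix dimension a
deterministic function of derivative length). `locus_copy` mode computes
`M[i,j] = Σ f_u f_v W[u,v]` and is exactly checkable against a per-bin-pair
oracle; `distance_adjusted` (default) multiplies each contribution by
`E(d_new)/E(d_ref)`. Pairs whose separation did not change are untouched,
pure inversions are exact permutations (mass-conserving, involutive), and
the identity SV returns the wild-type matrix bit-for-bit.

### What the model does and does not predict

Distance adjustment makes contacts across novel junctions follow the
distance decay `P(s)`, which is the dominant effect in real rearranged
maps: the *raw* predicted contact between a hijacked promoter and the
enhancers rises severalfold simply because they are now tens of kilobases
apart instead of hundreds. The model does *not* re-estimate insulation:
a pair that crossed a boundary in the wild type keeps its attenuated
(γ-scaled) value after rescaling. Consequently the distance-normalized
observed/expected score of an ectopic pair is approximately invariant
under the transformation (it reduces to the carried-over attenuation
divided by the local mean modulation), and can even decrease when the
duplicated span is TAD-rich. Reports therefore carry both normalizations
per ectopic pair — `wt_contact`/`mut_contact` (raw means, where the
directional neo-contact signal lives, as on raw count maps) and
`wt_score`/`mut_score` (observed/expected, which answers the different
question "is this contact enriched for its distance?"). The directional
tests assert on raw mean contact; treating the o/e ratio as a hijacking
gain detector would be a misreading of the model and is documented here
so nobody repeats it.

## Domain calling

Two independent routes are computed and cross-checked:

- **Insulation route.** `score[i] = log2(mean of the window×window square
  upstream×downstream of bin i / locus-wide mean square)`, window 5 bins
  by default; edge bins are NaN; all-zero matrices yield no defined
  scores and a single domain. Boundaries are local minima with prominence
  ≥ 0.2 (scipy `find_peaks` on the negated score). Both defaults are
  config-exposed because boundary-calling conventions vary across
  pipelines; at the synthetic generator's default signal strength the
  planted boundaries are recovered within ±1 bin in ≥95% of seeds.
- **CTCF route.** Boundary-flagged CTCF sites are lifted through the
  rearrangement — one hit per copy, motif orientation flipped inside
  inverted segments — and their bins delimit domains. This mirrors how
  domain models are drawn from CTCF orientation when only a wild-type map
  is available.

Partitions always tile the binned extent; a boundary that would create a
domain shorter than 2 bins is dropped (nearest-kept-boundary wins). On the
wild-type synthetic locus the two routes agree within one bin.

Ectopic-pair detection uses the CTCF partition (deterministic, matching
the schematic-modeling practice); matrices are used for scoring and for
the insulation cross-check. Gene presence in a domain is decided by the
*promoter* copy (TSS-side 2 kb, strand-aware, configurable): a partial
gene copy that lost its TSS is not a hijacking candidate, which is the
biologically intended behavior for boundary-clipped fragments.

## Junction analysis

Microhomology is exact-match only (no mismatches), case-insensitive, `N`
never matches — consistent with junction validation by Sanger sequencing.
The observed junction-spanning sequence is anchored by its longest left-
flank-suffix and right-flank-prefix overlaps; if the anchors cover it, the
call is the longest suffix-of-left equal to a prefix-of-right (≤ `max_mh`,
default 50 bp); otherwise the uncovered middle is an untemplated
insertion. Classes: insertion → `insertion_NHEJ`; length ≥ 70 →
`homology_mediated` (unequal crossover range); length ≥ 2 →
`microhomology_mediated` (MMEJ / template-switching range); else
`blunt_NHEJ`. The two thresholds are parameters because only qualitative
classes are reported for the cohort; a single shared base is classified as
blunt since it carries no mechanistic signal. The detector is validated
against exhaustive suffix/prefix enumeration and against planted fixtures.

## Synthetic data: what it emulates

The toy locus (1 Mb, 200 × 5 kb bins) reproduces the *topology* of the
disease locus: one structured TAD `[400, 700) kb` holding a YPEL2-like
gene and three enhancers labeled NRL/CRX/OTX2, boundary CTCFs at the TAD
edges (inward-pointing motifs), and insulated SMG8-like and GDPD1-like
genes 5′ of the TAD. Landmarks are jittered ±2 kb per seed; margins exceed
the jitter, so scenario ground truth is seed-invariant. The matrix model
is `depth·(1+s)^α` (α = −1, the typical Hi-C scaling) times β = 3 for
within-TAD pairs and γ = 0.3 per crossed boundary, with Poisson sampling
of the upper triangle mirrored for exact symmetry; β ≥ 2, γ ≤ 0.5 at
≥ 200 bins is the strong-signal regime in which boundary recovery is
reliable, and β = 1/γ = 1 gives structure-free power-law controls.
Defaults keep the full suite a sub-second computation.

The eight scenarios are parameterized on locus landmarks: a tandem
duplication and a triplication spanning neighbor gene + 5′ boundary +
enhancers; three duplicated inversions (small deletion replaced by a large
inverted copy whose enhancer-bearing end lands next to the GDPD1-like
gene — the only single-edit geometry that produces the hijack with an
inverted copy, since a plain head-to-head duplication keeps the copied
boundary between enhancers and gene); and two explicit-segment composites.
Every allele's designed outcome places a GDPD1-like promoter copy in a
neo-TAD with the enhancers (two copies for the triplication); five of the
eight also co-domain the SMG8-like gene, a generator choice — the real
cohort documents the SMG8 effect for one allele and leaves the others'
internal structure to supplementary material. An identity control rounds
out the suite and must produce zero ectopic pairs.

What the generator does **not** emulate: mappability and coverage bias,
ICE/KR normalization artifacts, compartment structure, loops/stripes,
inter-allele heterogeneity of bulk Hi-C (maps mix the two alleles in
heterozygotes), and trans contacts. Passing tests therefore demonstrate
correctness of the coordinate algebra, the rearrangement operator and the
detection logic under a clean contact model — not robustness to real-map
noise sources.

## Numerical and degenerate-input choices

- Decay floor `1e-6 · max E`; power-law extrapolation beyond the fitted
  range; separations are integer bins.
- Rearranged matrices are symmetrized by `(M + Mᵀ)/2` to cancel float
  summation-order asymmetry (exact for permutation cases).
- Insulation on all-zero matrices: undefined scores, zero boundaries, one
  domain. Zero boundary CTCF sites: single-domain partition plus a
  warning.
- The final derivative bin may be shorter than the bin size; its source
  fractions are normalized over covered length.
- Junction fixtures are rejection-sampled until the planted value is the
  unique maximal call, so fixture ground truth is exact by construction.
- Pipeline reports are deterministic for fixed config and seed; the
  provenance timestamp is excluded from the determinism check.

## Problem sizes used in tests and acceptance

Unit oracles run on ≤ 50–65 bin matrices and ≤ 60 bp flanks (exhaustive
enumeration stays instant); recovery suites use the 200-bin locus over 20
seeds; the full acceptance script completes in a few seconds. These sizes
were chosen so that brute-force oracles remain practical while the
generator stays in its documented strong-signal regime.

## Known limitations

- Single-chromosome, single-locus scope; no genome-wide application.
- `distance_adjusted` cannot create insulation changes it was not given
  (see above); predicted maps are a proximity model, not a polymer model.
- Microhomology is exact-match; mismatch-tolerant homology search and
  repeat masking are out of scope (repeat context takes a repeat BED as
  given).
- The CTCF route treats every boundary-flagged site as an absolute
  boundary; occupancy strength and orientation-dependent loop extrusion
  are not modeled beyond orientation bookkeeping.
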