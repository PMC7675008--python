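"""Contact-matrix I/O, decay fitting, bin maps and matrix rearrangement."""

import numpy as np
import pytest

from neotad.errors import DataFormatError, ModelError, UsageError
from neotad.hic_rearrangement import (
    ContactMatrix,
    build_bin_map,
    fit_decay,
    matrix_for_derivative,
    read_matrix,
    rearrange_matrix,
    write_matrix,
)
from neotad.intervals import GenomicInterval
from neotad.locus_model import build_derivative, identity_derivative, parse_sv
from neotad.synthetic_data import MatrixGenParams, gen_locus, gen_wt_matrix

BS = 100
EXT = GenomicInterval("chrT", 0, 5000)  # 50 bins of 100 bp


def toy_matrix(n=50, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.poisson(20, size=(n, n)).astype(float)
    counts = np.triu(a) + np.triu(a, 1).T
    return ContactMatrix(counts, BS, GenomicInterval("chrT", 0, BS))


def bin_aligned_src(d, bs):
    """Independent per-bin source map for bin-aligned derivatives:
    walk the segments in whole-bin steps (no fractions involved)."""
    src = []
    for seg in d.segments:
        bins = list(range(seg.source.start // bs, seg.source.end // bs))
        src.extend(bins if seg.orientation == "forward" else bins[::-1])
    return src


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


class TestMatrixIO:
    def test_zero_dense_matrix_valid(self, tmp_path):
        m = ContactMatrix(np.zeros((3, 3)), BS, GenomicInterval("chrT", 0, BS))
        p = tmp_path / "z.tsv"
        write_matrix(m, p, "dense_tsv")
        back = read_matrix(p)
        assert back.n == 3 and not back.counts.any()

    def test_triplet_symmetrized(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("0\t1\t5\n")
        m = read_matrix(p, dialect="triplet")
        assert m.counts[0, 1] == m.counts[1, 0] == 5

    @pytest.mark.parametrize("dialect", ["dense_tsv", "triplet"])
    def test_roundtrip_exact(self, tmp_path, dialect):
        m = toy_matrix()
        p = tmp_path / "m.tsv"
        write_matrix(m, p, dialect)
        back = read_matrix(p)
        assert back.bin_size == m.bin_size
        assert back.n == m.n
        np.testing.assert_array_equal(back.counts, m.counts)

    def test_non_square_dense_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0\t100\t200\n1\t2\t3\n4\t5\t6\n")
        with pytest.raises(DataFormatError):
            read_matrix(p, dialect="dense_tsv")

    def test_negative_and_out_of_range_triplets_rejected(self, tmp_path):
        p = tmp_path / "neg.txt"
        p.write_text("#neotad chrom=c start=0 bin_size=100 n=3 space=reference\n0\t1\t-2\n")
        with pytest.raises(DataFormatError):
            read_matrix(p, dialect="triplet")
        p.write_text("#neotad chrom=c start=0 bin_size=100 n=3 space=reference\n0\t7\t2\n")
        with pytest.raises(DataFormatError):
            read_matrix(p, dialect="triplet")

    def test_asymmetric_counts_rejected(self):
        bad = np.array([[1.0, 2.0], [3.0, 1.0]])
        with pytest.raises(DataFormatError):
            ContactMatrix(bad, BS, GenomicInterval("chrT", 0, BS))


# ---------------------------------------------------------------------------
# fit_decay
# ---------------------------------------------------------------------------


class TestFitDecay:
    def test_constant_matrix_flat_curve(self):
        m = ContactMatrix(np.full((10, 10), 7.0), BS, GenomicInterval("chrT", 0, BS))
        curve = fit_decay(m)
        np.testing.assert_allclose(curve.expected, 7.0)
        np.testing.assert_allclose(curve.value_at(np.arange(10)), 7.0)

    def test_recovers_power_law_scaling(self):
        """Expected curve of a noise-free power-law generator matches
        depth * (1+s)^alpha."""
        spec = gen_locus(0)
        p = MatrixGenParams(noise="none", beta=1.0, gamma=1.0)
        m = gen_wt_matrix(spec, p)
        curve = fit_decay(m)
        s = np.arange(m.n)
        np.testing.assert_allclose(curve.expected, p.depth * (1 + s) ** p.alpha,
                                   rtol=1e-9)

    def test_minimal_two_bin_matrix(self):
        m = ContactMatrix(np.array([[4.0, 2.0], [2.0, 4.0]]), BS,
                          GenomicInterval("chrT", 0, BS))
        curve = fit_decay(m)
        assert list(curve.expected) == [4.0, 2.0]

    def test_extrapolation_is_positive_and_decreasing(self):
        m = gen_wt_matrix(gen_locus(0), MatrixGenParams(noise="none"))
        curve = fit_decay(m)
        far = curve.value_at(np.array([m.n, 2 * m.n, 5 * m.n]))
        assert (far > 0).all()
        assert far[0] >= far[1] >= far[2]

    def test_monotone_smoothing_option(self):
        counts = np.array([[5.0, 1.0, 3.0], [1.0, 5.0, 1.0], [3.0, 1.0, 5.0]])
        m = ContactMatrix(counts, BS, GenomicInterval("chrT", 0, BS))
        curve = fit_decay(m, monotone=True)
        assert list(curve.expected) == [5.0, 1.0, 1.0]


# ---------------------------------------------------------------------------
# build_bin_map
# ---------------------------------------------------------------------------


class TestBuildBinMap:
    def test_identity_map(self):
        bm = build_bin_map(identity_derivative(EXT), BS)
        assert bm.n_bins == 50
        for i, entries in enumerate(bm.entries):
            assert len(entries) == 1
            assert entries[0].ref_bin == i
            assert entries[0].fraction == 1.0

    def test_bin_aligned_duplication_maps_twice(self):
        d = build_derivative(parse_sv("chrT:2,001_3,000dup", EXT))  # bins 20..29
        bm = build_bin_map(d, BS)
        assert bm.n_bins == 60
        src = [e[0].ref_bin for e in bm.entries]
        assert src == bin_aligned_src(d, BS)
        assert src[20:30] == src[30:40] == list(range(20, 30))

    def test_bin_aligned_inversion_reverses_block(self):
        d = build_derivative(parse_sv("chrT:2,001_3,000inv", EXT))
        bm = build_bin_map(d, BS)
        src = [e[0].ref_bin for e in bm.entries]
        ori = [e[0].orientation for e in bm.entries]
        assert src[20:30] == list(range(29, 19, -1))
        assert set(ori[20:30]) == {"reverse"}
        assert set(ori[:20]) == {"forward"}

    def test_unaligned_breakpoint_gives_fractional_bin(self):
        d = build_derivative(parse_sv("chrT:2,041_3,040dup", EXT))
        bm = build_bin_map(d, BS)
        straddlers = [e for e in bm.entries if len(e) > 1]
        assert straddlers, "junction bin should carry multiple fractional sources"
        for entries in bm.entries:
            assert sum(s.fraction for s in entries) == pytest.approx(1.0)

    def test_bad_bin_size_rejected(self):
        with pytest.raises(UsageError):
            build_bin_map(identity_derivative(EXT), 0)


# ---------------------------------------------------------------------------
# rearrange_matrix
# ---------------------------------------------------------------------------


class TestRearrangeMatrix:
    @pytest.mark.parametrize("mode", ["locus_copy", "distance_adjusted"])
    def test_identity_sv_returns_wt_exactly(self, mode):
        wt = toy_matrix()
        bm = build_bin_map(identity_derivative(EXT), BS)
        mut = rearrange_matrix(wt, bm, mode=mode)
        np.testing.assert_allclose(mut.counts, wt.counts)

    def test_inversion_is_row_column_permutation(self):
        wt = toy_matrix()
        d = build_derivative(parse_sv("chrT:2,001_3,000inv", EXT))
        mut = rearrange_matrix(wt, build_bin_map(d, BS), mode="locus_copy")
        perm = np.array(bin_aligned_src(d, BS))
        np.testing.assert_array_equal(mut.counts, wt.counts[np.ix_(perm, perm)])

    def test_inversion_involution_returns_original(self):
        """Applying a bin-aligned inversion's map twice restores the matrix."""
        wt = toy_matrix()
        d = build_derivative(parse_sv("chrT:1,001_4,000inv", EXT))
        bm = build_bin_map(d, BS)
        once = rearrange_matrix(wt, bm, mode="locus_copy")
        twice = rearrange_matrix(
            ContactMatrix(once.counts, BS, GenomicInterval("chrT", 0, BS)), bm,
            mode="locus_copy",
        )
        np.testing.assert_array_equal(twice.counts, wt.counts)

    @pytest.mark.parametrize(
        "notation", ["chrT:2,001_3,000dup", "chrT:1,001_2,000trip",
                     "chrT:3,001_3,800dupinv",
                     "chrT:1,001_1,500delins2,001_4,000inv"]
    )
    def test_locus_copy_equals_brute_force(self, notation):
        """Element-wise oracle: mutant[i,j] == wt[src[i], src[j]] for
        bin-aligned rearrangements."""
        wt = toy_matrix()
        d = build_derivative(parse_sv(notation, EXT))
        mut = rearrange_matrix(wt, build_bin_map(d, BS), mode="locus_copy")
        src = bin_aligned_src(d, BS)
        assert len(src) == mut.n
        for i in range(mut.n):
            for j in range(mut.n):
                assert mut.counts[i, j] == wt.counts[src[i], src[j]]

    @pytest.mark.parametrize("mode", ["locus_copy", "distance_adjusted"])
    @pytest.mark.parametrize("notation", ["chrT:2,001_3,000dup", "chrT:2,001_3,000inv"])
    def test_symmetry_preserved(self, mode, notation):
        wt = toy_matrix()
        d = build_derivative(parse_sv(notation, EXT))
        mut = rearrange_matrix(wt, build_bin_map(d, BS), mode=mode)
        np.testing.assert_array_equal(mut.counts, mut.counts.T)

    def test_mass_conserved_for_pure_inversion(self):
        wt = toy_matrix()
        d = build_derivative(parse_sv("chrT:1,201_3,700inv", EXT))
        mut = rearrange_matrix(wt, build_bin_map(d, BS), mode="locus_copy")
        assert mut.counts.sum() == pytest.approx(wt.counts.sum())

    def test_modes_agree_where_separation_unchanged(self):
        """Pairs whose derivative separation equals their reference
        separation get identical values in both modes."""
        wt = toy_matrix()
        d = build_derivative(parse_sv("chrT:2,001_3,000dup", EXT))
        bm = build_bin_map(d, BS)
        lc = rearrange_matrix(wt, bm, mode="locus_copy")
        da = rearrange_matrix(wt, bm, mode="distance_adjusted")
        src = np.array(bin_aligned_src(d, BS))
        n = lc.n
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        unchanged = np.abs(ii - jj) == np.abs(src[ii] - src[jj])
        np.testing.assert_allclose(da.counts[unchanged], lc.counts[unchanged])
        assert (~unchanged).any()  # the duplication does move some pairs

    def test_neo_contact_emergence_across_boundary(self, locus, wt_matrix, suite):
        """A duplication spanning a TAD boundary raises the mean contact
        between enhancer bins and the hijacked-gene promoter bin."""
        ann = locus.annotation
        sc = next(s for s in suite if s.sv_id == "NL-SV1-like")
        d = build_derivative(sc.definition)
        bs = wt_matrix.bin_size
        mut = matrix_for_derivative(wt_matrix, d)
        enh_ref = [e.interval.start // bs for e in ann.enhancers]
        prom_ref = ann.gene("GDPD1L").promoter().start // bs
        wt_mean = wt_matrix.counts[np.ix_(enh_ref, [prom_ref])].mean()
        # hijacked copy: second promoter hit on the derivative
        prom_hits = d.liftover_interval(ann.gene("GDPD1L").promoter())
        enh_hits = [d.liftover_interval(e.interval)[0] for e in ann.enhancers]
        enh_mut = [iv.start // bs for iv, _, _ in enh_hits]
        prom_mut = prom_hits[1][0].start // bs
        mut_mean = mut.counts[np.ix_(enh_mut, [prom_mut])].mean()
        assert mut_mean > wt_mean

    def test_extent_mismatch_rejected(self):
        wt = toy_matrix(n=40)
        with pytest.raises(ModelError):
            rearrange_matrix(wt, build_bin_map(identity_derivative(EXT), BS))
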