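"""bedGraph/BED parsing, histogram reduction, and round-trip properties."""

import gzip

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fixcount as fc
from fixcount.counts import read_chrom_sizes


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadBedgraph:
    def test_interval_expansion(self, tmp_path):
        p = _write(tmp_path, "a.bedGraph", "chr1\t0\t3\t2\n")
        counts = fc.read_bedgraph(p)
        assert list(counts.pos) == [0, 1, 2]
        assert list(counts.value) == [2, 2, 2]
        assert counts.total_bases == 3

    def test_empty_file_with_explicit_domain(self, tmp_path):
        p = _write(tmp_path, "a.bedGraph", "")
        counts = fc.read_bedgraph(p, total_bases=100)
        assert len(counts) == 0
        hist = fc.histogram(counts)
        assert hist.N == 100 and hist.levels == {0: 100}

    def test_negative_value_rejected(self, tmp_path):
        p = _write(tmp_path, "a.bedGraph", "chr1\t0\t3\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            fc.read_bedgraph(p)

    def test_overlap_rejected_with_position(self, tmp_path):
        p = _write(tmp_path, "a.bedGraph", "chr1\t0\t5\t1\nchr1\t3\t8\t2\n")
        with pytest.raises(ValueError, match="chr1 at 3"):
            fc.read_bedgraph(p)

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.bedGraph.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t0\t2\t3\n")
        counts = fc.read_bedgraph(p)
        assert counts.n_reads == 6

    def test_chrom_sizes_sets_domain(self, tmp_path):
        sizes = _write(tmp_path, "chrom.sizes", "chr1\t50\nchr2\t30\n")
        assert read_chrom_sizes(sizes) == {"chr1": 50, "chr2": 30}
        p = _write(tmp_path, "a.bedGraph", "chr1\t0\t2\t1\n")
        counts = fc.read_bedgraph(p, chrom_sizes=sizes)
        assert counts.total_bases == 80


class TestReadBedReads:
    def test_plus_strand_reads_pool_at_start(self, tmp_path):
        p = _write(tmp_path, "r.bed",
                   "chr1\t10\t40\tr1\t0\t+\nchr1\t10\t36\tr2\t0\t+\n")
        counts = fc.read_bed_reads(p)
        assert list(counts.pos) == [10] and list(counts.value) == [2]

    def test_minus_strand_five_prime_end(self, tmp_path):
        p = _write(tmp_path, "r.bed", "chr1\t10\t20\tr1\t0\t-\n")
        counts = fc.read_bed_reads(p)
        assert list(counts.pos) == [19]

    def test_shift_is_strand_aware(self, tmp_path):
        p = _write(tmp_path, "r.bed",
                   "chr1\t10\t20\tr1\t0\t+\nchr1\t10\t20\tr2\t0\t-\n")
        counts = fc.read_bed_reads(p, shift=3)
        assert list(counts.pos) == [13, 16]

    def test_empty(self, tmp_path):
        p = _write(tmp_path, "r.bed", "")
        assert len(fc.read_bed_reads(p)) == 0

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = _write(tmp_path, "r.bed", "chr1\t10\t20\n\nchr1\tten\t20\n")
        with pytest.raises(ValueError, match="line 3"):
            fc.read_bed_reads(p)


class TestHistogram:
    @pytest.mark.parametrize("values,total,expected", [
        ([1, 1, 2], 10, {0: 7, 1: 2, 2: 1}),
        ([], 5, {0: 5}),
        ([3], 1, {0: 0, 3: 1}),
    ])
    def test_levels(self, values, total, expected):
        counts = fc.PerBaseCounts(["chr1"] * len(values),
                                  np.arange(len(values)), values, total)
        hist = fc.histogram(counts)
        assert hist.levels == {k: v for k, v in expected.items() if v > 0}
        assert hist.N == total

    def test_fractional_values_rejected(self):
        counts = fc.PerBaseCounts(["chr1"], [0], [1.5], 10)
        with pytest.raises(ValueError, match="integer"):
            fc.histogram(counts)

    def test_read_mass_conserved(self):
        counts = fc.PerBaseCounts(["chr1"] * 4, range(4), [2, 0, 3, 1], 10)
        assert fc.histogram(counts).n_reads == counts.n_reads == 6

    def test_invariants(self, small_hist):
        assert small_hist.counts.sum() == small_hist.N
        assert small_hist.counts[0] == small_hist.N - small_hist.counts[1:].sum()


class TestWriteBedgraph:
    def test_adjacent_equal_values_merged(self, tmp_path):
        counts = fc.PerBaseCounts(["chr1", "chr1"], [0, 1], [2, 2], 2)
        p = tmp_path / "o.bedGraph"
        fc.write_bedgraph(counts, p)
        assert p.read_text() == "chr1\t0\t2\t2\n"

    def test_zero_values_omitted(self, tmp_path):
        counts = fc.PerBaseCounts(["chr1"] * 3, [0, 1, 2], [1, 0, 1], 3)
        p = tmp_path / "o.bedGraph"
        fc.write_bedgraph(counts, p)
        assert len(p.read_text().splitlines()) == 2

    def test_fractional_precision(self, tmp_path):
        counts = fc.PerBaseCounts(["chr1"], [5], [1.3742], 10)
        p = tmp_path / "o.bedGraph"
        fc.write_bedgraph(counts, p, precision=4)
        assert p.read_text().split()[-1] == "1.3742"

    @given(st.lists(st.tuples(st.integers(0, 50), st.floats(0.001, 20.0)),
                    max_size=25, unique_by=lambda t: t[0]))
    def test_roundtrip_values_within_precision(self, tmp_path_factory, records):
        tmp = tmp_path_factory.mktemp("rt") / "o.bedGraph"
        pos = np.array([r[0] for r in records], dtype=np.int64)
        val = np.round([r[1] for r in records], 6)
        counts = fc.PerBaseCounts(np.full(pos.size, "chr1"), pos, val, 60)
        fc.write_bedgraph(counts, tmp, precision=4)
        back = fc.read_bedgraph(tmp, total_bases=60)
        nz = val > 0
        assert len(back) == int(nz.sum())
        if nz.any():
            assert np.allclose(np.sort(back.value), np.sort(val[nz]), atol=1e-4)

    def test_histogram_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.poisson(2.0, 200).astype(float)
        counts = fc.PerBaseCounts(np.full(200, "chr1"), np.arange(200), vals, 200)
        p = tmp_path / "o.bedGraph"
        fc.write_bedgraph(counts, p)
        back = fc.read_bedgraph(p, total_bases=200)
        assert fc.histogram(back).levels == fc.histogram(counts).levels


class TestHistogramText:
    def test_roundtrip(self, tmp_path, small_hist):
        p = tmp_path / "h.tsv"
        fc.write_histogram(small_hist, p)
        back = fc.read_histogram(p)
        assert back.levels == small_hist.levels and back.N == small_hist.N

    def test_zero_line_derived_from_total(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("1\t2\n2\t1\n")
        hist = fc.read_histogram(p, total_bases=10)
        assert hist.levels == {0: 7, 1: 2, 2: 1}


class TestPerBaseCounts:
    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fc.PerBaseCounts(["chr1", "chr1"], [3, 3], [1, 2], 10)

    def test_nonzero_exceeding_domain_rejected(self):
        with pytest.raises(ValueError, match="total_bases"):
            fc.PerBaseCounts(["chr1"] * 3, [0, 1, 2], [1, 1, 1], 2)

    def test_canonical_sort(self):
        c = fc.PerBaseCounts(["chr2", "chr1", "chr1"], [0, 5, 1], [1, 2, 3], 10)
        assert list(c.chrom) == ["chr1", "chr1", "chr2"]
        assert list(c.pos) == [1, 5, 0]
        assert list(c.value) == [3, 2, 1]
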