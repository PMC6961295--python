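"""Fragment maps, the sparse TSV dialect, and fixed-bin -> RF conversion."""

import numpy as np
import pytest

from finehic import (
    FragmentMap,
    IFMatrix,
    ReadCountMatrix,
    convert_fixed_to_rf,
    load_fragment_map,
    read_if_matrix,
    read_sparse_matrix,
    write_sparse_matrix,
)
from finehic.fragments import FragmentMapError
from finehic.io import SparseMatrixFormatError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFragmentMap:
    def test_basic_construction_and_pos(self, tmp_path):
        p = _write(tmp_path, "f.bed", "chr1\t0\t1000\nchr1\t1000\t2500\nchr1\t2500\t2600\n")
        fmap = load_fragment_map(p)
        assert fmap.n_fragments == 3
        assert list(fmap.pos) == [1000, 2500, 2600]
        assert list(fmap.sizes) == [1000, 1500, 100]

    def test_empty_file_errors(self, tmp_path):
        p = _write(tmp_path, "f.bed", "")
        with pytest.raises(FragmentMapError, match="no fragments"):
            load_fragment_map(p)

    def test_out_of_order_lines_sorted(self, tmp_path):
        lines = ["chr1\t1000\t2500", "chr1\t0\t1000", "chr1\t2500\t2600"]
        p1 = _write(tmp_path, "shuffled.bed", "\n".join(lines) + "\n")
        p2 = _write(tmp_path, "sorted.bed", "\n".join(sorted(lines, key=lambda l: int(l.split("\t")[1]))) + "\n")
        m1, m2 = load_fragment_map(p1), load_fragment_map(p2)
        assert np.array_equal(m1.starts, m2.starts)
        assert np.array_equal(m1.ends, m2.ends)

    @pytest.mark.parametrize(
        "text,err",
        [
            ("chr1\t100\t50\n", "end <= start"),
            ("chr1\t0\t100\nchr1\t50\t150\n", "overlap"),
            ("chr1\t0\n", "columns"),
            ("chr1\t0\tx\n", "non-integer"),
            ("chr1\t0\t10\nchr2\t10\t20\n", "multiple chromosomes"),
        ],
    )
    def test_malformed_input(self, tmp_path, text, err):
        p = _write(tmp_path, "bad.bed", text)
        with pytest.raises(FragmentMapError, match=err):
            load_fragment_map(p)

    def test_pos_strictly_increasing_with_gaps(self):
        fmap = FragmentMap("chr1", [0, 2000], [1000, 2600])  # gap 1000-2000
        assert np.all(np.diff(fmap.pos) > 0)


@pytest.fixture
def fmap3():
    return FragmentMap("chr1", [0, 1000, 2500], [1000, 2500, 2600])


class TestSparseMatrix:
    def test_symmetry_and_default_zero(self, tmp_path, fmap3):
        p = _write(tmp_path, "m.tsv", "chr1\t0\t1\t4\nchr1\t0\t2\t2\n")
        rc = read_sparse_matrix(p, fmap3)
        assert rc[1, 0] == 4
        assert rc[0, 1] == 4
        assert rc[2, 2] == 0

    def test_duplicate_rows_summed(self, tmp_path, fmap3):
        p = _write(tmp_path, "m.tsv", "chr1\t0\t1\t2\nchr1\t0\t1\t3\n")
        assert read_sparse_matrix(p, fmap3)[0, 1] == 5

    def test_header_line_ignored(self, tmp_path, fmap3):
        p = _write(tmp_path, "m.tsv", "#chrom\ti\tj\tvalue\nchr1\t0\t1\t4\n")
        assert read_sparse_matrix(p, fmap3)[0, 1] == 4

    @pytest.mark.parametrize("row", ["chr1\t0\t9\t1", "chr1\t0\t1\t-2", "chr1\t0\t1\t1.5"])
    def test_bad_rows_raise(self, tmp_path, fmap3, row):
        p = _write(tmp_path, "m.tsv", row + "\n")
        with pytest.raises(SparseMatrixFormatError):
            read_sparse_matrix(p, fmap3)

    def test_count_round_trip_byte_identical(self, tmp_path, fmap3, rng):
        upper = rng.poisson(1.0, size=(3, 3))
        rc = ReadCountMatrix(np.triu(upper) + np.triu(upper, 1).T)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sparse_matrix(rc, p1, chrom="chr1")
        rc2 = read_sparse_matrix(p1, fmap3)
        write_sparse_matrix(rc2, p2, chrom="chr1")
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(rc.values, rc2.values)

    def test_if_round_trip_within_1e6(self, tmp_path, fmap3, rng):
        v = rng.random((3, 3))
        ifm = IFMatrix((v + v.T) / 2)
        p = tmp_path / "if.tsv"
        write_sparse_matrix(ifm, p, chrom="chr1")
        back = read_if_matrix(p, fmap3)
        assert np.allclose(back.values, ifm.values, rtol=1e-5, atol=1e-9)
        # upper-triangle contract: no (j, i) duplicates in the file
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        assert all(int(r[1]) <= int(r[2]) for r in rows)

    def test_symmetry_contract_random(self, random_rc):
        assert np.array_equal(random_rc.values, random_rc.values.T)
        assert random_rc.total() == random_rc.values.sum()


class TestFixedToRF:
    def test_direct_assigns_bin_value(self):
        fmap = FragmentMap("chr1", [0, 20_000], [20_000, 45_000])
        binned = np.array([[8.0]])
        out = convert_fixed_to_rf(binned, 50_000, fmap, "direct")
        assert np.all(out.values == 8.0)

    def test_counts_conserves_mass(self):
        fmap = FragmentMap("chr1", [0, 20_000], [20_000, 45_000])
        binned = np.array([[8.0]])
        out = convert_fixed_to_rf(binned, 50_000, fmap, "counts")
        # bin value split over the 2x2 fragment block
        assert out.values.sum() == pytest.approx(8.0)
        assert np.allclose(out.values, 2.0)

    def test_weighted_conserves_mass_across_bin_edge(self):
        # second fragment spans the edge between bins 0 and 1
        fmap = FragmentMap("chr1", [0, 60, 140], [60, 140, 200])
        binned = np.array([[4.0, 2.0], [2.0, 6.0]])
        out = convert_fixed_to_rf(binned, 100, fmap, "weighted")
        assert out.values.sum() == pytest.approx(binned.sum())
        assert np.allclose(out.values, out.values.T)

    def test_direct_does_not_conserve_mass(self):
        fmap = FragmentMap("chr1", [0, 20_000], [20_000, 45_000])
        out = convert_fixed_to_rf(np.array([[8.0]]), 50_000, fmap, "direct")
        assert out.values.sum() != pytest.approx(8.0)

    def test_out_of_range_end_raises(self):
        fmap = FragmentMap("chr1", [0], [120_000])
        with pytest.raises(ValueError, match="beyond last bin"):
            convert_fixed_to_rf(np.array([[1.0]]), 50_000, fmap, "direct")
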