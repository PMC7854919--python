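import numpy as np
import pytest

from grnbalance.expression_io import (
    ExpressionMatrix,
    compute_rpkm,
    gene_variances,
    read_expression_table,
    select_top_variance,
    write_expression_table,
)


@pytest.fixture
def tiny_tsv(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text(
        "gene_id\ts1\ts2\n"
        "gA\t1\t2\n"
        "gB\t3\t4\n"
        "gC\t5\t6\n"
    )
    return p


class TestReadExpressionTable:
    def test_identity_readback(self, tiny_tsv):
        em = read_expression_table(tiny_tsv)
        assert em.gene_ids == ["gA", "gB", "gC"]
        assert em.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(em.values, [[1, 2], [3, 4], [5, 6]])

    def test_orientation_symmetry(self, tiny_tsv, tmp_path):
        em = read_expression_table(tiny_tsv)
        t = tmp_path / "transposed.tsv"
        t.write_text(
            "sample\tgA\tgB\tgC\n" "s1\t1\t3\t5\n" "s2\t2\t4\t6\n"
        )
        em_t = read_expression_table(t, orientation="genes-in-columns")
        assert em_t.gene_ids == em.gene_ids
        assert em_t.sample_ids == em.sample_ids
        np.testing.assert_array_equal(em_t.values, em.values)

    def test_duplicate_gene_id_is_named(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene_id\ts1\ts2\ngA\t1\t2\ngA\t3\t4\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression_table(p)

    def test_non_numeric_cell_is_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\ts1\ts2\ngA\t1\t2\ngB\toops\t4\n")
        with pytest.raises(ValueError, match="gB.*s1|oops"):
            read_expression_table(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_expression_table(tmp_path / "nope.tsv")

    def test_write_read_roundtrip(self, tmp_path, rng):
        em = ExpressionMatrix(
            ["a", "b"], ["x", "y", "z"], rng.normal(size=(2, 3)).round(6)
        )
        p = tmp_path / "rt.tsv"
        write_expression_table(em, p)
        back = read_expression_table(p)
        assert back.gene_ids == em.gene_ids
        assert back.sample_ids == em.sample_ids
        np.testing.assert_array_equal(back.values, em.values)

    def test_csv_dialect(self, tmp_path):
        p = tmp_path / "expr.csv"
        p.write_text("gene_id,s1,s2\ngA,1,2\n")
        em = read_expression_table(p)
        np.testing.assert_array_equal(em.values, [[1, 2]])


class TestValidation:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionMatrix(["a"], ["x", "y"], np.zeros((2, 2)))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(["a"], ["x", "y"], np.array([[1.0, np.nan]]))


class TestComputeRpkm:
    def test_hand_arithmetic_one_cell(self):
        # count 100, length 1 kb, library 1e7 reads -> RPKM 10
        em = ExpressionMatrix(["g", "filler"], ["s"], [[100.0], [10_000_000 - 100.0]])
        out = compute_rpkm(em, {"g": 1000, "filler": 1000})
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_two_gene_toy(self):
        # counts [10, 90], lengths [500, 2000], library 100
        em = ExpressionMatrix(["a", "b"], ["s"], [[10.0], [90.0]])
        out = compute_rpkm(em, {"a": 500, "b": 2000})
        np.testing.assert_allclose(out.values[:, 0], [200_000.0, 450_000.0])

    def test_zero_count_gives_zero(self):
        em = ExpressionMatrix(["a", "b"], ["s"], [[0.0], [50.0]])
        out = compute_rpkm(em, {"a": 100, "b": 100})
        assert out.values[0, 0] == 0.0

    def test_row_permutation_commutes(self, rng):
        counts = rng.integers(1, 100, size=(5, 3)).astype(float)
        ids = [f"g{i}" for i in range(5)]
        lengths = {g: 100 * (i + 1) for i, g in enumerate(ids)}
        em = ExpressionMatrix(ids, ["x", "y", "z"], counts)
        perm = [3, 1, 4, 0, 2]
        em_p = ExpressionMatrix([ids[i] for i in perm], ["x", "y", "z"], counts[perm])
        np.testing.assert_allclose(
            compute_rpkm(em, lengths).values[perm], compute_rpkm(em_p, lengths).values
        )

    def test_missing_length_errors(self):
        em = ExpressionMatrix(["a"], ["s", "t"], [[1.0, 2.0]])
        with pytest.raises(KeyError, match="a"):
            compute_rpkm(em, {})

    def test_zero_library_errors(self):
        em = ExpressionMatrix(["a"], ["s", "t"], [[0.0, 1.0]])
        with pytest.raises(ValueError, match="library"):
            compute_rpkm(em, {"a": 100})


class TestGeneVariances:
    def test_constant_row_zero(self):
        em = ExpressionMatrix(["a"], ["x", "y", "z"], [[5.0, 5.0, 5.0]])
        assert gene_variances(em)["a"] == 0.0

    def test_unbiased_denominator(self):
        em = ExpressionMatrix(["a"], ["x", "y"], [[0.0, 2.0]])
        assert gene_variances(em)["a"] == pytest.approx(2.0)
        assert gene_variances(em, ddof=0)["a"] == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.normal(size=(4, 7))
        em = ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{j}" for j in range(7)], vals)
        var = gene_variances(em)
        for i, g in enumerate(em.gene_ids):
            mean = sum(vals[i]) / 7
            expected = sum((x - mean) ** 2 for x in vals[i]) / 6
            assert var[g] == pytest.approx(expected, rel=1e-12)

    def test_single_sample_errors(self):
        em = ExpressionMatrix(["a"], ["x"], [[1.0]])
        with pytest.raises(ValueError):
            gene_variances(em)


class TestSelectTopVariance:
    def test_selects_largest(self):
        vals = np.array([[0, 0], [1, -1], [2, -2], [3, -3], [4, -4]], dtype=float)
        em = ExpressionMatrix(list("abcde"), ["x", "y"], vals)
        out = select_top_variance(em, 2)
        assert out.gene_ids == ["e", "d"]

    def test_k_equals_all_keeps_all(self):
        vals = np.array([[1, 2], [5, 1], [0, 0]], dtype=float)
        em = ExpressionMatrix(list("abc"), ["x", "y"], vals)
        out = select_top_variance(em, 3)
        assert sorted(out.gene_ids) == ["a", "b", "c"]

    def test_tie_break_lexicographic(self):
        vals = np.array([[0, 2], [0, 2], [0, 0]], dtype=float)
        em = ExpressionMatrix(["zz", "aa", "mm"], ["x", "y"], vals)
        out = select_top_variance(em, 2)
        assert out.gene_ids == ["aa", "zz"]

    def test_housekeeping_filtered_out(self, rng):
        from grnbalance.synthetic_data import add_housekeeping_genes

        strong = rng.normal(scale=5.0, size=(10, 40))
        em = ExpressionMatrix(
            [f"hi{i}" for i in range(10)], [f"s{j}" for j in range(40)], strong
        )
        em = add_housekeeping_genes(em, 40, seed=7)
        out = select_top_variance(em, 10)
        assert sorted(out.gene_ids) == sorted(f"hi{i}" for i in range(10))

    def test_sample_permutation_invariant(self, rng):
        vals = rng.normal(size=(6, 9))
        em = ExpressionMatrix([f"g{i}" for i in range(6)], [f"s{j}" for j in range(9)], vals)
        perm = rng.permutation(9)
        em_p = ExpressionMatrix(
            em.gene_ids, [em.sample_ids[j] for j in perm], vals[:, perm]
        )
        assert select_top_variance(em, 3).gene_ids == select_top_variance(em_p, 3).gene_ids

    def test_k_too_large(self):
        em = ExpressionMatrix(["a"], ["x", "y"], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            select_top_variance(em, 2)
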