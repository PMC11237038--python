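import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gwalign import (
    DissimilarityMatrix,
    RatingTable,
    from_ratings,
    normalize,
    read_matrix_csv,
    write_matrix_csv,
)
from gwalign.synthetic import simulate_rater_panel


class TestDissimilarityMatrix:
    def test_rejects_invalid_constructions(self):
        good = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="square"):
            DissimilarityMatrix(("a", "b"), np.ones((2, 3)))
        with pytest.raises(ValueError, match="labels"):
            DissimilarityMatrix(("a",), good)
        with pytest.raises(ValueError, match="duplicate"):
            DissimilarityMatrix(("a", "a"), good)
        with pytest.raises(ValueError, match="asymmetric"):
            DissimilarityMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DissimilarityMatrix(("a", "b"), np.array([[0.5, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            DissimilarityMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_permuted_moves_items_with_labels(self, random_dissimilarity):
        D = random_dissimilarity(5, seed=3)
        perm = [2, 0, 4, 1, 3]
        P = D.permuted(perm)
        for i in range(5):
            for j in range(5):
                assert P.values[perm[i], perm[j]] == D.values[i, j]
            assert P.labels[perm[i]] == D.labels[i]


class TestFromRatings:
    def test_single_pair_mean(self):
        table = RatingTable.from_records(
            [("a", "b", 2.0, "r1"), ("a", "b", 4.0, "r2")]
        )
        D = from_ratings(table)
        assert D.values[0, 1] == D.values[1, 0] == 3.0
        assert D.values[0, 0] == 0.0
        assert not D.normalized

    def test_all_zero_ratings_give_zero_matrix(self):
        rows = [(a, b, 0.0, "r") for a, b in [("a", "b"), ("a", "c"), ("b", "c")]]
        D = from_ratings(RatingTable.from_records(rows))
        assert np.all(D.values == 0.0)

    def test_orderings_pool_into_unordered_pair(self):
        table = RatingTable.from_records(
            [("a", "b", 1.0, "r1"), ("b", "a", 5.0, "r2"), ("a", "b", 3.0, "r3")]
        )
        assert from_ratings(table).values[0, 1] == 3.0

    def test_matches_brute_force_mean_over_generated_panel(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.2, 1.0, (4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        base = normalize(DissimilarityMatrix(("a", "b", "c", "d"), vals))
        table = simulate_rater_panel(base, n_raters=3, rater_noise_sd=0.8, seed=5)
        D = from_ratings(table)
        # independent brute-force mean over the raw rows
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            la, lb = base.labels[i], base.labels[j]
            vals = [
                r
                for a, b, r, _ in table.data.itertuples(index=False)
                if {a, b} == {la, lb}
            ]
            assert D.values[i, j] == pytest.approx(sum(vals) / len(vals), abs=1e-12)

    def test_missing_pair_named_in_error(self):
        table = RatingTable.from_records(
            [("a", "b", 1.0, "r"), ("a", "c", 1.0, "r")]
        )
        with pytest.raises(ValueError, match=r"\(b, c\)"):
            from_ratings(table)

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValueError, match="outside scale"):
            RatingTable.from_records([("a", "b", 9.0, "r")], scale_max=7.0)
        table = RatingTable.from_records([("a", "b", 6.0, "r")], scale_max=7.0)
        with pytest.raises(ValueError, match="outside scale"):
            from_ratings(table, scale_max=5.0)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=15, deadline=None)
    def test_invariant_to_row_order_and_pair_orientation(self, pyrandom):
        rows = [
            ("a", "b", 1.0, "r1"), ("b", "c", 2.0, "r1"), ("a", "c", 3.0, "r1"),
            ("a", "b", 5.0, "r2"), ("c", "b", 4.0, "r2"), ("c", "a", 6.0, "r2"),
        ]
        baseline = from_ratings(RatingTable.from_records(rows))
        shuffled = [
            (b, a, r, who) if pyrandom.random() < 0.5 else (a, b, r, who)
            for a, b, r, who in rows
        ]
        pyrandom.shuffle(shuffled)
        assert np.array_equal(
            baseline.values, from_ratings(RatingTable.from_records(shuffled)).values
        )


class TestNormalize:
    def test_divides_by_max(self, random_dissimilarity):
        D = random_dissimilarity(5, seed=0, scale=7.0)
        N = normalize(D)
        assert N.normalized
        assert N.values.max() == pytest.approx(1.0)
        assert np.allclose(N.values, D.values / D.values.max())

    def test_idempotent(self, random_dissimilarity):
        N = normalize(random_dissimilarity(4, seed=1))
        assert np.array_equal(normalize(N).values, N.values)

    def test_three_item_example(self):
        values = np.array([[0, 2, 5], [2, 0, 0], [5, 0, 0]], dtype=float)
        N = normalize(DissimilarityMatrix(("a", "b", "c"), values))
        assert np.allclose(
            N.values, [[0, 0.4, 1.0], [0.4, 0, 0], [1.0, 0, 0]]
        )

    def test_zero_matrix_unchanged(self):
        Z = DissimilarityMatrix(("a", "b"), np.zeros((2, 2)))
        N = normalize(Z)
        assert N.normalized and np.all(N.values == 0)

    def test_preserves_rank_order(self, random_dissimilarity):
        D = random_dissimilarity(8, seed=4, scale=12.0)
        N = normalize(D)
        iu = np.triu_indices(8, k=1)
        rho = stats.spearmanr(D.values[iu], N.values[iu]).statistic
        assert rho == pytest.approx(1.0)


class TestMatrixCsv:
    def test_round_trip_preserves_labels_and_values(self, tmp_path, random_dissimilarity):
        D = random_dissimilarity(5, seed=9)
        path = tmp_path / "m.csv"
        write_matrix_csv(D, path)
        back = read_matrix_csv(path)
        assert back.labels == D.labels
        assert np.abs(back.values - D.values).max() < 1e-12

    def test_asymmetric_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n0,1.0\n0.5,0\n")
        with pytest.raises(ValueError, match="asymmetric"):
            read_matrix_csv(path)

    def test_duplicate_label_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("a,a\n0,1\n1,0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_matrix_csv(path)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "rect.csv"
        path.write_text("a,b\n0,1\n1,0\n0.5,0.5\n")
        with pytest.raises(ValueError, match="non-square"):
            read_matrix_csv(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "txt.csv"
        path.write_text("a,b\n0,x\nx,0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_matrix_csv(path)
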