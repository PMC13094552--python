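import numpy as np
import pytest
from scipy import stats

from suctionmorph.data_io import Character, CharacterMatrix
from suctionmorph.morphospace import (
    c1_group_test,
    c1_pair,
    phylomorphospace,
    standardized_pca,
)
from suctionmorph.phylo import parse_newick
from suctionmorph.synthetic import simulate_yule_tree


def matrix_from(arr, taxa=None) -> CharacterMatrix:
    arr = np.asarray(arr, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    chars = [Character(f"c{j}") for j in range(arr.shape[1])]
    return CharacterMatrix(taxa, chars, arr)


class TestStandardizedPCA:
    def test_perfectly_correlated_characters(self):
        m = matrix_from([[0, 0], [1, 1], [2, 2], [3, 3]])
        res = standardized_pca(m)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = matrix_from(rng.uniform(0, 3, size=(8, 5)))
            res = standardized_pca(m)
            assert res.variance_fraction.sum() == pytest.approx(1.0)
            assert (res.variance_fraction >= 0).all()

    def test_matches_eigen_oracle(self):
        """Scores and variance fractions against a direct correlation-
        matrix eigendecomposition on random 5x4 matrices."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.uniform(0, 3, size=(5, 4))
            m = matrix_from(X)
            res = standardized_pca(m)
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            C = Z.T @ Z / (Z.shape[0] - 1)
            w, v = np.linalg.eigh(C)
            w, v = w[::-1], v[:, ::-1]
            r = res.scores.shape[1]
            np.testing.assert_allclose(
                res.variance_fraction, (w / w.sum())[:r], atol=1e-8)
            for j in range(r):
                got = res.scores[:, j]
                want = Z @ v[:, j]
                # eigenvector sign is arbitrary in the oracle
                err = min(np.abs(got - want).max(), np.abs(got + want).max())
                assert err < 1e-8

    def test_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 3, size=(7, 4))
        res = standardized_pca(matrix_from(X))
        Z = (X - res.means) / res.sds
        np.testing.assert_allclose(res.scores @ res.loadings.T, Z, atol=1e-8)

    def test_scores_centered_and_orthogonal(self):
        rng = np.random.default_rng(3)
        res = standardized_pca(matrix_from(rng.uniform(0, 3, (9, 4))))
        np.testing.assert_allclose(res.scores.mean(0), 0, atol=1e-10)
        G = res.scores.T @ res.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_deterministic_sign(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 3, size=(6, 3))
        res = standardized_pca(matrix_from(X))
        for j in range(res.loadings.shape[1]):
            i = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[i, j] > 0

    def test_zero_variance_dropped_with_warning(self):
        X = np.array([[0, 1.0, 2], [0, 2, 1], [0, 0, 3], [0, 3, 0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = standardized_pca(matrix_from(X))
        assert res.dropped == ["c0"]
        assert len(res.characters) == 2

    def test_all_constant_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="constant"):
                standardized_pca(matrix_from(np.ones((4, 3))))

    def test_missing_values(self):
        X = np.array([[0, 1.0], [1, 2], [2, np.nan], [3, 0]])
        with pytest.raises(ValueError, match="missing"):
            standardized_pca(matrix_from(X))
        res = standardized_pca(matrix_from(X), impute_mean=True)
        assert np.isfinite(res.scores).all()


class TestPhylomorphospace:
    def test_single_point_collapses(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        m = matrix_from([[1.0, 2.0, 1.0], [1.0, 2.0, 1.0], [1.0, 2.0, 1.0]],
                        ["A", "B", "C"])
        res = standardized_pca(m) if False else None
        # identical rows have zero variance; place tips directly instead
        from suctionmorph.morphospace import MorphospaceResult
        scores = np.zeros((3, 2))
        fake = MorphospaceResult(["A", "B", "C"], scores, np.eye(2),
                                 np.array([0.5, 0.5]), [], np.zeros(2),
                                 np.ones(2), ["c0", "c1"])
        pm = phylomorphospace(t, fake)
        for coord in pm["nodes"].values():
            np.testing.assert_allclose(coord, 0.0)

    def test_two_tip_midpoint(self):
        t = parse_newick("(A:1,B:1);")
        from suctionmorph.morphospace import MorphospaceResult
        scores = np.array([[0.0, 0.0], [2.0, 4.0]])
        fake = MorphospaceResult(["A", "B"], scores, np.eye(2),
                                 np.array([0.5, 0.5]), [], np.zeros(2),
                                 np.ones(2), ["c0", "c1"])
        pm = phylomorphospace(t, fake)
        np.testing.assert_allclose(pm["nodes"][t.root], [1.0, 2.0])

    def test_matches_ancestral_states(self):
        t = simulate_yule_tree(10, 1.0, 1)
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 3, size=(10, 4))
        res = standardized_pca(matrix_from(X, list(t.tip_labels)))
        pm = phylomorphospace(t, res)
        anc = t.ancestral_states(res.scores[:, :2])
        for r in range(anc.shape[0]):
            np.testing.assert_allclose(pm["nodes"][t.n_tips + r], anc[r])


class TestC1Pair:
    @pytest.fixture
    def balanced(self):
        return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_hand_computed_value(self, balanced):
        """Tips (0,4,1,5): ancestors solve to E=13/6, F=17/6, root=2.5;
        for the pair (A, C): Dtip=1, Dmax=17/6, C1 = 11/17."""
        vals = {"A": 0.0, "B": 4.0, "C": 1.0, "D": 5.0}
        c1, dtip, dmax = c1_pair(balanced, vals, "A", "C")
        assert dtip == pytest.approx(1.0)
        assert dmax == pytest.approx(17 / 6)
        assert c1 == pytest.approx(11 / 17)

    def test_most_different_pair_scores_zero(self, balanced):
        vals = {"A": 0.0, "B": 4.0, "C": 1.0, "D": 5.0}
        c1, dtip, dmax = c1_pair(balanced, vals, "A", "D")
        assert dtip == dmax == pytest.approx(5.0)
        assert c1 == pytest.approx(0.0)

    def test_identical_tips_max_convergence(self, balanced):
        vals = {"A": 2.0, "B": 0.0, "C": 2.0, "D": 4.0}
        c1, dtip, _ = c1_pair(balanced, vals, "A", "C")
        assert dtip == 0.0
        assert c1 == pytest.approx(1.0)

    def test_no_divergence_warns(self, balanced):
        vals = {t: 1.0 for t in "ABCD"}
        with pytest.warns(UserWarning, match="Dmax"):
            c1, _, dmax = c1_pair(balanced, vals, "A", "C")
        assert c1 == 0.0 and dmax == 0.0

    def test_same_tip_error(self, balanced):
        with pytest.raises(ValueError, match="distinct"):
            c1_pair(balanced, {t: 1.0 for t in "ABCD"}, "A", "A")

    def test_rotation_invariance(self):
        t = simulate_yule_tree(12, 1.0, 7)
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(12, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a, b = t.tip_labels[0], t.tip_labels[5]
        base = c1_pair(t, Y, a, b)
        rot = c1_pair(t, Y @ Q.T, a, b)
        np.testing.assert_allclose(base, rot, atol=1e-10)

    def test_ancestors_only_variant(self, balanced):
        """Excluding the tips from the Dmax candidates can only shrink
        Dmax, never increase it."""
        vals = {"A": 0.0, "B": 4.0, "C": 1.0, "D": 5.0}
        _, _, dmax_full = c1_pair(balanced, vals, "A", "C")
        _, _, dmax_anc = c1_pair(balanced, vals, "A", "C",
                                 ancestors_only=True)
        assert dmax_anc <= dmax_full


class TestC1GroupTest:
    def test_planted_convergence_detected(self):
        t = simulate_yule_tree(24, 1.0, 9)
        rng = np.random.default_rng(10)
        Y = t.simulate_bm(np.eye(2), 0.0, 1, seed=11)[0] + \
            rng.normal(scale=0.01, size=(24, 2))
        focal = [t.tip_labels[i] for i in (0, 8, 16)]
        for f in focal:  # force identical phenotypes
            Y[t.tip_index(f)] = [5.0, 5.0]
        res = c1_group_test(t, Y, focal, n_sim=199, seed=12)
        assert res.mean_c1 > 0.9
        assert res.p <= 2 / 200

    def test_seed_determinism(self, default_dataset):
        ds = default_dataset
        from suctionmorph.morphospace import standardized_pca
        pca = standardized_pca(ds.skull_matrix)
        focal = ds.truth["specialist_tips"][:6]
        a = c1_group_test(ds.tree, pca.scores, focal, n_sim=99, seed=3)
        b = c1_group_test(ds.tree, pca.scores, focal, n_sim=99, seed=3)
        assert a.p == b.p and a.mean_c1 == b.mean_c1

    def test_low_n_sim_warns(self):
        t = simulate_yule_tree(8, 1.0, 13)
        Y = t.simulate_bm(np.eye(2), 0.0, 1, seed=14)[0]
        with pytest.warns(UserWarning, match="resolution"):
            c1_group_test(t, Y, list(t.tip_labels[:2]), n_sim=50, seed=0)

    def test_pair_count(self):
        t = simulate_yule_tree(10, 1.0, 15)
        Y = t.simulate_bm(np.eye(2), 0.0, 1, seed=16)[0]
        res = c1_group_test(t, Y, list(t.tip_labels[:4]), n_sim=100, seed=0)
        assert len(res.pairs) == 6
        assert res.c1.shape == (6,)
        assert res.mean_c1 == pytest.approx(res.c1.mean())
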