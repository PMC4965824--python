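import io as _stringio
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from biofacies.io import ValidationError
from biofacies.simulate import simulate_tree
from biofacies.turnover import (
    DEGENERATE,
    HOMOGENEOUS_SELECTION,
    NOT_DISTINGUISHED,
    VARIABLE_SELECTION,
    BntiResult,
    beta_mntd,
    bnti,
    classify_selection,
    cophenetic,
    taxa_shuffle_null,
)


from tests.oracles import beta_mntd_loops, path_distance, rel_abund_two_cherries

# --- cophenetic -------------------------------------------------------------

class TestCophenetic:
    def test_hand_values(self, three_tip_tree):
        dm = cophenetic(three_tip_tree)
        assert dm["A", "B"] == 2.0
        assert dm["A", "C"] == 4.0

    def test_star_tree(self):
        star = TreeNode.read(_stringio.StringIO("(A:3,B:3,C:3,D:3);"))
        dm = cophenetic(star)
        off = dm.data[np.triu_indices(4, 1)]
        np.testing.assert_allclose(off, 6.0)

    def test_matches_recursive_path_sums_on_random_trees(self):
        for seed in range(20):
            tree = simulate_tree(6, seed=seed)
            dm = cophenetic(tree)
            for a, b in itertools.combinations(dm.ids, 2):
                assert dm[a, b] == pytest.approx(path_distance(tree, a, b), rel=1e-12)


# --- betaMNTD ---------------------------------------------------------------

class TestBetaMntd:
    def test_identical_communities_zero(self, four_tip_tree):
        dm = cophenetic(four_tip_tree)
        f = np.array([0.25, 0.25, 0.25, 0.25])
        assert beta_mntd(f, f, dm.data) == pytest.approx(0.0)

    def test_single_taxon_pair(self, three_tip_tree):
        dm = cophenetic(three_tip_tree)
        order = list(dm.ids)
        f1 = np.array([1.0 if t == "A" else 0.0 for t in order])
        f2 = np.array([1.0 if t == "C" else 0.0 for t in order])
        assert beta_mntd(f1, f2, dm.data) == pytest.approx(4.0)  # d(A, C)

    def test_two_cherries(self, four_tip_tree):
        dm = cophenetic(four_tip_tree)
        order = list(dm.ids)
        f1 = np.array([0.5 if t in ("A", "B") else 0.0 for t in order])
        f2 = np.array([0.5 if t in ("C", "D") else 0.0 for t in order])
        assert beta_mntd(f1, f2, dm.data) == pytest.approx(4.0)

    def test_empty_community_rejected(self, four_tip_tree):
        dm = cophenetic(four_tip_tree)
        with pytest.raises(ValidationError):
            beta_mntd(np.zeros(4), np.ones(4) / 4, dm.data)

    def test_matches_loop_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            tree = simulate_tree(8, seed=seed)
            dm = cophenetic(tree)
            taxa = list(dm.ids)
            dist = {a: {b: dm[a, b] for b in taxa} for a in taxa}
            f1 = rng.dirichlet(np.ones(8)) * (rng.random(8) > 0.3)
            f2 = rng.dirichlet(np.ones(8)) * (rng.random(8) > 0.3)
            if f1.sum() == 0 or f2.sum() == 0:
                continue
            assert beta_mntd(f1, f2, dm.data) == pytest.approx(
                beta_mntd_loops(f1, f2, taxa, dist), rel=1e-12
            )

    def test_invariant_to_jointly_absent_taxa(self, four_tip_tree):
        dm = cophenetic(four_tip_tree)
        order = list(dm.ids)
        keep = [i for i, t in enumerate(order) if t != "D"]
        f1 = np.array([0.5, 0.5, 0.0, 0.0])
        f2 = np.array([0.0, 0.4, 0.6, 0.0])
        full = beta_mntd(f1, f2, dm.data)
        reduced = beta_mntd(f1[keep], f2[keep], dm.data[np.ix_(keep, keep)])
        assert full == pytest.approx(reduced)


# --- null model and betaNTI -------------------------------------------------

class TestNullModel:
    def test_star_tree_null_degenerate(self):
        star = TreeNode.read(_stringio.StringIO("(A:3,B:3,C:3,D:3);"))
        rel = rel_abund_two_cherries(star)
        result = bnti(rel, star, n_null=19, seed=1)
        assert result.degenerate.loc["s1", "s2"]
        assert math.isnan(result.bnti.loc["s1", "s2"])

    def test_exhaustive_matches_sampled_moments(self, four_tip_tree):
        rel = rel_abund_two_cherries(four_tip_tree)
        dm = cophenetic(four_tip_tree)
        F = rel.to_numpy()
        exact = taxa_shuffle_null(F, dm.data, exhaustive=True)
        sampled = taxa_shuffle_null(F, dm.data, n_null=9999, seed=3)
        np.testing.assert_allclose(
            exact[:, 0, 1].mean(), sampled[:, 0, 1].mean(), atol=0.03
        )
        np.testing.assert_allclose(
            exact[:, 0, 1].std(), sampled[:, 0, 1].std(), atol=0.03
        )

    def test_fixed_seed_identical_stream(self, four_tip_tree):
        rel = rel_abund_two_cherries(four_tip_tree)
        dm = cophenetic(four_tip_tree)
        a = taxa_shuffle_null(rel.to_numpy(), dm.data, n_null=50, seed=9)
        b = taxa_shuffle_null(rel.to_numpy(), dm.data, n_null=50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_small_pool_rejected(self, four_tip_tree):
        dm = cophenetic(four_tip_tree)
        with pytest.raises(ValidationError):
            taxa_shuffle_null(np.ones((1, 2)), dm.data[:1, :1], n_null=9)


class TestBnti:
    def test_identical_communities_nonpositive(self, four_tip_tree):
        """Identical communities have betaMNTD 0, never above the null.

        Every tip shuffle maps the shared support onto a common pair of
        tips, so the null collapses to 0 as well: the pair is flagged
        degenerate rather than scored (betaNTI would be 0/0)."""
        dm_order = list(cophenetic(four_tip_tree).ids)
        rel = pd.DataFrame(
            {"s1": [0.7, 0.3, 0.0, 0.0], "s2": [0.7, 0.3, 0.0, 0.0],
             "s3": [0.0, 0.3, 0.7, 0.0]},
            index=dm_order,
        )
        result = bnti(rel, four_tip_tree, n_null=99, seed=2)
        assert result.beta_mntd_obs.loc["s1", "s2"] == pytest.approx(0.0)
        assert result.beta_mntd_obs.loc["s1", "s2"] <= result.null_mean.loc["s1", "s2"]
        assert result.degenerate.loc["s1", "s2"]
        # non-identical pair on the same tree is scored normally
        assert np.isfinite(result.bnti.loc["s1", "s3"])

    def test_exhaustive_oracle_exact(self, four_tip_tree):
        """Full 24-permutation enumeration, recomputed with naive loops,
        reproduces the package betaNTI to 1e-12."""
        rel = rel_abund_two_cherries(four_tip_tree)
        dm = cophenetic(four_tip_tree)
        taxa = list(dm.ids)
        result = bnti(rel, four_tip_tree, exhaustive=True, seed=0)
        dist = {a: {b: dm[a, b] for b in taxa} for a in taxa}
        f1 = rel["s1"].to_numpy()
        f2 = rel["s2"].to_numpy()
        obs = beta_mntd_loops(f1, f2, taxa, dist)
        nulls = []
        for perm in itertools.permutations(taxa):
            relabel = {t: p for t, p in zip(taxa, perm)}
            d_perm = {
                a: {b: dist[relabel[a]][relabel[b]] for b in taxa} for a in taxa
            }
            nulls.append(beta_mntd_loops(f1, f2, taxa, d_perm))
        nulls = np.array(nulls)
        expected = (obs - nulls.mean()) / nulls.std(ddof=1)
        assert result.bnti.loc["s1", "s2"] == pytest.approx(expected, abs=1e-12)
        assert result.n_null == math.factorial(4)

    def test_symmetric_and_sample_order_invariant(self, four_tip_tree):
        rel = rel_abund_two_cherries(four_tip_tree)
        res = bnti(rel, four_tip_tree, n_null=99, seed=4)
        pd.testing.assert_frame_equal(res.bnti, res.bnti.T)
        shuffled = rel[["s3", "s1", "s2"]]
        res2 = bnti(shuffled, four_tip_tree, n_null=99, seed=4)
        assert res2.bnti.loc["s1", "s2"] == pytest.approx(res.bnti.loc["s1", "s2"])

    def test_taxa_not_in_tree_rejected(self, four_tip_tree):
        rel = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["ZZZ"])
        with pytest.raises(ValidationError):
            bnti(rel, four_tip_tree, n_null=9, seed=1)


class TestClassifySelection:
    def _result_with(self, z):
        ids = ("s1", "s2")
        frame = pd.DataFrame([[0.0, z], [z, 0.0]], index=list(ids), columns=list(ids))
        false = pd.DataFrame(False, index=list(ids), columns=list(ids))
        return BntiResult(ids, frame, frame, frame, frame, false, 99)

    @pytest.mark.parametrize(
        "z,label",
        [
            (2.5, VARIABLE_SELECTION),
            (-2.5, HOMOGENEOUS_SELECTION),
            (0.3, NOT_DISTINGUISHED),
        ],
    )
    def test_threshold_labels(self, z, label):
        labels = classify_selection(self._result_with(z))
        assert labels.loc["s1", "s2"] == label

    def test_degenerate_label(self):
        result = self._result_with(float("nan"))
        result.degenerate.loc["s1", "s2"] = True
        result.degenerate.loc["s2", "s1"] = True
        labels = classify_selection(result)
        assert labels.loc["s1", "s2"] == DEGENERATE
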