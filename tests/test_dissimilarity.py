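import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from biofacies.dissimilarity import (
    bray_curtis,
    env_delta_matrix,
    forward_select_distance,
    mantel,
    nmds,
    partial_correlation,
    partial_mantel,
)
from biofacies.io import SampleMetadata, ValidationError


def random_dm(n, rng, ids=None):
    x = rng.random((n, 3))
    return DistanceMatrix(squareform(pdist(x)),
                          ids=ids or [f"s{i}" for i in range(n)])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        rel = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]}, index=["A", "B"])
        assert bray_curtis(rel)["s1", "s2"] == 0.0

    def test_disjoint_samples_one(self):
        rel = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, index=["A", "B"])
        assert bray_curtis(rel)["s1", "s2"] == pytest.approx(1.0)

    def test_hand_value(self):
        rel = pd.DataFrame({"s1": [0.75, 0.25], "s2": [0.25, 0.75]}, index=["A", "B"])
        assert bray_curtis(rel)["s1", "s2"] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        rel = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 0.0]}, index=["A", "B"])
        with pytest.raises(ValidationError):
            bray_curtis(rel)

    def test_range_and_symmetry(self, small_dataset):
        from biofacies.community import rarefy, relative_abundance

        rel = relative_abundance(rarefy(small_dataset.otu_table, seed=1))
        bc = bray_curtis(rel)
        assert bc.data.min() >= 0 and bc.data.max() <= 1


class TestEnvDelta:
    def _meta(self, values):
        frame = pd.DataFrame(
            {
                "well_id": "W1",
                "facies": "oxidized",
                "elevation_m": 98.0,
                "rel_elevation_m": 0.5,
                "pH": values,
            },
            index=[f"s{i}" for i in range(len(values))],
        )
        return SampleMetadata(frame)

    def test_constant_variable_zero_matrix(self):
        dm = env_delta_matrix(self._meta([7.0, 7.0, 7.0]), "pH")
        assert (dm.data == 0).all()

    def test_hand_deltas(self):
        dm = env_delta_matrix(self._meta([1.0, 4.0, 6.0]), "pH")
        assert dm["s0", "s1"] == 3.0
        assert dm["s0", "s2"] == 5.0
        assert dm["s1", "s2"] == 2.0

    def test_translation_invariance(self):
        a = env_delta_matrix(self._meta([1.0, 4.0, 6.0]), "pH")
        b = env_delta_matrix(self._meta([101.0, 104.0, 106.0]), "pH")
        np.testing.assert_allclose(a.data, b.data)

    def test_missing_values_rejected(self):
        meta = self._meta([1.0, np.nan, 6.0])
        with pytest.raises(ValidationError, match="s1"):
            env_delta_matrix(meta, "pH")


class TestMantel:
    def test_self_correlation_is_one(self):
        dm = random_dm(6, np.random.default_rng(1))
        res = mantel(dm, dm, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        """n = 4: package p equals a brute-force enumeration over all 24
        relabelings computed independently here."""
        rng = np.random.default_rng(2)
        d1 = random_dm(4, rng)
        d2 = random_dm(4, rng)
        res = mantel(d1, d2, exhaustive=True)
        iu = np.triu_indices(4, 1)
        x = d1.data[iu]
        r_obs = pearsonr(x, d2.data[iu]).statistic
        count = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            y = d2.data[np.ix_(perm, perm)][iu]
            if pearsonr(x, y).statistic >= r_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / len(perms))

    def test_statistic_matches_reference_implementation(self):
        rng = np.random.default_rng(3)
        d1 = random_dm(12, rng)
        d2 = random_dm(12, rng)
        res = mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert res.statistic == pytest.approx(r_ref, abs=1e-12)

    def test_independent_matrices_weak_correlation(self):
        """|r| between independent random matrices stays small (n = 30)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d1 = random_dm(30, rng)
            d2 = random_dm(30, rng)
            if abs(mantel(d1, d2, n_perm=1, seed=0).statistic) < 0.3:
                hits += 1
        assert hits >= 95

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        d1 = random_dm(8, rng)
        d2 = random_dm(8, rng)
        scaled = DistanceMatrix(d2.data * 3.7, ids=list(d2.ids))
        a = mantel(d1, d2, n_perm=49, seed=5)
        b = mantel(d1, scaled, n_perm=49, seed=5)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == b.p_value

    def test_p_never_zero(self):
        dm = random_dm(8, np.random.default_rng(6))
        res = mantel(dm, dm, n_perm=99, seed=1)
        assert res.p_value >= 1 / 100

    def test_too_few_samples_rejected(self):
        dm = random_dm(3, np.random.default_rng(1))
        with pytest.raises(ValidationError):
            mantel(dm, dm, n_perm=9, seed=1)

    def test_zero_variance_rejected(self):
        flat = DistanceMatrix(1 - np.eye(5), ids=list("abcde"))
        other = random_dm(5, np.random.default_rng(1), ids=list("abcde"))
        with pytest.raises(ValidationError):
            mantel(flat, other, n_perm=9, seed=1)


class TestPartialMantel:
    def test_formula_matches_residual_correlation(self):
        """Closed-form first-order partial correlation equals the
        correlation of the two residual vectors on one fixed instance."""
        rng = np.random.default_rng(7)
        d1, d2, dc = (random_dm(6, rng) for _ in range(3))
        iu = np.triu_indices(6, 1)
        x, y, c = d1.data[iu], d2.data[iu], dc.data[iu]
        res = partial_mantel(d1, d2, dc, n_perm=9, seed=1)

        def residuals(v, on):
            A = np.column_stack([np.ones(len(on)), on])
            return v - A @ np.linalg.lstsq(A, v, rcond=None)[0]

        expected = pearsonr(residuals(x, c), residuals(y, c)).statistic
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_uncorrelated_conditioning_changes_little(self):
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(20):
            base = rng.random((50, 2))
            d1 = DistanceMatrix(squareform(pdist(base)))
            d2 = DistanceMatrix(squareform(pdist(base + rng.normal(0, 0.1, base.shape))))
            dc = DistanceMatrix(squareform(pdist(rng.random((50, 2)))))
            plain = mantel(d1, d2, n_perm=1, seed=0).statistic
            partial = partial_mantel(d1, d2, dc, n_perm=1, seed=0).statistic
            diffs.append(abs(plain - partial))
        assert np.mean(diffs) < 0.05

    def test_conditioning_on_common_driver_drives_partial_to_zero(self):
        """When two matrices are linked only through a shared driver,
        conditioning on the driver removes the association."""
        rng = np.random.default_rng(9)
        base = rng.random((40, 2))
        dc = DistanceMatrix(squareform(pdist(base)))  # the clean driver
        d1 = DistanceMatrix(squareform(pdist(base + rng.normal(0, 0.05, base.shape))))
        d2 = DistanceMatrix(squareform(pdist(base + rng.normal(0, 0.05, base.shape))))
        # conditioning identical to d2 is rejected (undefined partial)
        with pytest.raises(ValidationError):
            partial_mantel(d1, d2, d2, n_perm=9, seed=1)
        plain = mantel(d1, d2, n_perm=1, seed=0).statistic
        res = partial_mantel(d1, d2, dc, n_perm=9, seed=1)
        assert plain > 0.5
        assert abs(res.statistic) < 0.15

    def test_perfectly_correlated_conditioning_rejected(self):
        with pytest.raises(ValidationError):
            partial_correlation(0.5, 1.0, 0.3)


class TestForwardSelect:
    def test_exact_copy_selected_first(self):
        rng = np.random.default_rng(10)
        driver = random_dm(10, rng)
        noise = {f"n{i}": random_dm(10, rng) for i in range(3)}
        result = forward_select_distance(
            driver, {"driver": driver, **noise}, n_perm=99, seed=1
        )
        assert result.selected[0] == "driver"
        assert result.steps[0][1] == pytest.approx(1.0)

    def test_true_driver_recovered(self):
        """One candidate generating the response among 5 noise candidates
        is picked first in nearly all seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            ids = [f"s{i}" for i in range(20)]
            base = rng.random((20, 2))
            response = DistanceMatrix(
                squareform(pdist(base + rng.normal(0, 0.15, base.shape))), ids=ids
            )
            cands = {"driver": DistanceMatrix(squareform(pdist(base)), ids=ids)}
            for i in range(5):
                cands[f"noise{i}"] = random_dm(20, rng)
            result = forward_select_distance(response, cands, n_perm=99, seed=seed)
            hits += bool(result.selected) and result.selected[0] == "driver"
        assert hits >= 45

    def test_pure_noise_usually_empty(self):
        """With 5 independent noise candidates the best-of-five Mantel
        test at alpha = 0.05 stays non-significant in most runs (the
        expected empty rate is roughly 0.95^5 ~ 0.77)."""
        empty = 0
        for seed in range(50):
            rng = np.random.default_rng(2000 + seed)
            response = random_dm(20, rng)
            cands = {f"n{i}": random_dm(20, rng) for i in range(5)}
            result = forward_select_distance(response, cands, n_perm=199, seed=seed)
            empty += not result.selected
            if not result.selected:
                assert result.rejected is not None
        assert empty >= 30

    def test_no_candidates_rejected(self):
        dm = random_dm(5, np.random.default_rng(1))
        with pytest.raises(ValidationError):
            forward_select_distance(dm, {}, n_perm=9, seed=1)


class TestNmds:
    def test_embeddable_configuration_low_stress(self):
        rng = np.random.default_rng(11)
        points = rng.normal(size=(15, 2))
        dm = DistanceMatrix(squareform(pdist(points)))
        result = nmds(dm, n_dims=2, n_starts=8, seed=1)
        assert result.stress < 0.01

    def test_duplicate_sample_coincident(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(10, 2))
        points[1] = points[0]
        dm = DistanceMatrix(squareform(pdist(points)))
        result = nmds(dm, n_dims=2, n_starts=4, seed=2)
        coords = result.coordinates.to_numpy()
        gap = np.linalg.norm(coords[0] - coords[1])
        span = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
        assert gap < 0.02 * span

    def test_deterministic(self):
        dm = random_dm(12, np.random.default_rng(13))
        a = nmds(dm, seed=3)
        b = nmds(dm, seed=3)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_dimension_bound(self):
        dm = random_dm(4, np.random.default_rng(14))
        with pytest.raises(ValidationError):
            nmds(dm, n_dims=3)
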