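import numpy as np
import pytest
from scipy.stats import norm, ortho_group

from kompot import (
    compare_expression,
    fit_expression_gp,
    fold_change,
    impute_expression,
    local_expression_ptp,
    mahalanobis_distance,
    rank_genes,
)

PHI_MINUS_1 = norm.cdf(-1.0)


def _fit_pair(dataset, n_landmarks=100, seed=0):
    ma = dataset.condition == "A"
    mb = dataset.condition == "B"
    pa = fit_expression_gp(
        dataset.coords[ma], dataset.expression[ma], condition="A",
        gene_ids=dataset.gene_ids, n_landmarks=n_landmarks, seed=seed,
    )
    pb = fit_expression_gp(
        dataset.coords[mb], dataset.expression[mb], condition="B",
        gene_ids=dataset.gene_ids, n_landmarks=n_landmarks, seed=seed,
    )
    return pa, pb


class TestFoldChange:
    def test_identical_predictors_zero(self, planted_dataset):
        pa, _ = _fit_pair(planted_dataset)
        lfc = fold_change(pa, pa, planted_dataset.coords[:50])
        np.testing.assert_array_equal(lfc, 0.0)

    def test_antisymmetry(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        states = planted_dataset.coords[:100]
        np.testing.assert_allclose(
            fold_change(pa, pb, states), -fold_change(pb, pa, states), atol=1e-12
        )

    def test_planted_half_shift(self, planted_dataset):
        # genes 0-4 carry a global +1 shift in condition B
        pa, pb = _fit_pair(planted_dataset)
        lfc = fold_change(pa, pb, planted_dataset.coords)
        mean_shift = lfc[:, :5].mean()
        assert 0.8 <= mean_shift <= 1.2
        null_shift = np.abs(lfc[:, 10:].mean(axis=0)).max()
        assert null_shift < 0.2

    def test_gene_list_mismatch(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        pb.gene_ids = np.array([f"other_{i}" for i in range(len(pb.gene_ids))], dtype=object)
        with pytest.raises(ValueError, match="symmetric difference"):
            fold_change(pa, pb, planted_dataset.coords[:10])


class TestMahalanobisDistance:
    def test_euclidean_special_case(self):
        D = mahalanobis_distance(np.array([3.0, 4.0]), np.zeros(2), np.eye(2))
        assert D == pytest.approx(5.0, abs=1e-12)

    def test_identical_means_zero(self, rng):
        mu = rng.standard_normal((10, 4))
        S = np.eye(10)
        np.testing.assert_allclose(mahalanobis_distance(mu, mu, S), 0.0, atol=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 21)
            A = rng.standard_normal((k, k))
            S = A @ A.T + k * np.eye(k)
            v = rng.standard_normal((k, 3))
            D = mahalanobis_distance(v, np.zeros_like(v), S)
            oracle = np.sqrt(np.einsum("ij,ij->j", v, np.linalg.inv(S) @ v))
            np.testing.assert_allclose(D, oracle, rtol=1e-8)

    def test_orthogonal_invariance(self):
        rng = np.random.default_rng(1)
        k = 8
        A = rng.standard_normal((k, k))
        S = A @ A.T + k * np.eye(k)
        v = rng.standard_normal(k)
        Q = ortho_group.rvs(k, random_state=2)
        D1 = mahalanobis_distance(v, np.zeros(k), S)
        D2 = mahalanobis_distance(Q @ v, np.zeros(k), Q @ S @ Q.T)
        assert D1 == pytest.approx(D2, rel=1e-8)

    def test_k1_reduces_to_z_score(self):
        # for one landmark, D is |mu_a - mu_b| / sqrt(s_a^2 + s_b^2)
        D = mahalanobis_distance(
            np.array([2.0]), np.array([0.5]), np.array([[0.25 + 0.75]])
        )
        assert D == pytest.approx(1.5 / 1.0, rel=1e-12)

    def test_non_symmetric_rejected(self):
        S = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mahalanobis_distance(np.ones(2), np.zeros(2), S)

    def test_jitter_on_near_singular(self):
        S = np.ones((3, 3))  # rank one
        D = mahalanobis_distance(np.ones(3), np.zeros(3), S)
        assert np.isfinite(D) and D >= 0


class TestLocalExpressionPtp:
    def test_zero_lfc(self):
        assert local_expression_ptp(np.zeros(1), np.ones(1), np.ones(1))[0] == 0.5

    def test_unit_z(self):
        p = local_expression_ptp(np.array([1.0]), np.ones(1), np.zeros(1))
        assert p[0] == pytest.approx(PHI_MINUS_1, abs=1e-9)

    def test_antisymmetry_invariance(self, rng):
        lfc = rng.standard_normal((20, 5))
        sd = rng.uniform(0.1, 1.0, 20)
        np.testing.assert_array_equal(
            local_expression_ptp(lfc, sd, sd), local_expression_ptp(-lfc, sd, sd)
        )


class TestCompareExpression:
    def test_planted_genes_outrank_null(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        comp = compare_expression(pa, pb, planted_dataset.coords, n_landmarks=30, seed=0)
        D = comp.mahalanobis
        assert D[:10].min() > D[10:].max()

    def test_opposing_gene_low_lfc_high_d(self, planted_dataset):
        # genes 5-9: +1 on component 0, -1 on component 1, balanced
        pa, pb = _fit_pair(planted_dataset)
        comp = compare_expression(pa, pb, planted_dataset.coords, n_landmarks=30, seed=0)
        assert np.all(np.abs(comp.mean_lfc[5:10]) < 0.15)
        assert comp.mahalanobis[5:10].min() > comp.mahalanobis[10:].max()
        assert set(comp.category[5:10]) == {"divergent"}

    def test_near_duplicate_landmark_barely_changes_d(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        comp = compare_expression(pa, pb, planted_dataset.coords, n_landmarks=30, seed=0)
        lm = comp.landmarks
        lm_aug = np.vstack([lm, lm[0] + 1e-6])
        mu_a = impute_expression(pa, lm_aug)
        mu_b = impute_expression(pb, lm_aug)
        cov = pa.posterior_cov(lm_aug) + pb.posterior_cov(lm_aug)
        D_aug = mahalanobis_distance(mu_a, mu_b, cov)
        rel = np.abs(D_aug - comp.mahalanobis) / comp.mahalanobis
        assert rel.max() < 0.01

    def test_subset_mask(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        mask = planted_dataset.component == 0
        comp = compare_expression(
            pa, pb, planted_dataset.coords, cell_mask=mask, n_landmarks=20, seed=0,
            group="component0",
        )
        assert comp.lfc.shape[0] == int(mask.sum())
        # genes 5-9 are +1 on component 0 only: subset lfc should be near +1
        assert comp.mean_lfc[5:10].mean() == pytest.approx(1.0, abs=0.25)

    def test_empty_subset_rejected(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        with pytest.raises(ValueError, match="empty"):
            compare_expression(
                pa, pb, planted_dataset.coords,
                cell_mask=np.zeros(planted_dataset.n_cells, dtype=bool),
            )

    def test_subset_smaller_than_k_warns(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        mask = np.zeros(planted_dataset.n_cells, dtype=bool)
        mask[:10] = True
        with pytest.warns(UserWarning, match="reducing k"):
            comp = compare_expression(
                pa, pb, planted_dataset.coords, cell_mask=mask, n_landmarks=30, seed=0
            )
        assert comp.landmarks.shape[0] == 10

    def test_swap_conditions(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        fwd = compare_expression(pa, pb, planted_dataset.coords, n_landmarks=25, seed=1)
        bwd = compare_expression(pb, pa, planted_dataset.coords, n_landmarks=25, seed=1)
        np.testing.assert_allclose(fwd.mean_lfc, -bwd.mean_lfc, atol=1e-10)
        np.testing.assert_allclose(fwd.mahalanobis, bwd.mahalanobis, rtol=1e-8)


class TestRankGenes:
    def _null_comparison(self, planted_dataset):
        pa, pb = _fit_pair(planted_dataset)
        comp = compare_expression(pa, pb, planted_dataset.coords, n_landmarks=30, seed=0)
        return comp

    def test_planted_up_genes_listed(self, planted_dataset):
        comp = self._null_comparison(planted_dataset)
        up = rank_genes(comp, "up")
        assert set(up["gene_id"]) == set(comp.gene_ids[:5])

    def test_all_null_gives_empty_tables(self):
        from kompot import make_mixture_manifold, plant_expression

        ds = plant_expression(
            make_mixture_manifold(n_per_condition=(400, 400), seed=21),
            n_genes=20, effect_spec=None, noise_sd=0.2, seed=22,
        )
        ma, mb = ds.condition == "A", ds.condition == "B"
        pa = fit_expression_gp(ds.coords[ma], ds.expression[ma], gene_ids=ds.gene_ids,
                               n_landmarks=60, seed=0)
        pb = fit_expression_gp(ds.coords[mb], ds.expression[mb], gene_ids=ds.gene_ids,
                               n_landmarks=60, seed=0)
        comp = compare_expression(pa, pb, ds.coords, n_landmarks=25, seed=0)
        assert len(rank_genes(comp, "up")) == 0
        assert len(rank_genes(comp, "down")) == 0

    def test_permutation_invariance(self, planted_dataset):
        comp = self._null_comparison(planted_dataset)
        ranked = rank_genes(comp, "up")
        perm = np.random.default_rng(0).permutation(len(comp.gene_ids))
        import copy

        comp2 = copy.deepcopy(comp)
        comp2.gene_ids = comp.gene_ids[perm]
        comp2.mean_lfc = comp.mean_lfc[perm]
        comp2.mahalanobis = comp.mahalanobis[perm]
        ranked2 = rank_genes(comp2, "up")
        np.testing.assert_array_equal(
            ranked["gene_id"].to_numpy(), ranked2["gene_id"].to_numpy()
        )

    def test_unknown_mode(self, planted_dataset):
        comp = self._null_comparison(planted_dataset)
        with pytest.raises(ValueError, match="mode"):
            rank_genes(comp, "sideways")
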