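import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import norm

from kompot import (
    AbundanceComparison,
    classify_significance,
    log_fold_change,
    normalize_log_density,
    posterior_tail_probability,
    summarize_by_group,
)

PHI_MINUS_1 = norm.cdf(-1.0)  # 0.15865525...


class TestNormalize:
    def test_log_one(self):
        assert normalize_log_density(np.array([0.0]), 1)[0] == 0.0

    def test_algebra(self):
        # N = e^2 treated as a real-valued test input
        out = np.asarray([5.0]) - np.log(np.e**2)
        np.testing.assert_allclose(
            normalize_log_density(np.array([5.0]), int(np.e**2))[0],
            5.0 - np.log(int(np.e**2)),
        )
        np.testing.assert_allclose(out, 3.0)

    def test_dataset_duplication_cancels(self, rng):
        mu = rng.standard_normal(50)
        n = 123
        doubled = normalize_log_density(mu + np.log(2), 2 * n)
        np.testing.assert_allclose(doubled, normalize_log_density(mu, n), atol=1e-12)

    def test_nonpositive_count(self):
        with pytest.raises(ValueError):
            normalize_log_density(np.zeros(3), 0)


class TestLogFoldChange:
    def test_identity(self):
        mu = np.linspace(-2, 2, 9)
        np.testing.assert_array_equal(log_fold_change(mu, mu, 100, 100), np.zeros(9))

    def test_pure_size_correction(self):
        mu = np.zeros(5)
        delta = log_fold_change(mu, mu, 200, 100)
        np.testing.assert_allclose(delta, -np.log(2), atol=1e-12)

    @given(
        mu_a=arrays(np.float64, 10, elements=st.floats(-5, 5)),
        mu_b=arrays(np.float64, 10, elements=st.floats(-5, 5)),
        n_a=st.integers(1, 10_000),
        n_b=st.integers(1, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, mu_a, mu_b, n_a, n_b):
        fwd = log_fold_change(mu_a, mu_b, n_a, n_b)
        bwd = log_fold_change(mu_b, mu_a, n_b, n_a)
        np.testing.assert_allclose(fwd + bwd, 0.0, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            log_fold_change(np.zeros(3), np.zeros(4), 1, 1)


class TestPosteriorTailProbability:
    def test_zero_delta_is_half(self):
        assert posterior_tail_probability(np.array([0.0]), np.ones(1), np.ones(1))[0] == 0.5

    def test_phi_minus_one(self):
        ptp = posterior_tail_probability(np.array([1.0]), np.ones(1), np.zeros(1))
        assert ptp[0] == pytest.approx(PHI_MINUS_1, abs=1e-9)

    def test_same_z_score(self):
        s = np.array([np.sqrt(2.0)])
        ptp = posterior_tail_probability(np.array([2.0]), s, s)
        assert ptp[0] == pytest.approx(PHI_MINUS_1, abs=1e-9)

    def test_zero_sd_cases(self):
        z = np.zeros(2)
        ptp = posterior_tail_probability(np.array([1.0, 0.0]), z, z)
        assert ptp[0] == 0.0
        assert ptp[1] == 0.5

    def test_monotone_in_abs_delta(self):
        deltas = np.linspace(0, 5, 20)
        ptp = posterior_tail_probability(deltas, np.ones(20), np.ones(20))
        assert np.all(np.diff(ptp) < 0)

    def test_monotone_in_sd(self):
        sds = np.linspace(0.1, 5, 20)
        ptp = posterior_tail_probability(np.ones(20), sds, np.zeros(20))
        assert np.all(np.diff(ptp) > 0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            posterior_tail_probability(np.zeros(1), np.array([-1.0]), np.zeros(1))

    @given(
        delta=arrays(np.float64, 8, elements=st.floats(-10, 10)),
        sd=arrays(np.float64, 8, elements=st.floats(0.01, 10)),
    )
    @settings(max_examples=50, deadline=None)
    def test_range_and_symmetry(self, delta, sd):
        ptp = posterior_tail_probability(delta, sd, sd)
        assert np.all(ptp >= 0) and np.all(ptp <= 0.5)
        # strictly positive wherever the z-score does not underflow Phi
        z = np.abs(delta) / np.sqrt(2 * sd**2)
        assert np.all(ptp[z < 35] > 0)
        # swapping conditions negates delta, leaves PTP unchanged
        np.testing.assert_array_equal(
            ptp, posterior_tail_probability(-delta, sd, sd)
        )
        assert np.all(ptp[delta == 0] == 0.5)
        # strictly below 0.5 once the z-score is resolvable in floats
        assert np.all(ptp[z > 1e-7] < 0.5)


def _comparison(lfc, ptp):
    lfc = np.asarray(lfc, dtype=float)
    ptp = np.asarray(ptp, dtype=float)
    return AbundanceComparison(
        condition_from="a",
        condition_to="b",
        lfc=lfc,
        ptp=ptp,
        combined_sd=np.ones_like(lfc),
    )


class TestClassifySignificance:
    def test_both_criteria_met(self):
        c = classify_significance(_comparison([1.5], [1e-4]))
        assert c.significant[0] and c.direction[0] == "increase"

    def test_ptp_fails(self):
        c = classify_significance(_comparison([1.5], [0.01]))
        assert not c.significant[0] and c.direction[0] == "none"

    def test_lfc_fails(self):
        c = classify_significance(_comparison([-0.5], [1e-6]))
        assert not c.significant[0]

    def test_decrease_direction(self):
        c = classify_significance(_comparison([-2.0], [1e-5]))
        assert c.significant[0] and c.direction[0] == "decrease"

    def test_direction_consistent_with_sign(self, rng):
        lfc = rng.standard_normal(200) * 2
        ptp = rng.uniform(0, 0.5, 200)
        c = classify_significance(_comparison(lfc, ptp))
        sig = c.significant
        assert np.all(np.sign(lfc[sig]) == np.where(c.direction[sig] == "increase", 1, -1))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(_comparison([1.0], [0.1]), lfc_threshold=0)


class TestSummarizeByGroup:
    def test_all_increase(self):
        c = classify_significance(_comparison([2.0, 3.0], [1e-5, 1e-6]))
        table = summarize_by_group(c, np.array(["g", "g"]))
        assert table.loc[0, "frac_increase"] == 1.0

    def test_permutation_invariance(self, rng):
        lfc = rng.standard_normal(100) * 2
        ptp = rng.uniform(0, 0.5, 100)
        groups = rng.choice(["g1", "g2"], 100)
        c = classify_significance(_comparison(lfc, ptp))
        t1 = summarize_by_group(c, groups).sort_values("group").reset_index(drop=True)
        perm = rng.permutation(100)
        c2 = classify_significance(_comparison(lfc[perm], ptp[perm]))
        t2 = summarize_by_group(c2, groups[perm]).sort_values("group").reset_index(drop=True)
        for col in t1.columns:
            np.testing.assert_array_equal(t1[col].to_numpy(), t2[col].to_numpy())

    def test_hand_built_fractions(self):
        lfc = np.array([2.0, 2.0, -2.0, 0.1, 0.1, 0.1])
        ptp = np.array([1e-5, 1e-5, 1e-5, 0.4, 0.4, 0.4])
        c = classify_significance(_comparison(lfc, ptp))
        table = summarize_by_group(c, np.array(["g"] * 6))
        row = table.iloc[0]
        assert row["frac_increase"] == pytest.approx(1 / 3)
        assert row["frac_decrease"] == pytest.approx(1 / 6)
        assert row["frac_nonsignificant"] == pytest.approx(1 / 2)
        assert row[["frac_increase", "frac_decrease", "frac_nonsignificant"]].sum() == pytest.approx(1.0)
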