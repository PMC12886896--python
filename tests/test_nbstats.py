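"""Size factors, dispersion, the NB Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from germ_epimem.core_io import CountMatrix
from germ_epimem.nbstats import (
    DECallSet,
    add_q_values,
    bh_adjust,
    call_de,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)


def matrix(rows, samples, condition=None):
    frame = pd.DataFrame(rows, columns=samples)
    frame.index = [f"f{i}" for i in range(len(frame))]
    return CountMatrix(frame, condition=condition)


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        cm = matrix([[2, 4], [4, 8]], ["s1", "s2"])
        factors = size_factors(cm)
        np.testing.assert_allclose(factors, [0.7071, 1.4142], atol=1e-4)

    def test_identical_samples_unit_factors(self):
        cm = matrix([[5, 5], [9, 9], [2, 2]], ["s1", "s2"])
        np.testing.assert_allclose(size_factors(cm), [1.0, 1.0])

    def test_scale_equivariance_of_factor_ratios(self):
        # doubling one sample's counts also scales every per-feature
        # geometric mean by 2^(1/n), so raw factors pick up a global
        # rescaling; the identity that holds exactly is on factor ratios
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(100, 4))
        cm = matrix(counts, ["a", "b", "c", "d"])
        base = size_factors(cm)
        doubled = counts.copy()
        doubled[:, 2] *= 2
        factors = size_factors(matrix(doubled, ["a", "b", "c", "d"]))
        np.testing.assert_allclose(
            factors["c"] / factors["a"], 2 * base["c"] / base["a"], rtol=1e-12
        )
        np.testing.assert_allclose(
            (factors[["a", "b", "d"]] / factors["a"]).to_numpy(),
            (base[["a", "b", "d"]] / base["a"]).to_numpy(),
            rtol=1e-12,
        )

    def test_no_all_positive_feature_rejected(self):
        cm = matrix([[0, 5], [5, 0]], ["s1", "s2"])
        with pytest.raises(ValueError, match="median-of-ratios"):
            size_factors(cm)

    def test_agrees_with_deseq2_reference_implementation(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(21)
        counts = rng.poisson(rng.uniform(10, 300, size=(200, 1)), size=(200, 6))
        cm = matrix(counts, [f"s{i}" for i in range(6)])
        _, expected = pydeseq2.deseq2_norm(counts.T)
        np.testing.assert_allclose(size_factors(cm).to_numpy(), expected, rtol=1e-10)


class TestDispersion:
    def test_poisson_features_near_zero(self):
        rng = np.random.default_rng(31)
        counts = rng.poisson(100, size=(2000, 8))
        cm = matrix(counts, [f"s{i}" for i in range(8)])
        factors = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, factors)
        assert np.median(disp) < 0.01

    def test_constant_feature_at_floor(self):
        cm = matrix([[7, 7, 7, 7]], ["a", "b", "c", "d"])
        factors = pd.Series(1.0, index=cm.sample_ids)
        assert estimate_dispersion(cm, factors)["f0"] == pytest.approx(1e-8)

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(32)
        alpha, mu, n = 0.2, 200.0, 20
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mu), size=(2000, n))
        cm = matrix(counts, [f"s{i}" for i in range(n)])
        factors = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, factors)
        assert 0.1 <= np.median(disp) <= 0.3

    def test_group_aware_estimate_ignores_real_effects(self):
        rng = np.random.default_rng(33)
        counts = np.concatenate(
            [rng.poisson(100, size=(500, 4)), rng.poisson(400, size=(500, 4))], axis=1
        )
        cond = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        cm = matrix(counts, [f"s{i}" for i in range(8)], condition=cond)
        factors = pd.Series(1.0, index=cm.sample_ids)
        within = estimate_dispersion(cm, factors)
        pooled = estimate_dispersion(cm, factors, condition={s: "x" for s in cm.sample_ids})
        assert np.median(within) < 0.01
        assert np.median(pooled) > 0.1  # group effect read as overdispersion


def null_matrix(seed, n_feat=2000, mu=100.0, alpha=0.1, reps=4):
    rng = np.random.default_rng(seed)
    r = 1 / alpha
    counts = rng.negative_binomial(r, r / (r + mu), size=(n_feat, 2 * reps))
    cond = {f"s{i}": ("a" if i < reps else "b") for i in range(2 * reps)}
    return matrix(counts, [f"s{i}" for i in range(2 * reps)], condition=cond)


class TestWaldTest:
    def test_equal_counts_null_result(self):
        cond = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        cm = matrix([[10, 10, 10, 10]], ["a1", "a2", "b1", "b2"], condition=cond)
        factors = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.1, index=cm.feature_ids)
        res = nb_wald_test(cm, factors, disp)
        assert res["log2fc"]["f0"] == 0.0
        assert res["p_value"]["f0"] == 1.0

    def test_label_swap_negates_log2fc_keeps_p(self):
        cm = null_matrix(41, n_feat=200)
        factors = size_factors(cm)
        disp = estimate_dispersion(cm, factors)
        fwd = nb_wald_test(cm, factors, disp, group_order=("a", "b"))
        rev = nb_wald_test(cm, factors, disp, group_order=("b", "a"))
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_feature_relabeling_invariance(self):
        cm = null_matrix(42, n_feat=100)
        factors = size_factors(cm)
        disp = estimate_dispersion(cm, factors)
        res = nb_wald_test(cm, factors, disp)
        shuffled = CountMatrix(cm.counts.iloc[::-1], condition=cm.condition)
        res2 = nb_wald_test(shuffled, factors, disp.iloc[::-1])
        np.testing.assert_allclose(res["p_value"].iloc[::-1].to_numpy(),
                                   res2["p_value"].to_numpy())

    def test_null_type_one_error_calibrated(self):
        cm = null_matrix(43)
        factors = size_factors(cm)
        disp = estimate_dispersion(cm, factors)
        res = nb_wald_test(cm, factors, disp)
        assert 0.03 <= (res["p_value"] < 0.05).mean() <= 0.07

    def test_single_sample_group_rejected(self):
        cond = {"a1": "a", "b1": "b", "b2": "b"}
        cm = matrix([[1, 2, 3]], ["a1", "b1", "b2"], condition=cond)
        factors = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.1, index=cm.feature_ids)
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_wald_test(cm, factors, disp)


def brute_force_bh(p):
    """Step-up BH with monotonicity enforcement, written independently."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, p[i] * m / rank_from_top)
        q[i] = value
        prev = value
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(55)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(56)
        p = rng.uniform(size=500)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        # ordering by p implies ordering by q
        idx = np.argsort(p)
        assert (np.diff(q[idx]) >= -1e-15).all()


class TestCallDe:
    def test_threshold_rules(self):
        res = pd.DataFrame(
            {
                "log2fc": [1.5, 0.5, 3.0, -1.4],
                "q_value": [0.01, 0.01, 0.2, 0.04],
            },
            index=["up_ok", "weak_fc", "weak_q", "down_ok"],
        )
        calls = call_de(res, min_fold_change=2, max_fdr=0.05)
        assert calls.up == {"up_ok"}
        assert calls.down == {"down_ok"}

    def test_min_fold_change_below_one_rejected(self):
        res = pd.DataFrame({"log2fc": [1.0], "q_value": [0.01]}, index=["f"])
        with pytest.raises(ValueError):
            call_de(res, min_fold_change=0.5)

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValueError):
            DECallSet(up={"a"}, down={"a"})


class TestFdrAndSensitivity:
    def test_planted_effects_recovered_with_fdr_control(self):
        rng = np.random.default_rng(60)
        fdrs, sensitivities = [], []
        for _ in range(5):
            n_feat, reps, alpha, mu = 2000, 4, 0.1, 100.0
            affected = rng.choice(n_feat, n_feat // 10, replace=False)
            sign = rng.choice([-1.0, 1.0], size=len(affected))
            mu_mat = np.full((n_feat, 2 * reps), mu)
            for k, idx in enumerate(affected):
                mu_mat[idx, reps:] = mu * 2.0 ** (2.0 * sign[k])
            r = 1 / alpha
            counts = rng.negative_binomial(r, r / (r + mu_mat))
            cond = {f"s{i}": ("a" if i < reps else "b") for i in range(2 * reps)}
            cm = matrix(counts, [f"s{i}" for i in range(2 * reps)], condition=cond)
            factors = size_factors(cm)
            disp = estimate_dispersion(cm, factors)
            res = add_q_values(nb_wald_test(cm, factors, disp))
            called = set(res.index[res["q_value"] <= 0.05])
            true = {f"f{i}" for i in affected}
            fdrs.append(len(called - true) / max(len(called), 1))
            sensitivities.append(len(called & true) / len(true))
        assert np.mean(fdrs) <= 0.10
        assert np.mean(sensitivities) >= 0.8
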