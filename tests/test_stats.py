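import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dynconn
from dynconn.stats import (
    adjusted_group_test,
    compare_measures,
    fdr_adjust,
    normality_screen,
    partial_spearman,
)


def brute_bh(p):
    """Independent step-up oracle: adj_i = min_{j >= rank(i)} m * p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(running, 1.0)
    return adj


class TestNormalityScreen:
    def test_gaussian_samples_screen_normal(self):
        hits = sum(
            normality_screen(np.random.default_rng(s).standard_normal(1000))
            == "normal"
            for s in range(20)
        )
        assert hits >= 19

    def test_heavy_tailed_screen_non_normal(self):
        hits = sum(
            normality_screen(sps.t.rvs(2, size=1000,
                                       random_state=np.random.default_rng(s)))
            == "non-normal"
            for s in range(20)
        )
        assert hits >= 18

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_screen(np.full(20, 1.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_screen(np.arange(5))


class TestAdjustedGroupTest:
    def test_reduces_to_plain_t_without_covariates(self, rng):
        y = rng.standard_normal(40)
        group = np.array(["a"] * 18 + ["b"] * 22)
        res = adjusted_group_test(y, group, family="t")
        t_ref, p_ref = sps.ttest_ind(y[group == "b"], y[group == "a"],
                                     equal_var=True)
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_power_on_planted_shift(self, rng):
        """d=1 shift, 60/60: essentially always detected at alpha=0.05."""
        hits = 0
        for s in range(50):
            r = np.random.default_rng(s)
            y = np.r_[r.standard_normal(60), 1.0 + r.standard_normal(60)]
            res = adjusted_group_test(y, ["a"] * 60 + ["b"] * 60, family="t")
            hits += res.p < 0.05
        assert hits >= 49  # closed-form power at d=1, n=60/60 is > 0.999

    def test_null_type_one_error_calibrated(self):
        """Identical distributions: rejection rate ~ alpha over 2000 sims."""
        ps = np.empty(2000)
        group = ["a"] * 30 + ["b"] * 30
        for s in range(2000):
            y = np.random.default_rng(10_000 + s).standard_normal(60)
            ps[s] = adjusted_group_test(y, group, family="t").p
        rate = (ps < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.012)
        # and the p-value distribution is uniform
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 0.05

    def test_covariate_adjustment_removes_confound(self, rng):
        n = 100
        group = np.array(["a"] * n + ["b"] * n)
        age = np.r_[rng.uniform(20, 40, n), rng.uniform(40, 60, n)]
        y = 0.1 * age + rng.standard_normal(2 * n)  # age effect only
        raw = adjusted_group_test(y, group, family="t")
        adj = adjusted_group_test(y, group, covariates={"age": age}, family="t")
        assert raw.p < 0.01  # confounded
        assert adj.p > 0.05  # adjusted away

    def test_mannwhitney_fallback(self, rng):
        y = sps.t.rvs(1.5, size=60, random_state=rng)
        group = ["a"] * 30 + ["b"] * 30
        res = adjusted_group_test(y, group)
        assert res.family == "mannwhitney"

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            adjusted_group_test(rng.standard_normal(5), ["a"] * 5)


class TestFdrAdjust:
    def test_stepup_by_hand(self):
        """All of [.01,.02,.03,.04] survive at q=0.05 (max i with p_i<=.05 i/4 is 4)."""
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.all(adj <= 0.05)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_flat_case(self):
        np.testing.assert_allclose(fdr_adjust([0.5] * 6), 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.2, 1.2])

    def test_matches_brute_force_enumeration(self, rng):
        """BH equals the independent step-up oracle on a grid of p-vectors."""
        grid = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.9])
        for _ in range(200):
            m = rng.integers(1, 7)
            p = rng.choice(grid, size=m)
            np.testing.assert_allclose(fdr_adjust(p), brute_bh(p), atol=1e-12)

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=12)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


class TestPartialSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.standard_normal(50)
        res = partial_spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        assert res.p == 0.0

    def test_matches_plain_spearman_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 80))
        res = partial_spearman(x, y)
        ref = sps.spearmanr(x, y).statistic
        assert res.rho == pytest.approx(ref, abs=1e-10)

    def test_self_partialling_kills_correlation(self, rng):
        x = rng.standard_normal(60)
        y = x + 0.1 * rng.standard_normal(60)
        res = partial_spearman(x, y, covariates={"c": x})
        assert abs(res.rho) < 0.3  # only the noise component remains

    def test_invariant_to_monotone_transforms(self, rng):
        x = rng.uniform(1, 2, 70)
        y = rng.uniform(1, 2, 70)
        c = rng.standard_normal(70)
        a = partial_spearman(x, y, covariates={"c": c})
        b = partial_spearman(np.log(x), y**3, covariates={"c": c})
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            partial_spearman(np.ones(30), np.arange(30))

    def test_recovers_generated_clinical_coupling(self, gt):
        """Cohort generated at rho = -0.5 recovers in [-0.65, -0.35], n=120."""
        _, df, _ = dynconn.simulate_cohort(
            gt, n_per_group=60, T=230, clinical_model={"MoCA": -0.5}, seed=5
        )
        res = partial_spearman(
            df["true_occupancy_hyper"], df["MoCA"],
            covariates=df[["age", "education", "bmi", "head_motion"]],
        )
        assert -0.65 <= res.rho <= -0.35


def test_compare_measures_family_scope(rng):
    df = pd.DataFrame(
        dict(
            group=["a"] * 20 + ["b"] * 20,
            m1=rng.standard_normal(40),
            m2=np.r_[rng.standard_normal(20), 3 + rng.standard_normal(20)],
            age=rng.uniform(20, 60, 40),
        )
    )
    out = compare_measures(df, ["m1", "m2"], covariate_cols=["age"], family="t")
    assert list(out["measure"]) == ["m1", "m2"]
    assert (out["p_fdr"] >= out["p"] - 1e-12).all()
    assert out.loc[1, "p_fdr"] < 0.01
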