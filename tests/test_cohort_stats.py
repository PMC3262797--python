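"""Group deltas, rank tests, standardized regression, ROC/Youden, BPF."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from brainmre import (
    CohortSpec,
    compute_bpf,
    group_percent_delta,
    mann_whitney,
    roc_youden,
    simulate_cohort,
    spearman,
    standardized_regression,
)


def table_with_means(var, patient_mean, control_mean, n=4):
    """Degenerate cohort with every subject at the group mean."""
    rows = []
    for i in range(n):
        rows.append({"group": "patient", var: patient_mean})
        rows.append({"group": "control", var: control_mean})
    return pd.DataFrame(rows)


def pairwise_auc(scores, diseased, lower_is_diseased=True):
    """Concordant-pair AUC oracle with half credit for ties."""
    s = -np.asarray(scores, float) if lower_is_diseased else np.asarray(scores, float)
    pos = s[np.asarray(diseased, bool)]
    neg = s[~np.asarray(diseased, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mw_exact_p_oracle(x, y):
    """Two-sided exact p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n1):
        u = np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    mu = n1 * (n - n1) / 2
    return np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)


class TestGroupDelta:
    def test_mu_reduction_matches_published_group_means(self):
        t = table_with_means("mu_kpa", 2.607, 3.278)
        d = group_percent_delta(t, "mu_kpa")
        assert d.percent_delta == pytest.approx(-20.47, abs=0.02)

    def test_alpha_reduction(self):
        d = group_percent_delta(table_with_means("alpha", 0.2756, 0.2934), "alpha")
        assert d.percent_delta == pytest.approx(-6.07, abs=0.01)

    def test_identical_means_give_zero_delta(self):
        d = group_percent_delta(table_with_means("v", 1.5, 1.5), "v")
        assert d.absolute_delta == 0.0
        assert d.percent_delta == 0.0

    def test_scale_invariance_of_percent_delta(self):
        d1 = group_percent_delta(table_with_means("v", 2.0, 2.5), "v")
        d2 = group_percent_delta(table_with_means("v", 2000.0, 2500.0), "v")
        assert d1.percent_delta == pytest.approx(d2.percent_delta, rel=1e-12)

    def test_missing_variable_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            group_percent_delta(table_with_means("v", 1.0, 2.0), "nope")


class TestMannWhitney:
    def test_exact_p_for_complete_separation(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 0.1."""
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.p_value == pytest.approx(mw_exact_p_oracle([1, 2, 3], [4, 5, 6]))

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = rng.normal(loc=0.8, size=6)
        r = mann_whitney(x, y)
        assert r.p_value == pytest.approx(mw_exact_p_oracle(x, y), abs=1e-12)

    def test_identical_samples_midrank_u(self):
        x = [2.0, 2.0, 2.0, 2.0]
        r = mann_whitney(x, x)
        assert r.statistic == pytest.approx(len(x) * len(x) / 2)

    def test_large_shift_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(loc=10.0, size=20)
        y = rng.normal(loc=0.0, size=20)
        assert mann_whitney(x, y).p_value < 1e-4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_increasing(self):
        r = spearman([1, 2, 3, 4], [10, 20, 25, 100])
        assert r.statistic == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        r = spearman([1, 2, 3, 4], [5, 4, 2, -7])
        assert r.statistic == pytest.approx(-1.0)

    def test_midrank_tie_handling_matches_direct_computation(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0]
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(expected, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestStandardizedRegression:
    def test_single_covariate_beta_is_pearson_r(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        t = pd.DataFrame({"y": y, "x": x})
        beta = standardized_regression("y", ["x"], t)[0]
        assert beta.statistic == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-10)

    def test_null_simulation_betas_small_p_uniform(self):
        """Independent response: |beta| stays small and p-values are ~uniform."""
        rng = np.random.default_rng(11)
        pvals = []
        # null beta has sd ~ 1/sqrt(n); bound the 400 draws at 5 sigma
        bound = 5.0 / math.sqrt(500)
        for _ in range(200):
            t = pd.DataFrame(
                {
                    "y": rng.normal(size=500),
                    "a": rng.normal(size=500),
                    "b": rng.normal(size=500),
                }
            )
            res = standardized_regression("y", ["a", "b"], t)
            for r in res:
                assert abs(r.statistic) < bound
                pvals.append(r.p_value)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        t = pd.DataFrame({"y": rng.normal(size=30), "a": x, "b": x})
        with pytest.raises(ValueError, match="rank"):
            standardized_regression("y", ["a", "b"], t)


class TestRocYouden:
    def test_perfect_separation(self):
        scores = [1.0, 1.5, 2.0, 3.0, 3.5, 4.0]
        labels = ["patient"] * 3 + ["control"] * 3
        r = roc_youden(scores, labels, direction="lower")
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert 2.0 < r.cutoff < 3.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_null_auc_near_half(self):
        # null AUC has sd ~ sqrt((n+1)/(12 n1 n2)) ~ 0.013 at n = 2000;
        # bound each draw at ~4 sigma and the 10-seed mean much tighter
        rng = np.random.default_rng(13)
        aucs = []
        for _ in range(10):
            scores = rng.normal(size=2000)
            labels = np.array(["patient", "control"] * 1000)
            aucs.append(roc_youden(scores, labels).auc)
        assert np.max(np.abs(np.array(aucs) - 0.5)) < 0.05
        assert abs(np.mean(aucs) - 0.5) < 0.015

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_auc_equals_pair_counting(self, seed):
        """Trapezoid AUC coincides with the concordant-pair fraction (tie=1/2)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        diseased = rng.random(n) < 0.4
        if diseased.all() or not diseased.any():
            diseased[0] = ~diseased[0]
        labels = np.where(diseased, "patient", "control")
        r = roc_youden(scores, labels, direction="lower")
        assert r.auc == pytest.approx(pairwise_auc(scores, diseased), abs=1e-10)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=100)
        labels = np.where(rng.random(100) < 0.5, "patient", "control")
        lo = roc_youden(scores, labels, direction="lower")
        hi = roc_youden(scores, labels, direction="higher")
        assert lo.auc + hi.auc == pytest.approx(1.0)

    def test_auc_u_statistic_identity(self):
        """Cross-module identity: AUC = U'/(n1*n2) for the oriented U."""
        rng = np.random.default_rng(15)
        pat = rng.normal(loc=-0.5, size=23)
        ctl = rng.normal(loc=0.0, size=38)
        scores = np.concatenate([pat, ctl])
        labels = ["patient"] * 23 + ["control"] * 38
        r = roc_youden(scores, labels, direction="lower")
        u_ctl = mann_whitney(ctl, pat).statistic  # controls scoring above patients
        assert r.auc == pytest.approx(u_ctl / (23 * 38), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_youden([1.0, 2.0], ["patient", "patient"])


class TestBpf:
    def test_basic_ratio(self):
        assert compute_bpf(0.60, 0.35, 1.00) == pytest.approx(0.95)

    def test_full_parenchyma(self):
        assert compute_bpf(0.6, 0.4, 1.0) == pytest.approx(1.0)

    def test_published_group_means_delta(self):
        d = group_percent_delta(table_with_means("bpf", 0.9610, 0.9775), "bpf")
        assert d.percent_delta == pytest.approx(-1.69, abs=0.01)

    def test_excess_parenchyma_rejected(self):
        with pytest.raises(ValueError):
            compute_bpf(0.7, 0.4, 1.0)


def test_synthetic_cohort_reproduces_group_structure():
    table = simulate_cohort(CohortSpec(seed=21))
    d = group_percent_delta(table, "mu_kpa")
    assert d.percent_delta < -10  # patients substantially softer
    pats = table.loc[table.group == "patient", "mu_kpa"]
    ctls = table.loc[table.group == "control", "mu_kpa"]
    assert mann_whitney(pats, ctls).p_value < 0.01
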