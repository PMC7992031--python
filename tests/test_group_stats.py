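"""Mann-Whitney, ROC/AUC and covariate correlation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictonet.group_stats import (covariate_correlations, mann_whitney_one_sided,
                                 roc_analysis)


def _enumerated_p(patients, controls):
    """Exact one-sided p by exhausting all group labelings (oracle)."""
    pooled = np.concatenate([patients, controls])
    n1 = len(patients)

    def u_stat(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

    observed = u_stat(range(n1))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    return sum(u >= observed for u in us) / len(us)


class TestMannWhitney:
    def test_separated_groups_enumeration(self):
        u, p = mann_whitney_one_sided([3, 4, 5], [0, 1, 2])
        assert u == 9.0
        assert p == pytest.approx(1 / 20)
        assert p == pytest.approx(_enumerated_p(np.array([3, 4, 5]),
                                                np.array([0, 1, 2])))

    def test_identical_groups_not_significant(self):
        _, p = mann_whitney_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pat = rng.normal(0.5, 1.0, size=4)
        ctl = rng.normal(0.0, 1.0, size=4)
        _, p = mann_whitney_one_sided(pat, ctl)
        assert p == pytest.approx(_enumerated_p(pat, ctl))

    def test_label_swap_complement(self):
        pat, ctl = np.array([3.0, 4, 5]), np.array([0.0, 1, 2])
        _, p_fwd = mann_whitney_one_sided(pat, ctl)
        _, p_rev = mann_whitney_one_sided(ctl, pat)
        assert p_rev == pytest.approx(1.0)  # fully separated, wrong direction
        assert p_fwd < p_rev

    def test_degenerate_constant_data_flagged(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            _, p = mann_whitney_one_sided([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_nominal_false_positive_rate(self):
        # iid groups: one-sided test rejects at ~5% over replicates
        hits = 0
        n_rep = 400
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            _, p = mann_whitney_one_sided(rng.normal(size=10), rng.normal(size=10))
            hits += p < 0.05
        rate = hits / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([0.1, 0.2, 0.3, 0.7, 0.8, 0.9],
                           [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0
        assert res.accuracy == 1.0

    def test_identical_scores_chance_level(self):
        res = roc_analysis([0.5] * 8, [0, 0, 0, 0, 1, 1, 1, 1])
        assert res.auc == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_auc_equals_u_over_n1n2(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 12, size=2)
        # ties included deliberately: draw from a small discrete set
        scores = rng.choice([0.1, 0.2, 0.3, 0.4, 0.5], size=n1 + n2)
        labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
        res = roc_analysis(scores, labels)
        u_direct = sum((xi > yj) + 0.5 * (xi == yj)
                       for xi in scores[labels] for yj in scores[~labels])
        assert res.auc == pytest.approx(u_direct / (n1 * n2))
        assert res.u_statistic == pytest.approx(u_direct)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.random(14)
        labels = rng.random(14) < 0.5
        labels[:2] = [True, False]  # both classes present
        a = roc_analysis(scores, labels)
        b = roc_analysis(np.exp(3 * scores), labels)
        assert a.auc == pytest.approx(b.auc)
        assert a.u_statistic == pytest.approx(b.u_statistic)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.sensitivity == b.sensitivity
        assert a.specificity == b.specificity

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(6)
        res = roc_analysis(rng.random(20), rng.integers(0, 2, 20).astype(bool))
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])


class TestCovariates:
    def test_exact_linear_covariate(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        cov = pd.DataFrame({"epilepsy_duration_years": 2 + 3 * scores})
        out = covariate_correlations(scores, cov)
        assert out.loc["epilepsy_duration_years", "r"] == pytest.approx(1.0)

    def test_constant_covariate_skipped(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        cov = pd.DataFrame({"seizure_freq_mj": [5.0] * 4})
        out = covariate_correlations(scores, cov)
        assert out.loc["seizure_freq_mj", "flag"] == "zero variance"

    def test_too_few_pairs_skipped(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        cov = pd.DataFrame({"seizure_freq_abs": [1.0, 2.0, np.nan, np.nan]})
        out = covariate_correlations(scores, cov)
        assert out.loc["seizure_freq_abs", "flag"] == "fewer than 3 pairs"

    def test_total_frequency_derived(self):
        scores = np.linspace(0, 1, 6)
        cov = pd.DataFrame({
            "seizure_freq_mj": np.arange(6.0),
            "seizure_freq_abs": np.ones(6),
            "seizure_freq_gtcs": np.zeros(6),
        })
        out = covariate_correlations(scores, cov)
        assert "seizure_freq_total" in out.index
        assert out.loc["seizure_freq_total", "r"] == pytest.approx(1.0)

    def test_independent_covariate_null_calibration(self):
        # |r| exceeds the 95% permutation band in ~5% of replicates
        n, n_rep, n_perm = 26, 200, 99
        hits = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            scores = rng.random(n)
            cov = rng.random(n)
            r_obs = abs(np.corrcoef(scores, cov)[0, 1])
            perm = np.array([
                abs(np.corrcoef(scores, rng.permutation(cov))[0, 1])
                for _ in range(n_perm)
            ])
            hits += r_obs > np.quantile(perm, 0.95)
        rate = hits / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01
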