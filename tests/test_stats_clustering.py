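"""Repeated-measures statistics, q-values, clustering and enrichment."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import proteoturn.stats_clustering as sc


def anova_oracle(values):
    """Independent sums-of-squares decomposition via explicit loops."""
    s, t = values.shape
    grand = values.mean()
    ss_time = sum(
        s * (values[:, j].mean() - grand) ** 2 for j in range(t)
    )
    ss_subj = sum(
        t * (values[i, :].mean() - grand) ** 2 for i in range(s)
    )
    ss_err = 0.0
    for i in range(s):
        for j in range(t):
            resid = (
                values[i, j] - values[i, :].mean() - values[:, j].mean() + grand
            )
            ss_err += resid**2
    f = (ss_time / (t - 1)) / (ss_err / ((t - 1) * (s - 1)))
    from scipy.stats import f as fdist

    return f, fdist.sf(f, t - 1, (t - 1) * (s - 1))


class TestAnova:
    def test_no_time_effect_gives_f_zero_p_one(self):
        vals = np.tile(np.arange(5.0)[:, None], (1, 4))  # subject offsets only
        res = sc.within_subject_anova(vals)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(size=(10, 4))
            res = sc.within_subject_anova(vals)
            f_ref, p_ref = anova_oracle(vals)
            assert res.f == pytest.approx(f_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_strong_time_effect_detected(self, rng):
        noise_sd = 1.0
        effect = np.array([0.0, 0.0, 0.0, 5.0 * noise_sd])
        vals = rng.normal(0, noise_sd, (10, 4)) + effect
        assert sc.within_subject_anova(vals).p < 1e-6

    def test_degenerate_error_flagged(self):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (5, 1))
        res = sc.within_subject_anova(vals)
        assert "degenerate_error" in res.flags
        assert res.p == 0.0


class TestStoreyQ:
    def test_single_large_p_hits_ceiling(self):
        res = sc.storey_qvalues(np.array([1.0]))
        assert res.qvalues[0] == pytest.approx(1.0)

    def test_q_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=500)
        res = sc.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.qvalues[order]) >= -1e-12)

    def test_pi0_near_one_under_null(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=1000)
        res = sc.storey_qvalues(p)
        assert 0.85 <= res.pi0 <= 1.05

    def test_q_never_below_pi0_scaled_bh(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(size=450)])
        res = sc.storey_qvalues(p)
        m = len(p)
        order = np.argsort(p)
        bh = np.minimum.accumulate(
            (res.pi0 * m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        assert np.all(res.qvalues[order] >= bh - 1e-12)
        assert np.all(res.qvalues <= 1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            sc.storey_qvalues(np.array([]))


def permutation_oracle(a, b):
    """Exhaustive sign-flip distribution of the mean paired difference."""
    d = b - a
    obs = abs(d.mean())
    count = 0
    total = 0
    for signs in product((1, -1), repeat=len(d)):
        total += 1
        if abs(np.mean(np.array(signs) * d)) >= obs - 1e-12:
            count += 1
    return count / total


class TestPairedContrast:
    def _tables(self, rng, n_prot=5, n_subj=6):
        a = pd.DataFrame(
            rng.lognormal(1, 0.3, (n_prot, n_subj)),
            index=[f"P{i}" for i in range(n_prot)],
        )
        b = a * rng.lognormal(0, 0.3, (n_prot, n_subj))
        return a, b

    def test_identical_periods_null(self, rng):
        a, _ = self._tables(rng)
        res = sc.paired_contrast(a, a.copy())
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_exact_doubling_gives_unit_log2fc(self, rng):
        a, _ = self._tables(rng)
        res = sc.paired_contrast(a, 2 * a)
        assert np.allclose(res["log2fc"], 1.0)

    def test_permutation_p_matches_exhaustive_oracle(self, rng):
        a, b = self._tables(rng, n_prot=8, n_subj=6)
        res = sc.paired_contrast(a, b, method="permutation")
        for acc in a.index:
            expected = permutation_oracle(
                a.loc[acc].to_numpy(), b.loc[acc].to_numpy()
            )
            assert res.loc[acc, "p"] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_mean_flagged(self, rng):
        a, b = self._tables(rng, n_prot=2)
        a.iloc[0] = -a.iloc[0]
        res = sc.paired_contrast(a, b)
        assert bool(res["nonpositive_mean"].iloc[0])
        assert np.isnan(res["log2fc"].iloc[0])


def planted_profiles(rng, n_per=100, noise_sd=0.3):
    """Three temporal archetypes over 4 timepoints."""
    archetypes = np.array(
        [
            [-0.5, -0.5, -0.5, 1.5],  # flat then up at ED
            [-1.0, -0.2, 1.4, -0.2],  # up at EB, down at ED
            [1.2, -1.2, 0.8, -0.8],  # alternating
        ]
    )
    labels = np.repeat([0, 1, 2], n_per)
    x = archetypes[labels] + rng.normal(0, noise_sd, (3 * n_per, 4))
    return sc.standardize_profiles(x), labels


class TestFuzzyCMeans:
    def test_single_cluster_full_membership(self, rng):
        x = rng.normal(size=(20, 4))
        res = sc.fuzzy_cmeans(x, c=1, seed=0)
        assert np.allclose(res.membership, 1.0)

    def test_membership_rows_sum_to_one(self, rng):
        x, _ = planted_profiles(rng)
        res = sc.fuzzy_cmeans(x, c=3, seed=0)
        np.testing.assert_allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
        assert res.membership.min() >= 0.0

    def test_objective_non_increasing(self, rng):
        x, _ = planted_profiles(rng)
        res = sc.fuzzy_cmeans(x, c=3, seed=0)
        assert np.all(np.diff(res.objective_history) <= 1e-9)

    def test_recovers_planted_archetypes(self):
        rng = np.random.default_rng(5)
        x, labels = planted_profiles(rng, noise_sd=0.3)
        res = sc.fuzzy_cmeans(x, c=3, seed=0)
        assert adjusted_rand_score(labels, res.assignment) >= 0.9

    def test_membership_floor_unassigns(self, rng):
        x, _ = planted_profiles(rng, noise_sd=2.0)
        res = sc.fuzzy_cmeans(x, c=3, min_membership=0.9, seed=0)
        assert (res.assignment == -1).any()

    def test_more_clusters_than_profiles_rejected(self, rng):
        with pytest.raises(ValueError):
            sc.fuzzy_cmeans(rng.normal(size=(3, 4)), c=5)


class TestPairwisePeriodContrasts:
    def _sums(self, rng, ed_mult=1.0):
        base = rng.lognormal(3, 0.1, 10)
        return pd.DataFrame(
            {
                "FL": base * rng.lognormal(0, 0.05, 10),
                "EB": base * rng.lognormal(0, 0.05, 10),
                "ED": ed_mult * base * rng.lognormal(0, 0.05, 10),
            },
            index=[f"s{i}" for i in range(10)],
        )

    def test_identical_periods_all_adjusted_p_one(self, rng):
        sums = self._sums(rng)
        sums["EB"] = sums["FL"]
        sums["ED"] = sums["FL"]
        res = sc.pairwise_period_contrasts(sums)
        assert all(c["p_adj"] == 1.0 for c in res["contrasts"].values())

    def test_bonferroni_is_three_times_raw(self, rng):
        res = sc.pairwise_period_contrasts(self._sums(rng, ed_mult=1.2))
        for c in res["contrasts"].values():
            assert c["p_adj"] == pytest.approx(min(1.0, 3 * c["p_raw"]))

    def test_ed_shift_detected_only_where_injected(self, rng):
        res = sc.pairwise_period_contrasts(self._sums(rng, ed_mult=1.5))
        assert res["contrasts"]["ED_vs_EB"]["p_adj"] < 0.05
        assert res["contrasts"]["EB_vs_FL"]["p_adj"] > 0.05

    def test_missing_period_rejected(self, rng):
        with pytest.raises(ValueError):
            sc.pairwise_period_contrasts(self._sums(rng).drop(columns="ED"))


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestOra:
    def test_foreground_equals_background_all_p_one(self):
        bg = {f"P{i}" for i in range(20)}
        terms = {"T1": {f"P{i}" for i in range(5)}}
        res = sc.ora_hypergeometric(bg, bg, terms)
        assert res[0].p == pytest.approx(1.0)

    def test_exact_combinatorial_value(self):
        bg = {f"P{i}" for i in range(10)}
        term = {f"P{i}" for i in range(5)}
        fg = {f"P{i}" for i in range(3)}
        res = sc.ora_hypergeometric(fg, bg, {"T1": term})
        assert res[0].p == pytest.approx(comb(5, 3) / comb(10, 3), abs=1e-12)
        assert res[0].p == pytest.approx(10 / 120)

    def test_bh_matches_brute_force(self, rng):
        bg = {f"P{i}" for i in range(100)}
        fg = {f"P{i}" for i in range(20)}
        terms = {
            f"T{j}": set(
                rng.choice(sorted(bg), size=rng.integers(5, 30), replace=False)
            )
            for j in range(15)
        }
        res = sc.ora_hypergeometric(fg, bg, terms)
        adj = bh_oracle(np.array([r.p for r in res]))
        for r, expected in zip(res, adj):
            assert r.p_adj == pytest.approx(expected, abs=1e-12)
            assert r.p_adj >= r.p - 1e-12

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            sc.ora_hypergeometric(set(), {"P1"}, {})
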