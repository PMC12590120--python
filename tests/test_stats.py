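"""Cluster permutation, FDR, repeated-measures ANOVA, robust correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkassr.stats import (cluster_permutation_test, fdr_adjust, paired_t,
                            rm_anova, robust_spearman)


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((12, 200))
        res = cluster_permutation_test(A, A.copy(), n_perm=100, seed=1)
        assert res.clusters == []
        assert np.allclose(res.t_series, 0.0)

    def test_strong_effect_detected_with_correct_extent(self):
        rng = np.random.default_rng(2)
        times = np.linspace(-2, 2, 401)
        A = rng.standard_normal((20, 401))
        B = rng.standard_normal((20, 401))
        win = (times >= 0.2) & (times <= 0.8)
        A[:, win] += 2.0
        res = cluster_permutation_test(A, B, times=times, n_perm=500, seed=3)
        sig = res.significant_clusters
        assert len(sig) >= 1
        big = max(sig, key=lambda c: abs(c.mass))
        overlap = min(big.end_s, 0.8) - max(big.start_s, 0.2)
        assert overlap >= 0.3
        assert big.mass > 0

    def test_matches_mne_observed_clusters(self):
        # independent cross-check of the observed clustering (t series,
        # boundaries and masses) against mne's implementation
        from mne.stats import permutation_cluster_1samp_test
        from scipy import stats as sps
        rng = np.random.default_rng(4)
        D = rng.standard_normal((15, 300))
        D[:, 100:140] += 0.9
        res = cluster_permutation_test(D, np.zeros_like(D), n_perm=100, seed=0)
        thr = sps.t.ppf(1 - 0.025, 14)
        t_mne, clusters_mne, _, _ = permutation_cluster_1samp_test(
            D, threshold=thr, n_permutations=50, tail=0, seed=1, out_type="mask",
            verbose="error")
        assert np.allclose(res.t_series, t_mne, atol=1e-10)
        ours = {(int(c.start_s), int(c.end_s), round(c.mass, 6))
                for c in res.clusters}
        theirs = set()
        for m in clusters_mne:
            mask = np.zeros(D.shape[1], bool)
            mask[m] = True
            idx = np.flatnonzero(mask)
            theirs.add((int(idx[0]), int(idx[-1]),
                        round(float(t_mne[mask].sum()), 6)))
        assert ours == theirs

    def test_p_values_bounded_below_by_plus_one_rule(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((10, 100))
        A[:, 40:60] += 3.0
        res = cluster_permutation_test(A, np.zeros_like(A), n_perm=200, seed=6)
        assert all(c.p >= 1 / 201 for c in res.clusters)

    def test_seed_determinism_and_errors(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((8, 50))
        B = rng.standard_normal((8, 50))
        r1 = cluster_permutation_test(A, B, n_perm=100, seed=9)
        r2 = cluster_permutation_test(A, B, n_perm=100, seed=9)
        assert [(c.start_s, c.p) for c in r1.clusters] == [
            (c.start_s, c.p) for c in r2.clusters]
        with pytest.raises(ValueError):
            cluster_permutation_test(A[:1], B[:1])
        with pytest.raises(ValueError):
            cluster_permutation_test(A, B[:, :20])


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_stay_equal(self):
        out = fdr_adjust([0.04] * 6)
        assert np.allclose(out, 0.04)

    @staticmethod
    def _bh_bruteforce(p):
        # direct step-up enumeration oracle
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            prev = min(prev, p[i] * m / rank_from_top)
            adj[i] = prev
        return adj

    def test_matches_bruteforce_enumeration(self):
        cases = [np.array([0.01, 0.02, 0.03, 0.04]),
                 np.random.default_rng(0).uniform(0, 1, 17)]
        for p in cases:
            assert np.allclose(fdr_adjust(p), self._bh_bruteforce(p))

    def test_never_decreases_and_bounded(self):
        p = np.random.default_rng(1).uniform(0, 1, 50)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_adjustment_properties_hold_for_any_input(self, pvals):
        p = np.asarray(pvals)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)       # never decreases
        assert np.all(adj <= 1.0 + 1e-12)
        # monotone: ranking by p is preserved by the adjusted values
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _textbook_two_way_rm(Y):
    """Marginal-means sums-of-squares oracle for a subjects × a × b table."""
    n, a, b = Y.shape
    grand = Y.mean()
    ss = {}
    subj = Y.mean(axis=(1, 2))
    A = Y.mean(axis=(0, 2))
    B = Y.mean(axis=(0, 1))
    AB = Y.mean(axis=0)
    sA = Y.mean(axis=2)    # subject × a
    sB = Y.mean(axis=1)    # subject × b
    ss["A"] = n * b * np.sum((A - grand) ** 2)
    ss["B"] = n * a * np.sum((B - grand) ** 2)
    ss["AB"] = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    ss["subj"] = a * b * np.sum((subj - grand) ** 2)
    ss["As"] = b * np.sum((sA - subj[:, None] - A[None, :] + grand) ** 2)
    ss["Bs"] = a * np.sum((sB - subj[:, None] - B[None, :] + grand) ** 2)
    total = np.sum((Y - grand) ** 2)
    ss["ABs"] = (total - ss["A"] - ss["B"] - ss["AB"] - ss["subj"]
                 - ss["As"] - ss["Bs"])
    F = {
        "A": (ss["A"] / (a - 1)) / (ss["As"] / ((a - 1) * (n - 1))),
        "B": (ss["B"] / (b - 1)) / (ss["Bs"] / ((b - 1) * (n - 1))),
        "AB": (ss["AB"] / ((a - 1) * (b - 1)))
              / (ss["ABs"] / ((a - 1) * (b - 1) * (n - 1))),
    }
    return F


class TestRmAnova:
    def test_two_level_factor_F_equals_t_squared(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((12, 2))
        eff = rm_anova(Y, ["cond"])[0]
        t, df, p = paired_t(Y[:, 0], Y[:, 1])
        assert eff.F == pytest.approx(t ** 2, abs=1e-10)
        assert eff.p == pytest.approx(p, abs=1e-12)
        assert eff.epsilon == 1.0  # k = 2: no sphericity correction possible

    def test_matches_textbook_sums_of_squares(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((8, 3, 2))
        ours = {e.effect: e.F for e in rm_anova(Y, ["A", "B"])}
        oracle = _textbook_two_way_rm(Y)
        assert ours["A"] == pytest.approx(oracle["A"], abs=1e-8)
        assert ours["B"] == pytest.approx(oracle["B"], abs=1e-8)
        assert ours["A × B"] == pytest.approx(oracle["AB"], abs=1e-8)

    def test_three_way_design_runs(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((10, 2, 3, 2))
        effects = rm_anova(Y, ["state", "burst", "freq"])
        assert len(effects) == 7  # 3 mains + 3 two-way + 1 three-way
        assert all(e.F >= 0 for e in effects)
        assert all(0 < e.epsilon <= 1 for e in effects)

    def test_invariances(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((9, 3, 2))
        base = [(e.F, e.p) for e in rm_anova(Y, ["A", "B"])]
        perm = rng.permutation(9)
        relabeled = [(e.F, e.p) for e in rm_anova(Y[perm], ["A", "B"])]
        shifted = [(e.F, e.p) for e in rm_anova(Y + 100.0, ["A", "B"])]
        for a, b in zip(base, relabeled):
            assert a == pytest.approx(b, rel=1e-10)
        for a, b in zip(base, shifted):
            assert a == pytest.approx(b, rel=1e-8)

    def test_epsilon_below_one_under_nonsphericity(self):
        rng = np.random.default_rng(4)
        # heterogeneous correlations between levels violate sphericity
        base = rng.standard_normal((40, 1))
        Y = np.hstack([base + 0.1 * rng.standard_normal((40, 1)),
                       base + 1.0 * rng.standard_normal((40, 1)),
                       2.0 * rng.standard_normal((40, 1))])
        eff = rm_anova(Y[:, :, None].reshape(40, 3), ["A"])[0]
        assert eff.epsilon < 0.95
        assert eff.p >= eff.p_uncorrected

    def test_matches_pingouin_two_way(self):
        # independent library cross-check (F, uncorrected p, GG epsilon)
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((9, 3, 2))
        ours = {e.effect: e for e in rm_anova(Y, ["state", "freq"])}
        rows = [{"subj": s, "state": a, "freq": b, "y": Y[s, a, b]}
                for s in range(9) for a in range(3) for b in range(2)]
        aov = pg.rm_anova(dv="y", within=["state", "freq"], subject="subj",
                          data=pd.DataFrame(rows), detailed=True)
        for src, key in [("state", "state"), ("freq", "freq"),
                         ("state * freq", "state × freq")]:
            row = aov[aov["Source"] == src].iloc[0]
            assert ours[key].F == pytest.approx(row["F"], rel=1e-9)
            assert ours[key].p_uncorrected == pytest.approx(row["p_unc"],
                                                            rel=1e-9)
            assert ours[key].epsilon == pytest.approx(row["eps"], rel=1e-6)

    def test_missing_cells_rejected(self):
        Y = np.ones((5, 2, 2))
        Y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(Y, ["A", "B"])


class TestRobustSpearman:
    def test_monotone_relation_gives_rho_one(self):
        x = np.linspace(0, 10, 30)
        y = np.exp(x / 3)
        res = robust_spearman(x, y, sided="one", direction="positive")
        assert res.rho == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_far_outlier_flagged_by_all_three_and_removed(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30) * 0.5
        x = np.append(x, 10.0)   # ~10 robust SDs away on both axes
        y = np.append(y, -10.0)
        res = robust_spearman(x, y, sided="two", direction="positive")
        assert 30 in res.outliers
        for method in ("boxplot", "mad", "s"):
            assert 30 in res.flags[method]
        assert res.n_used <= 30  # the planted point is gone

    def test_intersection_rule(self):
        # a point flagged by only some methods must be kept
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        res = robust_spearman(x, y, sided="two", direction="positive")
        union = set()
        inter = set(range(40))
        for m, idx in res.flags.items():
            union |= set(idx)
            inter &= set(idx)
        assert set(res.outliers) == inter

    def test_null_correlation_is_small(self):
        rng = np.random.default_rng(2)
        res = robust_spearman(rng.standard_normal(1000),
                              rng.standard_normal(1000),
                              sided="two", direction="positive")
        assert abs(res.rho) < 0.08

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 2, 50)
        y = rng.uniform(1, 2, 50)
        a = robust_spearman(x, y, sided="two", direction="positive")
        b = robust_spearman(np.log(x), y ** 3, sided="two",
                            direction="positive")
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_one_sided_direction(self):
        x = np.linspace(0, 1, 20)
        y = -x + 0.01 * np.sin(x * 50)
        res = robust_spearman(x, y, sided="one", direction="negative")
        assert res.rho < -0.9
        assert res.p < 0.01
        res_wrong = robust_spearman(x, y, sided="one", direction="positive")
        assert res_wrong.p > 0.9

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            robust_spearman([1, 2, 3], [1, 2, 3])
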