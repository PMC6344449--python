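"""Repeated-measures ANOVA engine against brute-force and library oracles."""

import itertools

import numpy as np
import pytest

from posturemep.rmstats import (
    bonferroni_pairwise,
    gg_epsilon,
    mauchly_test,
    rm_anova_oneway,
    rm_anova_twoway,
)


def oneway_brute_force(y):
    """Definitional sums for the subject x treatment decomposition."""
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    ss_t = n * sum((c - grand) ** 2 for c in col)
    ss_e = sum(
        (y[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    df_t, df_e = k - 1, (n - 1) * (k - 1)
    f = (ss_t / df_t) / (ss_e / df_e)
    return ss_t, ss_e, df_t, df_e, f


def twoway_brute_force(y):
    """Definitional sums for the n x a x b within-subject decomposition."""
    n, a, b = y.shape
    grand = y.sum() / y.size
    ma = [y[:, i, :].sum() / (n * b) for i in range(a)]
    mb = [y[:, :, j].sum() / (n * a) for j in range(b)]
    mab = [[y[:, i, j].sum() / n for j in range(b)] for i in range(a)]
    ms = [y[i].sum() / (a * b) for i in range(n)]
    msa = [[y[i, j, :].sum() / b for j in range(a)] for i in range(n)]
    msb = [[y[i, :, j].sum() / a for j in range(b)] for i in range(n)]
    ss_a = n * b * sum((m - grand) ** 2 for m in ma)
    ss_b = n * a * sum((m - grand) ** 2 for m in mb)
    ss_ab = n * sum(
        (mab[i][j] - ma[i] - mb[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_as = b * sum(
        (msa[i][j] - ms[i] - ma[j] + grand) ** 2 for i in range(n) for j in range(a)
    )
    ss_bs = a * sum(
        (msb[i][j] - ms[i] - mb[j] + grand) ** 2 for i in range(n) for j in range(b)
    )
    ss_abs = sum(
        (
            y[i, p, q]
            - msa[i][p]
            - msb[i][q]
            - mab[p][q]
            + ms[i]
            + ma[p]
            + mb[q]
            - grand
        )
        ** 2
        for i in range(n)
        for p in range(a)
        for q in range(b)
    )
    return ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs


def box_epsilon_elementwise(s):
    """Box's epsilon from the covariance elements (dual formula)."""
    k = s.shape[0]
    sbar = s.mean()
    row = s.mean(axis=1)
    num = (k * (np.trace(s) / k - sbar)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row**2).sum() + k**2 * sbar**2
    )
    return num / den


class TestGGEpsilon:
    def test_identity_covariance_spherical(self):
        assert gg_epsilon(np.eye(5)) == pytest.approx(1.0)

    def test_rank_one_lower_bound(self):
        v = np.array([1.0, 2.0, -1.0, 0.5])
        s = np.outer(v, v)
        assert gg_epsilon(s) == pytest.approx(1.0 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_box_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((10, 5))
        s = np.cov(a, rowvar=False)
        eps = gg_epsilon(s)
        assert eps == pytest.approx(box_epsilon_elementwise(s), abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((3, 4)))

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(11)
        n, k = 4000, 4
        subj = rng.standard_normal((n, 1))
        y = subj + rng.standard_normal((n, k))
        res = rm_anova_oneway(y)
        assert res.epsilon_gg > 0.99


class TestOnewayAnova:
    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((5, 4))
        res = rm_anova_oneway(y)
        ss_t, ss_e, df_t, df_e, f = oneway_brute_force(y)
        assert res.ss_effect == pytest.approx(ss_t, rel=1e-10)
        assert res.ss_error == pytest.approx(ss_e, rel=1e-10)
        assert (res.df_effect, res.df_error) == (df_t, df_e)
        assert res.F == pytest.approx(f, rel=1e-10)
        assert res.partial_eta_sq == pytest.approx(ss_t / (ss_t + ss_e), rel=1e-12)

    def test_null_permuted_columns(self):
        """Columns that are permutations of each other within subjects give
        identical level means, hence F near 0."""
        rng = np.random.default_rng(1)
        base = rng.standard_normal(6)
        y = np.stack([np.roll(base, i) for i in range(4)], axis=1)
        res = rm_anova_oneway(y.T if y.shape[0] == 4 else y)
        assert res.ss_effect == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)

    def test_subject_constant_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((8, 5))
        shift = y + rng.standard_normal((8, 1)) * 50
        a, b = rm_anova_oneway(y), rm_anova_oneway(shift)
        assert a.F == pytest.approx(b.F, rel=1e-8)
        assert a.ss_effect == pytest.approx(b.ss_effect, rel=1e-8)

    def test_zero_error_variance_sentinel(self):
        y = np.tile([1.0, 2.0, 3.0], (4, 1))
        res = rm_anova_oneway(y)
        assert np.isinf(res.F) and res.p == 0.0
        y0 = np.ones((4, 3))
        res0 = rm_anova_oneway(y0)
        assert res0.F == 0.0 and res0.p == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rm_anova_oneway(np.ones((1, 5)))
        with pytest.raises(ValueError):
            rm_anova_oneway(np.ones((5, 1)))

    def test_matches_pingouin(self):
        """Independent library cross-check with forced GG correction."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        n, k = 12, 5
        y = rng.standard_normal((n, k)) + np.linspace(0, 1, k)
        df = pd.DataFrame(
            {
                "y": y.ravel(),
                "subj": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
            }
        )
        aov = pingouin.rm_anova(
            df, dv="y", within="cond", subject="subj", correction=True, detailed=True
        )
        res = rm_anova_oneway(y, sphericity_policy="always")
        assert res.F == pytest.approx(float(aov.loc[0, "F"]), rel=1e-8)
        assert res.p == pytest.approx(float(aov.loc[0, "p_GG_corr"]), rel=1e-6)
        assert res.epsilon_gg == pytest.approx(float(aov.loc[0, "eps"]), rel=1e-6)
        w, p_m = mauchly_test(y @ np.linalg.qr(np.ones((k, k)))[0][:, 1:])
        sph = pingouin.sphericity(df, dv="y", within="cond", subject="subj")
        assert w == pytest.approx(float(sph.W), rel=1e-8)
        assert p_m == pytest.approx(float(sph.pval), rel=1e-6)


class TestTwowayAnova:
    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((5, 2, 3))
        res = rm_anova_twoway(y)
        ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs = twoway_brute_force(y)
        assert res[0].ss_effect == pytest.approx(ss_a, rel=1e-10)
        assert res[0].ss_error == pytest.approx(ss_as, rel=1e-10)
        assert res[1].ss_effect == pytest.approx(ss_b, rel=1e-10)
        assert res[1].ss_error == pytest.approx(ss_bs, rel=1e-10)
        assert res[2].ss_effect == pytest.approx(ss_ab, rel=1e-10)
        assert res[2].ss_error == pytest.approx(ss_abs, rel=1e-10)
        assert res[0].df_effect == 1 and res[1].df_effect == 2 and res[2].df_effect == 2
        assert res[0].F == pytest.approx((ss_a / 1) / (ss_as / 4), rel=1e-10)

    def test_additive_effects_no_interaction(self):
        rng = np.random.default_rng(6)
        n, a, b = 6, 2, 3
        fa = np.array([0.0, 1.0])
        fb = np.array([0.0, 0.5, 1.5])
        y = fa[None, :, None] + fb[None, None, :] + rng.standard_normal((n, 1, 1))
        res = rm_anova_twoway(y)
        assert res[2].ss_effect == pytest.approx(0.0, abs=1e-20)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        n, a, b = 10, 2, 3
        y = rng.standard_normal((n, a, b)) + np.arange(a)[None, :, None]
        rows = [
            {"y": y[i, p, q], "subj": i, "A": p, "B": q}
            for i in range(n)
            for p in range(a)
            for q in range(b)
        ]
        aov = pingouin.rm_anova(
            pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subj", detailed=True
        )
        res = rm_anova_twoway(y, sphericity_policy="never")
        for eff, name in zip(res, ["A", "B", "A * B"]):
            row = aov[aov.Source == name].iloc[0]
            assert eff.F == pytest.approx(float(row["F"]), rel=1e-8)
            assert eff.p == pytest.approx(float(row["p_unc"]), rel=1e-6)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_twoway(np.ones((5, 2)))


class TestTypeIError:
    def test_null_rejection_rate_calibrated(self):
        """Under a spherical null the Mauchly-gated GG procedure rejects at
        ~5% (2,000 simulated 12 x 5 datasets)."""
        rng = np.random.default_rng(12345)
        n, k, reps = 12, 5, 2000
        rejections = 0
        for _ in range(reps):
            y = rng.standard_normal((n, 1)) + rng.standard_normal((n, k))
            if rm_anova_oneway(y).p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.015


class TestBonferroniPairwise:
    def test_k5_gives_ten_tests_alpha_005(self):
        rng = np.random.default_rng(13)
        y = rng.standard_normal((6, 5))
        out = bonferroni_pairwise(y, list("abcde"))
        assert len(out) == 10
        # per-test alpha 0.005: a comparison at p = 0.004 counts as significant
        for pc in out:
            assert pc.significant == (pc.p_uncorrected < 0.005)
            assert pc.p_bonferroni == pytest.approx(min(1.0, 10 * pc.p_uncorrected))

    def test_identical_samples_no_evidence(self):
        y = np.tile(np.arange(4.0)[:, None], (1, 3))
        out = bonferroni_pairwise(y)
        for pc in out:
            assert pc.p_uncorrected == 1.0 and not pc.significant

    def test_constant_nonzero_difference(self):
        y = np.column_stack([np.arange(4.0), np.arange(4.0) + 2.0])
        (pc,) = bonferroni_pairwise(y)
        assert pc.p_uncorrected == 0.0 and pc.mean_diff == -2.0

    @pytest.mark.parametrize("seed", range(4))
    def test_closed_form_paired_t(self, seed):
        from scipy import stats

        rng = np.random.default_rng(seed)
        y = rng.standard_normal((9, 3))
        out = bonferroni_pairwise(y, ["x", "y", "z"])
        for (i, j), pc in zip(itertools.combinations(range(3), 2), out):
            d = y[:, i] - y[:, j]
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p = 2 * stats.t.sf(abs(t), len(d) - 1)
            assert pc.t == pytest.approx(t, rel=1e-10)
            assert pc.p_uncorrected == pytest.approx(p, rel=1e-10)
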