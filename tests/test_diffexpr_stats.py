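import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chi2, rankdata

import hybridreg as hr
from hybridreg import StatConfig
from hybridreg.diffexpr_stats import tmm_factors


def _tmm_fixture():
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(10, 0.1, size=(200, 4)).astype(float)
    counts[:, 1] *= 2
    counts[:50, 2] *= 5
    return pd.DataFrame(np.round(counts).astype(int), columns=list("ABCD"))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [5, 10, 200], "b": [5, 10, 200]})
        assert np.allclose(tmm_factors(df), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        # column B = 2 x column A elementwise: all M-values against the
        # reference are equal, so the trimmed mean of M is 0 and the
        # hand-evaluated TMM factor is exactly 1 for both columns
        df = pd.DataFrame({"a": [5, 10, 200, 33], "b": [10, 20, 400, 66]})
        assert np.allclose(tmm_factors(df), 1.0)

    def test_two_column_case_matches_direct_tmm_formula(self):
        # independent direct evaluation of the trimmed weighted M-mean
        rng = np.random.default_rng(1)
        a = rng.integers(5, 500, 100)
        b = a.copy()
        b[:30] = b[:30] * 4  # composition difference
        df = pd.DataFrame({"a": a, "b": b})
        na, nb = a.sum(), b.sum()
        m = np.log2((b / nb) / (a / na))
        avg = 0.5 * np.log2((b / nb) * (a / na))
        w = (nb - b) / (nb * b) + (na - a) / (na * a)
        n = len(m)
        keep = ((rankdata(m) >= np.floor(n * .3) + 1)
                & (rankdata(m) <= n - np.floor(n * .3))
                & (rankdata(avg) >= np.floor(n * .05) + 1)
                & (rankdata(avg) <= n - np.floor(n * .05)))
        f_b_over_a = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        fac = tmm_factors(df)
        assert fac["b"] / fac["a"] == pytest.approx(f_b_over_a, rel=1e-9)

    def test_geometric_mean_is_one(self):
        fac = tmm_factors(_tmm_fixture())
        assert np.exp(np.log(fac).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bioconductor_edger_reference(self):
        # edgeR::calcNormFactors on this exact fixture (computed once with
        # edgeR 4.0.16): 1.089927 1.099458 0.735473 1.134638
        fac = tmm_factors(_tmm_fixture())
        expected = {"A": 1.089927, "B": 1.099458, "C": 0.735473, "D": 1.134638}
        for col, v in expected.items():
            assert fac[col] == pytest.approx(v, abs=0.012)

    def test_invariant_to_common_scaling(self):
        df = _tmm_fixture()
        np.testing.assert_allclose(tmm_factors(df), tmm_factors(df * 7),
                                   rtol=1e-9)

    def test_single_column_errors(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"a": [1, 2]}))


class TestDispersion:
    def _sim(self, phi, n=2000, seed=7, reps=3):
        rng = np.random.default_rng(seed)
        mu = 200 * np.exp(rng.normal(0, 1, n))
        def draw():
            base = np.outer(mu, np.ones(reps))
            if phi == 0:
                return rng.poisson(base)
            return rng.poisson(rng.gamma(1 / phi, base * phi))
        return np.hstack([draw(), draw()]), ["g1"] * reps + ["g2"] * reps

    def test_poisson_data_drives_phi_to_zero(self):
        y, g = self._sim(phi=0.0)
        assert hr.estimate_common_dispersion(y, g) < 0.01

    def test_recovers_simulated_dispersion(self):
        y, g = self._sim(phi=0.2)
        assert hr.estimate_common_dispersion(y, g) == pytest.approx(0.2, abs=0.05)

    def test_identical_replicates_hit_lower_clamp(self):
        y = np.array([[50, 50, 50]])
        assert hr.estimate_common_dispersion(y, ["g"] * 3) <= 2e-6

    def test_no_replication_errors(self):
        with pytest.raises(ValueError, match="replication"):
            hr.estimate_common_dispersion(np.array([[3, 4]]), ["g1", "g2"])


class TestNbTwoGroupTest:
    def test_identical_groups_are_null(self):
        res = hr.nb_two_group_test([10, 10, 10], [10, 10, 10], phi=0.1)
        assert res["log2fc"][0] == pytest.approx(0.0, abs=1e-9)
        assert res["p"][0] >= 0.99

    def test_tenfold_difference_has_definitional_log2fc(self):
        res = hr.nb_two_group_test([1000, 1000, 1000], [100, 100, 100],
                                   phi=0.1)
        assert res["log2fc"][0] == pytest.approx(np.log2(10), abs=1e-6)

    def test_poisson_limit_agrees_with_exact_conditional_binomial(self):
        # conditional on the total, Poisson two-group comparison is a
        # binomial test at p = 1/2; the chi-square LRT tracks its mid-p form
        for a, b in [([30, 25, 35], [15, 18, 12]), ([20, 22, 18], [10, 9, 12]),
                     ([50, 60, 55], [30, 33, 28])]:
            res = hr.nb_two_group_test(a, b, phi=0.0)
            x, n = int(np.sum(a)), int(np.sum(a) + np.sum(b))
            lo = n - x
            midp = (binom.sf(x - 1, n, .5) - .5 * binom.pmf(x, n, .5)
                    + binom.cdf(lo, n, .5) - .5 * binom.pmf(lo, n, .5))
            assert res["p"][0] == pytest.approx(midp, rel=0.10)

    def test_group_swap_negates_effect_and_preserves_p(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(100, (20, 3))
        b = rng.poisson(60, (20, 3))
        fwd = hr.nb_two_group_test(a, b, phi=0.05)
        rev = hr.nb_two_group_test(b, a, phi=0.05)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-8)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-10)

    def test_matches_statsmodels_glm_deviance(self):
        # independent route: statsmodels NB GLM with the same plug-in alpha
        import statsmodels.api as sm
        a = np.array([120, 95, 150], float)
        b = np.array([40, 55, 33], float)
        phi = 0.1
        res = hr.nb_two_group_test(a, b, phi=phi)
        y = np.concatenate([a, b])
        X = sm.add_constant(np.r_[np.ones(3), np.zeros(3)])
        fam = sm.families.NegativeBinomial(alpha=phi)
        alt = sm.GLM(y, X, family=fam).fit()
        null = sm.GLM(y, np.ones((6, 1)), family=fam).fit()
        p_sm = chi2.sf(null.deviance - alt.deviance, 1)
        assert res["p"][0] == pytest.approx(p_sm, rel=1e-6)

    def test_library_size_offsets_remove_depth_effect(self):
        res = hr.nb_two_group_test([200, 200, 200], [100, 100, 100],
                                   lib_sizes=([2e6] * 3, [1e6] * 3), phi=0.05)
        assert res["log2fc"][0] == pytest.approx(0.0, abs=1e-6)
        assert res["p"][0] > 0.9

    def test_negative_dispersion_errors(self):
        with pytest.raises(ValueError):
            hr.nb_two_group_test([1, 2, 3], [1, 2, 3], phi=-1)


class TestBinomialRatioTest:
    def test_equal_ratios_are_null_by_construction(self):
        res = hr.binomial_ratio_test([60, 80, 100], [30, 40, 50],
                                     [600, 500, 400], [300, 250, 200])
        assert abs(res["log2fc"][0]) < 1e-9
        assert res["p"][0] >= 0.99

    def test_parental_imbalance_with_balanced_hybrid_is_trans(self):
        # parents 8:1, hybrid 1:1 -> T = Rp - Rh = 3
        res = hr.binomial_ratio_test([400, 400, 400], [400, 400, 400],
                                     [800, 800, 800], [100, 100, 100])
        assert res["log2fc"][0] == pytest.approx(3.0, abs=0.01)
        assert res["p"][0] < 1e-6

    def test_plain_wald_agrees_with_two_proportion_lrt_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a1 = rng.poisson(110, 3); a2 = rng.poisson(90, 3)
            p1 = rng.poisson(130, 3); p2 = rng.poisson(80, 3)
            res = hr.binomial_ratio_test(a1, a2, p1, p2,
                                         dispersion_adjust=False)
            xh, nh = a1.sum(), a1.sum() + a2.sum()
            xp, npp = p1.sum(), p1.sum() + p2.sum()
            def ll(x, n, pr):
                return x * np.log(pr) + (n - x) * np.log(1 - pr)
            p_pool = (xh + xp) / (nh + npp)
            dev = 2 * (ll(xh, nh, xh / nh) + ll(xp, npp, xp / npp)
                       - ll(xh, nh, p_pool) - ll(xp, npp, p_pool))
            p_lrt = chi2.sf(dev, 1)
            if p_lrt > 1e-12:
                assert res["p"][0] == pytest.approx(p_lrt, rel=0.15)

    def test_overdispersed_replicates_raise_p_via_quasi_scale(self):
        # heterogeneous replicate ratios: the quasi-binomial scale must
        # make the default test more conservative than the plain Wald
        a1 = np.array([150, 60, 110]); a2 = np.array([60, 140, 95])
        p1 = np.array([220, 90, 160]); p2 = np.array([60, 180, 110])
        plain = hr.binomial_ratio_test(a1, a2, p1, p2,
                                       dispersion_adjust=False)
        quasi = hr.binomial_ratio_test(a1, a2, p1, p2)
        assert quasi["p"][0] > plain["p"][0]
        assert quasi["log2fc"][0] == plain["log2fc"][0]

    def test_matches_statsmodels_binomial_glm(self):
        import statsmodels.api as sm
        a1 = np.array([80, 95, 110]); a2 = np.array([100, 90, 105])
        p1 = np.array([240, 200, 260]); p2 = np.array([60, 75, 50])
        res = hr.binomial_ratio_test(a1, a2, p1, p2, dispersion_adjust=False)
        succ = np.array([a1.sum(), p1.sum()], float)
        tot = np.array([(a1 + a2).sum(), (p1 + p2).sum()], float)
        X = sm.add_constant(np.array([1.0, 0.0]))
        fit = sm.GLM(np.column_stack([succ, tot - succ]), X,
                     family=sm.families.Binomial()).fit()
        assert res["log2fc"][0] == pytest.approx(-fit.params[1] / np.log(2),
                                                 rel=1e-6)
        assert res["p"][0] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_separation_falls_back_to_lrt(self):
        res = hr.binomial_ratio_test([10, 10, 10], [0, 0, 0],
                                     [5, 5, 5], [5, 5, 5])
        assert np.isfinite(res["p"][0])
        assert res["p"][0] < 0.05


class TestFdrAndSignificance:
    def test_bh_step_up_on_worked_example(self):
        # step-up by hand: q_i = min_{j>=i} p_(j) * m / j
        np.testing.assert_allclose(hr.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert hr.bh_fdr([0.5])[0] == 0.5

    def test_outputs_in_unit_interval_and_rank_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = hr.bh_fdr(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            hr.bh_fdr([0.5, 1.5])

    @pytest.mark.parametrize("q,lfc,expected", [
        (0.01, 2.0, True),    # passes both clauses at the defaults
        (0.01, 1.0, False),   # fold change below 1.25
        (0.20, 3.0, False),   # FDR clause fails
    ])
    def test_dual_significance_rule(self, q, lfc, expected):
        df = pd.DataFrame({"log2fc": [lfc], "p": [q]})
        out = hr.call_significance(df, StatConfig())
        # with a single p-value, q == p
        assert bool(out["significant"][0]) is expected


def test_null_simulation_controls_significant_fraction():
    """No-effect NB data at n=3 keeps the significant ED fraction below
    alpha plus Monte-Carlo error."""
    rng = np.random.default_rng(12)
    phi, n = 0.1, 2000
    mu = 300 * np.exp(rng.normal(0, 1, n))
    draw = lambda: rng.poisson(rng.gamma(1 / phi, np.outer(mu, np.ones(3)) * phi))
    res = hr.nb_two_group_test(draw(), draw(), phi=phi)
    out = hr.call_significance(res, StatConfig())
    se = np.sqrt(0.05 * 0.95 / n)
    assert out["significant"].mean() <= 0.05 + 3 * se
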