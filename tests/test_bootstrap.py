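import itertools

import numpy as np
import pytest

import fdrboot as fb
from fdrboot.localfdr import SignificanceSet

SEED = 20150804


def brute_force_fdrB(p, G, fdr_star):
    """Exhaustive flanking-scan oracle for the per-feature imputation.

    Loops over every original feature; direct assignment when the
    feature was resampled, otherwise scans all resampled P-values for
    the flanks and interpolates, with the (0,0)/(1,1) boundary rules.
    """
    m = len(p)
    p_star = [p[g] for g in G]
    out = np.empty(m)
    for i in range(m):
        hits = [j for j in range(m) if G[j] == i]
        if hits:
            out[i] = fdr_star[hits[0]]
            continue
        left = [j for j in range(m) if p_star[j] <= p[i]]
        right = [j for j in range(m) if p_star[j] >= p[i]]
        if left:
            pmax = max(p_star[j] for j in left)
            u = [j for j in left if p_star[j] == pmax][0]
            pL, fL = p_star[u], fdr_star[u]
        else:
            pL, fL = 0.0, 0.0
        if right:
            pmin = min(p_star[j] for j in right)
            v = [j for j in right if p_star[j] == pmin][0]
            pR, fR = p_star[v], fdr_star[v]
        else:
            pR, fR = 1.0, 1.0
        if pL == pR:
            out[i] = fR
        else:
            out[i] = (fR * (p[i] - pL) + fL * (pR - p[i])) / (pR - pL)
    return out


class TestDrawIndices:
    def test_single_feature_always_itself(self, rng):
        assert fb.draw_bootstrap_indices(1, rng) == np.array([0])

    def test_missing_fraction_matches_classical_rate(self):
        # P(feature absent from a resample) = (1 - 1/m)^m ~ e^{-1}
        rng = np.random.default_rng(SEED)
        m, n_rep = 2000, 500
        frac = np.empty(n_rep)
        for k in range(n_rep):
            G = fb.draw_bootstrap_indices(m, rng)
            frac[k] = 1.0 - np.unique(G).size / m
        assert abs(frac.mean() - np.exp(-1.0)) < 0.01

    def test_fixed_seed_reproduces(self):
        g1 = fb.draw_bootstrap_indices(100, np.random.default_rng(SEED))
        g2 = fb.draw_bootstrap_indices(100, np.random.default_rng(SEED))
        np.testing.assert_array_equal(g1, g2)


class TestRefit:
    def test_identity_resample_returns_original_fdr(self, mixture_fit):
        pv, fit, _ = mixture_fit
        np.testing.assert_array_equal(fb.refit_star_fdr(pv.p), fit.fdr)

    def test_all_equal_pvalues_share_fdr(self):
        out = fb.refit_star_fdr(np.full(50, 0.2))
        assert np.unique(out).size == 1
        assert np.all((out >= 0) & (out <= 1))


class TestFlanksAndInterpolation:
    def test_unique_flanks(self, rng):
        fl = fb.find_flanks(0.3, [0.1, 0.5], [0.2, 0.6], rng)
        assert (fl.p_L, fl.fdr_L, fl.p_R, fl.fdr_R) == (0.1, 0.2, 0.5, 0.6)

    def test_empty_left_flank_uses_origin(self, rng):
        fl = fb.find_flanks(0.05, [0.1], [0.2], rng)
        assert (fl.p_L, fl.fdr_L) == (0.0, 0.0)
        assert (fl.p_R, fl.fdr_R) == (0.1, 0.2)

    def test_empty_right_flank_uses_unit_anchor(self, rng):
        fl = fb.find_flanks(0.9, [0.1], [0.2], rng)
        assert (fl.p_R, fl.fdr_R) == (1.0, 1.0)

    def test_exact_match_lands_in_both_flanks(self, rng):
        fl = fb.find_flanks(0.3, [0.1, 0.3, 0.6], [0.1, 0.4, 0.7], rng)
        assert fl.p_L == fl.p_R == 0.3
        assert fl.fdr_L == fl.fdr_R == 0.4

    def test_hand_evaluated_interpolation(self):
        fl = fb.FlankingPair(p_L=0.1, fdr_L=0.2, p_R=0.5, fdr_R=0.6)
        assert fb.interpolate_missing_fdr(0.3, fl) == pytest.approx(0.4)

    def test_degenerate_flanks_return_right_value(self):
        fl = fb.FlankingPair(p_L=0.3, fdr_L=0.7, p_R=0.3, fdr_R=0.7)
        assert fb.interpolate_missing_fdr(0.3, fl) == 0.7

    def test_left_boundary_interpolation(self):
        fl = fb.FlankingPair(p_L=0.0, fdr_L=0.0, p_R=0.1, fdr_R=0.2)
        assert fb.interpolate_missing_fdr(0.05, fl) == pytest.approx(0.1)

    def test_interpolation_stays_between_flank_values(self, rng):
        for _ in range(200):
            pL, pR = np.sort(rng.uniform(size=2))
            fL, fR = rng.uniform(size=2)
            p_i = rng.uniform(pL, pR)
            val = fb.interpolate_missing_fdr(
                p_i, fb.FlankingPair(pL, fL, pR, fR))
            assert min(fL, fR) - 1e-12 <= val <= max(fL, fR) + 1e-12


class TestImputation:
    def test_identity_resample_reproduces_fit(self, mixture_fit):
        pv, fit, _ = mixture_fit
        fdrB = fb.impute_all_fdrB(pv, np.arange(pv.m))
        np.testing.assert_array_equal(fdrB, fit.fdr)

    def test_duplicate_draws_well_defined(self):
        pv = fb.validate_pvalues(list("abcd"), [0.1, 0.2, 0.3, 0.4])
        fdrB = fb.impute_all_fdrB(pv, [1, 1, 1, 3],
                                  fdr_star=[0.2, 0.2, 0.2, 0.5])
        assert fdrB[1] == 0.2 and fdrB[3] == 0.5

    def test_inconsistent_fdr_star_rejected(self):
        pv = fb.validate_pvalues(list("abc"), [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="share one fdr"):
            fb.impute_all_fdrB(pv, [0, 0, 2], fdr_star=[0.1, 0.9, 0.5])

    @pytest.mark.parametrize("m", [3, 4])
    def test_matches_brute_force_on_all_resample_patterns(self, m):
        rng = np.random.default_rng(SEED)
        p = np.sort(rng.uniform(size=m))
        pv = fb.validate_pvalues([f"g{i}" for i in range(m)], p)
        for G in itertools.product(range(m), repeat=m):
            G = np.array(G)
            fdr_star = 0.1 + 0.8 * p[G]  # fixed deterministic fdr*
            expected = brute_force_fdrB(p, G, fdr_star)
            got = fb.impute_all_fdrB(pv, G, fdr_star=fdr_star)
            np.testing.assert_array_equal(got, expected)

    def test_matches_brute_force_on_sampled_patterns_m8(self):
        rng = np.random.default_rng(SEED)
        m = 8
        p = np.sort(rng.uniform(size=m))
        pv = fb.validate_pvalues([f"g{i}" for i in range(m)], p)
        for _ in range(2000):
            G = rng.integers(0, m, size=m)
            fdr_star = np.sqrt(p[G])
            expected = brute_force_fdrB(p, G, fdr_star)
            got = fb.impute_all_fdrB(pv, G, fdr_star=fdr_star)
            np.testing.assert_array_equal(got, expected)

    def test_imputed_values_always_within_unit_interval(self, mixture_fit):
        pv, _, _ = mixture_fit
        rng = np.random.default_rng(SEED)
        for _ in range(5):
            G = fb.draw_bootstrap_indices(pv.m, rng)
            fdrB = fb.impute_all_fdrB(pv, G, rng=rng)
            assert np.all((fdrB >= 0.0) & (fdrB <= 1.0))


class TestReplicateSummaries:
    def test_qB_is_arithmetic_mean_over_S(self, rng):
        S = SignificanceSet(alpha=0.05, members=np.array([0, 1, 2]))
        fdrB = np.array([0.0, 0.1, 0.2, 0.9])
        qB, _ = fb.replicate_summaries(fdrB, S, rng)
        assert qB == pytest.approx(0.1)

    def test_bernoulli_extremes_are_deterministic(self, rng):
        S = SignificanceSet(alpha=0.05, members=np.array([0, 1]))
        _, fdp0 = fb.replicate_summaries(np.array([0.0, 0.0, 0.5]), S, rng)
        _, fdp1 = fb.replicate_summaries(np.array([1.0, 1.0, 0.5]), S, rng)
        assert fdp0 == 0.0 and fdp1 == 1.0

    def test_empty_set_refused(self, rng):
        S = SignificanceSet(alpha=0.05, members=np.array([], dtype=int))
        with pytest.raises(ValueError, match="no significant features"):
            fb.replicate_summaries(np.array([0.1, 0.2]), S, rng)

    def test_single_feature_set_allowed(self, rng):
        S = SignificanceSet(alpha=0.05, members=np.array([1]))
        qB, fdpB = fb.replicate_summaries(np.array([0.5, 0.3]), S, rng)
        assert qB == pytest.approx(0.3)
        assert fdpB in (0.0, 1.0)


class TestRunBootstrap:
    def test_same_seed_bit_identical(self, mixture_fit):
        pv, fit, S = mixture_fit
        a = fb.run_bootstrap(pv, fit, S, B=50, seed=SEED)
        b = fb.run_bootstrap(pv, fit, S, B=50, seed=SEED)
        np.testing.assert_array_equal(a.qB, b.qB)
        np.testing.assert_array_equal(a.fdpB, b.fdpB)
        np.testing.assert_array_equal(a.se_lfdr, b.se_lfdr)
        np.testing.assert_array_equal(a.ci_lfdr, b.ci_lfdr)

    def test_all_equal_pvalues_give_zero_ses(self):
        pv = fb.validate_pvalues([f"g{i}" for i in range(30)],
                                 np.full(30, 0.01))
        fit = fb.local_fdr(pv)
        S = SignificanceSet(alpha=0.05, members=np.arange(30))
        summ = fb.run_bootstrap(pv, fit, S, B=100, seed=SEED)
        assert summ.se_q == 0.0
        assert np.all(summ.se_lfdr == 0.0)

    def test_summary_invariants(self, mixture_fit):
        pv, fit, S = mixture_fit
        summ = fb.run_bootstrap(pv, fit, S, B=200, seed=SEED)
        assert np.all(summ.se_lfdr >= 0.0)
        assert np.all(summ.ci_lfdr[:, 0] <= summ.ci_lfdr[:, 1])
        assert np.all((summ.ci_lfdr >= 0.0) & (summ.ci_lfdr <= 1.0))
        assert summ.ci_q[0] <= summ.ci_q[1]
        assert 0.0 <= summ.ci_fdp[0] <= summ.ci_fdp[1] <= 1.0
        # every replicate FDP is an integer count over r
        counts = summ.fdpB * S.r
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_rejects_degenerate_requests(self, mixture_fit):
        pv, fit, S = mixture_fit
        with pytest.raises(ValueError, match="B >= 2"):
            fb.run_bootstrap(pv, fit, S, B=1, seed=SEED)
        empty = SignificanceSet(alpha=0.05, members=np.array([], dtype=int))
        with pytest.raises(ValueError, match="no significant features"):
            fb.run_bootstrap(pv, fit, empty, B=10, seed=SEED)

    def test_se_insensitive_to_feature_order(self):
        """Permuting the input features leaves the SEs statistically alike."""
        t = fb.simulate_pvalues(fb.MixtureParams(m=400), seed=SEED)
        pv = t.pvalue_vector()
        fit = fb.local_fdr(pv)
        S = fb.significant_set(fit)
        a = fb.run_bootstrap(pv, fit, S, B=2000, seed=SEED)
        perm = np.random.default_rng(1).permutation(pv.m)
        pv2 = fb.validate_pvalues(pv.ids[perm], pv.p[perm])
        fit2 = fb.local_fdr(pv2)
        S2 = fb.significant_set(fit2)
        b = fb.run_bootstrap(pv2, fit2, S2, B=2000, seed=SEED + 1)
        assert S2.r == S.r
        # q SE is a smooth functional: agree within Monte-Carlo noise
        assert abs(a.se_q - b.se_q) <= 0.2 * max(a.se_q, b.se_q)

    def test_replicate_object_is_internally_consistent(self, mixture_fit):
        pv, fit, S = mixture_fit
        rep = fb.make_replicate(pv, S, np.random.default_rng(SEED))
        np.testing.assert_array_equal(rep.p_star, pv.p[rep.G])
        in_G = np.zeros(pv.m, bool)
        in_G[rep.G] = True
        np.testing.assert_array_equal(rep.missing, np.flatnonzero(~in_G))
        assert rep.qB == pytest.approx(rep.fdrB[S.members].mean())
        assert 0.0 <= rep.fdpB <= 1.0
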