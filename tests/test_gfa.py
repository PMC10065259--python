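import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import momfa
from momfa import gfa
from momfa.types import FactorFit, MomfaError


def single_view_ps(y, name="v"):
    """Wrap a feature-by-profile matrix as a fully observed ProfileSet."""
    d, n = y.shape
    profiles = pd.DataFrame({
        "mouse_id": [f"m{i}" for i in range(n)],
        "group": ["WT"] * n,
        "week": [6] * n,
    })
    view = momfa.OmicView(name, [f"f{i}" for i in range(d)],
                          [f"p{i}" for i in range(n)], y, "normalized")
    return momfa.ProfileSet(profiles=profiles, views={name: view},
                            observed={name: np.ones(n, dtype=bool)})


def manual_fit(z, w_by_view, feature_ids=None):
    """Hand-built FactorFit for testing the fit-independent operations."""
    k = z.shape[1]
    if feature_ids is None:
        feature_ids = {m: [f"f{i}" for i in range(w.shape[0])]
                       for m, w in w_by_view.items()}
    return FactorFit(
        Z=z, W=w_by_view,
        tau={m: np.ones(w.shape[0]) for m, w in w_by_view.items()},
        alpha={m: np.ones(k) for m in w_by_view},
        feature_ids=feature_ids,
        elbo_trace=[0.0], elbo_history=[0.0],
        k_active=k, seed=0, threshold=0.01,
    )


class TestFitGfa:
    def test_noiseless_rank_one_recovered(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(30)
        w = rng.standard_normal(25)
        y = np.outer(w, z)
        ps = single_view_ps(y)
        fit = momfa.fit_gfa(ps, k_init=1, threshold=0.01, seed=1)
        recon = momfa.reconstruct(fit, "v")
        rel = np.linalg.norm(recon - y) / np.linalg.norm(y)
        assert rel < 1e-3
        ve = momfa.variance_explained(fit, ps)
        assert ve.per_view_total["v"] > 0.999

    def test_true_factor_count_and_scores_recovered(self):
        # 2 views, 3 true factors each explaining >= 20% of the overall
        # variance, with distinct per-view activity (which is what makes
        # the factor axes identifiable); overspecified k_init with a
        # small pruning threshold
        shares = {"a": np.array([0.60, 0.05, 0.25]),
                  "b": np.array([0.05, 0.60, 0.25])}
        ps, z_true = momfa.make_gaussian_study(
            120, {"a": 80, "b": 60}, shares, seed=21
        )
        fit = momfa.fit_gfa(ps, k_init=10, threshold=0.01, seed=3)
        assert fit.k_active == 3
        pairs = gfa.match_factors(z_true, fit.Z)
        assert all(r >= 0.9 for _, _, r in pairs)

    @pytest.mark.parametrize("seed", range(10))
    def test_pure_noise_collapses(self, seed):
        rng = np.random.default_rng(1000 + seed)
        y = rng.standard_normal((40, 60))
        ps = single_view_ps(y)
        fit = momfa.fit_gfa(ps, k_init=6, threshold=0.05, seed=seed)
        assert fit.k_active <= 1
        ve = momfa.variance_explained(fit, ps)
        assert ve.overall_total < 0.05

    def test_elbo_trace_monotone(self, recovery_study):
        ps, _ = recovery_study
        for seed in (0, 7, 23):
            fit = momfa.fit_gfa(ps, k_init=8, threshold=0.03, seed=seed)
            diffs = np.diff(fit.elbo_trace)
            assert np.all(diffs >= -1e-6)

    def test_bit_identical_under_same_seed(self, recovery_study):
        ps, _ = recovery_study
        a = momfa.fit_gfa(ps, k_init=6, threshold=0.05, seed=9, max_iter=80)
        b = momfa.fit_gfa(ps, k_init=6, threshold=0.05, seed=9, max_iter=80)
        np.testing.assert_array_equal(a.Z, b.Z)
        for name in a.view_names:
            np.testing.assert_array_equal(a.W[name], b.W[name])
        assert a.elbo_trace == b.elbo_trace

    def test_k_init_clamped_with_warning(self):
        rng = np.random.default_rng(2)
        ps = single_view_ps(rng.standard_normal((5, 8)))
        with pytest.warns(UserWarning, match="clamp"):
            fit = momfa.fit_gfa(ps, k_init=50, threshold=0.05, seed=0,
                                max_iter=30)
        assert fit.k_active <= 5

    def test_unobserved_view_rejected(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((4, 6))
        ps = single_view_ps(y)
        ps.observed["v"][:] = False
        with pytest.raises(MomfaError, match="no observed"):
            momfa.fit_gfa(ps, 2, 0.05, 0)


class TestElbo:
    def test_equals_last_trace_element(self, recovery_study):
        ps, _ = recovery_study
        fit = momfa.fit_gfa(ps, k_init=5, threshold=0.05, seed=4, max_iter=60)
        assert momfa.elbo(fit, ps) == pytest.approx(fit.elbo_trace[-1],
                                                    rel=1e-12)

    def test_dimension_mismatch_rejected(self, recovery_study):
        ps, _ = recovery_study
        fit = momfa.fit_gfa(ps, k_init=3, threshold=0.05, seed=4, max_iter=30)
        rng = np.random.default_rng(0)
        other = single_view_ps(rng.standard_normal((4, 9)))
        with pytest.raises(MomfaError):
            momfa.elbo(fit, other)

    def test_deterministic_under_rescaling(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((10, 12))
        e1 = momfa.elbo(momfa.fit_gfa(single_view_ps(y), 2, 0.05, 7,
                                      max_iter=40), single_view_ps(y))
        e2 = momfa.elbo(momfa.fit_gfa(single_view_ps(2 * y), 2, 0.05, 7,
                                      max_iter=40), single_view_ps(2 * y))
        e1b = momfa.elbo(momfa.fit_gfa(single_view_ps(y), 2, 0.05, 7,
                                       max_iter=40), single_view_ps(y))
        assert e1 != e2
        assert e1 == e1b

    def test_matches_quadrature_oracle(self):
        # tiny instance: the analytic bound must agree with a numerical
        # evaluation of every expectation term under the fitted posterior
        rng = np.random.default_rng(6)
        z = rng.standard_normal(4)
        w = rng.standard_normal(3)
        y = np.outer(w, z) + 0.3 * rng.standard_normal((3, 4))
        ps = single_view_ps(y)
        fit = momfa.fit_gfa(ps, k_init=1, threshold=0.01, seed=8, max_iter=40)
        assert fit.k_active == 1
        analytic = momfa.elbo(fit, ps)
        numeric = _elbo_quadrature_oracle(fit.qstate)
        assert numeric == pytest.approx(analytic, abs=1e-4)


def _elbo_quadrature_oracle(st):
    """Numerically integrate each ELBO expectation term (K=1, one view)."""
    gh_x, gh_w = np.polynomial.hermite.hermgauss(40)

    def e_gauss(mean, sd, f):
        return float(np.sum(gh_w / np.sqrt(np.pi)
                            * f(mean + np.sqrt(2) * sd * gh_x)))

    def e_gamma(shape, rate, f):
        dist = stats.gamma(a=shape, scale=1.0 / rate)
        val, _ = integrate.quad(lambda x: dist.pdf(x) * f(x), 0, np.inf,
                                limit=200)
        return val

    v = st.views[0]
    d, n = v.Y.shape
    a_hat = gfa.A0 + 0.5 * d
    c_hat = gfa.C0 + 0.5 * v.n_obs
    mz = st.mz[:, 0]
    sz = np.sqrt(st.Sz[0][0, 0])
    mw = st.mw[0][:, 0]
    sw = np.sqrt(st.Sw[0][:, 0, 0])

    total = 0.0
    # likelihood: E[log N(y | z w, 1/tau)] per observed entry
    for di in range(d):
        e_log_tau = e_gamma(c_hat, st.d_tau[0][di], np.log)
        e_tau = e_gamma(c_hat, st.d_tau[0][di], lambda x: x)
        for ni in range(n):
            e_sq = e_gauss(
                mz[ni], sz,
                lambda zz: np.array([
                    e_gauss(mw[di], sw[di],
                            lambda ww: (v.Y[di, ni] - z_ * ww) ** 2)
                    for z_ in np.atleast_1d(zz)
                ]),
            )
            total += 0.5 * e_log_tau - 0.5 * np.log(2 * np.pi) - 0.5 * e_tau * e_sq
    # z prior minus entropy
    for ni in range(n):
        total += e_gauss(mz[ni], sz, lambda x: stats.norm.logpdf(x))
        total -= e_gauss(mz[ni], sz,
                         lambda x: stats.norm.logpdf(x, mz[ni], sz))
    # w prior (expectation over alpha too) minus entropy
    e_log_alpha = e_gamma(a_hat, st.b_alpha[0][0], np.log)
    e_alpha = e_gamma(a_hat, st.b_alpha[0][0], lambda x: x)
    for di in range(d):
        e_w2 = e_gauss(mw[di], sw[di], lambda x: x**2)
        total += 0.5 * e_log_alpha - 0.5 * np.log(2 * np.pi) - 0.5 * e_alpha * e_w2
        total -= e_gauss(mw[di], sw[di],
                         lambda x: stats.norm.logpdf(x, mw[di], sw[di]))
    # alpha and tau priors minus entropies
    prior_a = stats.gamma(a=gfa.A0, scale=1.0 / gfa.B0)
    q_a = stats.gamma(a=a_hat, scale=1.0 / st.b_alpha[0][0])
    total += e_gamma(a_hat, st.b_alpha[0][0],
                     lambda x: prior_a.logpdf(x) - q_a.logpdf(x))
    prior_t = stats.gamma(a=gfa.C0, scale=1.0 / gfa.D0)
    for di in range(d):
        q_t = stats.gamma(a=c_hat, scale=1.0 / st.d_tau[0][di])
        total += e_gamma(c_hat, st.d_tau[0][di],
                         lambda x: prior_t.logpdf(x) - q_t.logpdf(x))
    return total


class TestVarianceExplained:
    def test_exact_rank_one_gives_unity(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((12, 1))
        w = rng.standard_normal((9, 1))
        y = (z @ w.T).T
        ps = single_view_ps(y)
        fit = manual_fit(z, {"v": w})
        ve = momfa.variance_explained(fit, ps)
        assert ve.per_factor.loc["v", "LF1"] == pytest.approx(1.0)
        assert ve.per_view_total["v"] == pytest.approx(1.0)
        assert ve.overall_total == pytest.approx(1.0)

    def test_zero_loading_factor_explains_nothing(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((10, 2))
        w = np.column_stack([rng.standard_normal(6), np.zeros(6)])
        y = (z @ w.T).T
        fit = manual_fit(z, {"v": w})
        ve = momfa.variance_explained(fit, single_view_ps(y))
        assert ve.per_factor.loc["v", "LF2"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_decomposition_sums_to_total(self):
        # orthogonal scores and loadings: per-factor R2 values add up
        # exactly to the full-model total (Pythagoras)
        z, _ = np.linalg.qr(np.random.default_rng(9).standard_normal((20, 3)))
        w, _ = np.linalg.qr(np.random.default_rng(10).standard_normal((15, 3)))
        w = w * np.array([3.0, 2.0, 1.0])
        y = (z @ w.T).T
        fit = manual_fit(z, {"v": w})
        ve = momfa.variance_explained(fit, single_view_ps(y))
        assert ve.per_factor.loc["v"].sum() == pytest.approx(
            ve.per_view_total["v"], abs=1e-6
        )

    def test_invariant_to_permutation_and_sign(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal((14, 3))
        w = rng.standard_normal((10, 3))
        y = (z @ w.T).T + 0.1 * rng.standard_normal((10, 14))
        ps = single_view_ps(y)
        base = momfa.variance_explained(manual_fit(z, {"v": w}), ps)
        perm = [2, 0, 1]
        flip = np.array([1.0, -1.0, -1.0])
        z2 = z[:, perm] * flip
        w2 = w[:, perm] * flip
        other = momfa.variance_explained(manual_fit(z2, {"v": w2}), ps)
        assert other.per_view_total["v"] == pytest.approx(
            base.per_view_total["v"], abs=1e-12
        )
        assert sorted(other.per_factor.loc["v"]) == pytest.approx(
            sorted(base.per_factor.loc["v"]), abs=1e-12
        )


class TestReconstruct:
    def test_unknown_view_rejected(self):
        fit = manual_fit(np.zeros((3, 1)), {"v": np.zeros((2, 1))})
        with pytest.raises(MomfaError, match="unknown view"):
            momfa.reconstruct(fit, "nope")

    def test_masked_profiles_imputed(self):
        # rank-1 two-view data; two profiles hidden from view "a" are
        # imputed from the shared factor learned via view "b"
        rng = np.random.default_rng(12)
        z = rng.standard_normal(40)
        wa = rng.standard_normal(30)
        wb = rng.standard_normal(25)
        ya = np.outer(wa, z)
        yb = np.outer(wb, z)
        mask_a = np.ones(40, dtype=bool)
        mask_a[[3, 17]] = False
        ya_obs = ya.copy()
        ya_obs[:, ~mask_a] = np.nan
        profiles = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(40)],
            "group": ["WT"] * 40, "week": [6] * 40,
        })
        views = {
            "a": momfa.OmicView("a", [f"a{i}" for i in range(30)],
                                [f"p{i}" for i in range(40)], ya_obs,
                                "normalized"),
            "b": momfa.OmicView("b", [f"b{i}" for i in range(25)],
                                [f"p{i}" for i in range(40)], yb,
                                "normalized"),
        }
        ps = momfa.ProfileSet(profiles=profiles, views=views,
                              observed={"a": mask_a,
                                        "b": np.ones(40, dtype=bool)})
        fit = momfa.fit_gfa(ps, k_init=1, threshold=0.01, seed=13)
        recon = momfa.reconstruct(fit, "a")
        truth = ya[:, ~mask_a]
        rel = np.abs(recon[:, ~mask_a] - truth) / np.abs(truth)
        assert np.median(rel) < 0.05

def test_match_factors_greedy_assignment():
    rng = np.random.default_rng(14)
    z = rng.standard_normal((50, 3))
    perm = [2, 0, 1]
    z_est = z[:, perm] * np.array([-1.0, 1.0, -1.0])
    pairs = gfa.match_factors(z, z_est)
    assert [(i, j) for i, j, _ in pairs] == [(0, 1), (1, 2), (2, 0)]
    assert all(r > 0.999 for _, _, r in pairs)
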