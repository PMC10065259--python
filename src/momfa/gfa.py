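"""Multi-view factor decomposition by mean-field variational inference.

The model is Bayesian group factor analysis: for each view m with
feature-by-profile data Y_m,

    y_nd^m | z_n, w_d^m, tau_d^m  ~  N(z_n . w_d^m, 1 / tau_d^m)
    z_nk                          ~  N(0, 1)
    w_dk^m | alpha_k^m            ~  N(0, 1 / alpha_k^m)
    alpha_k^m                     ~  Gamma(a0, b0)
    tau_d^m                       ~  Gamma(c0, d0)

with the Gaussian likelihood evaluated over observed profiles only.
The per-(view, factor) ARD precisions alpha shrink unneeded factors;
on top of that, factors whose variance-explained fraction falls below a
user threshold in every view are dropped during fitting, mirroring the
component-dropping behaviour of multi-omics factor analysis tools.

Inference is coordinate-ascent mean-field VB with conjugate updates
cycled (Z, W, alpha, tau).  Each cycle provably does not decrease the
evidence lower bound, so the ELBO trace is monotone at fixed model
dimension; pruning changes the dimension, after which the trace restarts
(the full history is kept separately).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .types import FactorFit, MomfaError, ProfileSet, VarianceExplained

log = logging.getLogger("momfa")

# flat conjugate hyperpriors
A0 = B0 = 1e-3  # ARD Gamma(shape, rate)
C0 = D0 = 1e-3  # noise-precision Gamma(shape, rate)

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class _ViewData:
    name: str
    Y: np.ndarray          # D x N, unobserved columns zeroed
    obs: np.ndarray        # N bool
    sum_y2: np.ndarray     # per-feature sum of squares over observed profiles

    @property
    def d(self) -> int:
        return self.Y.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.obs.sum())


def _view_data(ps: ProfileSet) -> list[_ViewData]:
    out = []
    for name in ps.view_names:
        vals = ps.matrix(name)
        obs = ps.observed[name].copy()
        if not obs.any():
            raise MomfaError(f"view {name!r} has no observed profiles")
        y = np.nan_to_num(vals, nan=0.0).astype(float)
        y[:, ~obs] = 0.0
        if np.isnan(vals[:, obs]).any():
            raise MomfaError(
                f"view {name!r} has NaN entries inside observed profiles"
            )
        out.append(_ViewData(name, y, obs, (y**2).sum(axis=1)))
    return out


class _VBState:
    """Mutable variational state over all views."""

    def __init__(self, views: list[_ViewData], n: int, k: int, seed: int):
        self.views = views
        self.n = n
        self.k = k
        rng = np.random.default_rng(seed)

        # init Z from the SVD of the concatenated views + seed-dependent noise
        stacked = np.vstack([v.Y for v in views])
        _, s, vt = np.linalg.svd(stacked, full_matrices=False)
        kk = min(k, len(s))
        z0 = vt[:kk].T * np.sqrt(s[:kk])[None, :]
        z0 = z0 / max(np.abs(z0).max(), 1e-12)
        self.mz = np.zeros((n, k))
        self.mz[:, :kk] = z0
        self.mz += 0.1 * rng.standard_normal((n, k))

        # per-observation-pattern Z covariance (whole-view missingness means
        # few distinct patterns)
        pat = np.stack([v.obs for v in views], axis=1)
        self.pattern_ids, self.pattern_of = np.unique(
            pat, axis=0, return_inverse=True
        )
        self.Sz = [np.eye(k) * 1e-3 for _ in range(len(self.pattern_ids))]

        self.mw = [
            (v.Y @ self.mz) / max(v.n_obs, 1) for v in views
        ]
        self.Sw = [np.tile(np.eye(k)[None] * 1e-3, (v.d, 1, 1)) for v in views]
        self.e_alpha = [np.ones(k) for _ in views]
        self.e_log_alpha = [np.zeros(k) for _ in views]
        self.b_alpha = [np.ones(k) for _ in views]
        self.e_tau = [np.ones(v.d) for v in views]
        self.e_log_tau = [np.zeros(v.d) for v in views]
        self.d_tau = [np.ones(v.d) for v in views]
        # caches filled during the update cycle
        self.Cz: list[np.ndarray] = []     # per view: sum of E[z z^T] over obs
        self.R: list[np.ndarray] = []      # per view: Y @ mz  (D x K)
        self.resid: list[np.ndarray] = []  # per view: per-feature E residual SS

    # -- coordinate updates -------------------------------------------------

    def update_z(self) -> None:
        k = self.k
        T = []
        for m, v in enumerate(self.views):
            t = (self.mw[m] * self.e_tau[m][:, None]).T @ self.mw[m]
            t += np.einsum("d,dij->ij", self.e_tau[m], self.Sw[m])
            T.append(t)
        B = np.zeros((self.n, k))
        for m, v in enumerate(self.views):
            B += (v.Y * self.e_tau[m][:, None]).T @ self.mw[m]
        for p, pat in enumerate(self.pattern_ids):
            prec = np.eye(k) + sum(T[m] for m in range(len(T)) if pat[m])
            self.Sz[p] = np.linalg.inv(prec)
        for p in range(len(self.pattern_ids)):
            rows = self.pattern_of == p
            self.mz[rows] = B[rows] @ self.Sz[p]
        # per-view second-moment sums
        self.Cz = []
        for m, v in enumerate(self.views):
            c = self.mz[v.obs].T @ self.mz[v.obs]
            for p, pat in enumerate(self.pattern_ids):
                cnt = int(np.sum((self.pattern_of == p) & v.obs))
                if cnt:
                    c = c + cnt * self.Sz[p]
            self.Cz.append(c)

    def update_w(self) -> None:
        self.R = []
        for m, v in enumerate(self.views):
            r = v.Y @ self.mz
            phi = self.e_tau[m][:, None, None] * self.Cz[m][None, :, :]
            phi += np.diag(self.e_alpha[m])[None, :, :]
            self.Sw[m] = np.linalg.inv(phi)
            self.mw[m] = self.e_tau[m][:, None] * np.einsum(
                "dij,dj->di", self.Sw[m], r
            )
            self.R.append(r)

    def update_alpha(self) -> None:
        for m, v in enumerate(self.views):
            a_hat = A0 + 0.5 * v.d
            eww_diag = np.einsum("dkk->k", self.Sw[m]) + (self.mw[m] ** 2).sum(axis=0)
            self.b_alpha[m] = B0 + 0.5 * eww_diag
            self.e_alpha[m] = a_hat / self.b_alpha[m]
            self.e_log_alpha[m] = digamma(a_hat) - np.log(self.b_alpha[m])

    def update_tau(self) -> None:
        self.resid = []
        for m, v in enumerate(self.views):
            eww = self.Sw[m] + self.mw[m][:, :, None] * self.mw[m][:, None, :]
            rss = (
                v.sum_y2
                - 2.0 * (self.R[m] * self.mw[m]).sum(axis=1)
                + np.einsum("ij,dij->d", self.Cz[m], eww)
            )
            rss = np.maximum(rss, 1e-12)
            c_hat = C0 + 0.5 * v.n_obs
            self.d_tau[m] = D0 + 0.5 * rss
            self.e_tau[m] = c_hat / self.d_tau[m]
            self.e_log_tau[m] = digamma(c_hat) - np.log(self.d_tau[m])
            self.resid.append(rss)

    def cycle(self) -> None:
        self.update_z()
        self.update_w()
        self.update_alpha()
        self.update_tau()

    # -- evidence lower bound ----------------------------------------------

    def elbo(self) -> float:
        total = 0.0
        # likelihood over observed entries (resid computed with current q)
        for m, v in enumerate(self.views):
            total += 0.5 * v.n_obs * (self.e_log_tau[m].sum() - v.d * LOG2PI)
            total -= 0.5 * float(self.e_tau[m] @ self.resid[m])
        # Z: E[log p] - E[log q]
        for p in range(len(self.pattern_ids)):
            rows = self.pattern_of == p
            cnt = int(rows.sum())
            if not cnt:
                continue
            tr_s = np.trace(self.Sz[p])
            sign, logdet = np.linalg.slogdet(self.Sz[p])
            mm = float((self.mz[rows] ** 2).sum())
            total += -0.5 * (cnt * tr_s + mm) + 0.5 * cnt * (logdet + self.k)
        # W and alpha, tau
        for m, v in enumerate(self.views):
            eww_diag = np.einsum("dkk->k", self.Sw[m]) + (self.mw[m] ** 2).sum(axis=0)
            total += 0.5 * v.d * float(
                (self.e_log_alpha[m]).sum()
            ) - 0.5 * float(self.e_alpha[m] @ eww_diag)
            sign, logdet = np.linalg.slogdet(self.Sw[m])
            total += 0.5 * float(logdet.sum()) + 0.5 * v.d * self.k
            a_hat = A0 + 0.5 * v.d
            total += float(
                np.sum(
                    A0 * np.log(B0) - gammaln(A0)
                    + (A0 - 1.0) * self.e_log_alpha[m]
                    - B0 * self.e_alpha[m]
                )
            )
            total -= float(
                np.sum(
                    a_hat * np.log(self.b_alpha[m]) - gammaln(a_hat)
                    + (a_hat - 1.0) * self.e_log_alpha[m] - a_hat
                )
            )
            c_hat = C0 + 0.5 * v.n_obs
            total += float(
                np.sum(
                    C0 * np.log(D0) - gammaln(C0)
                    + (C0 - 1.0) * self.e_log_tau[m]
                    - D0 * self.e_tau[m]
                )
            )
            total -= float(
                np.sum(
                    c_hat * np.log(self.d_tau[m]) - gammaln(c_hat)
                    + (c_hat - 1.0) * self.e_log_tau[m] - c_hat
                )
            )
        return float(total)

    # -- pruning ------------------------------------------------------------

    def factor_r2(self) -> np.ndarray:
        """Per-(view, factor) variance-explained fraction (posterior means)."""
        r2 = np.zeros((len(self.views), self.k))
        for m, v in enumerate(self.views):
            tot = float(v.sum_y2.sum())
            if tot <= 0:
                continue
            z2 = (self.mz[v.obs] ** 2).sum(axis=0)  # per factor
            for k in range(self.k):
                rss = (
                    tot
                    - 2.0 * float(self.R[m][:, k] @ self.mw[m][:, k])
                    + z2[k] * float(self.mw[m][:, k] @ self.mw[m][:, k])
                )
                r2[m, k] = 1.0 - rss / tot
        return r2

    def prune(self, threshold: float) -> int:
        """Drop factors under the variance threshold in every view.

        The last surviving factor is never dropped (a zero-factor model
        is not a useful fit; ARD already drives a redundant last factor
        to zero loadings).  Returns the number of factors removed.
        """
        r2 = self.factor_r2()
        keep = (r2 >= threshold).any(axis=0)
        if not keep.any():
            keep[int(np.argmax(r2.sum(axis=0)))] = True
        if keep.all():
            return 0
        idx = np.flatnonzero(keep)
        self.k = len(idx)
        self.mz = self.mz[:, idx]
        self.Sz = [s[np.ix_(idx, idx)] for s in self.Sz]
        for m in range(len(self.views)):
            self.mw[m] = self.mw[m][:, idx]
            self.Sw[m] = self.Sw[m][np.ix_(np.arange(self.Sw[m].shape[0]), idx, idx)]
            self.e_alpha[m] = self.e_alpha[m][idx]
            self.e_log_alpha[m] = self.e_log_alpha[m][idx]
            self.b_alpha[m] = self.b_alpha[m][idx]
        return int((~keep).sum())


def fit_gfa(
    ps: ProfileSet,
    k_init: int,
    threshold: float,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FactorFit:
    """Fit the multi-view factor model on a matched ProfileSet.

    Views are expected centered and unit-variance scaled.  Factors are
    pruned every 5 iterations (after a 10-iteration burn-in) when their
    variance-explained fraction is below ``threshold`` in all views;
    convergence is declared when the relative ELBO change stays below
    ``tol`` for two consecutive iterations.  The returned fit has its
    factors ordered by total variance explained and sign-fixed so each
    factor's largest-magnitude loading is positive.
    """
    views = _view_data(ps)
    n = ps.n_profiles
    max_k = min(n, min(v.d for v in views))
    if k_init > max_k:
        warnings.warn(
            f"k_init={k_init} exceeds min(data dimension)={max_k}; clamping",
            stacklevel=2,
        )
        k_init = max_k
    if k_init < 1:
        raise MomfaError("k_init must be >= 1")
    if not 0.0 < threshold < 1.0:
        raise MomfaError("threshold must lie in (0, 1)")

    st = _VBState(views, n, k_init, seed)
    trace: list[float] = []
    history: list[float] = []
    prev = -np.inf
    small_steps = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        st.cycle()
        e = st.elbo()
        trace.append(e)
        history.append(e)
        if it > 10 and it % 5 == 0:
            dropped = st.prune(threshold)
            if dropped:
                log.info("fit_gfa[seed=%d]: pruned %d factor(s) at iter %d -> K=%d",
                         seed, dropped, it, st.k)
                # model dimension changed: restart the monotone trace
                st.cycle()
                e = st.elbo()
                trace = [e]
                history.append(e)
                prev = -np.inf
                small_steps = 0
                continue
        if np.isfinite(prev):
            denom = max(abs(prev), 1.0)
            if abs(e - prev) / denom < tol:
                small_steps += 1
                if small_steps >= 2:
                    converged = True
                    prev = e
                    break
            else:
                small_steps = 0
        prev = e

    fit = _finalize(st, ps, seed, threshold, trace, history, it, converged)
    return fit


def _finalize(st, ps, seed, threshold, trace, history, n_iter, converged) -> FactorFit:
    # order factors by total variance explained, descending
    r2 = st.factor_r2()
    weights = np.array([v.sum_y2.sum() for v in st.views])
    totals = (np.clip(r2, 0.0, None) * weights[:, None]).sum(axis=0)
    order = np.argsort(-totals, kind="stable")
    mz = st.mz[:, order]
    mw = {v.name: st.mw[m][:, order] for m, v in enumerate(st.views)}
    # sign fix: the largest-|loading| feature across views goes positive
    for k in range(st.k):
        stacked = np.concatenate([mw[v.name][:, k] for v in st.views])
        j = int(np.argmax(np.abs(stacked)))
        if stacked[j] < 0:
            mz[:, k] *= -1.0
            for v in st.views:
                mw[v.name][:, k] *= -1.0
    fit = FactorFit(
        Z=mz,
        W=mw,
        tau={v.name: st.e_tau[m].copy() for m, v in enumerate(st.views)},
        alpha={v.name: st.e_alpha[m][order] for m, v in enumerate(st.views)},
        feature_ids={name: list(ps.views[name].feature_ids) for name in ps.view_names},
        elbo_trace=list(trace),
        elbo_history=list(history),
        k_active=st.k,
        seed=seed,
        threshold=threshold,
        n_iter=n_iter,
        converged=converged,
    )
    fit.qstate = st  # live variational state; not serialized
    return fit


def elbo(fit: FactorFit, ps: ProfileSet) -> float:
    """Evidence lower bound of a fit on its data.

    For a live fit the bound is recomputed from the full variational
    state (and equals the last element of ``elbo_trace``); a fit
    reloaded from disk no longer carries covariance state, so its
    recorded final ELBO is returned instead.
    """
    if fit.Z.shape[0] != ps.n_profiles:
        raise MomfaError(
            f"fit has {fit.Z.shape[0]} profiles, data has {ps.n_profiles}"
        )
    for name in fit.view_names:
        if name not in ps.views:
            raise MomfaError(f"view {name!r} missing from data")
        if ps.views[name].n_features != fit.W[name].shape[0]:
            raise MomfaError(f"feature-count mismatch in view {name!r}")
    st = getattr(fit, "qstate", None)
    if st is not None:
        return st.elbo()
    return fit.elbo_final


def reconstruct(fit: FactorFit, view_name: str) -> np.ndarray:
    """Model reconstruction Z W_m^T as feature-by-profile (imputes
    unobserved profiles)."""
    if view_name not in fit.W:
        raise MomfaError(f"unknown view {view_name!r}")
    if fit.k_active == 0:
        return np.zeros((fit.W[view_name].shape[0], fit.Z.shape[0]))
    return (fit.Z @ fit.W[view_name].T).T


def match_factors(z_true: np.ndarray, z_est: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedily pair true and estimated factors by max |Pearson r|.

    Factor models are identified only up to column permutation and sign,
    so recovery is judged after matching.  Returns (true_index,
    est_index, |r|) triples, one per true factor (or fewer if the
    estimate has fewer columns).
    """
    z_true = np.atleast_2d(np.asarray(z_true, dtype=float))
    z_est = np.atleast_2d(np.asarray(z_est, dtype=float))
    kt, ke = z_true.shape[1], z_est.shape[1]
    c = np.zeros((kt, ke))
    for i in range(kt):
        for j in range(ke):
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(z_true[:, i], z_est[:, j])[0, 1]
            c[i, j] = abs(r) if np.isfinite(r) else 0.0
    pairs = []
    work = c.copy()
    for _ in range(min(kt, ke)):
        i, j = np.unravel_index(int(np.argmax(work)), work.shape)
        pairs.append((int(i), int(j), float(c[i, j])))
        work[i, :] = -1.0
        work[:, j] = -1.0
    return sorted(pairs)


def variance_explained(fit: FactorFit, ps: ProfileSet) -> VarianceExplained:
    """Per-factor and total R-squared by view.

    R2(m, k) = 1 - sum_obs (Y_m - z_k w_mk^T)^2 / sum_obs Y_m^2, clipped
    to [0, 1]; per-view totals use the full reconstruction; the overall
    total weights views by observed entry counts.
    """
    per_factor = {}
    per_view_total = {}
    weights = {}
    for name in fit.view_names:
        y = ps.matrix(name)
        obs = ps.observed[name]
        yo = np.nan_to_num(y[:, obs], nan=0.0)
        tot = float((yo**2).sum())
        z = fit.Z[obs]
        w = fit.W[name]
        ks = []
        for k in range(fit.k_active):
            res = yo - np.outer(w[:, k], z[:, k])
            ks.append(1.0 - float((res**2).sum()) / tot if tot > 0 else 0.0)
        per_factor[name] = np.clip(ks, 0.0, 1.0)
        full = yo - w @ z.T
        per_view_total[name] = (
            float(np.clip(1.0 - (full**2).sum() / tot, 0.0, 1.0)) if tot > 0 else 0.0
        )
        weights[name] = yo.size
    cols = [f"LF{k + 1}" for k in range(fit.k_active)]
    pf = pd.DataFrame(per_factor, index=cols).T
    pv = pd.Series(per_view_total)
    wt = pd.Series(weights, dtype=float)
    overall = float((pv * wt).sum() / wt.sum())
    return VarianceExplained(
        per_factor=pf, per_view_total=pv, overall_total=overall, weights=wt
    )
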