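"""Relate latent factors to genotype group and time, and summarize loadings.

For each factor three least-squares models are fit on the profile
scores — ``score ~ group``, ``score ~ week`` and
``score ~ group * week`` (both treated as categorical) — reporting each
model's R-squared and the overall F-test of the two main-effect models
against the intercept-only model.  P-values are Benjamini-Hochberg
adjusted across factors, separately within the group family and the
week family.  Post-hoc pairwise contrasts between group pairs and week
pairs use pooled-variance t statistics from the one-way fit (Welch
available by flag), again BH-adjusted within each (factor, family).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import FactorFit, MomfaError

log = logging.getLogger("momfa")

P_FLOOR = 1e-300


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise MomfaError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise MomfaError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _one_way(y: np.ndarray, labels: np.ndarray) -> dict:
    """One-way ANOVA by sums of squares: R2, F, p (overall F-test)."""
    n = y.size
    levels, inverse = np.unique(labels, return_inverse=True)
    g = len(levels)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    counts = np.bincount(inverse)
    flagged = bool((counts < 2).any())
    if sst == 0 or g < 2 or n - g < 1:
        return {"r2": 0.0, "F": 0.0, "p": 1.0, "flag": True}
    means = np.bincount(inverse, weights=y) / counts
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = sst - ssb
    r2 = ssb / sst
    if ssw <= 0:
        # perfect separation: F overflows; report the numerical floor
        return {"r2": min(r2, 1.0), "F": np.inf, "p": P_FLOOR, "flag": flagged}
    f = (ssb / (g - 1)) / (ssw / (n - g))
    p = float(stats.f.sf(f, g - 1, n - g))
    return {"r2": r2, "F": float(f), "p": max(p, P_FLOOR), "flag": flagged}


def _interaction_r2(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """R2 of the saturated two-way cell-means model (main + interaction)."""
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    if sst == 0:
        return 0.0
    cells = pd.Series(y).groupby([pd.Series(a), pd.Series(b)]).transform("mean")
    sse = float(((y - cells.to_numpy()) ** 2).sum())
    return max(0.0, 1.0 - sse / sst)


def lf_anova(Z: np.ndarray, meta: pd.DataFrame) -> pd.DataFrame:
    """Association of each factor with group, week, and their interaction.

    ``meta`` must align row-wise with Z and carry ``group`` and ``week``
    columns.  Returns one row per factor with r2_group, r2_week,
    r2_interaction, F/p for the group-only and week-only models, and
    BH-adjusted q-values (adjusted across factors, separately per
    family).  A constant factor reports R2 = 0 and p = 1 by convention.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if len(meta) != Z.shape[0]:
        raise MomfaError("metadata rows must align with factor scores")
    group = meta["group"].to_numpy()
    week = meta["week"].to_numpy()
    rows = []
    for k in range(Z.shape[1]):
        y = Z[:, k]
        if np.allclose(y, y[0]):
            rows.append({"factor": f"LF{k + 1}", "r2_group": 0.0, "r2_week": 0.0,
                         "r2_interaction": 0.0, "F_group": 0.0, "p_group": 1.0,
                         "F_week": 0.0, "p_week": 1.0, "flag": True})
            continue
        gi = _one_way(y, group)
        wi = _one_way(y, week)
        rows.append({
            "factor": f"LF{k + 1}",
            "r2_group": gi["r2"], "r2_week": wi["r2"],
            "r2_interaction": _interaction_r2(y, group, week),
            "F_group": gi["F"], "p_group": gi["p"],
            "F_week": wi["F"], "p_week": wi["p"],
            "flag": gi["flag"] or wi["flag"],
        })
    out = pd.DataFrame(rows)
    out["q_group"] = bh_adjust(out["p_group"].to_numpy())
    out["q_week"] = bh_adjust(out["p_week"].to_numpy())
    cols = ["factor", "r2_group", "r2_week", "r2_interaction",
            "F_group", "p_group", "q_group", "F_week", "p_week", "q_week", "flag"]
    return out[cols]


def pairwise_contrasts(
    Z: np.ndarray,
    meta: pd.DataFrame,
    factors: list[int] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise mean differences between group pairs and week pairs.

    For each selected factor (0-based indices; default all) and each
    family (group, week), all level pairs are tested with two-sided
    pooled-variance t-tests from the one-way fit (or Welch t-tests when
    ``welch``); BH adjustment is applied within each (factor, family).
    Pairs involving a level with < 2 profiles are skipped with a flag.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if factors is None:
        factors = list(range(Z.shape[1]))
    rows = []
    for k in factors:
        if not 0 <= k < Z.shape[1]:
            raise MomfaError(f"factor index {k} out of range")
        y = Z[:, k]
        for family in ("group", "week"):
            labels = meta[family].to_numpy()
            levels = sorted(pd.unique(labels).tolist(), key=str)
            groups = {lv: y[labels == lv] for lv in levels}
            n_tot = y.size
            g = len(levels)
            mse = (
                sum(((v - v.mean()) ** 2).sum() for v in groups.values())
                / max(n_tot - g, 1)
            )
            fam_rows = []
            for i, a in enumerate(levels):
                for b in levels[i + 1:]:
                    ya, yb = groups[a], groups[b]
                    if len(ya) < 2 or len(yb) < 2:
                        fam_rows.append({"level_a": a, "level_b": b,
                                         "diff": np.nan, "t": np.nan,
                                         "p": np.nan, "skipped": True})
                        continue
                    diff = float(ya.mean() - yb.mean())
                    if welch:
                        t, p = stats.ttest_ind(ya, yb, equal_var=False)
                        t, p = float(t), float(p)
                    else:
                        se = np.sqrt(mse * (1.0 / len(ya) + 1.0 / len(yb)))
                        if se == 0:
                            t, p = (np.inf if diff else 0.0,
                                    P_FLOOR if diff else 1.0)
                        else:
                            t = diff / se
                            p = float(2.0 * stats.t.sf(abs(t), n_tot - g))
                    fam_rows.append({"level_a": a, "level_b": b, "diff": diff,
                                     "t": t, "p": max(p, P_FLOOR),
                                     "skipped": False})
            tested = [r for r in fam_rows if not r["skipped"]]
            if tested:
                q = bh_adjust([r["p"] for r in tested])
                for r, qv in zip(tested, q):
                    r["q"] = float(qv)
            for r in fam_rows:
                r.setdefault("q", np.nan)
                rows.append({"factor": f"LF{k + 1}", "family": family, **r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Loading summaries


def top_loadings(fit: FactorFit, view: str, factor: int, k: int) -> pd.DataFrame:
    """Top-k features of one factor by |loading| (ties by feature ID)."""
    w = _factor_loadings(fit, view, factor)
    order = sorted(range(len(w)), key=lambda i: (-abs(w[i]), fit.feature_ids[view][i]))
    top = order[: min(k, len(w))]
    return pd.DataFrame({
        "feature_id": [fit.feature_ids[view][i] for i in top],
        "loading": [float(w[i]) for i in top],
    })


def threshold_loadings(fit: FactorFit, view: str, factor: int, cutoff: float) -> list[str]:
    """Features whose |loading| strictly exceeds the cutoff."""
    w = _factor_loadings(fit, view, factor)
    return [f for f, x in zip(fit.feature_ids[view], w) if abs(x) > cutoff]


def cross_view_loading_comparison(
    fit: FactorFit, view_a: str, view_b: str, factor: int
) -> tuple[pd.DataFrame, float]:
    """Compare one factor's loadings for features shared by two views.

    Inner-joins loadings by feature ID and reports the paired table
    (with a ``consistent_sign`` column) and their Pearson correlation.
    Needs at least 3 shared features.
    """
    wa = _factor_loadings(fit, view_a, factor)
    wb = _factor_loadings(fit, view_b, factor)
    a = pd.Series(wa, index=fit.feature_ids[view_a], name=view_a)
    b = pd.Series(wb, index=fit.feature_ids[view_b], name=view_b)
    joined = pd.concat([a, b], axis=1, join="inner")
    if len(joined) < 3:
        raise MomfaError(
            f"only {len(joined)} shared feature(s) between "
            f"{view_a!r} and {view_b!r}; need >= 3"
        )
    x, y = joined[view_a].to_numpy(), joined[view_b].to_numpy()
    r = float(np.corrcoef(x, y)[0, 1])
    joined = joined.reset_index(names="feature_id")
    joined["consistent_sign"] = np.sign(x) * np.sign(y) > 0
    return joined, r


def _factor_loadings(fit: FactorFit, view: str, factor: int) -> np.ndarray:
    if view not in fit.W:
        raise MomfaError(f"unknown view {view!r}")
    if not 0 <= factor < fit.k_active:
        raise MomfaError(
            f"factor index {factor} out of range for k_active={fit.k_active}"
        )
    return fit.W[view][:, factor]
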