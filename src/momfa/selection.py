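"""Ensemble fitting and ELBO-based model selection.

The selection protocol: fit the factor model over a grid of pruning
thresholds crossed with random seeds (the reference protocol uses 8
thresholds spanning 2%-20% with 100 seeds each, i.e. 800 fits), group
the fits by the number of factors they converged to, keep the
highest-ELBO fit per factor count, trace variance explained against
factor count, and pick the elbow — automated here as the smallest K
whose gain in overall R-squared to K+1 falls below ``elbow_delta``,
with an explicit override to reproduce a visual choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gfa import fit_gfa, variance_explained
from .types import FactorFit, MomfaError, ProfileSet, RunConfig

log = logging.getLogger("momfa")


def grid_seed(base_seed: int, threshold_index: int, rep: int) -> int:
    """Seed schedule: per-threshold streams never collide."""
    return int(base_seed + threshold_index * 10_000 + rep) % (2**31 - 1)


@dataclass
class FitEnsemble:
    """All fits over the threshold x seed grid, with provenance."""

    records: list = field(default_factory=list)  # dicts with threshold/seed/fit
    thresholds: tuple = ()
    seeds_per_threshold: int = 0

    def table(self) -> pd.DataFrame:
        rows = [
            {k: r[k] for k in ("threshold", "seed", "k_active", "elbo_final",
                               "converged", "error")}
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @property
    def n_ok(self) -> int:
        return sum(r["error"] is None for r in self.records)


def run_ensemble(ps: ProfileSet, cfg: RunConfig) -> FitEnsemble:
    """Fit every (threshold, seed) combination of the configured grid.

    Produces len(thresholds) * seeds_per_threshold records; a failing
    fit is recorded with its error message rather than dropped.
    """
    ens = FitEnsemble(thresholds=cfg.thresholds,
                      seeds_per_threshold=cfg.seeds_per_threshold)
    for i, th in enumerate(cfg.thresholds):
        for j in range(1, cfg.seeds_per_threshold + 1):
            seed = grid_seed(cfg.base_seed, i, j)
            rec = {"threshold": float(th), "seed": seed, "k_active": None,
                   "elbo_final": None, "converged": None, "fit": None,
                   "error": None}
            try:
                fit = fit_gfa(ps, cfg.k_init, th, seed,
                              tol=cfg.tol, max_iter=cfg.max_iter)
                rec.update(k_active=fit.k_active, elbo_final=fit.elbo_final,
                           converged=fit.converged, fit=fit)
            except Exception as exc:  # surfaced in the record
                rec["error"] = f"{type(exc).__name__}: {exc}"
                log.warning("ensemble fit failed (threshold=%g seed=%d): %s",
                            th, seed, exc)
            ens.records.append(rec)
        log.info("run_ensemble: threshold %g done (%d fits)", th,
                 cfg.seeds_per_threshold)
    return ens


def select_best_per_k(ens: FitEnsemble) -> dict[int, FactorFit]:
    """Highest-ELBO fit within each factor-count group (ties: smallest seed)."""
    ok = [r for r in ens.records if r["error"] is None]
    if not ok:
        raise MomfaError("ensemble contains no successful fits")
    best: dict[int, dict] = {}
    for r in ok:
        k = int(r["k_active"])
        cur = best.get(k)
        if (
            cur is None
            or r["elbo_final"] > cur["elbo_final"]
            or (r["elbo_final"] == cur["elbo_final"] and r["seed"] < cur["seed"])
        ):
            best[k] = r
    log.info("select_best_per_k: factor counts %s", sorted(best))
    return {k: best[k]["fit"] for k in sorted(best)}


def selection_curve(best: dict[int, FactorFit], ps: ProfileSet) -> pd.DataFrame:
    """Variance-explained curve over candidate factor counts.

    One row per K: final ELBO, overall total R-squared, and per-view
    total R-squared columns ``r2_<view>``.
    """
    rows = []
    for k in sorted(best):
        fit = best[k]
        ve = variance_explained(fit, ps)
        row = {"k": int(k), "elbo": fit.elbo_final,
               "overall_r2": ve.overall_total}
        for name in ve.per_view_total.index:
            row[f"r2_{name}"] = float(ve.per_view_total[name])
        rows.append(row)
    return pd.DataFrame(rows).sort_values("k").reset_index(drop=True)


def select_model(
    curve: pd.DataFrame,
    best: dict[int, FactorFit],
    elbow_delta: float = 0.01,
    k_override: int | None = None,
) -> tuple[int, FactorFit]:
    """Elbow rule on the variance-explained curve.

    Default: the smallest K whose overall R-squared gain to the next
    candidate K is below ``elbow_delta`` (absolute).  If gains never
    level off, the largest candidate wins with a warning.  An explicit
    ``k_override`` reproduces a visual selection.
    """
    ks = curve["k"].tolist()
    if k_override is not None:
        if k_override not in ks:
            raise MomfaError(f"k_override={k_override} not among candidates {ks}")
        log.info("select_model: override -> K=%d", k_override)
        return int(k_override), best[int(k_override)]
    r2 = curve.set_index("k")["overall_r2"]
    chosen = None
    for a, b in zip(ks, ks[1:]):
        gain = float(r2[b] - r2[a])
        if gain < elbow_delta:
            chosen = a
            break
    if chosen is None:
        chosen = ks[-1]
        warnings.warn(
            "variance-explained gains never levelled off; selecting the "
            f"largest candidate K={chosen}",
            stacklevel=2,
        )
    log.info("select_model: elbow rule (delta=%g) -> K=%d", elbow_delta, chosen)
    return int(chosen), best[int(chosen)]
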