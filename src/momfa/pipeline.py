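"""Stage orchestration: the simulate -> preprocess -> match -> fit ->
select -> associate workflow as plain functions over in-memory objects.

The CLI wraps these with on-disk artifacts; library users can call them
directly.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import association, matching, preprocess, selection
from .types import MomfaError, OmicView, ProfileSet, RunConfig

log = logging.getLogger("momfa")


def preprocess_views(
    views: dict[str, OmicView], cfg: RunConfig
) -> tuple[dict[str, OmicView], list[preprocess.NormalizationReport]]:
    """Normalize every view according to its modality.

    Counts views: low-expression filter, TMM, (log) cpm.  Abundance
    views: PQN, log transform.  Already-normalized views pass through.
    """
    out, reports = {}, []
    for name, view in views.items():
        if view.modality == "counts":
            norm, rep = preprocess.preprocess_rna(
                view, cfg.filter_min_cpm, cfg.filter_min_frac, cfg.log_cpm
            )
        elif view.modality == "abundance":
            norm, rep = preprocess.preprocess_abundance(view)
        else:
            norm, rep = view, None
        out[name] = norm
        if rep is not None:
            reports.append(rep)
    return out, reports


def build_profiles(
    views: dict[str, OmicView], meta: pd.DataFrame
) -> ProfileSet:
    """Match normalized views into multiomic profiles."""
    return matching.match_profiles(list(views.values()), meta)


def prepare_for_factors(ps: ProfileSet, cfg: RunConfig) -> ProfileSet:
    """Cap RNA views at the top-variance gene count and unit-scale all views.

    Only count-derived RNA views (names ending in ``rna``) are capped,
    so the low-dimensional LC-MS views are not underrepresented in the
    factor model.
    """
    views = {}
    for name, view in ps.views.items():
        v = view
        if name.endswith("rna") and cfg.top_k_genes and cfg.top_k_genes > 0:
            v = preprocess.select_top_variance(v, cfg.top_k_genes)
        v = preprocess.unit_variance_scale(v)
        views[name] = v
    return ProfileSet(
        profiles=ps.profiles.copy(),
        views=views,
        observed={n: ps.observed[n].copy() for n in views},
    )


def associate_factors(fit, ps: ProfileSet, loading_cutoff: float = 2.0,
                      top_k: int = 10) -> dict:
    """Association tables and loading summaries for a chosen fit."""
    assoc = association.lf_anova(fit.Z, ps.profiles)
    sig = assoc[(assoc["q_group"] < 0.05) | (assoc["q_week"] < 0.05)]
    sig_idx = [int(f[2:]) - 1 for f in sig["factor"]]
    pairwise = association.pairwise_contrasts(fit.Z, ps.profiles, sig_idx or None)
    tops = {
        name: pd.concat(
            [
                association.top_loadings(fit, name, k, top_k).assign(
                    factor=f"LF{k + 1}"
                )
                for k in range(fit.k_active)
            ],
            ignore_index=True,
        )
        for name in fit.view_names
    }
    cross = {}
    names = fit.view_names
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = set(fit.feature_ids[a]) & set(fit.feature_ids[b])
            if len(shared) >= 3 and fit.k_active >= 1:
                table, r = association.cross_view_loading_comparison(fit, a, b, 0)
                cross[(a, b)] = {"table": table, "pearson_r": r}
    above = {
        name: association.threshold_loadings(fit, name, 0, loading_cutoff)
        for name in names
        if fit.k_active >= 1
    }
    return {"association": assoc, "pairwise": pairwise, "top_loadings": tops,
            "cross_view": cross, "above_cutoff": above}
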