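"""Per-view normalization and feature selection.

RNA-seq count views follow the standard edgeR-style route: drop lowly
expressed genes (>= 5 cpm in >= 10% of samples by default), compute
trimmed-mean-of-M-values (TMM) scale factors, convert to normalized
counts per million, and log2(cpm + 1) transform.  LC-MS abundance views
are corrected for per-sample dilution with probabilistic quotient
normalization (PQN) and log-transformed.  Before factor modelling,
every view is reduced to its top-variance features (RNA only, by
default capped at 2500 genes) and each feature is centered and scaled
to unit variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import MomfaError, OmicView

log = logging.getLogger("momfa")


@dataclass
class NormalizationReport:
    """What a normalization step did to one view."""

    view_name: str
    scale_factors: pd.Series
    n_features_in: int
    n_features_out: int
    transform_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.scale_factors <= 0).any():
            raise MomfaError("scale factors must be strictly positive")
        if self.n_features_out > self.n_features_in:
            raise MomfaError("cannot gain features during normalization")


def cpm(view: OmicView, factors: np.ndarray | None = None) -> np.ndarray:
    """Counts per million against (optionally TMM-scaled) library sizes."""
    lib = view.values.sum(axis=0)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    return view.values / lib[None, :] * 1e6


def filter_low_expression(
    view: OmicView, min_cpm: float = 5.0, min_frac: float = 0.10
) -> OmicView:
    """Keep genes with cpm >= min_cpm in at least min_frac of samples.

    cpm is computed against raw library sizes (before any scaling); the
    fraction comparison is inclusive, so with 10 samples and
    min_frac=0.10 one qualifying sample suffices.
    """
    if view.modality != "counts":
        raise MomfaError("low-expression filter applies to counts views")
    if min_cpm < 0:
        raise MomfaError("min_cpm must be >= 0")
    if not 0 < min_frac <= 1:
        raise MomfaError("min_frac must lie in (0, 1]")
    frac = (cpm(view) >= min_cpm).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        warnings.warn(
            f"low-expression filter removed every feature of {view.view_name!r}",
            stacklevel=2,
        )
    log.info(
        "filter_low_expression(%s): kept %d / %d features (min_cpm=%g, min_frac=%g)",
        view.view_name, int(keep.sum()), view.n_features, min_cpm, min_frac,
    )
    return OmicView(
        view.view_name,
        [f for f, k in zip(view.feature_ids, keep) if k],
        view.sample_ids,
        view.values[keep, :],
        view.modality,
    )


def tmm_factors(
    view: OmicView, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, one per sample.

    The reference is the sample whose upper-quartile cpm is closest to
    the mean upper-quartile.  For each sample, M (log2 ratio) and A
    (average log2 abundance) values are computed against the reference
    over genes non-zero in both; after rank-trimming trim_m of the M
    tails and trim_a of the A tails, the factor is 2 to the
    precision-weighted mean of the surviving M values (delta-method
    binomial weights).  Factors are rescaled to geometric mean 1.
    """
    if view.modality != "counts":
        raise MomfaError("TMM applies to counts views")
    if view.n_samples < 2:
        raise MomfaError("TMM needs at least 2 samples")
    lib = view.values.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = [view.sample_ids[i] for i in zero]
        raise MomfaError(f"sample(s) with all-zero counts: {names}")
    uq = np.array(
        [np.quantile(view.values[:, j] / lib[j], 0.75) for j in range(view.n_samples)]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array(
        [
            _tmm_pair(view.values[:, j], lib[j], view.values[:, ref], lib[ref],
                      trim_m, trim_a)
            for j in range(view.n_samples)
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    log.info("tmm_factors(%s): reference sample %s", view.view_name,
             view.sample_ids[ref])
    return f


def _tmm_pair(obs, n_obs, ref, n_ref, trim_m, trim_a) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    p_obs, p_ref = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.max(np.abs(m)) < 1e-6:  # identical composition, pure depth
        return 1.0
    # delta-method precision of each M value
    v = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def normalize_cpm(
    view: OmicView, factors: np.ndarray, log2_transform: bool = True
) -> OmicView:
    """Convert counts to normalized cpm (optionally log2(cpm + 1))."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (view.n_samples,):
        raise MomfaError(
            f"got {factors.size} scale factors for {view.n_samples} samples"
        )
    x = cpm(view, factors)
    if log2_transform:
        x = np.log2(x + 1.0)
    return OmicView(view.view_name, list(view.feature_ids), list(view.sample_ids),
                    x, "normalized")


def pqn_normalize(
    view: OmicView, reference: str = "median", log2_transform: bool = True
) -> tuple[OmicView, np.ndarray]:
    """Probabilistic quotient normalization of an abundance view.

    The reference spectrum is the feature-wise median (or mean) across
    samples; each sample's dilution factor is the median of its
    quotients to the reference over features where the reference is
    positive, and the sample is divided by that factor.  Returns the
    normalized view and the estimated dilution factors.
    """
    if view.modality != "abundance":
        raise MomfaError("PQN applies to abundance views")
    if view.n_samples < 2:
        raise MomfaError("PQN needs at least 2 samples")
    if np.any(view.values < 0):
        raise MomfaError("PQN requires non-negative abundances")
    if reference == "median":
        ref = np.median(view.values, axis=1)
    elif reference == "mean":
        ref = view.values.mean(axis=1)
    else:
        raise MomfaError("reference must be 'median' or 'mean'")
    pos = ref > 0
    if not pos.any():
        raise MomfaError("reference spectrum is identically zero")
    q = view.values[pos, :] / ref[pos, None]
    dil = np.median(q, axis=0)
    bad = np.flatnonzero(dil <= 0)
    if bad.size:
        names = [view.sample_ids[i] for i in bad]
        raise MomfaError(f"sample(s) with zero median quotient: {names}")
    x = view.values / dil[None, :]
    modality = "abundance"
    if log2_transform:
        x = np.log2(x + 1.0)
        modality = "normalized"
    out = OmicView(view.view_name, list(view.feature_ids), list(view.sample_ids),
                   x, modality)
    log.info("pqn_normalize(%s): dilution factors in [%.3g, %.3g]",
             view.view_name, dil.min(), dil.max())
    return out, dil


def select_top_variance(view: OmicView, k: int) -> OmicView:
    """Keep the k features with largest sample variance (ties by ID).

    Variance is computed over observed (non-NaN) samples; the retained
    features keep their original row order.  k >= n_features is the
    identity.
    """
    if k <= 0:
        raise MomfaError("k must be positive")
    if k >= view.n_features:
        return view
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(view.values, axis=1, ddof=1)
    var = np.nan_to_num(var, nan=-np.inf)
    order = sorted(range(view.n_features),
                   key=lambda i: (-var[i], view.feature_ids[i]))
    keep_idx = sorted(order[:k])
    log.info("select_top_variance(%s): kept %d / %d features",
             view.view_name, k, view.n_features)
    return OmicView(
        view.view_name,
        [view.feature_ids[i] for i in keep_idx],
        list(view.sample_ids),
        view.values[keep_idx, :],
        view.modality,
    )


def unit_variance_scale(view: OmicView) -> OmicView:
    """Center each feature to mean 0 and scale to unit sample variance.

    Statistics are computed over observed (non-NaN) samples only;
    zero-variance features carry no usable signal and are dropped with
    a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(view.values, axis=1)
        sd = np.nanstd(view.values, axis=1, ddof=1)
    ok = np.isfinite(sd) & (sd > 0)
    if not ok.all():
        dropped = [f for f, o in zip(view.feature_ids, ok) if not o]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s) from "
            f"{view.view_name!r}: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        log.info("unit_variance_scale(%s): dropped %d zero-variance features",
                 view.view_name, len(dropped))
    x = (view.values[ok, :] - mean[ok, None]) / sd[ok, None]
    return OmicView(
        view.view_name,
        [f for f, o in zip(view.feature_ids, ok) if o],
        list(view.sample_ids),
        x,
        "normalized",
    )


def preprocess_rna(
    view: OmicView,
    min_cpm: float = 5.0,
    min_frac: float = 0.10,
    log2_transform: bool = True,
) -> tuple[OmicView, NormalizationReport]:
    """Filter low expression, TMM-normalize, and convert to (log) cpm."""
    filtered = filter_low_expression(view, min_cpm, min_frac)
    factors = tmm_factors(filtered)
    out = normalize_cpm(filtered, factors, log2_transform)
    report = NormalizationReport(
        view_name=view.view_name,
        scale_factors=pd.Series(factors, index=view.sample_ids, name="tmm_factor"),
        n_features_in=view.n_features,
        n_features_out=out.n_features,
        transform_log=["filter_low_expression", "tmm", "cpm"]
        + (["log2(x+1)"] if log2_transform else []),
    )
    return out, report


def preprocess_abundance(
    view: OmicView, reference: str = "median", log2_transform: bool = True
) -> tuple[OmicView, NormalizationReport]:
    """PQN-normalize an LC-MS abundance view (and log-transform)."""
    out, dil = pqn_normalize(view, reference, log2_transform)
    report = NormalizationReport(
        view_name=view.view_name,
        scale_factors=pd.Series(dil, index=view.sample_ids, name="pqn_dilution"),
        n_features_in=view.n_features,
        n_features_out=out.n_features,
        transform_log=["pqn"] + (["log2(x+1)"] if log2_transform else []),
    )
    return out, report
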