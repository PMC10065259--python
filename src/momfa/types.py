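"""Core in-memory containers for the longitudinal multi-omics pipeline.

The pipeline revolves around four container types:

* :class:`OmicView` — one feature-by-sample matrix for a single omic
  modality (RNA counts, LC-MS abundances, or normalized values).
* :class:`ProfileSet` — several views matched onto a shared axis of
  multiomic profiles, one per (mouse, group, week) key, with per-view
  observation masks.
* :class:`FactorFit` — one fitted multi-view factor decomposition
  ``Y_m = Z W_m^T + E_m``.
* :class:`VarianceExplained` — the per-factor / per-view R-squared
  decomposition of a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: The four genotype groups: wild type, dystrophin-deficient mdx, and mdx
#: carrying two (PP) or one (PM) functional utrophin copies.
GROUPS = ("WT", "mdx", "mdxUtrnPP", "mdxUtrnPM")

#: Sampling weeks of the longitudinal design (blood every 6 weeks).
WEEKS = (6, 12, 18, 24, 30)

#: Canonical view names.
VIEW_NAMES = ("muscle_rna", "blood_rna", "lipids", "metabolites")

MODALITIES = ("counts", "abundance", "normalized")

#: Required columns of a sample metadata table.
META_COLUMNS = ("sample_id", "mouse_id", "group", "week", "tissue")

TISSUES = ("blood", "muscle", "plasma")


class MomfaError(ValueError):
    """Base error for invalid inputs anywhere in the pipeline."""


@dataclass
class OmicView:
    """A feature-by-sample matrix for one omic modality.

    Parameters
    ----------
    view_name
        Identifier such as ``muscle_rna`` or ``lipids``.
    feature_ids, sample_ids
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        Real matrix of shape ``(n_features, n_samples)``.
    modality
        ``counts`` (non-negative integers), ``abundance`` (non-negative
        reals) or ``normalized`` (arbitrary reals).
    """

    view_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise MomfaError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        dup = _duplicates(self.feature_ids)
        if dup:
            raise MomfaError(f"duplicate feature IDs: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise MomfaError(f"duplicate sample IDs: {sorted(dup)}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise MomfaError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.modality == "normalized":
            # NaN marks unobserved profiles in matched data; infinities never valid
            if np.any(np.isinf(self.values)):
                raise MomfaError(f"view {self.view_name!r} contains infinite values")
        elif not np.all(np.isfinite(self.values)):
            raise MomfaError(f"view {self.view_name!r} contains non-finite values")
        if self.modality == "counts":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise MomfaError(
                    f"counts view {self.view_name!r} must hold non-negative integers"
                )
        elif self.modality == "abundance" and np.any(self.values < 0):
            raise MomfaError(f"abundance view {self.view_name!r} must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, view_name: str, modality: str) -> "OmicView":
        return cls(
            view_name=view_name,
            feature_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            modality=modality,
        )

    def replace(self, **kw) -> "OmicView":
        """Return a copy with the given fields replaced (re-validated)."""
        args = dict(
            view_name=self.view_name,
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            modality=self.modality,
        )
        args.update(kw)
        return OmicView(**args)


def _duplicates(ids) -> set:
    seen: set = set()
    dup: set = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a sample metadata table.

    Requires the columns ``sample_id, mouse_id, group, week, tissue``;
    group must be one of the four genotype levels, week a positive
    integer, sample_id unique.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise MomfaError(f"metadata missing required columns: {missing}")
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["mouse_id"] = meta["mouse_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MomfaError(f"duplicate sample_id values: {dups}")
    bad = sorted(set(meta["group"]) - set(GROUPS))
    if bad:
        raise MomfaError(f"unknown group level(s) {bad}; expected one of {GROUPS}")
    week = pd.to_numeric(meta["week"], errors="coerce")
    if week.isna().any():
        bad_rows = meta.loc[week.isna(), "sample_id"].tolist()
        raise MomfaError(f"non-numeric week for sample(s) {bad_rows}")
    if (week <= 0).any() or (week != week.round()).any():
        raise MomfaError("week must be a positive integer")
    meta["week"] = week.astype(int)
    bad = sorted(set(meta["tissue"]) - set(TISSUES))
    if bad:
        raise MomfaError(f"unknown tissue level(s) {bad}; expected one of {TISSUES}")
    return meta.reset_index(drop=True)


@dataclass
class ProfileSet:
    """Matched multi-view dataset indexed by multiomic profile.

    ``profiles`` has one row per (mouse_id, group, week) key, sorted by
    mouse then week.  Each view matrix is feature-by-profile; columns of
    unobserved profiles are NaN and flagged False in ``observed``.
    """

    profiles: pd.DataFrame  # columns: mouse_id, group, week
    views: dict[str, OmicView]
    observed: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.profiles)
        if set(self.views) != set(self.observed):
            raise MomfaError("views and observed masks must cover the same view names")
        if not self.views:
            raise MomfaError("a ProfileSet needs at least one view")
        for name, view in self.views.items():
            if view.n_samples != n:
                raise MomfaError(
                    f"view {name!r} has {view.n_samples} profiles, expected {n}"
                )
            mask = np.asarray(self.observed[name], dtype=bool)
            if mask.shape != (n,):
                raise MomfaError(f"observed mask for {name!r} has wrong length")
            self.observed[name] = mask
        any_obs = np.zeros(n, dtype=bool)
        for mask in self.observed.values():
            any_obs |= mask
        if not any_obs.all():
            raise MomfaError("every profile must be observed in at least one view")

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)

    @property
    def view_names(self) -> list[str]:
        return list(self.views)

    def matrix(self, name: str) -> np.ndarray:
        """Feature-by-profile values of one view (NaN where unobserved)."""
        return self.views[name].values


@dataclass
class FactorFit:
    """One fitted decomposition ``Y_m = Z W_m^T + E_m``.

    Z is profiles-by-K (shared factor scores); W maps each view to its
    feature-by-K loading matrix; tau holds per-feature noise precisions
    and alpha the per-factor ARD scales.  ``elbo_trace`` is the
    coordinate-ascent trace since the last factor-pruning event (and is
    therefore monotone non-decreasing); ``elbo_history`` keeps the full
    trace across pruning events.
    """

    Z: np.ndarray
    W: dict[str, np.ndarray]
    tau: dict[str, np.ndarray]
    alpha: dict[str, np.ndarray]
    feature_ids: dict[str, list[str]]
    elbo_trace: list[float]
    elbo_history: list[float]
    k_active: int
    seed: int
    threshold: float
    n_iter: int = 0
    converged: bool = False

    @property
    def elbo_final(self) -> float:
        return float(self.elbo_trace[-1]) if self.elbo_trace else float("-inf")

    @property
    def view_names(self) -> list[str]:
        return list(self.W)


@dataclass
class VarianceExplained:
    """Per-factor and total R-squared of a fit, by view.

    ``per_factor`` is a view-by-K table of fractions in [0, 1];
    ``per_view_total`` is computed from the full K-factor reconstruction
    (not the per-factor sum); ``overall_total`` weights views by their
    observed entry counts.
    """

    per_factor: pd.DataFrame  # index: view, columns: factor index (1-based labels)
    per_view_total: pd.Series
    overall_total: float
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class RunConfig:
    """Configuration of the full pipeline.

    Defaults mirror the study protocol: low-expression filter at
    >= 5 cpm in >= 10% of samples, top-2500-variance gene cap, and a
    selection grid of 8 pruning thresholds spanning 2%-20% with 100
    random seeds each.
    """

    filter_min_cpm: float = 5.0
    filter_min_frac: float = 0.10
    top_k_genes: int = 2500
    log_cpm: bool = True
    thresholds: tuple = tuple(np.round(np.linspace(0.02, 0.20, 8), 6))
    seeds_per_threshold: int = 100
    k_init: int = 15
    tol: float = 1e-6
    max_iter: int = 2000
    elbow_delta: float = 0.01
    base_seed: int = 0

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.thresholds)
        if not th:
            raise MomfaError("thresholds must be non-empty")
        if any(not (0.0 < t < 1.0) for t in th):
            raise MomfaError("each threshold must lie in (0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise MomfaError("thresholds must be strictly increasing")
        self.thresholds = th
        if self.seeds_per_threshold < 1:
            raise MomfaError("seeds_per_threshold must be >= 1")
        if self.k_init < 1:
            raise MomfaError("k_init must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise MomfaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})
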