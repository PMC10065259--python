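"""Synthetic longitudinal four-view studies with known latent structure.

The generator emulates a 30-week dystrophic-mouse study: 4 genotype
groups (WT, mdx, and mdx with two or one functional utrophin copies),
blood sampled every 6 weeks from week 6 to 30, muscle only at the
sacrifice week.  Because blood volume does not allow both RNA-seq and
plasma mass spectrometry on the same draw, each (mouse, week) pair is
assayed either by blood RNA or by the two plasma views — the source of
the cross-view missingness the downstream factor model must absorb.

Ground truth is explicit: shared latent factor scores driven by group,
week and group-by-week effects; view-specific loadings; negative-
binomial counts for the RNA views; log-normal dilution-confounded
abundances for the plasma views.  Everything the generator injects
(scores, loadings, dilutions) is returned so downstream estimates can
be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GROUPS, WEEKS, MomfaError, OmicView, ProfileSet, validate_metadata

DYSTROPHIC = ("mdx", "mdxUtrnPP", "mdxUtrnPM")


@dataclass
class StudyDesign:
    """Layout of the longitudinal experiment.

    ``blood_rna_fraction`` is the probability that a (mouse, week) blood
    draw is assayed by RNA-seq rather than by the plasma LC-MS views —
    every draw goes to exactly one of the two, which is what creates the
    disjoint observation patterns across views.
    """

    n_mice_per_group: int = 10
    groups: tuple = GROUPS
    weeks: tuple = WEEKS
    muscle_week: int = 30
    blood_rna_fraction: float = 0.5
    dropout_rate: float = 0.0  # per-mouse chance of early humane-endpoint censoring
    muscle_replicate_fraction: float = 0.0  # fraction of mice with duplicate muscle samples

    def __post_init__(self) -> None:
        if self.n_mice_per_group < 1:
            raise MomfaError("n_mice_per_group must be >= 1")
        if self.muscle_week not in self.weeks:
            raise MomfaError("muscle_week must be one of the sampling weeks")
        if not 0.0 <= self.blood_rna_fraction <= 1.0:
            raise MomfaError("blood_rna_fraction must lie in [0, 1]")

    def mouse_table(self) -> pd.DataFrame:
        rows = []
        i = 0
        for g in self.groups:
            for _ in range(self.n_mice_per_group):
                i += 1
                rows.append({"mouse_id": f"m{i:03d}", "group": g})
        return pd.DataFrame(rows)


@dataclass
class FactorEffect:
    """Phenotype structure of one true latent factor.

    The score of mouse *i* (group g) at week w is
    ``group[g] + week[w] + interaction[(g, w)] + N(0, sd)``.
    """

    group: dict = field(default_factory=dict)
    week: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    sd: float = 0.3

    def mean(self, g: str, w: int) -> float:
        return (
            float(self.group.get(g, 0.0))
            + float(self.week.get(int(w), 0.0))
            + float(self.interaction.get((g, int(w)), 0.0))
        )


def factor_effect_preset(name: str, *, sd: float = 0.3, weeks: tuple = WEEKS) -> FactorEffect:
    """Named phenotype presets for true factors.

    ``dystrophic_offset`` — WT offset vs the three dystrophic groups
    plus an extra week-6 offset (disease signature strongest during the
    early degeneration/regeneration phase).
    ``growth_trend`` — linear in week, identical in all groups
    (physiological growth).
    ``early_disease`` — week-6 offset in the dystrophic groups only
    (group-by-week interaction with no main effects to speak of).
    """
    if name == "dystrophic_offset":
        return FactorEffect(
            group={"WT": -1.2, "mdx": 0.5, "mdxUtrnPP": 0.9, "mdxUtrnPM": 0.9},
            week={6: 1.0},
            sd=sd,
        )
    if name == "growth_trend":
        slope = 1.0 / 6.0
        return FactorEffect(week={int(w): slope * (w - np.mean(weeks)) for w in weeks}, sd=sd)
    if name == "early_disease":
        return FactorEffect(
            interaction={(g, 6): 1.5 for g in DYSTROPHIC}, sd=sd
        )
    raise MomfaError(f"unknown factor preset {name!r}")


@dataclass
class TruthModel:
    """Generative ground truth: factor phenotypes and per-view emissions."""

    effects: list = field(
        default_factory=lambda: [
            factor_effect_preset("dystrophic_offset"),
            factor_effect_preset("growth_trend"),
            factor_effect_preset("early_disease"),
        ]
    )
    n_features: dict = field(
        default_factory=lambda: {
            "muscle_rna": 3000,
            "blood_rna": 3000,
            "lipids": 524,
            "metabolites": 106,
        }
    )
    loading_sparsity: float = 0.25  # fraction of features loading on each factor
    loading_scale: dict = field(
        default_factory=lambda: {
            "muscle_rna": 0.8,
            "blood_rna": 0.8,
            "lipids": 0.8,
            "metabolites": 0.8,
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {"lipids": 0.25, "metabolites": 0.35}
    )
    nb_dispersion: float = 0.05
    dilution_sd: float = 0.3
    lib_size_mean: float = 2e6
    lib_size_sd_log: float = 0.3

    @property
    def n_factors_true(self) -> int:
        return len(self.effects)

    def __post_init__(self) -> None:
        if not self.effects:
            raise MomfaError("TruthModel needs at least one factor effect")
        for v, sd in self.noise_sd.items():
            if sd < 0:
                raise MomfaError(f"noise_sd for {v!r} must be >= 0")
        if self.dilution_sd < 0:
            raise MomfaError("dilution_sd must be >= 0")


# ---------------------------------------------------------------------------
# Score / loading / view simulation


def simulate_factor_scores(
    design: StudyDesign, truth: TruthModel, seed: int
) -> pd.DataFrame:
    """Draw one true score vector per (mouse, week).

    Returns a table with columns ``mouse_id, group, week, Z1..ZK``; the
    score of factor k is its design mean (group + week + interaction
    effect) plus Gaussian residual with the factor's own SD.
    """
    rng = np.random.default_rng(seed)
    mice = design.mouse_table()
    rows = []
    for _, m in mice.iterrows():
        for w in design.weeks:
            rows.append({"mouse_id": m.mouse_id, "group": m.group, "week": int(w)})
    df = pd.DataFrame(rows)
    for k, eff in enumerate(truth.effects):
        mean = np.array([eff.mean(g, w) for g, w in zip(df["group"], df["week"])])
        df[f"Z{k + 1}"] = mean + rng.normal(0.0, eff.sd, size=len(df))
    return df


def score_matrix(scores: pd.DataFrame) -> np.ndarray:
    """Extract the (samples x K) score matrix from a score table."""
    cols = [c for c in scores.columns if c.startswith("Z")]
    return scores[cols].to_numpy(dtype=float)


def simulate_loadings(
    n_features: int, n_factors: int, sparsity: float, scale: float, seed: int
) -> np.ndarray:
    """Sparse Gaussian loading matrix (features x factors)."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, scale, size=(n_features, n_factors))
    keep = rng.random((n_features, n_factors)) < sparsity
    # guarantee every factor touches at least one feature
    for k in range(n_factors):
        if not keep[:, k].any():
            keep[rng.integers(n_features), k] = True
    return w * keep


def simulate_counts_view(
    z: np.ndarray,
    w: np.ndarray,
    lib_sizes: np.ndarray,
    dispersion: float,
    seed: int,
    *,
    baseline: np.ndarray | None = None,
    view_name: str = "rna",
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> OmicView:
    """Negative-binomial RNA-seq counts driven by the latent signal.

    The per-sample expression rate of feature f is
    ``exp(baseline_f + (Z W^T)_sf)`` renormalized to proportions, so
    library size and composition stay decoupled; counts are drawn as
    NB(mean = lib_size * proportion, dispersion) via a gamma-Poisson
    mixture (``dispersion`` is the quadratic overdispersion coefficient;
    0 gives Poisson).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise MomfaError("library sizes must be positive")
    if dispersion < 0:
        raise MomfaError("dispersion must be >= 0")
    n_features, n_samples = w.shape[0], z.shape[0]
    if lib_sizes.shape != (n_samples,):
        raise MomfaError("lib_sizes length must equal the number of samples")
    rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = rng.normal(2.0, 1.5, size=n_features)
    eta = baseline[:, None] + (z @ w.T).T  # features x samples, log scale
    eta = eta - eta.max(axis=0, keepdims=True)  # guard overflow
    prop = np.exp(eta)
    prop /= prop.sum(axis=0, keepdims=True)
    mu = prop * lib_sizes[None, :]
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        counts = rng.poisson(lam)
    if feature_ids is None:
        feature_ids = [f"G{i + 1}" for i in range(n_features)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    return OmicView(view_name, feature_ids, sample_ids, counts.astype(float), "counts")


def simulate_abundance_view(
    z: np.ndarray,
    w: np.ndarray,
    noise_sd: float,
    dilution_sd: float,
    seed: int,
    *,
    baseline: np.ndarray | None = None,
    dilutions: np.ndarray | None = None,
    view_name: str = "abundance",
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[OmicView, np.ndarray]:
    """LC-MS-style abundances with per-sample dilution confounding.

    ``abundance_fs = dilution_s * exp(baseline_f + (Z W^T)_fs + eps)``,
    with eps ~ N(0, noise_sd) and dilution ~ LogNormal(0, dilution_sd)
    unless explicit dilutions are injected.  The true dilutions are
    returned so probabilistic quotient normalization can be checked
    against them.
    """
    if noise_sd < 0:
        raise MomfaError("noise_sd must be >= 0")
    if dilution_sd < 0:
        raise MomfaError("dilution_sd must be >= 0")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    n_features, n_samples = w.shape[0], z.shape[0]
    rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = rng.normal(5.0, 1.0, size=n_features)
    if dilutions is None:
        dilutions = np.exp(rng.normal(0.0, dilution_sd, size=n_samples))
    else:
        dilutions = np.asarray(dilutions, dtype=float)
        if np.any(dilutions <= 0):
            raise MomfaError("dilution multipliers must be positive")
    eps = rng.normal(0.0, noise_sd, size=(n_features, n_samples))
    log_x = baseline[:, None] + (z @ w.T).T + eps
    values = dilutions[None, :] * np.exp(log_x)
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(n_features)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    view = OmicView(view_name, feature_ids, sample_ids, values, "abundance")
    return view, dilutions


# ---------------------------------------------------------------------------
# Missingness / study assembly


def assign_assays(design: StudyDesign, scores: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Partition (mouse, week) pairs into blood-RNA vs plasma assay sets.

    Every pair lands in exactly one of the two sets (conservation);
    assignment is Bernoulli(blood_rna_fraction) per pair.
    """
    rng = np.random.default_rng(seed)
    pairs = scores[["mouse_id", "group", "week"]].copy()
    pairs["assay"] = np.where(
        rng.random(len(pairs)) < design.blood_rna_fraction, "blood_rna", "plasma"
    )
    return pairs


def apply_missingness(
    views: dict[str, OmicView],
    design: StudyDesign,
    assays: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> tuple[dict[str, OmicView], pd.DataFrame]:
    """Restrict simulated views to the samples their assay set covers.

    The muscle view keeps only ``muscle_week`` samples; blood RNA keeps
    pairs assigned ``blood_rna``; lipids and metabolites keep pairs
    assigned ``plasma``.  Returns the restricted views plus the matching
    master metadata table.
    """
    meta = sample_meta.set_index("sample_id")
    key = {
        (r.mouse_id, int(r.week)): r.assay for r in assays.itertuples(index=False)
    }
    out: dict[str, OmicView] = {}
    kept_samples: list[str] = []
    for name, view in views.items():
        keep = []
        for sid in view.sample_ids:
            row = meta.loc[sid]
            mw = (row["mouse_id"], int(row["week"]))
            if name == "muscle_rna":
                ok = int(row["week"]) == design.muscle_week
            elif name == "blood_rna":
                ok = key.get(mw) == "blood_rna"
            else:  # plasma views
                ok = key.get(mw) == "plasma"
            if ok:
                keep.append(sid)
        idx = [view.sample_ids.index(s) for s in keep]
        out[name] = OmicView(
            view.view_name, view.feature_ids, keep, view.values[:, idx], view.modality
        )
        kept_samples.extend(keep)
    master = sample_meta[sample_meta["sample_id"].isin(kept_samples)].reset_index(
        drop=True
    )
    return out, master


def simulate_study(
    design: StudyDesign | None = None,
    truth: TruthModel | None = None,
    seed: int = 0,
) -> dict:
    """Generate a complete four-view study.

    Returns a dict with ``views`` (raw OmicViews after missingness),
    ``meta`` (master sample metadata), ``scores`` (true factor score
    table), ``loadings`` (true per-view loading matrices),
    ``dilutions`` (true per-plasma-view dilution factors) and
    ``assays`` (the blood-RNA/plasma partition).
    """
    design = design or StudyDesign()
    truth = truth or TruthModel()
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    scores = simulate_factor_scores(design, truth, sub())
    if design.dropout_rate > 0:
        # humane-endpoint censoring: drop late weeks of unlucky mice
        mice = scores["mouse_id"].unique()
        drop_rng = np.random.default_rng(sub())
        dropped = mice[drop_rng.random(len(mice)) < design.dropout_rate]
        censor_week = {m: int(drop_rng.choice(design.weeks[1:])) for m in dropped}
        keep = [
            w <= censor_week.get(m, max(design.weeks))
            for m, w in zip(scores["mouse_id"], scores["week"])
        ]
        scores = scores[keep].reset_index(drop=True)

    z = score_matrix(scores)
    k = truth.n_factors_true
    loadings = {
        name: simulate_loadings(
            truth.n_features[name], k, truth.loading_sparsity,
            truth.loading_scale[name], sub(),
        )
        for name in truth.n_features
    }

    # every simulated sample carries metadata; views then get restricted
    meta_rows, views, dilutions = [], {}, {}
    tissue = {"muscle_rna": "muscle", "blood_rna": "blood",
              "lipids": "plasma", "metabolites": "plasma"}
    n = len(scores)
    prefix = {"muscle_rna": "mus", "blood_rna": "blo",
              "lipids": "lip", "metabolites": "met"}
    for name in truth.n_features:
        sample_ids = [
            f"{prefix[name]}_{m}_w{w}"
            for m, w in zip(scores["mouse_id"], scores["week"])
        ]
        for sid, (_, r) in zip(sample_ids, scores.iterrows()):
            meta_rows.append(
                {"sample_id": sid, "mouse_id": r.mouse_id, "group": r.group,
                 "week": int(r.week), "tissue": tissue[name]}
            )
        feat = [f"{prefix[name].upper()}{i + 1}" for i in range(truth.n_features[name])]
        if name.endswith("rna"):
            libs = np.exp(rng.normal(np.log(truth.lib_size_mean),
                                     truth.lib_size_sd_log, size=n))
            views[name] = simulate_counts_view(
                z, loadings[name], libs, truth.nb_dispersion, sub(),
                view_name=name, feature_ids=feat, sample_ids=sample_ids,
            )
        else:
            views[name], dil = simulate_abundance_view(
                z, loadings[name], truth.noise_sd[name], truth.dilution_sd, sub(),
                view_name=name, feature_ids=feat, sample_ids=sample_ids,
            )
            dilutions[name] = pd.Series(dil, index=sample_ids)
    meta = validate_metadata(pd.DataFrame(meta_rows))

    assays = assign_assays(design, scores, sub())
    views, meta = apply_missingness(views, design, assays, meta)
    for name in dilutions:
        dilutions[name] = dilutions[name].loc[views[name].sample_ids]

    if design.muscle_replicate_fraction > 0:
        views, meta = _add_muscle_replicates(
            views, meta, design, truth, z, loadings, scores, sub()
        )

    return {
        "views": views,
        "meta": meta,
        "scores": scores,
        "loadings": loadings,
        "dilutions": dilutions,
        "assays": assays,
    }


def _add_muscle_replicates(views, meta, design, truth, z, loadings, scores, seed):
    """Duplicate the muscle assay for a random subset of mice."""
    rng = np.random.default_rng(seed)
    mus = views["muscle_rna"]
    pick = rng.random(mus.n_samples) < design.muscle_replicate_fraction
    if not pick.any():
        return views, meta
    meta_idx = meta.set_index("sample_id")
    rows = scores.set_index(["mouse_id", "week"])
    new_ids, new_cols, new_meta = [], [], []
    zcols = [c for c in scores.columns if c.startswith("Z")]
    for j, sid in enumerate(mus.sample_ids):
        if not pick[j]:
            continue
        r = meta_idx.loc[sid]
        zvec = rows.loc[(r["mouse_id"], int(r["week"])), zcols].to_numpy(dtype=float)
        lib = np.exp(rng.normal(np.log(truth.lib_size_mean), truth.lib_size_sd_log))
        rep = simulate_counts_view(
            zvec[None, :], loadings["muscle_rna"], np.array([lib]),
            truth.nb_dispersion, int(rng.integers(0, 2**31 - 1)),
            view_name="muscle_rna", feature_ids=mus.feature_ids,
            sample_ids=[sid + "_rep"],
        )
        new_ids.append(sid + "_rep")
        new_cols.append(rep.values[:, 0])
        new_meta.append({"sample_id": sid + "_rep", "mouse_id": r["mouse_id"],
                         "group": r["group"], "week": int(r["week"]),
                         "tissue": "muscle"})
    values = np.column_stack([mus.values] + [c[:, None] for c in new_cols])
    views = dict(views)
    views["muscle_rna"] = OmicView(
        "muscle_rna", mus.feature_ids, mus.sample_ids + new_ids, values, "counts"
    )
    meta = pd.concat([meta, pd.DataFrame(new_meta)], ignore_index=True)
    return views, validate_metadata(meta)


# ---------------------------------------------------------------------------
# Direct Gaussian studies (for factor-recovery experiments)


def make_gaussian_study(
    n_profiles: int,
    n_features: dict[str, int],
    shares: dict[str, np.ndarray],
    seed: int,
    *,
    scores: pd.DataFrame | None = None,
    observed: dict[str, np.ndarray] | None = None,
) -> tuple[ProfileSet, np.ndarray]:
    """Fully Gaussian multi-view data with exact per-factor variance shares.

    Each view m gets ``Y_m = Z W_m^T + E``, where factor k contributes a
    fraction ``shares[m][k]`` of every feature's variance (loadings are
    random-sign sqrt(share), noise variance is the remainder).  Scores
    default to iid standard normal; a score table from
    :func:`simulate_factor_scores` may be passed instead (columns are
    standardized so the shares still hold).  Returns the ProfileSet and
    the true Z.
    """
    rng = np.random.default_rng(seed)
    k = len(next(iter(shares.values())))
    if scores is None:
        z = rng.standard_normal((n_profiles, k))
        profiles = pd.DataFrame(
            {"mouse_id": [f"m{i + 1:03d}" for i in range(n_profiles)],
             "group": [GROUPS[i % 4] for i in range(n_profiles)],
             "week": [WEEKS[i % 5] for i in range(n_profiles)]}
        )
    else:
        z = score_matrix(scores)
        if z.shape != (n_profiles, k):
            raise MomfaError("score table does not match n_profiles / n_factors")
        profiles = scores[["mouse_id", "group", "week"]].reset_index(drop=True)
    zs = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    labels = [f"{m}_w{w}" for m, w in zip(profiles["mouse_id"], profiles["week"])]

    views, obs = {}, {}
    for name, d in n_features.items():
        s = np.asarray(shares[name], dtype=float)
        if np.any(s < 0) or s.sum() > 1:
            raise MomfaError(f"variance shares for {name!r} must be >= 0 and sum <= 1")
        signs = rng.choice([-1.0, 1.0], size=(d, k))
        w = signs * np.sqrt(s)[None, :]
        noise = rng.standard_normal((d, n_profiles)) * np.sqrt(1.0 - s.sum())
        y = (zs @ w.T).T + noise
        mask = (
            np.ones(n_profiles, dtype=bool)
            if observed is None
            else np.asarray(observed[name], dtype=bool)
        )
        y[:, ~mask] = np.nan
        views[name] = OmicView(
            name,
            [f"{name}_f{i + 1}" for i in range(d)],
            labels,
            y,
            "normalized",
        )
        obs[name] = mask
    ps = ProfileSet(profiles=profiles, views=views, observed=obs)
    return ps, zs
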