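"""On-disk artifacts: TSV matrices, metadata tables, fits, and configs.

Everything is plain delimited text so that artifacts stay diffable:
matrices are TSVs with features in rows (first column = feature ID) and
samples in columns; a fitted factor model is a directory of TSVs plus a
JSON manifest carrying provenance (seed, pruning threshold, k_active).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import FactorFit, MomfaError, OmicView, ProfileSet, RunConfig, validate_metadata

log = logging.getLogger("momfa")


def read_view(path, modality: str, view_name: str | None = None) -> OmicView:
    """Read a feature-by-sample TSV into an :class:`OmicView`.

    The first column holds feature IDs, the header row sample IDs.
    Duplicate feature IDs and non-numeric cells are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     float_precision="round_trip")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise MomfaError(f"{path.name}: duplicate feature IDs: {dup}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # float() round-trips %.17g output exactly
            values[:, j] = np.array([float(t) for t in df[col]])
        except (ValueError, TypeError):
            bad = [
                i for i, t in zip(df.index, df[col])
                if not _is_number(t)
            ]
            raise MomfaError(
                f"{path.name}: non-numeric value in column {col!r}, row(s) {bad}"
            ) from None
    name = view_name if view_name is not None else path.stem
    return OmicView(
        view_name=name,
        feature_ids=list(df.index),
        sample_ids=list(df.columns.astype(str)),
        values=values,
        modality=modality,
    )


def _is_number(t) -> bool:
    try:
        float(t)
        return True
    except (ValueError, TypeError):
        return False


def write_view(view: OmicView, path) -> None:
    """Write a view as a feature-by-sample TSV (feature IDs first column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = view.to_frame()
    df.index.name = "feature_id"
    if view.modality == "counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV (5 required columns)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index=False)


def read_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file mirroring its field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise MomfaError(f"config file {path} must hold a mapping")
    if "thresholds" in data:
        data["thresholds"] = tuple(float(t) for t in data["thresholds"])
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path) -> None:
    d = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    d["thresholds"] = [float(t) for t in d["thresholds"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ProfileSet


def write_profile_set(ps: ProfileSet, outdir) -> None:
    """Write one TSV per view over the shared profile index + mask TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = _profile_labels(ps.profiles)
    prof = ps.profiles.copy()
    prof.insert(0, "profile_id", labels)
    prof.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    mask = pd.DataFrame(
        {name: ps.observed[name].astype(int) for name in ps.view_names}, index=labels
    )
    mask.index.name = "profile_id"
    mask.to_csv(outdir / "observed.tsv", sep="\t")
    for name, view in ps.views.items():
        df = pd.DataFrame(view.values, index=view.feature_ids, columns=labels)
        df.index.name = "feature_id"
        df.to_csv(outdir / f"view_{name}.tsv", sep="\t", float_format="%.17g")


def read_profile_set(indir) -> ProfileSet:
    indir = Path(indir)
    prof = pd.read_csv(indir / "profiles.tsv", sep="\t", dtype={"mouse_id": str})
    labels = prof["profile_id"].astype(str).tolist()
    profiles = prof[["mouse_id", "group", "week"]].copy()
    mask = pd.read_csv(indir / "observed.tsv", sep="\t", index_col=0)
    views: dict[str, OmicView] = {}
    observed: dict[str, np.ndarray] = {}
    for name in mask.columns:
        df = pd.read_csv(indir / f"view_{name}.tsv", sep="\t", index_col=0,
                         float_precision="round_trip")
        df.columns = labels  # column labels round-trip as strings
        views[name] = OmicView(
            view_name=name,
            feature_ids=list(df.index.astype(str)),
            sample_ids=labels,
            values=df.to_numpy(dtype=float),
            modality="normalized",
        )
        observed[name] = mask[name].to_numpy(dtype=bool)
    return ProfileSet(profiles=profiles, views=views, observed=observed)


def _profile_labels(profiles: pd.DataFrame) -> list[str]:
    return [
        f"{m}_w{int(w)}" for m, w in zip(profiles["mouse_id"], profiles["week"])
    ]


# ---------------------------------------------------------------------------
# FactorFit


def write_fit(fit: FactorFit, outdir) -> None:
    """Serialize a fit as a directory of TSVs plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"LF{k + 1}" for k in range(fit.k_active)]
    z = pd.DataFrame(fit.Z, columns=cols)
    z.index.name = "profile"
    z.to_csv(outdir / "Z.tsv", sep="\t", float_format="%.17g")
    for name in fit.view_names:
        w = pd.DataFrame(fit.W[name], index=fit.feature_ids[name], columns=cols)
        w.index.name = "feature_id"
        w.to_csv(outdir / f"W_{name}.tsv", sep="\t", float_format="%.17g")
        t = pd.Series(fit.tau[name], index=fit.feature_ids[name], name="tau")
        t.index.name = "feature_id"
        t.to_csv(outdir / f"tau_{name}.tsv", sep="\t", float_format="%.17g")
        a = pd.Series(fit.alpha[name], index=cols, name="alpha")
        a.index.name = "factor"
        a.to_csv(outdir / f"alpha_{name}.tsv", sep="\t", float_format="%.17g")
    pd.Series(fit.elbo_trace, name="elbo").rename_axis("iteration").to_csv(
        outdir / "elbo_trace.tsv", sep="\t", float_format="%.17g"
    )
    pd.Series(fit.elbo_history, name="elbo").rename_axis("step").to_csv(
        outdir / "elbo_history.tsv", sep="\t", float_format="%.17g"
    )
    manifest = {
        "seed": int(fit.seed),
        "threshold": float(fit.threshold),
        "k_active": int(fit.k_active),
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
        "views": fit.view_names,
        "elbo_final": fit.elbo_final,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_fit(indir) -> FactorFit:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    Z = pd.read_csv(indir / "Z.tsv", sep="\t", index_col=0,
                    float_precision="round_trip").to_numpy(dtype=float)
    W, tau, alpha, feature_ids = {}, {}, {}, {}
    for name in manifest["views"]:
        w = pd.read_csv(indir / f"W_{name}.tsv", sep="\t", index_col=0,
                        float_precision="round_trip")
        W[name] = w.to_numpy(dtype=float)
        feature_ids[name] = list(w.index.astype(str))
        tau[name] = pd.read_csv(indir / f"tau_{name}.tsv", sep="\t", index_col=0,
                                float_precision="round_trip")[
            "tau"
        ].to_numpy(dtype=float)
        alpha[name] = pd.read_csv(indir / f"alpha_{name}.tsv", sep="\t", index_col=0,
                                  float_precision="round_trip")[
            "alpha"
        ].to_numpy(dtype=float)
    trace = pd.read_csv(indir / "elbo_trace.tsv", sep="\t", index_col=0,
                        float_precision="round_trip")["elbo"]
    history = pd.read_csv(indir / "elbo_history.tsv", sep="\t", index_col=0,
                          float_precision="round_trip")["elbo"]
    return FactorFit(
        Z=Z,
        W=W,
        tau=tau,
        alpha=alpha,
        feature_ids=feature_ids,
        elbo_trace=trace.tolist(),
        elbo_history=history.tolist(),
        k_active=int(manifest["k_active"]),
        seed=int(manifest["seed"]),
        threshold=float(manifest["threshold"]),
        n_iter=int(manifest["n_iter"]),
        converged=bool(manifest["converged"]),
    )


def setup_logging(level: int = logging.INFO) -> None:
    """Configure the package logger to echo filter and selection decisions."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    if not log.handlers:
        log.addHandler(handler)
    log.setLevel(level)
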