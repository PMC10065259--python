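"""Match samples across omic views into multiomic profiles.

A profile is one (mouse_id, group, week) key.  Views are matched by
assigning each of their samples to its key; a profile missing from a
view is marked unobserved there, and keys carrying more than one sample
in a view are replaced by the per-feature arithmetic mean of the
duplicates (legitimate only on normalized data).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import MomfaError, OmicView, ProfileSet

log = logging.getLogger("momfa")

KEY = ["mouse_id", "group", "week"]


def _sample_keys(view: OmicView, meta: pd.DataFrame) -> pd.DataFrame:
    m = meta.set_index("sample_id")
    missing = [s for s in view.sample_ids if s not in m.index]
    if missing:
        raise MomfaError(
            f"view {view.view_name!r}: sample(s) missing from metadata: {missing[:5]}"
        )
    keys = m.loc[view.sample_ids, KEY].reset_index()
    return keys


def _check_key_conflicts(meta: pd.DataFrame) -> None:
    groups_per_mouse = meta.groupby("mouse_id")["group"].nunique()
    bad = groups_per_mouse[groups_per_mouse > 1].index.tolist()
    if bad:
        raise MomfaError(f"mouse assigned to multiple groups: {bad}")


def average_duplicates(view: OmicView, meta: pd.DataFrame) -> OmicView:
    """Collapse samples sharing one (mouse, group, week) key to their mean.

    Only normalized values may be averaged (averaging raw counts would
    corrupt library sizes).  The surviving sample keeps the ID of the
    first duplicate in input order.
    """
    if view.modality == "counts":
        raise MomfaError("refusing to average raw counts; normalize first")
    keys = _sample_keys(view, meta)
    _check_key_conflicts(meta)
    tup = list(zip(keys["mouse_id"], keys["group"], keys["week"]))
    first_idx: dict = {}
    members: dict = {}
    for i, t in enumerate(tup):
        first_idx.setdefault(t, i)
        members.setdefault(t, []).append(i)
    order = sorted(first_idx, key=lambda t: first_idx[t])
    cols, ids = [], []
    n_avg = 0
    for t in order:
        idx = members[t]
        if len(idx) > 1:
            n_avg += 1
        cols.append(view.values[:, idx].mean(axis=1))
        ids.append(view.sample_ids[first_idx[t]])
    if n_avg:
        log.info("average_duplicates(%s): averaged %d duplicated key(s)",
                 view.view_name, n_avg)
    return OmicView(view.view_name, list(view.feature_ids), ids,
                    np.column_stack(cols), view.modality)


def match_profiles(views: list[OmicView], meta: pd.DataFrame) -> ProfileSet:
    """Assemble a ProfileSet over the union of (mouse, group, week) keys.

    The profile index is sorted by mouse then week; a view's column for
    a profile it never measured is NaN with observed=False.  Duplicate
    samples within a view for one key are averaged, which makes
    matching commute with :func:`average_duplicates`.
    """
    if not views:
        raise MomfaError("match_profiles needs at least one view")
    _check_key_conflicts(meta)
    all_keys: set = set()
    per_view_keys = {}
    for v in views:
        keys = _sample_keys(v, meta)
        tup = list(zip(keys["mouse_id"], keys["group"], keys["week"]))
        per_view_keys[v.view_name] = tup
        all_keys.update(tup)
    index = sorted(all_keys, key=lambda t: (t[0], t[2]))
    profiles = pd.DataFrame(index, columns=KEY)
    pos = {t: i for i, t in enumerate(index)}

    out_views: dict[str, OmicView] = {}
    observed: dict[str, np.ndarray] = {}
    labels = [f"{m}_w{w}" for m, _, w in index]
    for v in views:
        tup = per_view_keys[v.view_name]
        members: dict = {}
        for i, t in enumerate(tup):
            members.setdefault(t, []).append(i)
        mat = np.full((v.n_features, len(index)), np.nan)
        mask = np.zeros(len(index), dtype=bool)
        for t, idx in members.items():
            mat[:, pos[t]] = v.values[:, idx].mean(axis=1)
            mask[pos[t]] = True
        out_views[v.view_name] = OmicView(
            v.view_name, list(v.feature_ids), labels, mat, "normalized"
        )
        observed[v.view_name] = mask
        log.info("match_profiles: view %s observed in %d / %d profiles",
                 v.view_name, int(mask.sum()), len(index))
    return ProfileSet(profiles=profiles, views=out_views, observed=observed)


def missingness_report(ps: ProfileSet) -> pd.DataFrame:
    """Observed profile counts per view, plus the grand total of data points."""
    rows = [
        {"view": name, "n_observed": int(ps.observed[name].sum()),
         "n_features": ps.views[name].n_features}
        for name in ps.view_names
    ]
    df = pd.DataFrame(rows)
    total = int(df["n_observed"].sum())
    df = pd.concat(
        [df, pd.DataFrame([{"view": "total", "n_observed": total,
                            "n_features": int(df["n_features"].sum())}])],
        ignore_index=True,
    )
    return df
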