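"""Longitudinal survival data containers, I/O and landmarking transforms.

The canonical in-memory object is :class:`LongitudinalDataset`: per-subject
baseline covariates, an ordered table of time-stamped multivariate visits,
and the survival outcome (observed time, event indicator).  Landmarking
transforms produce :class:`LandmarkedView` objects that restrict each
subject's history to the information available at a landmark time, which is
the basic currency of dynamic survival prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = [
    "LongitudinalDataset",
    "LandmarkedView",
    "SchemaError",
    "ValidationError",
    "read_long_table",
    "write_long_table",
    "locf_impute",
    "landmark",
    "super_landmark",
    "random_truncate",
    "kfold_split",
]


class SchemaError(ValueError):
    """A mandatory column is missing or mis-declared in the schema mapping."""


class ValidationError(ValueError):
    """The data violate a dataset invariant (naming the offending subject)."""


@dataclass(frozen=True)
class LongitudinalDataset:
    """Subjects with baseline covariates, longitudinal visits and outcomes.

    Parameters
    ----------
    baseline : pd.DataFrame
        One row per subject (index = subject id), K numeric baseline columns.
    visits : pd.DataFrame
        Long format, one row per visit: ``subject_id``, ``time`` and Q
        longitudinal value columns (NaN = missing).  Sorted by subject then
        time, strictly increasing within subject.
    outcomes : pd.DataFrame
        One row per subject (index = subject id) with columns ``time``
        (observed time T_i = min(T*_i, C_i)) and ``event`` (delta in {0,1}).
    """

    baseline: pd.DataFrame
    visits: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def subject_ids(self) -> np.ndarray:
        return self.baseline.index.to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.baseline)

    @property
    def baseline_cols(self) -> list[str]:
        return list(self.baseline.columns)

    @property
    def long_cols(self) -> list[str]:
        return [c for c in self.visits.columns if c not in ("subject_id", "time")]

    @property
    def n_visits(self) -> pd.Series:
        """Visit count J_i per subject, indexed like ``baseline``."""
        counts = self.visits.groupby("subject_id", sort=False).size()
        return counts.reindex(self.baseline.index, fill_value=0)

    def validate(self) -> "LongitudinalDataset":
        """Check all dataset invariants, raising :class:`ValidationError`."""
        idx = self.baseline.index
        if idx.has_duplicates:
            raise ValidationError("duplicate subject ids in baseline table")
        if not idx.equals(self.outcomes.index):
            raise ValidationError("baseline and outcomes must index the same subjects")
        t = self.outcomes["time"]
        if (t <= 0).any():
            bad = t.index[t <= 0][0]
            raise ValidationError(f"subject {bad!r}: observed time must be > 0")
        ev = self.outcomes["event"]
        if not ev.isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        visit_sub = set(self.visits["subject_id"])
        if not visit_sub.issubset(set(idx)):
            raise ValidationError("visit rows reference unknown subjects")
        missing = set(idx) - visit_sub
        if missing:
            raise ValidationError(
                f"subject {sorted(missing, key=str)[0]!r}: every subject needs >= 1 visit"
            )
        for sid, grp in self.visits.groupby("subject_id", sort=False):
            times = grp["time"].to_numpy()
            if np.any(np.diff(times) <= 0):
                raise ValidationError(f"subject {sid!r}: visit times not strictly increasing")
            if times[-1] > self.outcomes.at[sid, "time"]:
                raise ValidationError(
                    f"subject {sid!r}: visit at t={times[-1]} after observed time"
                )
        return self

    def subset(self, ids) -> "LongitudinalDataset":
        """Restrict to the given subject ids (order preserved as given)."""
        ids = pd.Index(ids)
        return LongitudinalDataset(
            baseline=self.baseline.loc[ids],
            visits=self.visits[self.visits["subject_id"].isin(set(ids))].reset_index(drop=True),
            outcomes=self.outcomes.loc[ids],
        )

    def equals(self, other: "LongitudinalDataset") -> bool:
        return (
            self.baseline.equals(other.baseline)
            and self.visits.reset_index(drop=True).equals(other.visits.reset_index(drop=True))
            and self.outcomes.equals(other.outcomes)
        )


@dataclass(frozen=True)
class LandmarkedView:
    """A landmark-truncated dataset together with its provenance.

    ``data`` satisfies all :class:`LongitudinalDataset` invariants; every
    retained subject is still at risk at its landmark and carries only the
    visits observed up to it.  Under the ``super`` strategy a subject may
    appear once per landmark under a replicate id; ``source_id`` maps each
    (possibly replicated) id back to the original subject.
    """

    data: LongitudinalDataset
    landmarks: pd.Series  # per (replicate) subject id: the truncation time l
    strategy: str  # none | strict | super | random
    source_id: pd.Series = field(default=None)  # replicate id -> original id

    def __post_init__(self):
        if self.source_id is None:
            object.__setattr__(
                self,
                "source_id",
                pd.Series(self.data.baseline.index, index=self.data.baseline.index),
            )


def _default_schema() -> dict:
    return {
        "subject_id": "subject_id",
        "time": "visit_time",
        "event_time": "event_time",
        "event": "event",
    }


def read_long_table(path, schema: dict | None = None) -> LongitudinalDataset:
    """Read a long-format CSV (one row per subject-visit) into a dataset.

    ``schema`` maps the roles ``subject_id``/``time``/``event_time``/``event``
    to column names and may carry ``baseline`` and ``longitudinal`` column
    lists; unlisted columns are inferred from ``baseline_*`` / ``long_*``
    prefixes.  Categorical baseline columns are one-hot encoded (first level
    dropped, levels sorted) so the encoding is deterministic.
    """
    schema = {**_default_schema(), **(schema or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for role in ("subject_id", "time", "event_time", "event"):
        if schema[role] not in df.columns:
            raise SchemaError(f"column {schema[role]!r} (role {role}) missing from {path}")

    id_c, t_c, et_c, ev_c = (schema[r] for r in ("subject_id", "time", "event_time", "event"))
    if df.duplicated(subset=[id_c, t_c]).any():
        dup = df[df.duplicated(subset=[id_c, t_c])].iloc[0]
        raise ValidationError(f"duplicated (id, time) row: ({dup[id_c]!r}, {dup[t_c]!r})")

    base_cols = schema.get("baseline") or [c for c in df.columns if c.startswith("baseline_")]
    long_cols = schema.get("longitudinal") or [c for c in df.columns if c.startswith("long_")]
    if not long_cols:
        raise SchemaError("no longitudinal columns found (prefix 'long_' or schema['longitudinal'])")

    df = df.sort_values([id_c, t_c], kind="mergesort").reset_index(drop=True)
    first = df.groupby(id_c, sort=False).first()

    baseline = first[base_cols].copy()
    cat_cols = [c for c in base_cols if not pd.api.types.is_numeric_dtype(baseline[c])]
    if cat_cols:
        baseline = pd.get_dummies(baseline, columns=cat_cols, drop_first=True, dtype=float)
        baseline = baseline[sorted(baseline.columns)] if schema.get("sort_dummies") else baseline
    baseline = baseline.astype(float)
    baseline.index.name = "subject_id"

    outcomes = pd.DataFrame(
        {"time": first[et_c].astype(float), "event": first[ev_c].astype(int)}
    )
    outcomes.index.name = "subject_id"

    visits = df[[id_c, t_c] + long_cols].rename(columns={id_c: "subject_id", t_c: "time"})
    visits["time"] = visits["time"].astype(float)
    visits[long_cols] = visits[long_cols].astype(float)

    return LongitudinalDataset(baseline, visits, outcomes.astype({"time": float})).validate()


def write_long_table(ds: LongitudinalDataset, path) -> None:
    """Write ``ds`` as a long-format CSV inverting :func:`read_long_table`.

    Baseline columns are prefixed ``baseline_`` and longitudinal columns
    ``long_`` unless already so prefixed; numeric fields are written at full
    precision (repr round-trip).
    """
    rows = ds.visits.copy()
    ren = {c: (c if c.startswith("long_") else f"long_{c}") for c in ds.long_cols}
    rows = rows.rename(columns={"time": "visit_time", **ren})
    base = ds.baseline.rename(
        columns={c: (c if c.startswith("baseline_") else f"baseline_{c}") for c in ds.baseline_cols}
    )
    out = ds.outcomes.rename(columns={"time": "event_time"})
    merged = rows.merge(base, left_on="subject_id", right_index=True, how="left")
    merged = merged.merge(out, left_on="subject_id", right_index=True, how="left")
    cols = (
        ["subject_id", "visit_time", "event_time", "event"]
        + list(base.columns)
        + [ren.get(c, c) for c in ds.long_cols]
    )
    merged[cols].to_csv(path, index=False, float_format="%.17g")


def locf_impute(ds: LongitudinalDataset) -> LongitudinalDataset:
    """Last observation carried forward within each subject's visit series.

    Values missing at every visit up to j stay missing; encoders resolve
    those with training-set means at encoding time.
    """
    visits = ds.visits.copy()
    visits[ds.long_cols] = visits.groupby("subject_id", sort=False)[ds.long_cols].ffill()
    return replace(ds, visits=visits)


def landmark(ds: LongitudinalDataset, l: float) -> LandmarkedView:
    """Landmark at time ``l``: drop subjects with T_i <= l and visits after l.

    Subjects whose first visit falls after ``l`` are also dropped (no usable
    history).  Visits with t_ij exactly equal to ``l`` are kept.
    """
    if l < 0:
        raise ValueError("landmark time must be >= 0")
    at_risk = ds.outcomes.index[ds.outcomes["time"] > l]
    visits = ds.visits[
        ds.visits["subject_id"].isin(set(at_risk)) & (ds.visits["time"] <= l)
    ].reset_index(drop=True)
    keep = pd.Index(pd.unique(visits["subject_id"]))
    keep = at_risk[at_risk.isin(set(keep))]  # preserve original order
    if len(keep) == 0:
        warnings.warn(f"landmark l={l}: no subjects remain at risk", stacklevel=2)
    data = LongitudinalDataset(
        baseline=ds.baseline.loc[keep],
        visits=visits[visits["subject_id"].isin(set(keep))].reset_index(drop=True),
        outcomes=ds.outcomes.loc[keep],
    )
    return LandmarkedView(
        data=data,
        landmarks=pd.Series(float(l), index=keep),
        strategy="strict",
    )


def super_landmark(ds: LongitudinalDataset, landmarks) -> LandmarkedView:
    """Stack landmark(ds, l) over all ``landmarks`` into one training set.

    Each retained copy of a subject gets a replicate id ``"{sid}::l{l}"`` and
    is tagged with its landmark; a subject appears once per landmark at which
    it is still at risk with at least one visit.
    """
    landmarks = list(landmarks)
    if not landmarks:
        raise ValueError("landmarks must be non-empty")
    if len(set(landmarks)) != len(landmarks):
        raise ValueError("duplicate landmark values")
    bases, visits, outs, lms, src = [], [], [], [], []
    for l in landmarks:
        view = landmark(ds, l)
        d = view.data
        rep = pd.Index([f"{sid}::l{l:g}" for sid in d.baseline.index])
        b = d.baseline.copy()
        b.index = rep
        o = d.outcomes.copy()
        o.index = rep
        v = d.visits.copy()
        v["subject_id"] = v["subject_id"].map(
            dict(zip(d.baseline.index, rep))
        )
        bases.append(b)
        visits.append(v)
        outs.append(o)
        lms.append(pd.Series(float(l), index=rep))
        src.append(pd.Series(d.baseline.index, index=rep))
    data = LongitudinalDataset(
        pd.concat(bases), pd.concat(visits, ignore_index=True), pd.concat(outs)
    )
    return LandmarkedView(
        data=data,
        landmarks=pd.concat(lms),
        strategy="super",
        source_id=pd.concat(src),
    )


def random_truncate(ds: LongitudinalDataset, rng: np.random.Generator) -> LandmarkedView:
    """Truncate each subject to a uniformly drawn number of visits.

    For subject i an index l ~ Uniform{1, ..., J_i} is drawn independently
    and only the first l visits are kept; outcomes and baselines are
    untouched.  Intended to be called anew every training epoch.
    """
    counts = ds.n_visits
    draw = {
        sid: int(rng.integers(1, j + 1)) for sid, j in counts.items()
    }
    keep_mask = np.zeros(len(ds.visits), dtype=bool)
    lm = {}
    pos = ds.visits.groupby("subject_id", sort=False).indices
    times = ds.visits["time"].to_numpy()
    for sid, idx in pos.items():
        k = draw[sid]
        keep_mask[idx[:k]] = True
        lm[sid] = float(times[idx[k - 1]])
    data = replace(ds, visits=ds.visits[keep_mask].reset_index(drop=True))
    return LandmarkedView(
        data=data,
        landmarks=pd.Series(lm).reindex(ds.baseline.index),
        strategy="random",
    )


def as_view(ds: LongitudinalDataset) -> LandmarkedView:
    """Wrap a full dataset as a no-landmarking view (l = last visit time)."""
    last = ds.visits.groupby("subject_id", sort=False)["time"].max()
    return LandmarkedView(
        data=ds, landmarks=last.reindex(ds.baseline.index), strategy="none"
    )


def kfold_split(ds: LongitudinalDataset, k: int, seed: int):
    """Subject-level k-fold partition, deterministic under ``seed``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > ds.n_subjects:
        raise ValueError(f"k={k} exceeds the number of subjects ({ds.n_subjects})")
    ids = ds.subject_ids
    folds = []
    for tr, te in KFold(n_splits=k, shuffle=True, random_state=seed).split(ids):
        folds.append((ds.subset(ids[tr]), ds.subset(ids[te])))
    return folds
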