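"""Ingestion of ADNI TADPOLE-schema tables into the longitudinal data model.

The TADPOLE table is long format (one row per subject-visit, id ``RID``,
visit time ``Years_bl`` in years since baseline, diagnosis ``DX``).  The
time-to-event outcome is the time to the first dementia diagnosis; subjects
never diagnosed are censored at their last non-dementia visit, and subjects
already demented at baseline are excluded.  Access to the actual dataset is
restricted; these helpers only require a CSV following its schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LongitudinalDataset

__all__ = ["TADPOLE_BASELINE", "TADPOLE_LONGITUDINAL", "prepare_tadpole", "read_tadpole_csv"]

TADPOLE_BASELINE = ["APOE4", "PTEDUCAT", "PTETHCAT", "PTGENDER", "PTMARRY", "PTRACCAT"]

TADPOLE_LONGITUDINAL = [
    "AGE_t",
    "ADAS11",
    "ADAS13",
    "CDRSB",
    "Entorhinal",
    "Fusiform",
    "Hippocampus",
    "ICV",
    "MMSE",
    "MidTemp",
    "RAVLT_forgetting",
    "RAVLT_immediate",
    "RAVLT_learning",
    "RAVLT_perc_forgetting",
    "Ventricles",
    "WholeBrain",
]


def _is_dementia(dx: pd.Series) -> pd.Series:
    return dx.astype(str).str.contains("Dementia", case=False, na=False)


def prepare_tadpole(df: pd.DataFrame, id_col: str = "RID", time_col: str = "Years_bl",
                    dx_col: str = "DX", baseline_cols=None, long_cols=None
                    ) -> LongitudinalDataset:
    """Build a :class:`LongitudinalDataset` from a TADPOLE-schema frame.

    Event time = time of the first dementia diagnosis; censoring time = last
    visit with a non-dementia diagnosis; subjects with dementia at their
    first visit are removed.  Categorical baseline features are one-hot
    encoded (first level dropped, levels sorted).  Visits at or after the
    event time are discarded.
    """
    baseline_cols = list(baseline_cols or [c for c in TADPOLE_BASELINE if c in df.columns])
    long_cols = list(long_cols or [c for c in TADPOLE_LONGITUDINAL if c in df.columns])
    if not long_cols:
        raise ValueError("no longitudinal feature columns found")
    df = df.sort_values([id_col, time_col], kind="mergesort").reset_index(drop=True)
    df["_dem"] = _is_dementia(df[dx_col])

    # exclusion is based on the first *observed* (non-missing) diagnosis
    with_dx = df[df[dx_col].notna()]
    first_dx_dem = with_dx.groupby(id_col, sort=False)["_dem"].first()
    keep_ids = first_dx_dem.index[~first_dx_dem]
    df = df[df[id_col].isin(set(keep_ids))]

    outcomes = {}
    for rid, grp in df.groupby(id_col, sort=False):
        dem = grp["_dem"].to_numpy()
        t = grp[time_col].to_numpy(float)
        if dem.any():
            j = int(np.argmax(dem))
            outcomes[rid] = (float(t[j]), 1)
        else:
            nd = ~grp[dx_col].isna().to_numpy()
            outcomes[rid] = (float(t[nd][-1]), 0)
    out = pd.DataFrame.from_dict(outcomes, orient="index", columns=["time", "event"])
    out.index.name = "subject_id"
    out = out[out["time"] > 0]

    df = df[df[id_col].isin(set(out.index))]
    base = df.groupby(id_col, sort=False).first()[baseline_cols]
    cat = [c for c in baseline_cols if not pd.api.types.is_numeric_dtype(base[c])]
    if cat:
        base = pd.get_dummies(base, columns=cat, drop_first=True, dtype=float)
    base = base.astype(float).loc[out.index]
    base.index.name = "subject_id"

    visits = df[[id_col, time_col] + long_cols].rename(
        columns={id_col: "subject_id", time_col: "time"}
    )
    visits = visits.merge(out["time"].rename("T"), left_on="subject_id", right_index=True)
    visits = visits[visits["time"] <= visits["T"]].drop(columns="T")
    # a recorded visit at the event time itself belongs to the outcome, keep
    # strictly earlier history for event subjects
    ev_ids = set(out.index[out["event"] == 1])
    is_ev = visits["subject_id"].isin(ev_ids)
    at_event = is_ev & (visits["time"] >= visits["subject_id"].map(out["time"]))
    visits = visits[~at_event].reset_index(drop=True)
    visits[long_cols] = visits[long_cols].astype(float)
    has_visit = set(visits["subject_id"])
    out = out.loc[[i for i in out.index if i in has_visit]]
    base = base.loc[out.index]
    return LongitudinalDataset(base, visits, out).validate()


def read_tadpole_csv(path, **kwargs) -> LongitudinalDataset:
    """Read a TADPOLE-schema CSV and apply :func:`prepare_tadpole`."""
    return prepare_tadpole(pd.read_csv(path, low_memory=False), **kwargs)
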