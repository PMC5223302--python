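"""CSV dialect for person-week and analysis-row tables.

Comma delimiter, UTF-8, header row, '.' decimal, booleans written as 0/1,
missing values as empty fields.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import DAY_COLUMNS, PERSON_WEEK_COLUMNS, ClusterSpec, TrialDesign

ANALYSIS_COLUMNS = ["person_id", "cluster_id", "arm", "week_index", "month",
                    "outcome", "y", "exp_same", "exp_lag", "site"]

_BOOL_PW = ["reported", "rti_symptoms", "gti_symptoms", "rti_exposure", "gti_exposure"]
_BOOL_AR = ["y", "exp_same", "exp_lag"]


def _encode_bool(s: pd.Series) -> pd.Series:
    out = s.astype("boolean").astype("Int8")
    return out


def write_person_weeks(df: pd.DataFrame, path: str | Path) -> None:
    cols = PERSON_WEEK_COLUMNS + [c for c in DAY_COLUMNS if c in df.columns]
    out = df[cols].copy()
    for c in _BOOL_PW:
        out[c] = _encode_bool(out[c])
    out.to_csv(path, index=False, encoding="utf-8")


def read_person_weeks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8",
                     dtype={"person_id": str, "cluster_id": str, "arm": str})
    for c in _BOOL_PW:
        df[c] = df[c].astype("Int8").astype("boolean")
    df["reported"] = df["reported"].fillna(False).astype(bool)
    for c in ("rti_site", "gti_site"):
        df[c] = df[c].fillna("").astype(str)
        df.loc[~df["reported"], c] = ""
    return df


def write_analysis_rows(df: pd.DataFrame, path: str | Path) -> None:
    out = df[[c for c in ANALYSIS_COLUMNS if c in df.columns]].copy()
    for c in _BOOL_AR:
        if c in out.columns:
            out[c] = _encode_bool(out[c])
    out.to_csv(path, index=False, encoding="utf-8")


def read_analysis_rows(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8",
                     dtype={"person_id": str, "cluster_id": str, "arm": str})
    for c in _BOOL_AR:
        if c in df.columns:
            df[c] = df[c].astype("Int8").astype("boolean")
    if "site" in df.columns:
        df["site"] = df["site"].fillna("").astype(str)
    return df


def write_design(design: TrialDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_design(path: str | Path) -> TrialDesign:
    df = pd.read_csv(path, encoding="utf-8", dtype={"cluster_id": str,
                                                    "corporation_id": str, "arm": str})
    clusters = [ClusterSpec(r.cluster_id, r.corporation_id, int(r.n_eligible),
                            float(r.risk_score)) for r in df.itertuples()]
    triplets = [list(df.loc[df["triplet"] == k, "cluster_id"])
                for k in sorted(df["triplet"].unique())]
    arm_of = {}
    if "arm" in df.columns and df["arm"].notna().all() and (df["arm"] != "").all():
        arm_of = dict(zip(df["cluster_id"], df["arm"]))
    design = TrialDesign(clusters=clusters, triplets=triplets, arm_of=arm_of)
    design.validate()
    return design
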