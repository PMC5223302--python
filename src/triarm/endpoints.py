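"""Endpoint construction: weekly symptom flags, designated episodes, and
lag-aligned exposure covariates.

The analysis endpoint is the "week with reported symptoms": a report week
containing at least one symptomatic day.  A designated episode is a maximal
run of successive symptomatic days for one outcome; runs continue across
the boundary of two adjacent reported weeks (an episode spanning a weekend
is counted in both weeks' flags) but cannot be asserted through unreported
weeks, which therefore terminate a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OUTCOMES
from .errors import DataError


@dataclass(frozen=True)
class EpisodeRecord:
    """A maximal run of consecutive symptomatic days for one person/outcome."""

    person_id: str
    outcome: str
    start_day: int      # absolute day index: (week_index - 1) * 7 + weekday, 0-based
    length_days: int


def _day_cols(outcome: str) -> list[str]:
    return [f"{outcome}_d{d}" for d in range(1, 8)]


def daily_to_weekly(records: pd.DataFrame) -> pd.DataFrame:
    """Recompute each weekly symptom flag as 'any symptomatic day this week'.

    Requires day vectors; weeks that carry neither a day vector nor a weekly
    flag are a data error.  All other columns pass through unchanged.
    """
    out = records.copy()
    for o in OUTCOMES:
        cols = _day_cols(o)
        if not all(c in out.columns for c in cols):
            if f"{o}_symptoms" not in out.columns:
                raise DataError(f"no day vectors and no weekly flag for outcome {o}")
            continue
        days = out[cols].to_numpy(dtype=float)
        reported = out["reported"].to_numpy(dtype=bool)
        missing_days = np.isnan(days).all(axis=1)
        flag_absent = out[f"{o}_symptoms"].isna().to_numpy()
        bad = reported & missing_days & flag_absent
        if bad.any():
            raise DataError(
                f"{int(bad.sum())} reported weeks have neither day vector nor "
                f"weekly flag for outcome {o}")
        any_day = np.nansum(days, axis=1) > 0
        flag = pd.array(any_day, dtype="boolean")
        flag[~reported | missing_days] = pd.NA
        # weeks with a stored flag but no day vector keep the stored flag
        keep = reported & missing_days & ~flag_absent
        flag[keep] = out.loc[keep, f"{o}_symptoms"]
        flag[~reported] = pd.NA
        out[f"{o}_symptoms"] = flag
    return out


def episodes_from_daily(records: pd.DataFrame) -> list[EpisodeRecord]:
    """Extract designated episodes as maximal runs of consecutive symptomatic
    absolute days, per person and outcome.

    Adjacent reported weeks share consecutive day indices, so a run crossing
    a week boundary merges automatically; an unreported week contributes no
    days and thus breaks any run.
    """
    episodes: list[EpisodeRecord] = []
    for o in OUTCOMES:
        cols = _day_cols(o)
        if not all(c in records.columns for c in cols):
            raise DataError(f"day vectors required for episode extraction ({o})")
        rep = records[records["reported"].astype(bool)]
        for pid, grp in rep.groupby("person_id", sort=True):
            grp = grp.sort_values("week_index")
            days = grp[cols].to_numpy(dtype=float)
            week_idx = grp["week_index"].to_numpy(dtype=int)
            abs_days = ((week_idx[:, None] - 1) * 7 + np.arange(7)[None, :]).ravel()
            sympt = np.nan_to_num(days, nan=0.0).ravel() > 0
            hit = abs_days[sympt]
            if hit.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(hit) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [hit.size - 1]))
            for s, e in zip(starts, ends):
                episodes.append(EpisodeRecord(
                    person_id=str(pid), outcome=o.upper(),
                    start_day=int(hit[s]), length_days=int(hit[e] - hit[s] + 1)))
    return episodes


def build_analysis_rows(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """One analysis row per reported person-week for the chosen outcome.

    ``exp_same`` is the same week's homologous exposure; ``exp_lag`` comes
    from the immediately preceding week index of the same person and is
    missing when that week was not reported (or does not exist).  Site is
    carried through for description but never modelled.
    """
    outcome = outcome.lower()
    if outcome not in OUTCOMES:
        raise DataError(f"unknown outcome {outcome!r}")
    rep = records[records["reported"].astype(bool)].copy()
    dup = rep.duplicated(subset=["person_id", "week_index"])
    if dup.any():
        pair = rep.loc[dup, ["person_id", "week_index"]].iloc[0]
        raise DataError(f"duplicate person-week: {pair.person_id} week {pair.week_index}")
    rep = rep.sort_values(["person_id", "week_index"], kind="mergesort")

    rows = pd.DataFrame({
        "person_id": rep["person_id"].to_numpy(),
        "cluster_id": rep["cluster_id"].to_numpy(),
        "arm": rep["arm"].to_numpy(),
        "week_index": rep["week_index"].to_numpy(dtype=int),
        "month": rep["month"].to_numpy(dtype=int),
        "outcome": outcome,
        "y": rep[f"{outcome}_symptoms"].astype("boolean").to_numpy(na_value=False),
        "exp_same": rep[f"{outcome}_exposure"].astype("boolean").to_numpy(na_value=False),
        "site": rep[f"{outcome}_site"].to_numpy(),
    })
    prev_week = rows["week_index"] - 1
    key = pd.MultiIndex.from_arrays([rows["person_id"], rows["week_index"]])
    prev_key = pd.MultiIndex.from_arrays([rows["person_id"], prev_week])
    exp_by_key = pd.Series(rows["exp_same"].to_numpy(), index=key)
    lag = exp_by_key.reindex(prev_key)
    rows["exp_lag"] = pd.array(lag.to_numpy(), dtype="boolean")
    rows["y"] = rows["y"].astype("boolean")
    rows["exp_same"] = rows["exp_same"].astype("boolean")
    return rows.reset_index(drop=True)
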