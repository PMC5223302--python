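"""Descriptive summaries: arm-level weekly prevalences, exposure-week
proportions with site breakdown, exposure-conditioned relative risks (ReR),
and descriptive intervention risk ratios (RRa).

ReR at a given timing is the ratio of conditional symptom proportions,

    ReR = P(symptoms | homologous exposure) / P(symptoms | no exposure),

with "same week" conditioning on the current week's reported exposure and
"following week" on the previous week's (rows whose previous week was not
reported are excluded from the latter).  The descriptive RRa of an
intervention arm is its ReR divided by the control arm's ReR.

All counts are kept as exact integers; proportions are derived quantities.
Uncertainty intervals for raw proportions are central 95% Jeffreys
(Beta(1/2, 1/2) posterior) intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARMS
from .errors import DataError

TIMINGS = ("same_week", "following_week")


def jeffreys_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Central equal-tailed Beta(k + 1/2, n - k + 1/2) interval."""
    if n == 0:
        return (math.nan, math.nan)
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k + 0.5, n - k + 0.5))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 0.5, n - k + 0.5))
    return (lo, hi)


def round_display(x: float, ndigits: int = 3) -> float:
    """Half-even rounding used for printed proportions."""
    if not math.isfinite(x):
        return x
    from decimal import ROUND_HALF_EVEN, Decimal
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class ArmSummary:
    """Counts and proportions for one arm and outcome (weekly prevalence,
    exposure weeks, and site-of-exposure breakdown)."""

    arm: str
    outcome: str
    n_weeks: int
    n_symptom_weeks: int
    n_exposure_weeks: int
    site_counts: tuple[int, int, int]      # (only work, only elsewhere, both)
    flagged: bool = False                  # True when proportions are undefined

    @property
    def prevalence(self) -> float:
        return self.n_symptom_weeks / self.n_weeks if self.n_weeks else math.nan

    @property
    def exposure_proportion(self) -> float:
        return self.n_exposure_weeks / self.n_weeks if self.n_weeks else math.nan

    @property
    def prevalence_interval(self) -> tuple[float, float]:
        return jeffreys_interval(self.n_symptom_weeks, self.n_weeks)

    @property
    def exposure_interval(self) -> tuple[float, float]:
        return jeffreys_interval(self.n_exposure_weeks, self.n_weeks)


@dataclass
class StratumCounts:
    n_weeks: int
    n_symptom_weeks: int

    @property
    def proportion(self) -> float:
        return self.n_symptom_weeks / self.n_weeks if self.n_weeks else math.nan

    @property
    def interval(self) -> tuple[float, float]:
        return jeffreys_interval(self.n_symptom_weeks, self.n_weeks)


@dataclass
class ExposureStratifiedSummary:
    """Per-arm 2x2 of symptom weeks by exposure status at one timing."""

    arm: str
    outcome: str
    timing: str
    exposed: StratumCounts
    unexposed: StratumCounts
    rra_vs_control: float = math.nan
    flagged: bool = False

    @property
    def rer(self) -> float:
        pu = self.unexposed.proportion
        pe = self.exposed.proportion
        if not self.unexposed.n_weeks or not self.exposed.n_weeks:
            return math.nan
        if pu == 0.0:
            return math.inf if pe > 0 else math.nan
        return pe / pu


def arm_summary(rows: pd.DataFrame) -> list[ArmSummary]:
    """Tabulate reported weeks, symptom weeks, exposure weeks, and site counts
    per arm from analysis rows of a single outcome."""
    if rows.empty:
        raise DataError("no analysis rows")
    outcome = _single_outcome(rows)
    out = []
    for arm in ARMS:
        sub = rows[rows["arm"] == arm]
        n = len(sub)
        if n == 0:
            out.append(ArmSummary(arm, outcome, 0, 0, 0, (0, 0, 0), flagged=True))
            continue
        y = sub["y"].astype("boolean").fillna(False).to_numpy(dtype=bool)
        e = sub["exp_same"].astype("boolean").fillna(False).to_numpy(dtype=bool)
        site = sub["site"].astype(str).to_numpy()
        sites = (int(((site == "work") & e).sum()),
                 int(((site == "elsewhere") & e).sum()),
                 int(((site == "both") & e).sum()))
        out.append(ArmSummary(arm, outcome, n, int(y.sum()), int(e.sum()), sites))
    return out


def _single_outcome(rows: pd.DataFrame) -> str:
    vals = rows["outcome"].unique()
    if len(vals) != 1:
        raise DataError(f"rows mix outcomes: {sorted(vals)}")
    return str(vals[0])


def _exposure_at(rows: pd.DataFrame, timing: str) -> tuple[pd.DataFrame, np.ndarray]:
    if timing not in TIMINGS:
        raise DataError(f"unknown timing {timing!r}")
    if timing == "same_week":
        used = rows
        expo = rows["exp_same"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    else:
        keep = rows["exp_lag"].notna()
        used = rows[keep]
        expo = used["exp_lag"].astype("boolean").to_numpy(na_value=False)
    return used, expo


def rer(rows: pd.DataFrame, timing: str) -> list[ExposureStratifiedSummary]:
    """Exposure-conditioned relative risk per arm at the given timing."""
    outcome = _single_outcome(rows)
    used, expo = _exposure_at(rows, timing)
    out = []
    for arm in ARMS:
        mask = (used["arm"] == arm).to_numpy()
        y = used.loc[mask, "y"].astype("boolean").fillna(False).to_numpy(dtype=bool)
        e = expo[mask]
        exposed = StratumCounts(int(e.sum()), int(y[e].sum()))
        unexposed = StratumCounts(int((~e).sum()), int(y[~e].sum()))
        s = ExposureStratifiedSummary(arm, outcome, timing, exposed, unexposed)
        s.flagged = (not math.isfinite(s.rer)) or exposed.n_weeks == 0 or unexposed.n_weeks == 0
        out.append(s)
    return out


def rra_descriptive(summaries: list[ExposureStratifiedSummary]) -> list[ExposureStratifiedSummary]:
    """Attach descriptive RRa = ReR(arm) / ReR(control) to each summary.

    The control row is marked not relevant (NaN).  If the control ReR is
    undefined or zero, every RRa is undefined and flagged.
    """
    by_arm = {s.arm: s for s in summaries}
    control = by_arm.get("control")
    control_rer = control.rer if control is not None else math.nan
    ok = control is not None and math.isfinite(control_rer) and control_rer > 0
    for s in summaries:
        if s.arm == "control":
            s.rra_vs_control = math.nan
        elif ok and math.isfinite(s.rer):
            s.rra_vs_control = s.rer / control_rer
        else:
            s.rra_vs_control = math.nan
            s.flagged = True
    return summaries


def arm_summary_frame(summaries: list[ArmSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        pi = s.prevalence_interval
        ei = s.exposure_interval
        rows.append({
            "arm": s.arm, "outcome": s.outcome, "n_weeks": s.n_weeks,
            "n_symptom_weeks": s.n_symptom_weeks, "prevalence": s.prevalence,
            "prevalence_lo": pi[0], "prevalence_hi": pi[1],
            "n_exposure_weeks": s.n_exposure_weeks,
            "exposure_proportion": s.exposure_proportion,
            "exposure_lo": ei[0], "exposure_hi": ei[1],
            "site_only_work": s.site_counts[0],
            "site_only_elsewhere": s.site_counts[1],
            "site_both": s.site_counts[2],
            "flagged": s.flagged,
        })
    return pd.DataFrame(rows)


def rer_frame(summaries: list[ExposureStratifiedSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "arm": s.arm, "outcome": s.outcome, "timing": s.timing,
            "exposed_n_weeks": s.exposed.n_weeks,
            "exposed_n_symptom_weeks": s.exposed.n_symptom_weeks,
            "exposed_proportion": s.exposed.proportion,
            "unexposed_n_weeks": s.unexposed.n_weeks,
            "unexposed_n_symptom_weeks": s.unexposed.n_symptom_weeks,
            "unexposed_proportion": s.unexposed.proportion,
            "rer": s.rer, "rra_vs_control": s.rra_vs_control,
            "flagged": s.flagged,
        })
    return pd.DataFrame(rows)


def describe(rows: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Full descriptive report for one outcome's analysis rows."""
    arm = arm_summary_frame(arm_summary(rows))
    tables = {"arm_summary": arm}
    for timing in TIMINGS:
        tables[f"rer_{timing}"] = rer_frame(rra_descriptive(rer(rows, timing)))
    return tables
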