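"""Posterior predictive margins, arm risk ratios, and P(RRa < 1).

A predictive margin is the population-standardized weekly symptom
prevalence at a fixed arm and exposure status: for each posterior draw, the
arm and exposure of every row in the standardization population (all
reported person-weeks pooled across arms, months kept as observed) are set
to the target values, the person and cluster intercepts are integrated out
by drawing fresh u, v ~ N(0, sigma^2) per row ("new-individual" margin),
and exp(eta) is averaged over rows.  Any exp(eta) >= 1 met during the
integration is truncated to just below 1 and the truncation rate is
reported (the support constraint binds at observed patterns, not at
integrated tail draws).

Risk ratios versus control are per-draw ratios of paired margin samples
(same posterior draw and same random-effect draws), summarized by the
posterior median, the central 95% interval, and the fraction of draws
below 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ARMS
from .errors import TruncationError
from .model import ModelSpec, PosteriorDraws, collapse_interaction, rows_for_timing

logger = logging.getLogger(__name__)

EXPOSURE_STATUSES = ("exposed", "unexposed")
_TRUNC_AT = 1.0 - 1e-9


@dataclass
class MarginSample:
    """Posterior sample of one standardized margin."""

    arm: str
    exposure_status: str
    samples: np.ndarray
    truncation_rate: float

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.samples, [2.5, 97.5])
        return float(lo), float(hi)


@dataclass
class RiskRatioSummary:
    samples: np.ndarray
    median: float
    interval: tuple[float, float]
    p_below_1: float


def _margin_matrix(draws: PosteriorDraws, rows: pd.DataFrame,
                   combos: list[tuple[str, str]], seed: int,
                   triplet_of: dict[str, int] | None = None,
                   chunk: int = 200) -> tuple[dict, float]:
    """Margins for several (arm, exposure_status) combos sharing RE draws.

    Sharing the fresh random-effect draws across combos within a posterior
    draw pairs the margin samples, so ratios are free of independent
    integration noise.
    """
    spec = draws.spec
    rows = rows_for_timing(rows, spec.timing)
    months = rows["month"].to_numpy(dtype=int)
    n = len(rows)
    names = draws.colnames
    beta = draws.stacked("beta")              # (S, p)
    sp = draws.stacked("sigma_person")
    sc = draws.stacked("sigma_cluster")
    S = beta.shape[0]

    month_cols = {int(c[len("month["):-1]): j for j, c in enumerate(names)
                  if c.startswith("month[")}
    month_code = np.zeros(n, dtype=int)
    month_coef_idx = np.full(13, -1, dtype=int)
    for m, j in month_cols.items():
        month_coef_idx[m] = j
    row_month_j = month_coef_idx[months]      # -1 -> reference month

    trip_part_idx = None
    if any(c.startswith("triplet[") for c in names):
        if triplet_of is None:
            raise ValueError("draws include triplet terms; triplet_of required")
        trip_cols = {int(c[len("triplet["):-1]): j for j, c in enumerate(names)
                     if c.startswith("triplet[")}
        trips = np.array([triplet_of[c] for c in rows["cluster_id"]])
        trip_coef_idx = np.full(int(trips.max()) + 1, -1, dtype=int)
        for t, j in trip_cols.items():
            trip_coef_idx[t] = j
        trip_part_idx = trip_coef_idx[trips]

    def const_for(arm: str, status: str) -> np.ndarray:
        e = 1.0 if status == "exposed" else 0.0
        c = beta[:, names.index("intercept")].copy()
        if f"arm[{arm}]" in names:
            c += beta[:, names.index(f"arm[{arm}]")]
        if "exposure" in names:
            c += e * beta[:, names.index("exposure")]
        if f"arm[{arm}]:exposure" in names:
            c += e * beta[:, names.index(f"arm[{arm}]:exposure")]
        return c

    consts = {combo: const_for(*combo) for combo in combos}
    sums = {combo: np.zeros(S) for combo in combos}
    trunc = 0
    total = 0
    rng = np.random.default_rng(seed)
    log_cap = np.log(_TRUNC_AT)

    for s0 in range(0, S, chunk):
        s1 = min(s0 + chunk, S)
        m = s1 - s0
        u = rng.standard_normal((n, m)) * sp[s0:s1][None, :]
        u += rng.standard_normal((n, m)) * sc[s0:s1][None, :]   # u now holds u + v
        month_part = np.zeros((n, m))
        has_month = row_month_j >= 0
        if month_cols:
            month_part[has_month] = beta[s0:s1][:, row_month_j[has_month]].T
        if trip_part_idx is not None:
            has_t = trip_part_idx >= 0
            month_part[has_t] += beta[s0:s1][:, trip_part_idx[has_t]].T
        base = month_part + u
        for combo in combos:
            eta = base + consts[combo][s0:s1][None, :]
            over = eta >= log_cap
            trunc += int(over.sum())
            total += eta.size
            np.minimum(eta, log_cap, out=eta)
            sums[combo][s0:s1] = np.exp(eta).mean(axis=0)

    rate = trunc / total if total else 0.0
    return {combo: sums[combo] for combo in combos}, rate


def predictive_margin(draws: PosteriorDraws, rows: pd.DataFrame, arm: str,
                      exposure_status: str, seed: int = 0, *,
                      triplet_of: dict[str, int] | None = None,
                      strict: bool = False,
                      max_truncation: float = 0.01) -> MarginSample:
    """Posterior sample of the standardized margin for one arm/exposure cell."""
    samples, rate = _margin_matrix(draws, rows, [(arm, exposure_status)], seed,
                                   triplet_of=triplet_of)
    _check_truncation(rate, strict, max_truncation)
    return MarginSample(arm, exposure_status, samples[(arm, exposure_status)], rate)


def _check_truncation(rate: float, strict: bool, max_truncation: float) -> None:
    if rate > max_truncation:
        msg = (f"margin truncation rate {rate:.3%} exceeds {max_truncation:.1%}")
        if strict:
            raise TruncationError(msg)
        warnings.warn(msg, stacklevel=3)
    elif rate > 0:
        logger.info("margin truncation rate: %.4f%%", 100 * rate)


def risk_ratio(margins_a: np.ndarray, margins_control: np.ndarray) -> RiskRatioSummary:
    """Paired per-draw ratio of margin samples with median, 95% interval,
    and the posterior probability that the ratio is below 1."""
    a = np.asarray(margins_a, dtype=float)
    c = np.asarray(margins_control, dtype=float)
    if a.shape != c.shape:
        raise ValueError(f"unpaired margin samples: {a.shape} vs {c.shape}")
    ratio = a / c
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return RiskRatioSummary(samples=ratio, median=float(np.median(ratio)),
                            interval=(float(lo), float(hi)),
                            p_below_1=float(np.mean(ratio < 1.0)))


def margin_table(draws: PosteriorDraws, rows: pd.DataFrame, seed: int = 0, *,
                 triplet_of: dict[str, int] | None = None, strict: bool = False,
                 max_truncation: float = 0.01,
                 collapsed: bool = False) -> pd.DataFrame:
    """Margins, risk ratios and P(RRa < 1) for every arm x exposure cell of
    one fit.

    For a collapsed fit (no interaction) the risk ratio does not depend on
    the exposure stratum, and a single per-arm estimate is written to both
    strata.
    """
    combos = [(a, e) for a in ARMS for e in EXPOSURE_STATUSES]
    samples, rate = _margin_matrix(draws, rows, combos, seed, triplet_of=triplet_of)
    _check_truncation(rate, strict, max_truncation)

    recs = []
    for arm in ARMS:
        rr_by_status: dict[str, RiskRatioSummary | None] = {}
        for status in EXPOSURE_STATUSES:
            if arm == draws.spec.reference_arm:
                rr_by_status[status] = None
            elif collapsed:
                rr = risk_ratio(samples[(arm, "unexposed")],
                                samples[(draws.spec.reference_arm, "unexposed")])
                rr_by_status[status] = rr
            else:
                rr = risk_ratio(samples[(arm, status)],
                                samples[(draws.spec.reference_arm, status)])
                rr_by_status[status] = rr
        for status in EXPOSURE_STATUSES:
            marg = samples[(arm, status)]
            lo, hi = np.percentile(marg, [2.5, 97.5])
            rr = rr_by_status[status]
            recs.append({
                "outcome": draws.spec.outcome, "timing": draws.spec.timing,
                "arm": arm, "exposure_status": status,
                "margin": float(np.median(marg)),
                "margin_lo": float(lo), "margin_hi": float(hi),
                "rra": rr.median if rr else np.nan,
                "rra_lo": rr.interval[0] if rr else np.nan,
                "rra_hi": rr.interval[1] if rr else np.nan,
                "p_below_1": rr.p_below_1 if rr else np.nan,
                "collapsed": collapsed,
                "truncation_rate": rate,
            })
    return pd.DataFrame(recs)


def margin_report(fits: dict[tuple[str, str], PosteriorDraws],
                  rows_map: dict[tuple[str, str], pd.DataFrame],
                  refit, seed: int = 0, *,
                  triplet_of: dict[str, int] | None = None,
                  strict: bool = False) -> pd.DataFrame:
    """Full margin table set over outcomes and timings.

    For following-week fits the interaction-collapse rule is applied: when
    every arm x exposure interaction is credibly null the model is refit
    without it (via ``refit(spec, rows)``) and a single per-arm risk ratio
    is reported for both exposure strata.
    """
    tables = []
    for key, fit in fits.items():
        outcome, timing = key
        rows = rows_map[key]
        collapsed = False
        if timing == "following_week" and fit.spec.include_interaction:
            new_spec = collapse_interaction(fit, fit.spec)
            if not new_spec.include_interaction:
                fit = refit(new_spec, rows)
                collapsed = True
        tables.append(margin_table(fit, rows, seed=seed, triplet_of=triplet_of,
                                   strict=strict, collapsed=collapsed))
    return pd.concat(tables, ignore_index=True)
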