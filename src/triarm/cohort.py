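"""Synthetic three-arm cluster-randomized cohort generator.

The trial being emulated: 21 office clusters in 7 risk-score-matched
triplets, one cluster of each triplet randomized to each of three arms
(control, soap-and-water wash, alcohol hand rub), with weekly self-reports
of respiratory (RTI) and gastrointestinal (GTI) symptoms and of exposure to
persons with homologous symptoms, over ~70 weeks.

The generative model mirrors the analysis model: weekly symptom risk follows
a log-linear (log-binomial) regression

    log p = beta0 + beta_arm + beta_exp_same * E_t + beta_exp_lag * E_{t-1}
            + beta_interact * (arm x E_t) + beta_month(month) + u_i + v_j

with normal person (u_i) and cluster (v_j) random intercepts on the log
scale.  Exposure is a marked Bernoulli process per reported week, with a
site mark (work / elsewhere / both).  Reporting is incomplete: a per-week
reporting probability plus a geometric dropout time.  RTI and GTI outcomes
share the random intercepts but are otherwise drawn independently.

Because the link is log, the model only exists while every admissible
covariate pattern keeps exp(eta) < 1; `SimulationParams` enforces this at
construction with random effects pushed out to +/-4 SD, which in turn caps
how much log-scale heterogeneity the generator can carry.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calendar as _cal
from .errors import DesignError, GenerationError

ARMS = ("control", "soap_water", "alcohol_rub")
OUTCOMES = ("rti", "gti")
SITES = ("work", "elsewhere", "both")

N_CLUSTERS = 21
N_TRIPLETS = 7

PERSON_WEEK_COLUMNS = [
    "person_id", "cluster_id", "arm", "week_index", "month", "reported",
    "rti_symptoms", "gti_symptoms", "rti_exposure", "gti_exposure",
    "rti_site", "gti_site",
]
DAY_COLUMNS = [f"{o}_d{d}" for o in OUTCOMES for d in range(1, 8)]


@dataclass(frozen=True)
class ClusterSpec:
    """One office work unit eligible for randomization."""

    cluster_id: str
    corporation_id: str
    n_eligible: int
    risk_score: float

    def __post_init__(self):
        if self.n_eligible < 50:
            raise DesignError(
                f"cluster {self.cluster_id}: clusters require >= 50 eligible "
                f"employees, got {self.n_eligible}")
        if not math.isfinite(self.risk_score):
            raise DesignError(f"cluster {self.cluster_id}: risk_score not finite")


@dataclass
class TrialDesign:
    """21 clusters partitioned into 7 score-ranked triplets, one arm each."""

    clusters: list[ClusterSpec]
    triplets: list[list[str]]                 # 7 lists of 3 cluster ids
    arm_of: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.clusters)
        if n < 3 or n % 3:
            raise DesignError(f"cluster count must be a positive multiple of 3, got {n}")
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate cluster ids")
        if len(self.triplets) != n // 3 or any(len(t) != 3 for t in self.triplets):
            raise DesignError(f"triplets must be {n // 3} groups of 3")
        flat = [cid for t in self.triplets for cid in t]
        if sorted(flat) != sorted(ids):
            raise DesignError("triplets are not a partition of the cluster ids")
        if self.arm_of:
            for t in self.triplets:
                arms = sorted(self.arm_of[cid] for cid in t)
                if arms != sorted(ARMS):
                    raise DesignError(f"triplet {t} does not contain one cluster per arm")

    @property
    def triplet_of(self) -> dict[str, int]:
        return {cid: k + 1 for k, t in enumerate(self.triplets) for cid in t}

    def to_frame(self) -> pd.DataFrame:
        trip = self.triplet_of
        return pd.DataFrame({
            "cluster_id": [c.cluster_id for c in self.clusters],
            "corporation_id": [c.corporation_id for c in self.clusters],
            "n_eligible": [c.n_eligible for c in self.clusters],
            "risk_score": [c.risk_score for c in self.clusters],
            "triplet": [trip[c.cluster_id] for c in self.clusters],
            "arm": [self.arm_of.get(c.cluster_id, "") for c in self.clusters],
        })


def generate_clusters(seed: int, n_clusters: int = N_CLUSTERS,
                      n_corporations: int = 6) -> list[ClusterSpec]:
    """Draw cluster specs with uniform risk scores (only ranks matter downstream)."""
    rng = np.random.default_rng(seed)
    corps = rng.integers(0, n_corporations, size=n_clusters)
    sizes = rng.integers(50, 121, size=n_clusters)
    scores = rng.uniform(0.0, 100.0, size=n_clusters)
    return [
        ClusterSpec(cluster_id=f"C{i + 1:02d}", corporation_id=f"corp{corps[i] + 1}",
                    n_eligible=int(sizes[i]), risk_score=float(scores[i]))
        for i in range(n_clusters)
    ]


def assign_triplets(clusters: list[ClusterSpec],
                    n_triplets: int | None = None) -> TrialDesign:
    """Rank clusters by descending risk score; adjacent ranks of three form triplets.

    The canonical trial has 21 clusters in 7 triplets, which is enforced
    unless ``n_triplets`` is given explicitly (reduced presets).  Ties are
    broken lexicographically on cluster_id so the design is deterministic.
    """
    expected = N_CLUSTERS if n_triplets is None else 3 * n_triplets
    if len(clusters) != expected:
        raise DesignError(f"expected {expected} clusters, got {len(clusters)}")
    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate cluster ids")
    ranked = sorted(clusters, key=lambda c: (-c.risk_score, c.cluster_id))
    triplets = [[c.cluster_id for c in ranked[3 * k:3 * k + 3]]
                for k in range(len(clusters) // 3)]
    design = TrialDesign(clusters=ranked, triplets=triplets)
    design.validate()
    return design


def randomize_arms(design: TrialDesign, seed: int) -> TrialDesign:
    """Permute the three arms uniformly at random within each triplet."""
    if not design.triplets:
        raise DesignError("triplets must be assigned before randomization")
    rng = np.random.default_rng(seed)
    arm_of: dict[str, str] = {}
    for triplet in design.triplets:
        perm = rng.permutation(3)
        for cid, a in zip(triplet, perm):
            arm_of[cid] = ARMS[a]
    out = TrialDesign(clusters=list(design.clusters),
                      triplets=[list(t) for t in design.triplets],
                      arm_of=arm_of)
    out.validate()
    return out


@dataclass
class SimulationParams:
    """All generative coefficients (log-risk scale) plus the adherence model.

    ``beta_month`` holds one entry per calendar month and outcome with the
    reference month fixed at 0.  Exposure rates are weekly Bernoulli
    probabilities per outcome and arm; ``site_probs`` are the probabilities
    of (only work, only elsewhere, both) given an exposure.
    """

    beta0: dict[str, float]
    beta_arm: dict[str, dict[str, float]]          # arm -> outcome -> log RR
    beta_exp_same: dict[str, float]
    beta_exp_lag: dict[str, float]
    beta_interact: dict[str, dict[str, float]]     # arm -> outcome -> log RR
    beta_month: dict[str, np.ndarray]              # outcome -> length-12, ref month = 0
    sigma_person: float
    sigma_cluster: float
    exposure_rate: dict[str, dict[str, float]]     # outcome -> arm -> weekly prob
    site_probs: dict[str, tuple[float, float, float]]
    n_weeks: int = 70
    n_per_cluster: int = 37
    reporting_prob: float = 0.85
    dropout_hazard: float = 0.004
    with_days: bool = False
    start_year: int = _cal.DEFAULT_START_YEAR
    start_month: int = _cal.DEFAULT_START_MONTH
    seed: int = 0

    def __post_init__(self):
        for o in OUTCOMES:
            self.beta_month[o] = np.asarray(self.beta_month[o], dtype=float)
            if self.beta_month[o].shape != (12,):
                raise GenerationError(f"beta_month[{o}] must have 12 entries")
        if self.sigma_person < 0 or self.sigma_cluster < 0:
            raise GenerationError("random-effect SDs must be >= 0")
        for o in OUTCOMES:
            for a in ARMS:
                r = self.exposure_rate[o][a]
                if not 0.0 <= r <= 1.0:
                    raise GenerationError(f"exposure_rate[{o}][{a}]={r} outside [0,1]")
            s = self.site_probs[o]
            if len(s) != 3 or any(p < 0 for p in s) or abs(sum(s) - 1.0) > 1e-9:
                raise GenerationError(f"site_probs[{o}] must be 3 probabilities summing to 1")
        if not 0.0 <= self.reporting_prob <= 1.0:
            raise GenerationError("reporting_prob outside [0,1]")
        if not 0.0 <= self.dropout_hazard <= 1.0:
            raise GenerationError("dropout_hazard outside [0,1]")
        self._validate_support()

    def max_eta(self, outcome: str) -> tuple[float, str]:
        """Maximum linear predictor over admissible covariate patterns,
        with both random effects at +4 SD."""
        best, best_pat = -np.inf, ""
        months = self.beta_month[outcome]
        for arm in ARMS:
            for e_same in (0, 1):
                for e_lag in (0, 1):
                    eta = (self.beta0[outcome]
                           + self.beta_arm[arm][outcome]
                           + e_same * self.beta_exp_same[outcome]
                           + e_lag * self.beta_exp_lag[outcome]
                           + e_same * self.beta_interact[arm][outcome]
                           + float(months.max())
                           + 4.0 * self.sigma_person + 4.0 * self.sigma_cluster)
                    if eta > best:
                        best = eta
                        best_pat = (f"{outcome} arm={arm} exp_same={e_same} "
                                    f"exp_lag={e_lag} month={int(months.argmax()) + 1}")
        return best, best_pat

    def _validate_support(self) -> None:
        for o in OUTCOMES:
            eta, pat = self.max_eta(o)
            if eta >= 0.0:
                raise GenerationError(
                    f"log-link support violated: exp(eta) >= 1 at pattern [{pat}] "
                    f"(eta={eta:.4f} with random effects at +4 SD)")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)


def _seasonal(amplitude: float) -> np.ndarray:
    """Cosine month effects peaking in January (the reference month, fixed at 0)."""
    m = np.arange(12)
    return amplitude * (np.cos(2.0 * np.pi * m / 12.0) - 1.0)


def default_calibration(seed: int = 0, **overrides) -> SimulationParams:
    """Parameter set calibrated to the trial's observed arm-level summaries.

    Targets (approximate, at full trial size): control weekly RTI prevalence
    ~0.126 and GTI ~0.027; RTI exposure-week proportion ~0.27-0.29 and GTI
    ~0.06-0.07; same-week exposed/unexposed risk ratio ~5 for RTI and ~15
    for GTI with weaker lagged effects; soap-and-water arm protective mainly
    in unexposed weeks; alcohol-rub arm near null.
    """
    params = SimulationParams(
        beta0={"rti": math.log(0.0609), "gti": math.log(0.0144)},
        beta_arm={
            "control": {"rti": 0.0, "gti": 0.0},
            "soap_water": {"rti": math.log(0.68), "gti": math.log(0.59)},
            "alcohol_rub": {"rti": math.log(0.99), "gti": math.log(0.90)},
        },
        beta_exp_same={"rti": math.log(4.8), "gti": math.log(14.5)},
        beta_exp_lag={"rti": math.log(1.35), "gti": math.log(2.0)},
        beta_interact={
            "control": {"rti": 0.0, "gti": 0.0},
            "soap_water": {"rti": math.log(1.55), "gti": math.log(2.12)},
            "alcohol_rub": {"rti": math.log(0.95), "gti": math.log(1.26)},
        },
        beta_month={"rti": _seasonal(0.12), "gti": _seasonal(0.10)},
        sigma_person=0.10,
        sigma_cluster=0.04,
        exposure_rate={
            "rti": {"control": 0.282, "soap_water": 0.268, "alcohol_rub": 0.293},
            "gti": {"control": 0.066, "soap_water": 0.062, "alcohol_rub": 0.067},
        },
        site_probs={"rti": (0.325, 0.445, 0.230), "gti": (0.330, 0.560, 0.110)},
        seed=seed,
    )
    return params.replace(**overrides) if overrides else params


def recovery_calibration(seed: int = 0) -> SimulationParams:
    """Reduced-preset calibration for parameter-recovery studies.

    Keeps the 7-triplet design but shortens follow-up to 40 weeks with 50
    reporters per cluster, and switches off seasonality, lagged exposure
    effects and arm x exposure interactions so that the generating values of
    the same-week exposure effect and the arm effects are exactly the
    coefficients the reduced model fits.
    """
    return default_calibration(seed=seed).replace(
        n_weeks=40, n_per_cluster=50,
        beta_month={"rti": np.zeros(12), "gti": np.zeros(12)},
        beta_exp_lag={"rti": 0.0, "gti": 0.0},
        beta_interact={a: {"rti": 0.0, "gti": 0.0} for a in ARMS},
        seed=seed)


def null_calibration(seed: int = 0) -> SimulationParams:
    """Null-effect calibration for posterior-probability calibration studies:
    no arm effects, no interactions, equal exposure rates across arms, no
    seasonality, at a small per-replicate size (12 weeks, 8 reporters per
    cluster across the full 7-triplet design)."""
    return default_calibration(seed=seed).replace(
        n_weeks=12, n_per_cluster=8,
        beta_arm={a: {"rti": 0.0, "gti": 0.0} for a in ARMS},
        beta_interact={a: {"rti": 0.0, "gti": 0.0} for a in ARMS},
        beta_exp_lag={"rti": 0.0, "gti": 0.0},
        beta_month={"rti": np.zeros(12), "gti": np.zeros(12)},
        exposure_rate={"rti": {a: 0.28 for a in ARMS},
                       "gti": {a: 0.066 for a in ARMS}},
        seed=seed)


def simulate_dataset(design: TrialDesign, params: SimulationParams,
                     seed: int | None = None) -> pd.DataFrame:
    """Generate one person-week DataFrame for a randomized design.

    Each person gets normal log-scale random intercepts shared between the
    two outcomes; exposure is drawn before the same-week symptom it
    influences (the within-week causal direction is a modelling choice the
    data cannot identify); unreported weeks carry no symptom or exposure
    values.  The returned frame has one row per person-week including
    unreported ones, flagged by ``reported``.
    """
    design.validate()
    if not design.arm_of:
        raise DesignError("design has no arm assignment")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    n_weeks = params.n_weeks
    months = _cal.month_of_week(np.arange(1, n_weeks + 1),
                                params.start_year, params.start_month)

    cluster_ids = [c.cluster_id for c in design.clusters]
    n_per = params.n_per_cluster
    n_persons = n_per * len(cluster_ids)

    person_cluster = np.repeat(np.arange(len(cluster_ids)), n_per)
    arm_idx = np.array([ARMS.index(design.arm_of[cluster_ids[j]]) for j in person_cluster])

    u = rng.normal(0.0, params.sigma_person, size=n_persons)
    v = rng.normal(0.0, params.sigma_cluster, size=len(cluster_ids))

    # adherence: geometric dropout (week index after which reporting stops) + weekly gaps
    if params.dropout_hazard > 0:
        dropout = rng.geometric(params.dropout_hazard, size=n_persons)
    else:
        dropout = np.full(n_persons, np.iinfo(np.int64).max)
    reported = (rng.random((n_persons, n_weeks)) < params.reporting_prob)
    reported &= (np.arange(1, n_weeks + 1)[None, :] <= dropout[:, None])

    frames: dict[str, dict[str, np.ndarray]] = {}
    for o in OUTCOMES:
        rate = np.array([params.exposure_rate[o][ARMS[a]] for a in arm_idx])
        exposure = (rng.random((n_persons, n_weeks)) < rate[:, None]) & reported
        exp_lag = np.zeros_like(exposure)
        exp_lag[:, 1:] = exposure[:, :-1]   # unreported previous week => no exposure

        b_arm = np.array([params.beta_arm[a][o] for a in ARMS])[arm_idx]
        b_int = np.array([params.beta_interact[a][o] for a in ARMS])[arm_idx]
        eta = (params.beta0[o]
               + b_arm[:, None]
               + params.beta_exp_same[o] * exposure
               + params.beta_exp_lag[o] * exp_lag
               + b_int[:, None] * exposure
               + params.beta_month[o][months - 1][None, :]
               + u[:, None] + v[person_cluster][:, None])
        p = np.exp(eta)
        bad = (p >= 1.0) & reported
        if bad.any():
            i, t = np.argwhere(bad)[0]
            raise GenerationError(
                f"realized weekly risk >= 1 for outcome {o}: person {i}, week {t + 1}, "
                f"arm {ARMS[arm_idx[i]]}, exposure={bool(exposure[i, t])}, "
                f"lag={bool(exp_lag[i, t])}, month={months[t]} (p={p[i, t]:.4f})")
        symptoms = (rng.random((n_persons, n_weeks)) < p) & reported

        site = np.full((n_persons, n_weeks), "none", dtype=object)
        n_exp = int(exposure.sum())
        if n_exp:
            site[exposure] = rng.choice(np.array(SITES, dtype=object), size=n_exp,
                                        p=np.asarray(params.site_probs[o]))
        frames[o] = {"exposure": exposure, "symptoms": symptoms, "site": site}

    data = {
        "person_id": np.repeat([f"P{i + 1:04d}" for i in range(n_persons)], n_weeks),
        "cluster_id": np.repeat([cluster_ids[j] for j in person_cluster], n_weeks),
        "arm": np.repeat([ARMS[a] for a in arm_idx], n_weeks),
        "week_index": np.tile(np.arange(1, n_weeks + 1), n_persons),
        "month": np.tile(months, n_persons),
        "reported": reported.ravel(),
    }
    df = pd.DataFrame(data)
    rep = df["reported"].to_numpy()
    for o in OUTCOMES:
        sym = pd.array(frames[o]["symptoms"].ravel(), dtype="boolean")
        exp_ = pd.array(frames[o]["exposure"].ravel(), dtype="boolean")
        sym[~rep] = pd.NA
        exp_[~rep] = pd.NA
        df[f"{o}_symptoms"] = sym
        df[f"{o}_exposure"] = exp_
        site_col = frames[o]["site"].ravel().copy()
        site_col[~rep] = ""
        df[f"{o}_site"] = site_col

    if params.with_days:
        _add_day_vectors(df, rng)
    return df


def _add_day_vectors(df: pd.DataFrame, rng: np.random.Generator) -> None:
    """Draw per-day symptom vectors consistent with the weekly flags.

    A symptomatic week gets one within-week run (uniform start, geometric
    length clipped to the week); runs may touch the week edges so episodes
    can continue across adjacent reported weeks.
    """
    n = len(df)
    rep = df["reported"].to_numpy()
    for o in OUTCOMES:
        days = np.zeros((n, 7), dtype=float)
        days[~rep] = np.nan
        flag = df[f"{o}_symptoms"].fillna(False).to_numpy(dtype=bool)
        idx = np.flatnonzero(flag)
        starts = rng.integers(0, 7, size=idx.size)
        lengths = np.minimum(rng.geometric(0.45, size=idx.size), 7 - starts)
        for k, row in enumerate(idx):
            days[row, starts[k]:starts[k] + lengths[k]] = 1.0
        for d in range(7):
            df[f"{o}_d{d + 1}"] = days[:, d]
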