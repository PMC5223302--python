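"""Bayesian multilevel log-binomial regression for weekly symptom prevalence.

Model: for reported person-week r with symptom indicator y_r,

    y_r ~ Bernoulli(p_r),  log p_r = x_r' beta + u_person(r) + v_cluster(r)
    u_i ~ N(0, sigma_person^2),  v_j ~ N(0, sigma_cluster^2)

with fixed effects for intervention arm, reported homologous exposure
(same-week or lagged), optional arm x exposure interaction, calendar month,
and optionally the randomization triplet.  The log link makes exponentiated
coefficients risk ratios, at the cost of a bounded support: every fitted
probability must stay below 1, enforced by rejecting any proposal that
pushes a linear predictor to 0 or above.

Priors are proper but vague: Normal(0, sd^2) on fixed effects (default
sd = 10 on the log scale) and half-normal (default scale 2) on both
random-effect SDs.

Sampling is adaptive Metropolis-within-Gibbs: random-walk updates per fixed
effect coordinate (proposals touch only rows where the design column is
nonzero), simultaneous single-site updates for all person and all cluster
intercepts via grouped reductions, and log-scale random walks for the SDs.
Proposal scales adapt during burn-in only.  Convergence is checked with
split-R-hat and bulk ESS (arviz) on the reported parameters and failure
raises, carrying the offending parameters.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .errors import ConvergenceError, ModelDesignError
from .cohort import ARMS

REPORTED_RHAT_MAX = 1.05
REPORTED_ESS_MIN = 200.0


@dataclass(frozen=True)
class PriorSpec:
    """Vague proper priors: Normal(0, fixed_effect_sd^2) on fixed effects,
    half-normal(re_sd_scale) on random-effect SDs."""

    fixed_effect_sd: float = 10.0
    re_sd_family: str = "halfnormal"
    re_sd_scale: float = 2.0

    def __post_init__(self):
        if self.fixed_effect_sd <= 0 or self.re_sd_scale <= 0:
            raise ModelDesignError("prior scales must be positive")
        if self.re_sd_family != "halfnormal":
            raise ModelDesignError(f"unsupported RE-SD prior {self.re_sd_family!r}")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "rti"
    timing: str = "same_week"
    include_interaction: bool = True
    include_month: bool = True
    include_triplet: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)
    reference_month: int = 1
    reference_arm: str = "control"

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class ModelDesign:
    """Design matrix plus grouping indices, rows sorted by (cluster, person, week)."""

    X: np.ndarray
    colnames: list[str]
    y: np.ndarray
    person_idx: np.ndarray
    cluster_idx: np.ndarray
    person_ids: list[str]
    cluster_ids: list[str]
    months: np.ndarray
    spec: ModelSpec

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def interaction_cols(self) -> list[int]:
        return [i for i, c in enumerate(self.colnames) if ":exposure" in c]


def rows_for_timing(rows: pd.DataFrame, timing: str) -> pd.DataFrame:
    """Rows usable at a timing: following-week models drop missing-lag rows."""
    if timing == "following_week":
        return rows[rows["exp_lag"].notna()]
    return rows


def build_design(rows: pd.DataFrame, spec: ModelSpec,
                 triplet_of: dict[str, int] | None = None) -> ModelDesign:
    """Reference-coded design: intercept, 2 arm indicators, exposure, optional
    2 interaction columns, month indicators (reference month omitted, block
    dropped with a warning if only one month is present), optional 6 triplet
    indicators."""
    rows = rows_for_timing(rows, spec.timing)
    if rows.empty:
        raise ModelDesignError("no rows for the requested timing")
    rows = rows.sort_values(["cluster_id", "person_id", "week_index"],
                            kind="mergesort").reset_index(drop=True)
    n = len(rows)
    y = rows["y"].astype("boolean").fillna(False).to_numpy(dtype=bool)

    if spec.timing == "following_week":
        expo = rows["exp_lag"].astype("boolean").to_numpy(na_value=False).astype(float)
    else:
        expo = rows["exp_same"].astype("boolean").fillna(False).to_numpy(dtype=bool).astype(float)

    arms = rows["arm"].to_numpy()
    unseen = set(arms) - set(ARMS)
    if unseen:
        raise ModelDesignError(f"unseen arm levels: {sorted(unseen)}")

    present_arms = [a for a in ARMS if (arms == a).any()]
    if spec.reference_arm not in present_arms:
        raise ModelDesignError(f"reference arm {spec.reference_arm!r} absent from data")

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for arm in present_arms:
        if arm == spec.reference_arm:
            continue
        cols.append((arms == arm).astype(float))
        names.append(f"arm[{arm}]")
    cols.append(expo)
    names.append("exposure")
    if spec.include_interaction:
        for arm in present_arms:
            if arm == spec.reference_arm:
                continue
            cols.append((arms == arm).astype(float) * expo)
            names.append(f"arm[{arm}]:exposure")

    months = rows["month"].to_numpy(dtype=int)
    if spec.include_month:
        present = sorted(np.unique(months))
        if len(present) < 2:
            warnings.warn("single calendar month in data: month block dropped",
                          stacklevel=2)
        else:
            ref = spec.reference_month if spec.reference_month in present else present[0]
            for m in present:
                if m == ref:
                    continue
                cols.append((months == m).astype(float))
                names.append(f"month[{m}]")

    if spec.include_triplet:
        if triplet_of is None:
            raise ModelDesignError("include_triplet requires a cluster->triplet map")
        trip = np.array([triplet_of[c] for c in rows["cluster_id"]])
        present_t = sorted(np.unique(trip))
        for t in present_t[1:]:
            cols.append((trip == t).astype(float))
            names.append(f"triplet[{t}]")

    X = np.column_stack(cols)
    for j, name in enumerate(names[1:], start=1):
        s = X[:, j].sum()
        if s == 0:
            raise ModelDesignError(f"column {name} is identically zero")
        if s == n:
            raise ModelDesignError(f"column {name} is identically one")
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        raise ModelDesignError("design matrix is rank deficient")

    p_codes, p_ids = pd.factorize(rows["person_id"])
    c_codes, c_ids = pd.factorize(rows["cluster_id"])
    return ModelDesign(X=X, colnames=names, y=y.astype(np.uint8),
                       person_idx=p_codes.astype(np.int64),
                       cluster_idx=c_codes.astype(np.int64),
                       person_ids=list(p_ids), cluster_ids=list(c_ids),
                       months=months, spec=spec)


# ---------------------------------------------------------------------------
# log posterior (reference implementation; the sampler uses incremental forms)

_LOG_2PI = float(np.log(2.0 * np.pi))


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * x * x / (scale * scale)


def theta_layout(design: ModelDesign) -> dict[str, slice]:
    p = design.n_fixed
    n_u = len(design.person_ids)
    n_v = len(design.cluster_ids)
    return {
        "beta": slice(0, p),
        "sigma_person": slice(p, p + 1),
        "sigma_cluster": slice(p + 1, p + 2),
        "u": slice(p + 2, p + 2 + n_u),
        "v": slice(p + 2 + n_u, p + 2 + n_u + n_v),
    }


def log_posterior(theta: np.ndarray, design: ModelDesign, priors: PriorSpec) -> float:
    """Joint log density of fixed effects, RE SDs, and realized intercepts.

    ``theta`` is the flat vector [beta, sigma_person, sigma_cluster, u, v].
    Returns -inf outside the support (any fitted p >= 1, any SD <= 0).
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite theta")
    lay = theta_layout(design)
    beta = theta[lay["beta"]]
    sp = float(theta[lay["sigma_person"]][0])
    sc = float(theta[lay["sigma_cluster"]][0])
    u = theta[lay["u"]]
    v = theta[lay["v"]]
    if sp <= 0 or sc <= 0:
        return -np.inf
    eta = design.X @ beta + u[design.person_idx] + v[design.cluster_idx]
    if np.any(eta >= 0):
        return -np.inf
    y = design.y.astype(bool)
    ll = float(eta[y].sum() + np.log1p(-np.exp(eta[~y])).sum())
    sd = priors.fixed_effect_sd
    lp = float(-0.5 * np.sum(beta * beta) / (sd * sd)
               - beta.size * (0.5 * _LOG_2PI + np.log(sd)))
    lp += _halfnormal_logpdf(sp, priors.re_sd_scale)
    lp += _halfnormal_logpdf(sc, priors.re_sd_scale)
    lp += float(-0.5 * np.sum(u * u) / (sp * sp) - u.size * (0.5 * _LOG_2PI + np.log(sp)))
    lp += float(-0.5 * np.sum(v * v) / (sc * sc) - v.size * (0.5 * _LOG_2PI + np.log(sc)))
    return ll + lp


# ---------------------------------------------------------------------------
# sampler

@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned MCMC draws with convergence diagnostics."""

    beta: np.ndarray            # (chains, draws, p)
    sigma_person: np.ndarray    # (chains, draws)
    sigma_cluster: np.ndarray   # (chains, draws)
    u: np.ndarray               # (chains, draws, n_person)
    v: np.ndarray               # (chains, draws, n_cluster)
    colnames: list[str]
    person_ids: list[str]
    cluster_ids: list[str]
    diagnostics: pd.DataFrame
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: beta -> (draws, p), sigmas -> (draws,)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def beta_column(self, colname: str) -> np.ndarray:
        return self.stacked("beta")[:, self.colnames.index(colname)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value (fixed effects + SDs)."""
        recs = []
        for c in range(self.n_chains):
            for j, name in enumerate(self.colnames):
                recs.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(self.n_draws),
                    "parameter": name, "value": self.beta[c, :, j]}))
            recs.append(pd.DataFrame({"chain": c, "iteration": np.arange(self.n_draws),
                                      "parameter": "sigma_person",
                                      "value": self.sigma_person[c]}))
            recs.append(pd.DataFrame({"chain": c, "iteration": np.arange(self.n_draws),
                                      "parameter": "sigma_cluster",
                                      "value": self.sigma_cluster[c]}))
        return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# sampler

@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned MCMC draws with convergence diagnostics."""

    beta: np.ndarray            # (chains, draws, p)
    sigma_person: np.ndarray    # (chains, draws)
    sigma_cluster: np.ndarray   # (chains, draws)
    u: np.ndarray               # (chains, draws, n_person)
    v: np.ndarray               # (chains, draws, n_cluster)
    colnames: list[str]
    person_ids: list[str]
    cluster_ids: list[str]
    diagnostics: pd.DataFrame
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: beta -> (draws, p), sigmas -> (draws,)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def beta_column(self, colname: str) -> np.ndarray:
        return self.stacked("beta")[:, self.colnames.index(colname)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value (fixed effects + SDs)."""
        recs = []
        for c in range(self.n_chains):
            for j, name in enumerate(self.colnames):
                recs.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(self.n_draws),
                    "parameter": name, "value": self.beta[c, :, j]}))
            recs.append(pd.DataFrame({"chain": c, "iteration": np.arange(self.n_draws),
                                      "parameter": "sigma_person",
                                      "value": self.sigma_person[c]}))
            recs.append(pd.DataFrame({"chain": c, "iteration": np.arange(self.n_draws),
                                      "parameter": "sigma_cluster",
                                      "value": self.sigma_cluster[c]}))
        return pd.concat(recs, ignore_index=True)


@numba.njit(cache=True, fastmath=False)
def _chain_core(X, kk, w, pidx, cidx, u_ptr, v_ptr, n1_u, n1_v,
                col_ptr, col_idx, col_val, col_s1,
                sd2, re_scale2, n_iter, burn, seed, store_idx,
                kept_beta, kept_sp, kept_sc, kept_u, kept_v):
    """One MCMC chain over binomial cells.

    Rows with identical (person, covariate pattern) are pre-aggregated into
    cells with ``kk`` successes and ``w`` failures (the Bernoulli likelihood
    factorizes, so the posterior is unchanged).  Cells are sorted so that
    person groups (u_ptr) and cluster groups (v_ptr) are contiguous ranges.

    Moves per iteration: per-coordinate random walks on beta (sparse column
    updates), a joint beta move with covariance learned during burn-in,
    parallel single-site updates of all person then all cluster intercepts,
    log-scale random walks on both SDs, a joint (sigma, intercepts) rescale
    move that traverses the funnel, and a likelihood-invariant translation
    trading the fixed intercept against the random-intercept means.
    """
    np.random.seed(seed)
    n, p = X.shape
    n_u = n1_u.size
    n_v = n1_v.size
    tot_k = 0.0
    tot_m = 0.0
    for r in range(n):
        tot_k += kk[r]
        tot_m += kk[r] + w[r]
    pbar = max(tot_k / tot_m, 1e-4)

    beta = np.zeros(p)
    beta[0] = np.log(min(pbar, 0.5))
    # small jitter keeps sum(u^2) > 0 so the centered sigma conditional
    # stays proper at initialization
    u = np.empty(n_u)
    v = np.empty(n_v)
    for g in range(n_u):
        u[g] = 0.01 * np.random.normal()
    for g in range(n_v):
        v[g] = 0.01 * np.random.normal()
    sp = 0.1
    sc = 0.1
    eta = np.empty(n)
    ll0 = np.empty(n)
    for r in range(n):
        eta[r] = beta[0] + u[pidx[r]] + v[cidx[r]]
        ll0[r] = np.log1p(-np.exp(eta[r]))

    s_beta = np.full(p, 0.05)
    s_u = np.full(n_u, 0.5)
    s_v = np.full(n_v, 0.5)
    s_joint = 0.3
    s_trans_u = 0.1
    s_trans_v = 0.1
    target = 0.44
    target_joint = 0.23

    hist = np.empty((burn, p))
    L = np.zeros((p, p))
    have_chol = False
    scratch = np.empty(n)
    k_store = 0

    for it in range(n_iter):
        adapt = it < burn
        gamma = min(0.25, 2.0 / np.sqrt(it + 10.0)) if adapt else 0.0

        # ---- per-coordinate fixed effects
        for j in range(p):
            d = s_beta[j] * np.random.normal()
            lo = col_ptr[j]
            hi = col_ptr[j + 1]
            ok = True
            for k in range(lo, hi):
                if eta[col_idx[k]] + col_val[k] * d >= 0.0:
                    ok = False
                    break
            acc = 0.0
            if ok:
                dll = d * col_s1[j]
                for k in range(lo, hi):
                    r = col_idx[k]
                    if w[r] > 0.0:
                        dll += w[r] * (np.log1p(-np.exp(eta[r] + col_val[k] * d))
                                       - ll0[r])
                b_new = beta[j] + d
                dlp = (beta[j] * beta[j] - b_new * b_new) / (2.0 * sd2)
                if np.log(np.random.random()) < dll + dlp:
                    beta[j] = b_new
                    for k in range(lo, hi):
                        r = col_idx[k]
                        eta[r] += col_val[k] * d
                        ll0[r] = np.log1p(-np.exp(eta[r]))
                    acc = 1.0
            if adapt:
                s_beta[j] *= np.exp(gamma * (acc - target))

        # ---- joint fixed-effect move with learned covariance
        if adapt:
            for j in range(p):
                hist[it, j] = beta[j]
            if it >= 400 and it % 200 == 0:
                m0 = it // 2
                cnt = it - m0
                mean = np.zeros(p)
                for t in range(m0, it):
                    for j in range(p):
                        mean[j] += hist[t, j]
                for j in range(p):
                    mean[j] /= cnt
                cov = np.zeros((p, p))
                for t in range(m0, it):
                    for a in range(p):
                        da = hist[t, a] - mean[a]
                        for b in range(a, p):
                            cov[a, b] += da * (hist[t, b] - mean[b])
                ridge = 0.0
                for j in range(p):
                    cov[j, j] /= (cnt - 1)
                    ridge += cov[j, j]
                for a in range(p):
                    for b in range(a + 1, p):
                        cov[a, b] /= (cnt - 1)
                        cov[b, a] = cov[a, b]
                ridge = 1e-12 + 1e-6 * ridge / p
                for j in range(p):
                    cov[j, j] += ridge
                L = np.linalg.cholesky(cov)
                have_chol = True
        if have_chol:
            z = np.empty(p)
            for j in range(p):
                z[j] = np.random.normal()
            step = s_joint * (L @ z)
            xs = X @ step
            ok = True
            for r in range(n):
                scratch[r] = eta[r] + xs[r]
                if scratch[r] >= 0.0:
                    ok = False
                    break
            acc = 0.0
            if ok:
                dll = 0.0
                dlp = 0.0
                for j in range(p):
                    dll += step[j] * col_s1[j]
                    dlp += beta[j] * beta[j] - (beta[j] + step[j]) ** 2
                dlp /= 2.0 * sd2
                for r in range(n):
                    if w[r] > 0.0:
                        dll += w[r] * (np.log1p(-np.exp(scratch[r])) - ll0[r])
                if np.log(np.random.random()) < dll + dlp:
                    for j in range(p):
                        beta[j] += step[j]
                    for r in range(n):
                        eta[r] = scratch[r]
                        ll0[r] = np.log1p(-np.exp(eta[r]))
                    acc = 1.0
            if adapt:
                s_joint *= np.exp(gamma * (acc - target_joint))

        # ---- person then cluster intercepts (contiguous row ranges)
        for which in range(2):
            if which == 0:
                n_g, ptr, n1, scales, sig, vec = n_u, u_ptr, n1_u, s_u, sp, u
            else:
                n_g, ptr, n1, scales, sig, vec = n_v, v_ptr, n1_v, s_v, sc, v
            for g in range(n_g):
                z = scales[g] * np.random.normal()
                lo = ptr[g]
                hi = ptr[g + 1]
                ok = True
                for r in range(lo, hi):
                    if eta[r] + z >= 0.0:
                        ok = False
                        break
                acc = 0.0
                if ok:
                    dll = z * n1[g]
                    for r in range(lo, hi):
                        if w[r] > 0.0:
                            dll += w[r] * (np.log1p(-np.exp(eta[r] + z)) - ll0[r])
                    g_new = vec[g] + z
                    dlp = (vec[g] * vec[g] - g_new * g_new) / (2.0 * sig * sig)
                    if np.log(np.random.random()) < dll + dlp:
                        vec[g] = g_new
                        for r in range(lo, hi):
                            eta[r] += z
                            ll0[r] = np.log1p(-np.exp(eta[r]))
                        acc = 1.0
                if adapt:
                    scales[g] *= np.exp(gamma * (acc - target))
                    if scales[g] < 1e-4:
                        scales[g] = 1e-4
                    elif scales[g] > 10.0:
                        scales[g] = 10.0

        # ---- RE SDs, centered conditional: slice sample log sigma | u
        for which in range(2):
            cur = sp if which == 0 else sc
            vec = u if which == 0 else v
            ssq = 0.0
            for g in range(vec.size):
                ssq += vec[g] * vec[g]
            m = vec.size
            t0 = np.log(cur)

            def f_cent(t):
                s2 = np.exp(2.0 * t)
                return (-0.5 * ssq / s2 - m * t
                        - 0.5 * s2 / re_scale2 + t
                        - (-0.5 * ssq / (cur * cur) - m * t0
                           - 0.5 * cur * cur / re_scale2 + t0))

            logy = np.log(np.random.random())
            wstep = 0.5
            lo = t0 - wstep * np.random.random()
            hi = lo + wstep
            for _ in range(12):
                if lo <= -18.0 or f_cent(lo) <= logy:
                    break
                lo -= wstep
            for _ in range(12):
                if f_cent(hi) <= logy:
                    break
                hi += wstep
            t_new = t0
            for _ in range(60):
                t_try = lo + (hi - lo) * np.random.random()
                if f_cent(t_try) > logy:
                    t_new = t_try
                    break
                if t_try < t0:
                    lo = t_try
                else:
                    hi = t_try
            if t_new < -18.0:      # floor keeps sigma representable
                t_new = -18.0
            if which == 0:
                sp = np.exp(t_new)
            else:
                sc = np.exp(t_new)

        # ---- non-centered scale move: slice sample log sigma with the
        # standardized intercepts held fixed (u -> c*u as sigma -> c*sigma).
        # The RE prior cancels against the Jacobian c^(n+1), leaving
        # dll + d(halfnormal kernel) + dt.  This is the move that traverses
        # the sigma-u funnel.
        for which in range(2):
            if which == 0:
                cur, vec, gidx, n1 = sp, u, pidx, n1_u
            else:
                cur, vec, gidx, n1 = sc, v, cidx, n1_v
            dots = 0.0
            for g in range(vec.size):
                dots += n1[g] * vec[g]

            def f_resc(dt):
                c = np.exp(dt)
                dll = (c - 1.0) * dots
                for r in range(n):
                    en = eta[r] + (c - 1.0) * vec[gidx[r]]
                    if en >= 0.0:
                        return -1e300
                    if w[r] > 0.0:
                        dll += w[r] * (np.log1p(-np.exp(en)) - ll0[r])
                new_sig = c * cur
                return dll + 0.5 * (cur * cur - new_sig * new_sig) / re_scale2 + dt

            logy = np.log(np.random.random())
            wstep = 0.5
            lo = -wstep * np.random.random()
            hi = lo + wstep
            for _ in range(8):
                if f_resc(lo) <= logy:
                    break
                lo -= wstep
            for _ in range(8):
                if f_resc(hi) <= logy:
                    break
                hi += wstep
            for _ in range(60):
                dt = lo + (hi - lo) * np.random.random()
                if f_resc(dt) > logy:
                    c = np.exp(dt)
                    for r in range(n):
                        eta[r] += (c - 1.0) * vec[gidx[r]]
                        ll0[r] = np.log1p(-np.exp(eta[r]))
                    for g in range(vec.size):
                        vec[g] *= c
                    if which == 0:
                        sp = c * cur
                    else:
                        sc = c * cur
                    break
                if dt < 0.0:
                    lo = dt
                else:
                    hi = dt

        # ---- likelihood-invariant translation: intercept vs RE means
        for which in range(2):
            cur = sp if which == 0 else sc
            vec = u if which == 0 else v
            s_t = s_trans_u if which == 0 else s_trans_v
            delta = s_t * np.random.normal()
            tot = 0.0
            for g in range(vec.size):
                tot += vec[g]
            dlp = ((beta[0] * beta[0] - (beta[0] + delta) ** 2) / (2.0 * sd2)
                   + (2.0 * delta * tot - vec.size * delta * delta)
                   / (2.0 * cur * cur))
            acc = 0.0
            if np.log(np.random.random()) < dlp:
                beta[0] += delta
                for g in range(vec.size):
                    vec[g] -= delta
                acc = 1.0
            if adapt:
                if which == 0:
                    s_trans_u *= np.exp(gamma * (acc - target))
                else:
                    s_trans_v *= np.exp(gamma * (acc - target))

        # ---- periodic refresh against incremental float drift
        if (it + 1) % 2000 == 0:
            for g in range(n_v):
                for r in range(v_ptr[g], v_ptr[g + 1]):
                    e = v[g]
                    for j in range(p):
                        e += X[r, j] * beta[j]
                    eta[r] = e
            for g in range(n_u):
                for r in range(u_ptr[g], u_ptr[g + 1]):
                    eta[r] += u[g]
            for r in range(n):
                ll0[r] = np.log1p(-np.exp(eta[r]))

        if k_store < store_idx.size and it == store_idx[k_store]:
            for j in range(p):
                kept_beta[k_store, j] = beta[j]
            kept_sp[k_store] = sp
            kept_sc[k_store] = sc
            for g in range(n_u):
                kept_u[k_store, g] = u[g]
            for g in range(n_v):
                kept_v[k_store, g] = v[g]
            k_store += 1


def _run_chain(design: ModelDesign, priors: PriorSpec, n_iter: int, burn: int,
               seed: int, store_idx: np.ndarray):
    X = np.ascontiguousarray(design.X)
    y1 = design.y.astype(float)
    n, p = X.shape
    pidx, cidx = design.person_idx, design.cluster_idx
    n_u, n_v = len(design.person_ids), len(design.cluster_ids)

    # aggregate rows into binomial cells per (person, covariate pattern);
    # the Bernoulli likelihood factorizes so the posterior is unchanged
    arr = np.column_stack([pidx.astype(float), X])
    uniq, inverse = np.unique(arr, axis=0, return_inverse=True)
    m = np.bincount(inverse).astype(float)
    kk = np.bincount(inverse, weights=y1)
    w = m - kk
    pidx_c = uniq[:, 0].astype(np.int64)
    Xc = np.ascontiguousarray(uniq[:, 1:])
    cluster_of_person = np.zeros(n_u, dtype=np.int64)
    cluster_of_person[pidx] = cidx
    cidx_c = cluster_of_person[pidx_c]
    nc = Xc.shape[0]

    # CSR structure of nonzero design entries per column
    col_idx_list, col_val_list, col_ptr = [], [], [0]
    for j in range(p):
        nz = np.flatnonzero(Xc[:, j])
        col_idx_list.append(nz)
        col_val_list.append(Xc[nz, j])
        col_ptr.append(col_ptr[-1] + nz.size)
    col_idx = np.concatenate(col_idx_list).astype(np.int64)
    col_val = np.concatenate(col_val_list)
    col_ptr = np.asarray(col_ptr, dtype=np.int64)
    col_s1 = Xc.T @ kk

    # contiguous group ranges (cells sorted by person, persons by cluster)
    u_ptr = np.concatenate((np.searchsorted(pidx_c, np.arange(n_u)), [nc])).astype(np.int64)
    v_ptr = np.concatenate((np.searchsorted(cidx_c, np.arange(n_v)), [nc])).astype(np.int64)
    n1_u = np.bincount(pidx_c, weights=kk, minlength=n_u)
    n1_v = np.bincount(cidx_c, weights=kk, minlength=n_v)

    kept_beta = np.empty((store_idx.size, p))
    kept_sp = np.empty(store_idx.size)
    kept_sc = np.empty(store_idx.size)
    kept_u = np.empty((store_idx.size, n_u))
    kept_v = np.empty((store_idx.size, n_v))
    _chain_core(Xc, kk, w, pidx_c, cidx_c, u_ptr, v_ptr, n1_u, n1_v,
                col_ptr, col_idx, col_val, col_s1,
                float(priors.fixed_effect_sd) ** 2, float(priors.re_sd_scale) ** 2,
                n_iter, burn, seed, store_idx.astype(np.int64),
                kept_beta, kept_sp, kept_sc, kept_u, kept_v)
    return kept_beta, kept_sp, kept_sc, kept_u, kept_v


def _diagnostics(beta, sp, sc, colnames) -> pd.DataFrame:
    import arviz as az
    data = {name: beta[:, :, j] for j, name in enumerate(colnames)}
    data["sigma_person"] = sp
    data["sigma_cluster"] = sc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    recs = [{"parameter": k, "rhat": float(rhat[k].values), "ess": float(ess[k].values)}
            for k in data]
    return pd.DataFrame(recs)


def fit_mcmc(rows: pd.DataFrame, spec: ModelSpec, n_iter: int = 20_000,
             n_chains: int = 2, seed: int = 0, *,
             triplet_of: dict[str, int] | None = None,
             target_stored: int = 1000,
             rhat_max: float = REPORTED_RHAT_MAX,
             ess_min: float = REPORTED_ESS_MIN) -> PosteriorDraws:
    """Fit the model by adaptive Metropolis-within-Gibbs MCMC.

    Burn-in is the first half of ``n_iter`` (adaptation happens only there);
    the kept half is thinned to at most ``target_stored`` draws per chain
    (never more than 10,000).  Raises ConvergenceError when split-R-hat
    exceeds ``rhat_max`` or bulk ESS falls below ``ess_min`` for any fixed
    effect or random-effect SD.
    """
    if n_chains < 2:
        raise ModelDesignError("n_chains must be >= 2 for convergence diagnostics")
    design = build_design(rows, spec, triplet_of=triplet_of)
    burn = n_iter // 2
    if burn < 1 or n_iter <= burn:
        raise ModelDesignError("n_iter too small for 50% burn-in")
    n_keep = n_iter - burn
    n_store = min(n_keep, target_stored, 10_000)
    store_idx = burn + np.unique(
        np.floor(np.linspace(0, n_keep - 1, n_store)).astype(int))

    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
             for s in np.random.SeedSequence(seed).spawn(n_chains)]
    out = [_run_chain(design, spec.priors, n_iter, burn, s, store_idx)
           for s in seeds]
    beta = np.stack([o[0] for o in out])
    sp = np.stack([o[1] for o in out])
    sc = np.stack([o[2] for o in out])
    u = np.stack([o[3] for o in out])
    v = np.stack([o[4] for o in out])

    diag = _diagnostics(beta, sp, sc, design.colnames)
    bad = diag[(diag["rhat"] > rhat_max) | (diag["ess"] < ess_min)]
    if not bad.empty:
        raise ConvergenceError(
            "MCMC did not converge: "
            + "; ".join(f"{r.parameter} (rhat={r.rhat:.3f}, ess={r.ess:.0f})"
                        for r in bad.itertuples()),
            offending={r.parameter: {"rhat": r.rhat, "ess": r.ess}
                       for r in bad.itertuples()})
    return PosteriorDraws(beta=beta, sigma_person=sp, sigma_cluster=sc, u=u, v=v,
                          colnames=design.colnames, person_ids=design.person_ids,
                          cluster_ids=design.cluster_ids, diagnostics=diag, spec=spec)


def fit_mcmc_retry(rows: pd.DataFrame, spec: ModelSpec,
                   schedule: tuple[int, ...] = (8000, 16000, 24000),
                   seed: int = 0, **kw) -> PosteriorDraws:
    """``fit_mcmc`` with an escalating iteration schedule.

    A fit that fails the convergence diagnostics is repeated with more
    iterations (and fresh chain seeds); the last failure is re-raised if the
    whole schedule is exhausted.
    """
    last: ConvergenceError | None = None
    for k, n_iter in enumerate(schedule):
        try:
            return fit_mcmc(rows, spec, n_iter=n_iter, seed=seed + k, **kw)
        except ConvergenceError as exc:
            last = exc
    raise last


def collapse_interaction(fit: PosteriorDraws, spec: ModelSpec) -> ModelSpec:
    """Drop the arm x exposure interaction when it is credibly null.

    If every interaction coefficient's central 95% credible interval contains
    0, returns ``spec`` with ``include_interaction=False`` (the caller
    refits); otherwise returns ``spec`` unchanged.
    """
    inter = [i for i, c in enumerate(fit.colnames) if ":exposure" in c]
    if not inter:
        raise ModelDesignError("fit has no interaction terms to collapse")
    stacked = fit.stacked("beta")
    for j in inter:
        lo, hi = np.percentile(stacked[:, j], [2.5, 97.5])
        if not (lo <= 0.0 <= hi):
            return spec
    return spec.replace(include_interaction=False)
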