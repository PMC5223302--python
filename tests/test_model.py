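"""Design construction, log-posterior, MCMC behaviour, interaction collapse."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triarm import cohort
from triarm.errors import ConvergenceError, ModelDesignError
from triarm.model import (ModelDesign, ModelSpec, PosteriorDraws, PriorSpec,
                          build_design, collapse_interaction, fit_mcmc,
                          log_posterior, theta_layout)


def _rows(n, rng, months=(1,), arms=cohort.ARMS, n_person=None, outcome="rti"):
    n_person = n_person or max(6, n // 10)
    person = np.arange(n) % n_person       # deterministic coverage of levels
    cluster = person % 6
    return pd.DataFrame({
        "person_id": [f"P{i:03d}" for i in person],
        "cluster_id": [f"C{i}" for i in cluster],
        "arm": [arms[i % len(arms)] for i in cluster],
        "week_index": np.arange(n) + 1,
        "month": [months[j] for j in rng.integers(0, len(months), size=n)],
        "outcome": outcome,
        "y": pd.array(rng.random(n) < 0.2, dtype="boolean"),
        "exp_same": pd.array(rng.random(n) < 0.3, dtype="boolean"),
        "exp_lag": pd.array(rng.random(n) < 0.3, dtype="boolean"),
        "site": "none",
    })


class TestBuildDesign:
    def test_full_model_column_count(self):
        rows = _rows(600, np.random.default_rng(0), months=tuple(range(1, 13)))
        design = build_design(rows, ModelSpec(include_interaction=True))
        # 1 intercept + 2 arms + 1 exposure + 2 interactions + 11 months
        assert design.n_fixed == 17
        assert design.colnames[0] == "intercept"

    def test_single_month_drops_block_with_warning(self):
        rows = _rows(300, np.random.default_rng(1), months=(3,))
        with pytest.warns(UserWarning, match="month block dropped"):
            design = build_design(rows, ModelSpec())
        assert not any(c.startswith("month[") for c in design.colnames)

    def test_column_sums_match_tabulation(self):
        rows = _rows(500, np.random.default_rng(2), months=(1, 2, 3))
        design = build_design(rows, ModelSpec(include_interaction=False))
        used = rows.sort_values(["cluster_id", "person_id", "week_index"])
        for j, name in enumerate(design.colnames):
            if name.startswith("arm["):
                arm = name[4:-1]
                assert design.X[:, j].sum() == (used.arm == arm).sum()
            elif name.startswith("month["):
                m = int(name[6:-1])
                assert design.X[:, j].sum() == (used.month == m).sum()
            elif name == "exposure":
                assert design.X[:, j].sum() == used.exp_same.sum()

    def test_following_week_drops_missing_lag(self):
        rows = _rows(200, np.random.default_rng(3))
        rows.loc[:49, "exp_lag"] = pd.NA
        design = build_design(rows, ModelSpec(timing="following_week",
                                              include_month=False))
        assert design.n_rows == 150

    def test_unseen_arm_level_rejected(self):
        rows = _rows(100, np.random.default_rng(4))
        rows.loc[0, "arm"] = "placebo"
        with pytest.raises(ModelDesignError, match="unseen arm"):
            build_design(rows, ModelSpec(include_month=False))

    def test_triplet_block_requires_map(self):
        rows = _rows(100, np.random.default_rng(5))
        with pytest.raises(ModelDesignError, match="triplet"):
            build_design(rows, ModelSpec(include_triplet=True, include_month=False))


class TestLogPosterior:
    @staticmethod
    def _naive(theta, design, priors):
        """Term-by-term summation oracle using scipy densities."""
        lay = theta_layout(design)
        beta = theta[lay["beta"]]
        sp = theta[lay["sigma_person"]][0]
        sc = theta[lay["sigma_cluster"]][0]
        u, v = theta[lay["u"]], theta[lay["v"]]
        if sp <= 0 or sc <= 0:
            return -np.inf
        total = 0.0
        for r in range(design.n_rows):
            eta = float(design.X[r] @ beta + u[design.person_idx[r]]
                        + v[design.cluster_idx[r]])
            if eta >= 0:
                return -np.inf
            p = math.exp(eta)
            total += math.log(p) if design.y[r] else math.log(1.0 - p)
        for b in beta:
            total += stats.norm.logpdf(b, 0, priors.fixed_effect_sd)
        total += stats.halfnorm.logpdf(sp, scale=priors.re_sd_scale)
        total += stats.halfnorm.logpdf(sc, scale=priors.re_sd_scale)
        total += stats.norm.logpdf(u, 0, sp).sum()
        total += stats.norm.logpdf(v, 0, sc).sum()
        return total

    def test_matches_naive_oracle_on_small_datasets(self):
        priors = PriorSpec()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rows = _rows(rng.integers(5, 21), rng, months=(1, 2))
            design = build_design(rows, ModelSpec(include_month=True,
                                                  include_interaction=False))
            lay = theta_layout(design)
            dim = lay["v"].stop
            theta = rng.normal(0, 0.3, size=dim)
            theta[lay["beta"]][0] = -2.5
            theta[lay["sigma_person"]] = abs(theta[lay["sigma_person"]]) + 0.1
            theta[lay["sigma_cluster"]] = abs(theta[lay["sigma_cluster"]]) + 0.1
            got = log_posterior(theta, design, priors)
            want = self._naive(theta, design, priors)
            assert got == pytest.approx(want, abs=1e-10)

    def test_single_row_likelihood_term(self):
        # intercept-only design with one observed success: construct directly
        spec = ModelSpec(include_month=False, include_interaction=False)
        design = ModelDesign(
            X=np.ones((1, 1)), colnames=["intercept"],
            y=np.array([1], dtype=np.uint8),
            person_idx=np.array([0]), cluster_idx=np.array([0]),
            person_ids=["P0"], cluster_ids=["C0"],
            months=np.array([1]), spec=spec)
        # force p = 0.5 through the intercept, everything else zero
        lay = theta_layout(design)
        theta = np.zeros(lay["v"].stop)
        theta[0] = math.log(0.5)
        theta[lay["sigma_person"]] = 1.0
        theta[lay["sigma_cluster"]] = 1.0
        priors = PriorSpec()
        base = log_posterior(theta, design, priors)
        prior_only = (stats.norm.logpdf(theta[lay["beta"]], 0, 10).sum()
                      + 2 * stats.halfnorm.logpdf(1.0, scale=2)
                      + stats.norm.logpdf(0, 0, 1) * 2)
        assert base - prior_only == pytest.approx(math.log(0.5), abs=1e-12)

    def test_support_violation_is_minus_inf(self):
        rng = np.random.default_rng(8)
        rows = _rows(10, rng)
        design = build_design(rows, ModelSpec(include_month=False,
                                              include_interaction=False))
        lay = theta_layout(design)
        theta = np.zeros(lay["v"].stop)
        theta[0] = 0.5       # implies p > 1
        theta[lay["sigma_person"]] = theta[lay["sigma_cluster"]] = 1.0
        assert log_posterior(theta, design, PriorSpec()) == -np.inf

    def test_non_finite_theta_rejected(self):
        rng = np.random.default_rng(9)
        design = build_design(_rows(30, rng), ModelSpec(include_month=False,
                                                        include_interaction=False))
        theta = np.full(theta_layout(design)["v"].stop, np.nan)
        with pytest.raises(ValueError):
            log_posterior(theta, design, PriorSpec())


@pytest.fixture(scope="module")
def flat_fit_rows():
    """Homogeneous cohort: single arm-free structure for intercept checks."""
    rng = np.random.default_rng(100)
    n_person, weeks = 60, 30
    person = np.repeat(np.arange(n_person), weeks)
    y = rng.random(person.size) < 0.1
    return pd.DataFrame({
        "person_id": [f"P{i:03d}" for i in person],
        "cluster_id": [f"C{i % 6}" for i in person],
        "arm": [cohort.ARMS[i % 3] for i in person % 6 // 2],
        "week_index": np.tile(np.arange(weeks) + 1, n_person),
        "month": 1, "outcome": "rti",
        "y": pd.array(y, dtype="boolean"),
        "exp_same": pd.array(rng.random(person.size) < 0.3, dtype="boolean"),
        "exp_lag": pd.array([None] * person.size, dtype="boolean"),
        "site": "none",
    })


class TestFitMcmc:
    def test_identical_seed_identical_draws(self, flat_fit_rows):
        spec = ModelSpec(include_month=False, include_interaction=False)
        kw = dict(n_iter=3000, n_chains=2, seed=17, target_stored=200,
                  ess_min=0, rhat_max=np.inf)
        f1 = fit_mcmc(flat_fit_rows, spec, **kw)
        f2 = fit_mcmc(flat_fit_rows, spec, **kw)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.sigma_person, f2.sigma_person)

    def test_retained_draws_respect_support(self, flat_fit_rows):
        spec = ModelSpec(include_month=False, include_interaction=False)
        fit = fit_mcmc(flat_fit_rows, spec, n_iter=3000, n_chains=2, seed=18,
                       target_stored=100, ess_min=0, rhat_max=np.inf)
        design = build_design(flat_fit_rows, spec)
        for c in range(fit.n_chains):
            for k in range(0, fit.n_draws, 10):
                eta = (design.X @ fit.beta[c, k]
                       + fit.u[c, k][design.person_idx]
                       + fit.v[c, k][design.cluster_idx])
                assert (eta < 0).all()

    def test_intercept_only_limit_matches_proportion_posterior(self, flat_fit_rows):
        """With negligible heterogeneity the intercept margin agrees with the
        Beta-style posterior of the raw proportion."""
        spec = ModelSpec(include_month=False, include_interaction=False,
                         reference_arm="control")
        rows = flat_fit_rows.copy()
        rows["arm"] = "control"
        rows["exp_same"] = pd.array(
            [bool(b) for b in np.arange(len(rows)) % 7 == 0], dtype="boolean")
        fit = fit_mcmc(rows, spec, n_iter=8000, n_chains=2, seed=19,
                       target_stored=500)
        y = rows["y"].astype(bool).to_numpy()
        k, n = int(y.sum()), y.size
        beta_post = stats.beta(k + 0.5, n - k + 0.5)
        # compare overall risk: exp(b0 + b_exp * P(exp)) integrated crudely
        b0 = fit.beta_column("intercept")
        be = fit.beta_column("exposure")
        pexp = rows["exp_same"].astype(bool).mean()
        marg = np.exp(b0) * (1 - pexp + pexp * np.exp(be))
        assert abs(np.median(marg) - beta_post.median()) < 4 * beta_post.std()

    def test_nonconvergence_raises_with_offenders(self, flat_fit_rows):
        spec = ModelSpec(include_month=False, include_interaction=False)
        with pytest.raises(ConvergenceError) as exc:
            fit_mcmc(flat_fit_rows, spec, n_iter=300, n_chains=2, seed=20,
                     target_stored=100, ess_min=1e5)
        assert exc.value.offending

    def test_min_chain_count_enforced(self, flat_fit_rows):
        with pytest.raises(ModelDesignError):
            fit_mcmc(flat_fit_rows, ModelSpec(), n_chains=1, seed=0)


def _draws_with_beta(colnames, beta_matrix, sigma=1e-12):
    beta = np.asarray(beta_matrix)[None, :, :]
    s = np.full((1, beta.shape[1]), sigma)
    return PosteriorDraws(
        beta=beta, sigma_person=s, sigma_cluster=s,
        u=np.zeros((1, beta.shape[1], 1)), v=np.zeros((1, beta.shape[1], 1)),
        colnames=list(colnames), person_ids=["P0"], cluster_ids=["C0"],
        diagnostics=pd.DataFrame(), spec=ModelSpec())


class TestCollapseInteraction:
    COLS = ["intercept", "arm[soap_water]", "arm[alcohol_rub]", "exposure",
            "arm[soap_water]:exposure", "arm[alcohol_rub]:exposure"]

    def test_credibly_null_interactions_collapse(self):
        rng = np.random.default_rng(30)
        beta = rng.normal(0, 0.2, size=(500, 6))
        fit = _draws_with_beta(self.COLS, beta)
        spec = ModelSpec(include_interaction=True)
        assert collapse_interaction(fit, spec).include_interaction is False

    def test_strong_interaction_kept(self):
        rng = np.random.default_rng(31)
        beta = rng.normal(0, 0.05, size=(500, 6))
        beta[:, 4] += -0.5
        fit = _draws_with_beta(self.COLS, beta)
        spec = ModelSpec(include_interaction=True)
        assert collapse_interaction(fit, spec).include_interaction is True

    def test_missing_interaction_columns_rejected(self):
        fit = _draws_with_beta(["intercept", "exposure"],
                               np.zeros((10, 2)))
        with pytest.raises(ModelDesignError):
            collapse_interaction(fit, ModelSpec())


class TestSensitivity:
    def test_prior_scale_and_triplet_adjustment_negligible(self, small_rows_rti,
                                                           small_design):
        """Doubling the fixed-effect prior SD, or adding triplet indicators,
        moves the arm-contrast posterior medians by < 0.5 posterior SD."""
        spec = ModelSpec(include_month=False, include_interaction=False)
        kw = dict(n_iter=8000, n_chains=2, target_stored=500)
        base = fit_mcmc(small_rows_rti, spec, seed=40, **kw)
        wide = fit_mcmc(small_rows_rti, spec.replace(
            priors=PriorSpec(fixed_effect_sd=20.0)), seed=40, **kw)
        trip = fit_mcmc(small_rows_rti, spec.replace(include_triplet=True),
                        seed=40, triplet_of=small_design.triplet_of, **kw)
        for col in ("arm[soap_water]", "arm[alcohol_rub]"):
            ref = base.beta_column(col)
            for other in (wide, trip):
                diff = abs(np.median(other.beta_column(col)) - np.median(ref))
                assert diff < 0.5 * ref.std()
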