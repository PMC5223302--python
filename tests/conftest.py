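import numpy as np
import pytest

from triarm import cohort, endpoints


@pytest.fixture(scope="session")
def small_design():
    """9 clusters in 3 triplets, randomized."""
    clusters = cohort.generate_clusters(7, n_clusters=9)
    return cohort.randomize_arms(cohort.assign_triplets(clusters, n_triplets=3), 7)


@pytest.fixture(scope="session")
def small_params():
    return cohort.default_calibration(seed=7).replace(
        n_weeks=20, n_per_cluster=30, seed=7)


@pytest.fixture(scope="session")
def small_records(small_design, small_params):
    return cohort.simulate_dataset(small_design, small_params, seed=7)


@pytest.fixture(scope="session")
def small_rows_rti(small_records):
    return endpoints.build_analysis_rows(small_records, "rti")


def flat_params(**overrides):
    """Parameters with no arm, exposure, interaction or month effects, no
    heterogeneity, full reporting: weekly risk is exactly exp(beta0)."""
    base = dict(
        beta0={"rti": np.log(0.12), "gti": np.log(0.02)},
        beta_arm={a: {"rti": 0.0, "gti": 0.0} for a in cohort.ARMS},
        beta_exp_same={"rti": 0.0, "gti": 0.0},
        beta_exp_lag={"rti": 0.0, "gti": 0.0},
        beta_interact={a: {"rti": 0.0, "gti": 0.0} for a in cohort.ARMS},
        beta_month={"rti": np.zeros(12), "gti": np.zeros(12)},
        sigma_person=0.0,
        sigma_cluster=0.0,
        exposure_rate={"rti": {a: 0.0 for a in cohort.ARMS},
                       "gti": {a: 0.0 for a in cohort.ARMS}},
        site_probs={"rti": (0.3, 0.5, 0.2), "gti": (0.3, 0.5, 0.2)},
        reporting_prob=1.0,
        dropout_hazard=0.0,
    )
    base.update(overrides)
    return cohort.SimulationParams(**base)
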