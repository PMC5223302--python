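"""Trial-design and generative-model tests for the synthetic cohort."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triarm import cohort
from triarm.cohort import ARMS, ClusterSpec
from triarm.errors import DesignError, GenerationError
from tests.conftest import flat_params


def _clusters(scores):
    return [ClusterSpec(f"C{i + 1:02d}", "corp1", 60, float(s))
            for i, s in enumerate(scores)]


class TestTripletAssignment:
    def test_descending_scores_forced_partition(self):
        design = cohort.assign_triplets(_clusters(range(21, 0, -1)))
        scores = {c.cluster_id: c.risk_score for c in design.clusters}
        assert sorted(scores[c] for c in design.triplets[0]) == [19, 20, 21]
        assert sorted(scores[c] for c in design.triplets[6]) == [1, 2, 3]

    def test_tied_scores_deterministic_by_id(self):
        d1 = cohort.assign_triplets(_clusters([5.0] * 21))
        d2 = cohort.assign_triplets(_clusters([5.0] * 21))
        assert d1.triplets == d2.triplets
        assert d1.triplets[0] == ["C01", "C02", "C03"]

    def test_random_scores_reproducible(self):
        c1 = cohort.generate_clusters(42)
        c2 = cohort.generate_clusters(42)
        assert cohort.assign_triplets(c1).triplets == cohort.assign_triplets(c2).triplets

    def test_wrong_cluster_count_rejected(self):
        with pytest.raises(DesignError):
            cohort.assign_triplets(_clusters(range(20)))
        with pytest.raises(DesignError):
            cohort.assign_triplets(_clusters(range(9)))  # needs explicit n_triplets
        cohort.assign_triplets(_clusters(range(9)), n_triplets=3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=21, max_size=21))
    def test_triplets_respect_contiguous_ranks(self, scores):
        design = cohort.assign_triplets(_clusters(scores))
        ranked = sorted(design.clusters, key=lambda c: (-c.risk_score, c.cluster_id))
        expected = [[c.cluster_id for c in ranked[3 * k:3 * k + 3]] for k in range(7)]
        assert design.triplets == expected


class TestRandomization:
    def test_each_arm_seven_clusters(self):
        design = cohort.randomize_arms(cohort.assign_triplets(_clusters(range(21))), 1)
        counts = pd.Series(list(design.arm_of.values())).value_counts()
        assert all(counts[a] == 7 for a in ARMS)

    def test_seed_reproducible(self):
        base = cohort.assign_triplets(_clusters(range(21)))
        assert cohort.randomize_arms(base, 5).arm_of == cohort.randomize_arms(base, 5).arm_of

    def test_uniform_assignment_frequencies_and_balance(self):
        """Each cluster lands in each arm ~1/3 of the time; every seeded
        design keeps one cluster per arm per triplet."""
        base = cohort.assign_triplets(_clusters(range(21)))
        n = 10_000
        hits = {cid: {a: 0 for a in ARMS} for cid in base.arm_of or
                [c.cluster_id for c in base.clusters]}
        for seed in range(n):
            d = cohort.randomize_arms(base, seed)   # validates triplet balance
            for cid, a in d.arm_of.items():
                hits[cid][a] += 1
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for cid, arm_counts in hits.items():
            for a in ARMS:
                assert abs(arm_counts[a] / n - 1 / 3) < 3 * se


class TestSimulation:
    def test_zero_risk_limit_no_symptom_weeks(self, small_design):
        params = flat_params(beta0={"rti": -800.0, "gti": -800.0},
                             n_weeks=10, n_per_cluster=5)
        rec = cohort.simulate_dataset(small_design, params, seed=0)
        assert not rec["rti_symptoms"].fillna(False).any()
        assert not rec["gti_symptoms"].fillna(False).any()

    def test_bernoulli_mean_recovered_without_heterogeneity(self):
        """sigmas = 0, no covariate effects: empirical prevalence matches
        exp(beta0) = 0.12 within 3 binomial SEs at ~50k person-weeks."""
        clusters = cohort.generate_clusters(3)
        design = cohort.randomize_arms(cohort.assign_triplets(clusters), 3)
        params = flat_params(n_weeks=64, n_per_cluster=38)   # 21*38*64 > 50k
        rec = cohort.simulate_dataset(design, params, seed=3)
        y = rec["rti_symptoms"].to_numpy(dtype=bool, na_value=False)
        n = len(rec)
        se = math.sqrt(0.12 * 0.88 / n)
        assert abs(y.mean() - 0.12) < 3 * se

    def test_lognormal_marginal_mean_identity(self):
        """With log-normal random intercepts the marginal prevalence is
        exp(beta0 + (sigma_p^2 + sigma_c^2)/2) when truncation is negligible."""
        clusters = cohort.generate_clusters(4)
        design = cohort.randomize_arms(cohort.assign_triplets(clusters), 4)
        params = flat_params(beta0={"rti": np.log(0.05), "gti": np.log(0.01)},
                             sigma_person=0.5, n_weeks=64, n_per_cluster=38)
        rec = cohort.simulate_dataset(design, params, seed=4)
        y = rec["rti_symptoms"].to_numpy(dtype=bool, na_value=False)
        expected = 0.05 * math.exp(0.5 ** 2 / 2)
        # person effects are shared within persons: SE from the lognormal
        # variance across persons, not the Bernoulli variance across weeks
        n_person = 21 * 38
        var_p = 0.05 ** 2 * (math.exp(2 * 0.25) - math.exp(0.25))
        se = math.sqrt(var_p / n_person + expected / len(rec))
        assert abs(y.mean() - expected) < 3 * se

    def test_exposure_effect_recovered(self):
        """sigmas = 0: conditional prevalence ratio converges to
        exp(beta_exp_same) (3 MC SE at ~1e5 person-weeks)."""
        clusters = cohort.generate_clusters(5)
        design = cohort.randomize_arms(cohort.assign_triplets(clusters), 5)
        params = flat_params(
            beta0={"rti": np.log(0.05), "gti": np.log(0.01)},
            beta_exp_same={"rti": np.log(2.0), "gti": 0.0},
            exposure_rate={"rti": {a: 0.3 for a in ARMS},
                           "gti": {a: 0.0 for a in ARMS}},
            n_weeks=70, n_per_cluster=70)
        rec = cohort.simulate_dataset(design, params, seed=5)
        e = rec["rti_exposure"].to_numpy(dtype=bool, na_value=False)
        y = rec["rti_symptoms"].to_numpy(dtype=bool, na_value=False)
        p1, p0 = y[e].mean(), y[~e].mean()
        ratio = p1 / p0
        se = ratio * math.sqrt((1 - p1) / (p1 * e.sum()) + (1 - p0) / (p0 * (~e).sum()))
        assert abs(ratio - 2.0) < 3 * se

    def test_identical_seed_identical_records(self, small_design, small_params):
        r1 = cohort.simulate_dataset(small_design, small_params, seed=11)
        r2 = cohort.simulate_dataset(small_design, small_params, seed=11)
        pd.testing.assert_frame_equal(r1, r2)

    def test_unreported_weeks_carry_no_values(self, small_records):
        unrep = small_records[~small_records["reported"]]
        assert unrep["rti_symptoms"].isna().all()
        assert unrep["gti_exposure"].isna().all()
        assert (unrep["rti_site"] == "").all()

    def test_site_none_iff_unexposed(self, small_records):
        rep = small_records[small_records["reported"]]
        exposed = rep["rti_exposure"].to_numpy(dtype=bool, na_value=False)
        assert ((rep["rti_site"] != "none") == exposed).all()

    def test_day_vectors_consistent_with_weekly_flag(self, small_design):
        params = flat_params(beta0={"rti": np.log(0.3), "gti": np.log(0.05)},
                             with_days=True, n_weeks=8, n_per_cluster=10)
        rec = cohort.simulate_dataset(small_design, params, seed=6)
        rep = rec[rec["reported"]]
        days = rep[[f"rti_d{d}" for d in range(1, 8)]].to_numpy()
        assert ((np.nansum(days, axis=1) > 0)
                == rep["rti_symptoms"].to_numpy(dtype=bool)).all()


class TestParams:
    def test_support_validation_rejects_risky_parameters(self):
        with pytest.raises(GenerationError, match="support"):
            flat_params(beta0={"rti": np.log(0.5), "gti": np.log(0.01)},
                        sigma_person=0.5)

    def test_probability_bounds_checked(self):
        with pytest.raises(GenerationError):
            flat_params(reporting_prob=1.2)
        with pytest.raises(GenerationError):
            flat_params(site_probs={"rti": (0.5, 0.5, 0.5),
                                    "gti": (0.3, 0.5, 0.2)})

    def test_default_calibration_control_prevalence_in_range(self):
        """Control-arm weekly RTI prevalence stays in [0.10, 0.15] across
        20 simulated trials at full size."""
        for seed in range(20):
            clusters = cohort.generate_clusters(seed)
            design = cohort.randomize_arms(cohort.assign_triplets(clusters), seed)
            params = cohort.default_calibration(seed=seed)
            rec = cohort.simulate_dataset(design, params, seed=seed)
            ctrl = rec[(rec["arm"] == "control") & rec["reported"]]
            prev = ctrl["rti_symptoms"].to_numpy(dtype=bool, na_value=False).mean()
            assert 0.10 <= prev <= 0.15

    def test_default_calibration_valid_and_in_range(self):
        params = cohort.default_calibration(seed=0)
        eta_r, _ = params.max_eta("rti")
        eta_g, _ = params.max_eta("gti")
        assert eta_r < 0 and eta_g < 0
        assert 0.05 <= params.exposure_rate["gti"]["control"] <= 0.08
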