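"""Canned test datasets.

``toy_contingency_rows`` rebuilds, per outcome, a synthetic analysis-row
table whose arm-level marginal counts equal the trial's published
descriptive tables: total reported person-weeks, symptom weeks, exposure
weeks with site breakdown, and the same-week symptom x exposure cross-tab.
Only those marginals are reproduced — the joint arrangement of flags across
rows, and the persons/weeks themselves, are synthetic.  Lagged-exposure
columns reproduce the published exposed-stratum counts; rows whose lagged
status cannot be made consistent with the weekly totals carry a missing
lag (the published following-week table reuses the same-week denominators,
which no single dataset can satisfy exactly).

``smoke_rows`` is a small simulated analysis table with known generator
values for model smoke tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, endpoints
from .cohort import ARMS

# Published arm-level counts (control, soap_water, alcohol_rub) used as the
# reconstruction input.  Week totals per arm are shared by both outcomes.
WEEK_TOTALS = {"control": 11644, "soap_water": 15014, "alcohol_rub": 11986}

TABLE_COUNTS = {
    "rti": {
        "symptom_weeks": {"control": 1470, "soap_water": 1646, "alcohol_rub": 1546},
        "exposure_weeks": {"control": 3279, "soap_water": 4031, "alcohol_rub": 3507},
        "site": {"control": (1068, 1448, 763),
                 "soap_water": (1308, 1826, 897),
                 "alcohol_rub": (882, 1672, 953)},
        "exposed_symptom_weeks": {"control": 976, "soap_water": 1151,
                                  "alcohol_rub": 1042},
        "lag_exposed_weeks": {"control": 3279, "soap_water": 4031,
                              "alcohol_rub": 3507},
        "lag_exposed_symptom_weeks": {"control": 805, "soap_water": 848,
                                      "alcohol_rub": 838},
        "lag_unexposed_symptom_weeks": {"control": 594, "soap_water": 707,
                                        "alcohol_rub": 627},
    },
    "gti": {
        "symptom_weeks": {"control": 313, "soap_water": 282, "alcohol_rub": 274},
        "exposure_weeks": {"control": 767, "soap_water": 937, "alcohol_rub": 806},
        "site": {"control": (261, 437, 69),
                 "soap_water": (313, 493, 131),
                 "alcohol_rub": (251, 463, 92)},
        "exposed_symptom_weeks": {"control": 159, "soap_water": 159,
                                  "alcohol_rub": 143},
        "lag_exposed_weeks": {"control": 767, "soap_water": 937, "alcohol_rub": 806},
        "lag_exposed_symptom_weeks": {"control": 67, "soap_water": 51,
                                      "alcohol_rub": 63},
        "lag_unexposed_symptom_weeks": {"control": 226, "soap_water": 210,
                                        "alcohol_rub": 193},
    },
}

_SITES = ("work", "elsewhere", "both")


def toy_contingency_rows(outcome: str) -> pd.DataFrame:
    """Analysis rows whose arm-level count structure matches the published
    tables for one outcome.  Deterministic (no randomness)."""
    t = TABLE_COUNTS[outcome]
    frames = []
    for arm in ARMS:
        n = WEEK_TOTALS[arm]
        n_y = t["symptom_weeks"][arm]
        n_e = t["exposure_weeks"][arm]
        n_ey = t["exposed_symptom_weeks"][arm]
        n_le = t["lag_exposed_weeks"][arm]
        n_ley = t["lag_exposed_symptom_weeks"][arm]
        n_luy = t["lag_unexposed_symptom_weeks"][arm]

        y = np.zeros(n, dtype=bool)
        y[:n_y] = True
        e = np.zeros(n, dtype=bool)
        e[:n_ey] = True                       # symptomatic & exposed
        e[n_y:n_y + (n_e - n_ey)] = True      # non-symptomatic & exposed

        # lagged exposure: exposed-stratum counts exact; symptomatic weeks
        # that fit neither published lag stratum get a missing lag
        lag = pd.array(np.zeros(n, dtype=bool), dtype="boolean")
        lag[:n_ley] = True
        n_missing_y = n_y - n_ley - n_luy
        lag[n_ley:n_ley + n_missing_y] = pd.NA
        lag[n_y:n_y + (n_le - n_ley)] = True

        site = np.full(n, "none", dtype=object)
        exp_idx = np.flatnonzero(e)
        w, el, b = t["site"][arm]
        site[exp_idx[:w]] = "work"
        site[exp_idx[w:w + el]] = "elsewhere"
        site[exp_idx[w + el:w + el + b]] = "both"

        frames.append(pd.DataFrame({
            "person_id": [f"{arm}_{i:05d}" for i in range(n)],
            "cluster_id": [f"{arm}_cl{i % 7 + 1}" for i in range(n)],
            "arm": arm,
            "week_index": 1,
            "month": 1,
            "outcome": outcome,
            "y": pd.array(y, dtype="boolean"),
            "exp_same": pd.array(e, dtype="boolean"),
            "exp_lag": lag,
            "site": site,
        }))
    return pd.concat(frames, ignore_index=True)


def smoke_rows(seed: int, n_rows: int = 200) -> pd.DataFrame:
    """Small simulated analysis table with known generator values."""
    params = cohort.default_calibration(seed=seed).replace(
        n_weeks=12, n_per_cluster=4, seed=seed)
    design = cohort.randomize_arms(
        cohort.assign_triplets(cohort.generate_clusters(seed)), seed)
    records = cohort.simulate_dataset(design, params)
    rows = endpoints.build_analysis_rows(records, "rti")
    return rows.iloc[:n_rows].reset_index(drop=True)


def make_fixtures(seed: int, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Fixture bundle: the (constant) printed-table contingency datasets and
    a seed-dependent simulated smoke table."""
    bundle = {
        "contingency_rti": toy_contingency_rows("rti"),
        "contingency_gti": toy_contingency_rows("gti"),
        "smoke": smoke_rows(seed),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from . import io as _io
        for name, df in bundle.items():
            _io.write_analysis_rows(df, out / f"{name}.csv")
    return bundle
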