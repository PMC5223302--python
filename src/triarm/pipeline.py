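"""End-to-end pipeline: simulate -> endpoints -> describe -> fit -> margins.

Configuration is a nested key-value structure (YAML on disk) validated
strictly: unknown keys are an error naming the key.  Every run writes a
manifest recording the seed, a hash of the resolved configuration, package
versions, and a SHA-256 content hash of every output file.  Descriptive
outputs are bit-identical across reruns of the same config; MCMC outputs
are identical given the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort, descriptives, endpoints, fixtures, io as _io, margins as _margins
from .errors import ConfigError, TriarmError
from .model import ModelSpec, PriorSpec, fit_mcmc
from .cohort import OUTCOMES

logger = logging.getLogger(__name__)

_TIMINGS = ("same_week", "following_week")


@dataclass
class SimulationSection:
    enabled: bool = True
    n_triplets: int = 7
    n_weeks: int = 70
    n_per_cluster: int = 37
    reporting_prob: float = 0.85
    dropout_hazard: float = 0.004
    with_days: bool = False


@dataclass
class ModelSection:
    n_iter: int = 20_000
    n_chains: int = 2
    target_stored: int = 1000
    include_interaction: bool = True
    include_month: bool = True
    include_triplet: bool = False
    fixed_effect_sd: float = 10.0
    re_sd_scale: float = 2.0


@dataclass
class PipelineConfig:
    seed: int = 0
    out: str = "triarm_out"
    input: str | None = None           # existing person-week CSV; None -> simulate
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOMES))
    timings: list[str] = field(default_factory=lambda: list(_TIMINGS))
    strict: bool = False
    simulation: SimulationSection = field(default_factory=SimulationSection)
    model: ModelSection = field(default_factory=ModelSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _from_dict(cls, data: dict, path: str = "") -> object:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        ftype = fields[key].type
        if key == "simulation":
            value = _from_dict(SimulationSection, value or {}, "simulation.")
        elif key == "model":
            value = _from_dict(ModelSection, value or {}, "model.")
        kwargs[key] = value
    return cls(**kwargs)


def parse_config(data: dict) -> PipelineConfig:
    cfg = _from_dict(PipelineConfig, data)
    for o in cfg.outcomes:
        if o not in OUTCOMES:
            raise ConfigError(f"unknown outcome: {o}")
    for t in cfg.timings:
        if t not in _TIMINGS:
            raise ConfigError(f"unknown timing: {t}")
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return parse_config(yaml.safe_load(fh) or {})


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _simulation_params(cfg: PipelineConfig) -> cohort.SimulationParams:
    sim = cfg.simulation
    return cohort.default_calibration(seed=cfg.seed).replace(
        n_weeks=sim.n_weeks, n_per_cluster=sim.n_per_cluster,
        reporting_prob=sim.reporting_prob, dropout_hazard=sim.dropout_hazard,
        with_days=sim.with_days, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; outputs land under ``cfg.out``.

    On a stage failure the partial outputs are moved under ``<out>/failed/``
    and the error is re-raised annotated with the stage name.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    result: dict = {"out": out}
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    try:
        # ------------------------------------------------ simulate / load
        stage = "simulate"
        triplet_of = None
        if cfg.input is None:
            sim = cfg.simulation
            clusters = cohort.generate_clusters(cfg.seed, n_clusters=3 * sim.n_triplets)
            design = cohort.randomize_arms(
                cohort.assign_triplets(clusters, n_triplets=sim.n_triplets), cfg.seed)
            params = _simulation_params(cfg)
            records = cohort.simulate_dataset(design, params, seed=cfg.seed)
            emit("design.csv", lambda p: _io.write_design(design, p))
            emit("person_weeks.csv", lambda p: _io.write_person_weeks(records, p))
            triplet_of = design.triplet_of
            result["design"] = design
        else:
            records = _io.read_person_weeks(cfg.input)
        result["records"] = records

        # ------------------------------------------------ endpoints
        stage = "endpoints"
        rows_by_outcome: dict[str, pd.DataFrame] = {}
        for o in cfg.outcomes:
            rows = endpoints.build_analysis_rows(records, o)
            rows_by_outcome[o] = rows
            emit(f"analysis_rows_{o}.csv", lambda p, r=rows: _io.write_analysis_rows(r, p))
        result["rows"] = rows_by_outcome

        # ------------------------------------------------ describe
        stage = "describe"
        report_lines = []
        for o in cfg.outcomes:
            tables = descriptives.describe(rows_by_outcome[o])
            for name, df in tables.items():
                emit(f"describe_{o}_{name}.csv", lambda p, d=df: d.to_csv(p, index=False))
                report_lines += [f"== {o.upper()} {name} ==", df.to_string(index=False), ""]
        emit("describe_report.txt",
             lambda p: p.write_text("\n".join(report_lines), encoding="utf-8"))
        result["describe"] = True

        # ------------------------------------------------ fit
        stage = "fit"
        mdl = cfg.model
        priors = PriorSpec(fixed_effect_sd=mdl.fixed_effect_sd,
                           re_sd_scale=mdl.re_sd_scale)
        fits, rows_map = {}, {}
        for o in cfg.outcomes:
            for t in cfg.timings:
                spec = ModelSpec(outcome=o, timing=t,
                                 include_interaction=mdl.include_interaction,
                                 include_month=mdl.include_month,
                                 include_triplet=mdl.include_triplet, priors=priors)
                fit = fit_mcmc(rows_by_outcome[o], spec, n_iter=mdl.n_iter,
                               n_chains=mdl.n_chains, seed=cfg.seed,
                               triplet_of=triplet_of,
                               target_stored=mdl.target_stored)
                fits[(o, t)] = fit
                rows_map[(o, t)] = rows_by_outcome[o]
                emit(f"draws_{o}_{t}.csv",
                     lambda p, f=fit: f.to_frame().to_csv(p, index=False))
                emit(f"diagnostics_{o}_{t}.json",
                     lambda p, f=fit: p.write_text(
                         f.diagnostics.to_json(orient="records"), encoding="utf-8"))
        result["fits"] = fits

        # ------------------------------------------------ margins
        stage = "margins"

        def refit(spec, rows):
            return fit_mcmc(rows, spec, n_iter=mdl.n_iter, n_chains=mdl.n_chains,
                            seed=cfg.seed, triplet_of=triplet_of,
                            target_stored=mdl.target_stored)

        table = _margins.margin_report(fits, rows_map, refit, seed=cfg.seed,
                                       triplet_of=triplet_of, strict=cfg.strict)
        emit("margins.csv", lambda p: table.to_csv(p, index=False))
        emit("margins_report.txt",
             lambda p: p.write_text(table.to_string(index=False), encoding="utf-8"))
        result["margins"] = table

        # ------------------------------------------------ manifest
        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_hash": config_hash(cfg),
            "versions": _versions(),
            "files": {p.name: _sha256(p) for p in written},
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True),
                        encoding="utf-8")
        result["manifest"] = manifest
        return result

    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                shutil.move(str(p), failed / p.name)
        raise TriarmError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _versions() -> dict[str, str]:
    import arviz
    import numpy
    import scipy
    out = {"numpy": numpy.__version__, "scipy": scipy.__version__,
           "pandas": pd.__version__, "arviz": arviz.__version__}
    try:
        from importlib.metadata import version
        out["triarm"] = version("triarm")
    except Exception:
        out["triarm"] = "unknown"
    return out


def small_preset_config(seed: int, out: str, **model_overrides) -> PipelineConfig:
    """Reduced problem size for quick end-to-end runs: 3 triplets, 20 weeks,
    30 persons per cluster, short chains."""
    cfg = PipelineConfig(seed=seed, out=out)
    cfg.simulation = SimulationSection(n_triplets=3, n_weeks=20, n_per_cluster=30)
    cfg.model = ModelSection(n_iter=8000, n_chains=2, target_stored=500)
    for k, v in model_overrides.items():
        setattr(cfg.model, k, v)
    return cfg
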