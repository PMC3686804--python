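"""End-to-end orchestration: simulate/read -> filter -> fit -> check -> derive.

Every stage consumes and emits plain files, so runs are reproducible
bit-for-bit from the manifest alone, and each stage can be driven
separately from the command line.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import data as dmod
from . import derived, diagnostics
from .errors import ConvergenceError
from .model import CircleCountModel, Hyperpriors, MCMCConfig
from .regions import load_region_rules
from .simulate import SimulationConfig, default_config, simulate_dataset
from .util import to_plain_python

log = logging.getLogger("cbctrend")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: str
    input_csv: str | None = None          # read this table ...
    scenario: SimulationConfig | None = None  # ... or simulate this one
    min_total: int = 10
    min_coverage: float = 0.5
    region_rules: str | None = None       # YAML path; None = shipped default
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: Hyperpriors = field(default_factory=Hyperpriors)
    shift_years: tuple = (1980, 2010)
    halt_on_nonconvergence: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "input_csv": self.input_csv,
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "min_total": self.min_total,
            "min_coverage": self.min_coverage,
            "region_rules": self.region_rules,
            "mcmc": vars(self.mcmc),
            "priors": self.priors.to_dict(),
            "shift_years": list(self.shift_years),
            "halt_on_nonconvergence": self.halt_on_nonconvergence,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scenario"):
            d["scenario"] = SimulationConfig(**d["scenario"])
        if d.get("mcmc"):
            d["mcmc"] = MCMCConfig(**d["mcmc"])
        if d.get("priors"):
            d["priors"] = Hyperpriors(**d["priors"])
        if d.get("shift_years"):
            d["shift_years"] = tuple(d["shift_years"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write every intermediate artifact.

    Stage order: load/simulate, allocate unidentified counts, filter
    circles, fit, convergence check, posterior predictive check, derived
    tables (indices, trends, range centres), manifest.  Fails fast with
    the stage name on error; a non-converged fit halts after writing the
    diagnostics unless ``halt_on_nonconvergence`` is off.

    Returns the run manifest (also written to ``manifest.yaml``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}}
    t_start = time.time()

    def _stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t_start, 2)}

    try:
        _stage("load")
        rules = (load_region_rules(config.region_rules)
                 if config.region_rules else None)
        if config.scenario is not None:
            dataset, truth = simulate_dataset(config.scenario)
            truth.save(out / "truth.csv")
        elif config.input_csv is not None:
            dataset = dmod.read_count_table(config.input_csv, rules=rules)
            truth = None
        else:
            raise ValueError("RunConfig needs input_csv or scenario")
        dataset.write_csv(out / "dataset.csv")
        dmod.coverage_summary(dataset).to_csv(out / "coverage.csv", index=False)

        _stage("allocate")
        dataset = dmod.allocate_unidentified(dataset)

        _stage("filter")
        dataset, excluded = dmod.filter_circles(dataset, config.min_total,
                                                config.min_coverage)
        dataset.write_csv(out / "filtered.csv")
        excluded.to_csv(out / "excluded.csv", index=False)
        with open(out / "exclusions.txt", "w") as fh:
            for row in excluded.itertuples(index=False):
                fh.write(f"{row.circle_id}: {row.reason}\n")

        _stage("fit")
        model = CircleCountModel(dataset)
        results = model.fit(config.mcmc, config.priors)
        results.save(out / "draws.csv")
        results.convergence.to_csv(out / "convergence.csv", index=False)
        manifest["converged"] = bool(results.converged)
        manifest["max_rhat"] = float(results.convergence["rhat"].max())
        if not results.converged and config.halt_on_nonconvergence:
            raise ConvergenceError(
                "fit failed convergence checks (see convergence.csv); "
                "rerun with more iterations or halt_on_nonconvergence=False")

        _stage("ppc")
        ppc = results.ppc(seed=config.seed,
                          thin=max(1, results.draws.n_draws // 500))
        ppc.save(out / "ppc.csv")
        manifest["bayesian_p"] = float(ppc.bayesian_p)

        _stage("derive")
        results.abundance_index().to_csv(out / "indices.csv", index=False)
        trends = results.trend_table()
        trends.to_csv(out / "trends.csv", index=False)
        y0, y1 = config.shift_years
        shift = results.range_shift(int(y0), int(y1))
        centres = [results.range_centre(int(y)) for y in (y0, y1)]
        import pandas as pd

        pd.DataFrame(
            [(c.year, c.latitude_cm, c.lower95, c.upper95) for c in centres],
            columns=["year", "latitude_cm", "lower95", "upper95"]
        ).to_csv(out / "centres.csv", index=False)
        manifest["range_shift"] = shift
        manifest["trends"] = trends.to_dict("records")
        if truth is not None:
            manifest["true_rates"] = {
                r.name: truth.annual_percent_trend(r.name)
                for r in config.scenario.regions}
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        log.error("pipeline failed at stage %r: %s", failed, exc)
        manifest["failed_stage"] = failed
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(to_plain_python(manifest), fh, sort_keys=False)
        raise

    manifest["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(to_plain_python(manifest), fh, sort_keys=False)
    log.info("pipeline done in %.1fs", manifest["runtime_s"])
    return manifest


def rerun_from_manifest(manifest_path) -> dict:
    """Re-execute a run from its manifest; same seed, same outputs."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    return run_pipeline(RunConfig.from_dict(manifest["config"]))
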