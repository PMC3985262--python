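"""Run configuration, validation, and the end-to-end pipeline.

A run is described by a small YAML or JSON mapping: a parameter preset
(or inline per-hormone overrides), a scenario, grid settings, an output
directory and a seed.  Validation collects *all* problems before
raising, and unknown keys are rejected by name so typos surface
immediately.

``run_pipeline`` simulates both hormones for the configured scenario and
writes trajectory CSVs, per-hormone summaries, a therapeutic-window
report and a manifest (package version, seed, config hash) into the
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .metrics import range_crossings, summarize, DEFAULT_PLATEAU_WINDOW
from .model import SimulationGrid, simulate_difference
from .params import DrugParams, PRESET_NAMES, load_preset
from .scenarios import ScenarioSpec, build_regimen

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_TOP_KEYS = {"preset", "params", "scenario", "grid", "outdir", "seed",
             "plateau_window"}
_SCENARIO_KEYS = {"kind", "delay_days", "boundary_h", "detach_time",
                  "area_fraction", "duration", "reattach_vs_new"}
_GRID_KEYS = {"dt", "horizon"}
#: DrugParams fields overridable inline; decay_const_per_day is accepted as
#: the printed-table convention and divided by 24
_PARAM_KEYS = {f.name for f in dataclasses.fields(DrugParams)} | {"decay_const_per_day"}


class ConfigError(ValueError):
    """All configuration problems, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one pipeline run."""

    preset: str = "table1-verbatim"
    params: dict[str, DrugParams] = field(default_factory=dict)
    scenario: ScenarioSpec = field(
        default_factory=lambda: ScenarioSpec("standard_cycle"))
    dt: float = 0.1
    outdir: str = "patchpk-run"
    seed: int = 0
    plateau_window: tuple[float, float] = DEFAULT_PLATEAU_WINDOW

    def resolved_params(self) -> dict[str, DrugParams]:
        base = load_preset(self.preset)
        base.update(self.params)
        return base

    def to_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "scenario": {"kind": self.scenario.kind, **self.scenario.parameters},
            "grid": {"dt": self.dt},
            "outdir": self.outdir,
            "seed": self.seed,
            "plateau_window": list(self.plateau_window),
        }
        if self.params:
            d["params"] = {
                name: dataclasses.asdict(p) for name, p in self.params.items()
            }
        return d


def _parse_params(raw: dict, problems: list[str]) -> dict[str, DrugParams]:
    out: dict[str, DrugParams] = {}
    base = load_preset("table1-verbatim")
    for hormone, overrides in raw.items():
        if hormone not in base:
            problems.append(f"params: unknown hormone {hormone!r}")
            continue
        if not isinstance(overrides, dict):
            problems.append(f"params.{hormone}: expected a mapping of fields")
            continue
        unknown = set(overrides) - _PARAM_KEYS
        for key in sorted(unknown):
            problems.append(f"params.{hormone}: unknown key {key!r}")
        fields = {k: v for k, v in overrides.items() if k in _PARAM_KEYS}
        if "decay_const_per_day" in fields:
            if "decay_const" in fields:
                problems.append(
                    f"params.{hormone}: give decay_const or decay_const_per_day, not both")
            fields["decay_const"] = fields.pop("decay_const_per_day") / 24.0
        if unknown:
            continue
        try:
            out[hormone] = dataclasses.replace(base[hormone], **fields)
        except (TypeError, ValueError) as exc:
            problems.append(f"params.{hormone}: {exc}")
    return out


def _parse(raw: dict) -> RunConfig:
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])

    for key in sorted(set(raw) - _TOP_KEYS):
        problems.append(f"unknown key {key!r}")

    preset = raw.get("preset", "table1-verbatim")
    if preset not in PRESET_NAMES:
        problems.append(
            f"unknown preset {preset!r}; available: {', '.join(PRESET_NAMES)}")

    params: dict[str, DrugParams] = {}
    if "params" in raw:
        if isinstance(raw["params"], dict):
            params = _parse_params(raw["params"], problems)
        else:
            problems.append("params: expected a mapping keyed by hormone name")

    scenario = ScenarioSpec("standard_cycle")
    raw_scen = raw.get("scenario", {"kind": "standard_cycle"})
    if isinstance(raw_scen, str):
        raw_scen = {"kind": raw_scen}
    if not isinstance(raw_scen, dict):
        problems.append("scenario: expected a mapping or a kind name")
    else:
        for key in sorted(set(raw_scen) - _SCENARIO_KEYS):
            problems.append(f"scenario: unknown key {key!r}")
        kind = raw_scen.get("kind", "standard_cycle")
        scen_params = {k: v for k, v in raw_scen.items()
                       if k in _SCENARIO_KEYS and k != "kind"}
        try:
            scenario = ScenarioSpec(kind, scen_params)
            build_regimen(scenario)  # surface constructor errors at load time
        except (ValueError, KeyError) as exc:
            problems.append(f"scenario: {exc}")

    dt = 0.1
    raw_grid = raw.get("grid", {})
    if not isinstance(raw_grid, dict):
        problems.append("grid: expected a mapping")
    else:
        for key in sorted(set(raw_grid) - _GRID_KEYS):
            problems.append(f"grid: unknown key {key!r}")
        dt = raw_grid.get("dt", 0.1)
        if not (isinstance(dt, (int, float)) and 0 < dt <= 1.0):
            problems.append(f"grid.dt must lie in (0, 1] h, got {dt!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append(f"seed must be a non-negative integer, got {seed!r}")

    window = raw.get("plateau_window", list(DEFAULT_PLATEAU_WINDOW))
    if (not isinstance(window, (list, tuple)) or len(window) != 2
            or not all(isinstance(x, (int, float)) for x in window)
            or not window[0] < window[1]):
        problems.append(f"plateau_window must be an increasing [start, end] pair, got {window!r}")
        window = DEFAULT_PLATEAU_WINDOW

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        preset=preset, params=params, scenario=scenario, dt=float(dt),
        outdir=str(raw.get("outdir", "patchpk-run")), seed=seed,
        plateau_window=(float(window[0]), float(window[1])),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    return _parse(raw if raw is not None else {})


def dump_config(config: RunConfig, path) -> None:
    """Write a config back out as YAML; load(dump(c)) == c."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig, outdir=None) -> dict[str, Path]:
    """Simulate both hormones for the configured scenario and write artifacts.

    Returns a mapping of artifact names to paths.  Raises on any stage
    error after logging the stage name.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    stage = "build-regimen"
    try:
        regimen = build_regimen(config.scenario)
        grid = SimulationGrid(dt=config.dt, horizon=regimen.horizon)
        params = config.resolved_params()

        reports = {}
        for hormone, p in params.items():
            stage = f"simulate-{hormone}"
            series = simulate_difference(p, regimen, grid)
            csv_path = out / f"trajectory_{hormone}.csv"
            series.to_csv(csv_path)
            artifacts[f"trajectory_{hormone}"] = csv_path

            stage = f"metrics-{hormone}"
            summary = summarize(series, p.therapeutic_low, p.therapeutic_high,
                                p.k_elim, plateau_window=config.plateau_window)
            summary_path = out / f"summary_{hormone}.json"
            summary.to_json(summary_path)
            artifacts[f"summary_{hormone}"] = summary_path

            report = range_crossings(series, p.therapeutic_low, p.therapeutic_high)
            reports[hormone] = {
                "unit": p.conc_unit,
                "band": [p.therapeutic_low, p.therapeutic_high],
                "risk_windows_h": [list(w) for w in report.risk_windows],
                "overexposure_windows_h": [list(w) for w in report.over_windows],
                "time_in_range_h": report.time_in_range,
            }

        stage = "risk-report"
        risk_path = out / "risk_report.json"
        with open(risk_path, "w") as fh:
            json.dump(reports, fh, indent=2)
            fh.write("\n")
        artifacts["risk_report"] = risk_path

        stage = "manifest"
        config_text = json.dumps(config.to_dict(), sort_keys=True)
        manifest = {
            "package": "patchpk",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "scenario": config.scenario.kind,
            "preset": config.preset,
            "dt_h": config.dt,
            "artifacts": sorted(str(p.name) for p in artifacts.values()),
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
        artifacts["manifest"] = manifest_path
    except Exception:
        logger.error("pipeline failed at stage %s", stage)
        raise
    return artifacts
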