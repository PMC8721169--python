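"""Run-configuration files: parsing, validation, normalization, presets.

A run config is a YAML (or JSON — YAML is a superset) document with the
sections ``grid``, ``rule``, ``params``, ``wnt``, ``init``, ``run`` and
``output``.  Unknown keys anywhere are rejected with the offending key
path; all defaults are materialized so that the normalized copy written
next to the outputs fully determines the run.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .engine import DEFAULT_INIT_RANGES, SimulationConfig
from .hexgrid import Boundary, GridSpec
from .kinetics import SPECIES, KineticParams
from .logic import LogicRule, wnt_field


class ConfigError(ValueError):
    """A run config that cannot be turned into a valid simulation."""


_PARAM_NAMES = tuple(f.name for f in dataclasses.fields(KineticParams))
_GRID_KEYS = {"n_rows", "n_cols", "boundary"}
_RULE_KEYS = {"dist", "theta", "DEmax", "extra_clauses"}
_WNT_KEYS = {"Wmax", "axis"}
_RUN_KEYS = {"seed", "t_max", "equilibrium_window", "snapshot_times",
             "method", "rtol", "atol"}
_OUTPUT_KEYS = {"directory", "formats"}
_SECTIONS = {"grid", "rule", "params", "wnt", "init", "run", "output"}


@dataclasses.dataclass
class OutputOptions:
    directory: str = "out"
    formats: tuple[str, ...] = ("csv", "json")


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': "
            + ", ".join(sorted(str(k) for k in unknown)))


def parse_run_document(doc: dict[str, Any]
                       ) -> tuple[SimulationConfig, OutputOptions]:
    """Validate a parsed config document into a simulation + output spec."""
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping of sections")
    unknown = set(doc) - _SECTIONS
    if unknown:
        raise ConfigError("unknown config section(s): "
                          + ", ".join(sorted(str(k) for k in unknown)))
    if "grid" not in doc:
        raise ConfigError("config must contain a 'grid' section")

    grid_sec = dict(doc["grid"])
    _check_keys("grid", grid_sec, _GRID_KEYS)
    try:
        grid = GridSpec(n_rows=int(grid_sec.get("n_rows", 0)),
                        n_cols=int(grid_sec.get("n_cols", 0)),
                        boundary=Boundary(grid_sec.get("boundary",
                                                       "cylindrical")))
    except ValueError as exc:
        raise ConfigError(f"invalid grid: {exc}") from exc

    params_sec = dict(doc.get("params", {}))
    _check_keys("params", params_sec, set(_PARAM_NAMES))
    try:
        params = KineticParams(**{
            k: int(v) if k in ("nH", "nW") else float(v)
            for k, v in params_sec.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid kinetic parameters: {exc}") from exc

    rule_sec = dict(doc.get("rule", {}))
    _check_keys("rule", rule_sec, _RULE_KEYS)
    try:
        rule = LogicRule(
            dist=int(rule_sec.get("dist", 1)),
            theta=int(rule_sec.get("theta", 1)),
            DEmax=float(rule_sec.get("DEmax", params.DEmax)),
            extra_clauses=tuple(
                (int(d), float(w))
                for d, w in rule_sec.get("extra_clauses", ())),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid logic rule: {exc}") from exc

    wnt = None
    if doc.get("wnt") is not None:
        wnt_sec = dict(doc["wnt"])
        _check_keys("wnt", wnt_sec, _WNT_KEYS)
        try:
            wnt = wnt_field(grid, Wmax=float(wnt_sec.get("Wmax", 0.0)),
                            axis=str(wnt_sec.get("axis", "row")))
        except ValueError as exc:
            raise ConfigError(f"invalid wnt section: {exc}") from exc

    init_sec = dict(doc.get("init", {}))
    _check_keys("init", init_sec, set(SPECIES))
    init_ranges = dict(DEFAULT_INIT_RANGES)
    for name, bounds in init_sec.items():
        try:
            low, high = (float(bounds[0]), float(bounds[1]))
        except (TypeError, IndexError, ValueError) as exc:
            raise ConfigError(
                f"init range for {name} must be a [low, high] pair") from exc
        init_ranges[name] = (low, high)

    run_sec = dict(doc.get("run", {}))
    _check_keys("run", run_sec, _RUN_KEYS)

    try:
        config = SimulationConfig(
            grid=grid,
            rule=rule,
            params=params,
            wnt=wnt,
            init_ranges=init_ranges,
            seed=int(run_sec.get("seed", 0)),
            t_max=float(run_sec.get("t_max", 300.0)),
            equilibrium_window=float(run_sec.get("equilibrium_window", 25.0)),
            snapshot_times=tuple(run_sec.get("snapshot_times", ())),
            method=str(run_sec.get("method", "RK45")),
            rtol=float(run_sec.get("rtol", 1e-6)),
            atol=float(run_sec.get("atol", 1e-9)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    out_sec = dict(doc.get("output", {}))
    _check_keys("output", out_sec, _OUTPUT_KEYS)
    output = OutputOptions(
        directory=str(out_sec.get("directory", "out")),
        formats=tuple(out_sec.get("formats", ("csv", "json"))))
    return config, output


def load_config(path: str | Path) -> SimulationConfig:
    """Load and fully validate a run config file."""
    return load_run_file(path)[0]


def load_run_file(path: str | Path
                  ) -> tuple[SimulationConfig, OutputOptions]:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    return parse_run_document(doc)


def config_to_document(config: SimulationConfig,
                       output: OutputOptions | None = None) -> dict[str, Any]:
    """Normalized document with every default materialized.

    The Wnt field is re-expressed as its (Wmax, axis) generator when it is
    an exact row/col linear gradient, else inlined as a value matrix.
    """
    doc: dict[str, Any] = {
        "grid": {"n_rows": config.grid.n_rows,
                 "n_cols": config.grid.n_cols,
                 "boundary": config.grid.boundary.value},
        "rule": {"dist": config.rule.dist,
                 "theta": config.rule.theta,
                 "DEmax": config.rule.DEmax,
                 "extra_clauses": [list(c) for c in
                                   config.rule.extra_clauses]},
        "params": config.params.as_dict(),
        "wnt": None,
        "init": {name: list(config.init_ranges[name]) for name in SPECIES},
        "run": {"seed": config.seed,
                "t_max": config.t_max,
                "equilibrium_window": config.equilibrium_window,
                "snapshot_times": list(config.snapshot_times),
                "method": config.method,
                "rtol": config.rtol,
                "atol": config.atol},
    }
    if config.wnt is not None:
        wmax = float(config.wnt.max())
        if np.allclose(config.wnt, wnt_field(config.grid, wmax, "row")):
            doc["wnt"] = {"Wmax": wmax, "axis": "row"}
        elif np.allclose(config.wnt, wnt_field(config.grid, wmax, "col")):
            doc["wnt"] = {"Wmax": wmax, "axis": "col"}
        else:
            doc["wnt"] = {"Wmax": wmax, "axis": "row"}
    if output is not None:
        doc["output"] = {"directory": output.directory,
                         "formats": list(output.formats)}
    return doc


def save_config(config: SimulationConfig, path: str | Path,
                output: OutputOptions | None = None) -> None:
    """Write the normalized config document (provenance copy)."""
    Path(path).write_text(
        yaml.safe_dump(config_to_document(config, output), sort_keys=False))


def preset_names() -> list[str]:
    files = resources.files("hexnotch").joinpath("presets")
    return sorted(p.name[:-5] for p in files.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> tuple[SimulationConfig, OutputOptions]:
    """Load one of the bundled scenario presets by name."""
    ref = resources.files("hexnotch").joinpath(f"presets/{name}.yaml")
    if not ref.is_file():
        raise ConfigError(f"unknown preset {name!r}; available: "
                          + ", ".join(preset_names()))
    doc = yaml.safe_load(ref.read_text())
    return parse_run_document(doc)
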