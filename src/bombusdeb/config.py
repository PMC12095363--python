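"""Run configuration: YAML/JSON parsing, validation, and output writing."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import DebParams, resolve_param_name
from .scenarios import SCENARIO_IDS, ScenarioConfig, build_scenario, run_scenario


@dataclass
class RunConfig:
    """A validated simulation request."""

    scenario: str
    scenario_overrides: dict = field(default_factory=dict)
    param_overrides: dict = field(default_factory=dict)
    years: int | None = None
    record_stride: int = 1
    snapshots: bool = False
    out_dir: str = "."

    def resolved_params(self) -> DebParams:
        return DebParams(**self.param_overrides)

    def build(self) -> ScenarioConfig:
        overrides = dict(self.scenario_overrides)
        if self.years is not None:
            overrides["years"] = self.years
        return build_scenario(self.scenario, **overrides)


_KNOWN_KEYS = {
    "scenario", "scenario_overrides", "params", "years",
    "record_stride", "snapshots", "out_dir",
}


def load_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a config from a path, YAML/JSON text, or mapping.

    Parameter overrides may use either field names or the conventional
    symbols (``lambda``, ``delta_R``, ``C_H``, ...).  Unknown keys raise a
    descriptive error.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")

    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    scenario = raw.get("scenario")
    if scenario is None:
        raise ValueError(
            "configuration must name a scenario; valid ids: "
            + ", ".join(SCENARIO_IDS)
        )

    param_overrides = {}
    for key, value in (raw.get("params") or {}).items():
        try:
            name = resolve_param_name(str(key))
        except KeyError:
            raise ValueError(f"unknown parameter name {key!r}") from None
        if isinstance(value, (int, float)) and value < 0:
            raise ValueError(f"parameter {key!r} must be nonnegative")
        param_overrides[name] = value

    config = RunConfig(
        scenario=str(scenario),
        scenario_overrides=dict(raw.get("scenario_overrides") or {}),
        param_overrides=param_overrides,
        years=raw.get("years"),
        record_stride=int(raw.get("record_stride", 1)),
        snapshots=bool(raw.get("snapshots", False)),
        out_dir=str(raw.get("out_dir", ".")),
    )
    # Validate eagerly so malformed configs fail before a long run.
    config.resolved_params()
    config.build()
    return config


def run_command(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run a configured scenario and write CSV + provenance outputs.

    Writes ``trajectory.csv`` (per-sample state, allocation summaries,
    landscape totals, and fluxes), ``annual_summary.csv`` (V and R sampled
    immediately before each reproductive impulse), and
    ``resolved_config.json`` capturing the full parameter set actually used.
    Returns the output paths.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = config.resolved_params()
    scenario = config.build()
    trajectories, summary = run_scenario(
        scenario, params, record_stride=config.record_stride,
        record_nodes=config.snapshots,
    )

    import pandas as pd

    frames = []
    for year, traj in enumerate(trajectories, start=1):
        df = traj.to_dataframe()
        df.insert(0, "year", year)
        frames.append(df)
    trajectory_df = pd.concat(frames, ignore_index=True)

    traj_path = out / "trajectory.csv"
    summary_path = out / "annual_summary.csv"
    provenance_path = out / "resolved_config.json"
    trajectory_df.to_csv(traj_path, index=False)
    summary.to_csv(summary_path, index=False)
    paths_extra = {}
    if config.snapshots:
        grid, _, _, _ = scenario.realize()
        snaps = pd.concat(
            [t.node_snapshot_frame(grid) for t in trajectories],
            ignore_index=True,
        )
        snap_path = out / "node_snapshots.csv"
        snaps.to_csv(snap_path, index=False)
        paths_extra["node_snapshots"] = snap_path
    provenance = {
        "scenario": config.scenario,
        "scenario_overrides": config.scenario_overrides,
        "years": scenario.years,
        "record_stride": config.record_stride,
        "params": dataclasses.asdict(params),
        "scenario_description": scenario.description,
    }
    provenance_path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return {
        "trajectory": traj_path,
        "annual_summary": summary_path,
        "provenance": provenance_path,
        **paths_extra,
    }
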