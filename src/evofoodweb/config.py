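"""Run configuration, serialization and output writing.

All quantities are dimensionless model units (the resource has body
mass 1); there is no unit-conversion layer.  A run is fully determined by
its configuration plus the seed, and the configuration round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import Community, DynamicsParams, EvolutionParams, Resource, Species
from .evolution import RunResult

__all__ = ["RunConfig", "load_config", "save_config", "write_outputs",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    t_end: float = 1e6
    snapshot_start: float | None = None
    snapshot_interval: float | None = None
    seed: int = 0
    output_dir: str = "run_output"
    checkpoint_interval: float | None = 1e7

    def to_dict(self) -> dict:
        return {
            "dynamics": dataclasses.asdict(self.dynamics),
            "evolution": dataclasses.asdict(self.evolution),
            "run": {
                "t_end": self.t_end,
                "snapshot_start": self.snapshot_start,
                "snapshot_interval": self.snapshot_interval,
                "seed": self.seed,
                "output_dir": self.output_dir,
                "checkpoint_interval": self.checkpoint_interval,
            },
        }


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    dyn = _build_section(DynamicsParams, data.pop("dynamics", {}) or {}, "dynamics")
    evo = _build_section(EvolutionParams, data.pop("evolution", {}) or {}, "evolution")
    run_keys = data.pop("run", {}) or {}
    if data:
        raise ValueError(f"unknown section(s): {sorted(data)}")
    valid = {
        "t_end",
        "snapshot_start",
        "snapshot_interval",
        "seed",
        "output_dir",
        "checkpoint_interval",
    }
    unknown = set(run_keys) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in [run]: {sorted(unknown)}")
    return RunConfig(dynamics=dyn, evolution=evo, **run_keys)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML configuration; missing keys fall back to the defaults
    (omega = 1e-4, K = 100, R = 1, e = 0.85/0.45, epsilon = 2e-4,
    c_food = 0.8, c_intra = 1.4).  Unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _versioned_dir(base: Path) -> Path:
    """Return ``base`` or, if it already contains files, a suffixed sibling."""
    if not base.exists() or not any(base.iterdir()):
        base.mkdir(parents=True, exist_ok=True)
        return base
    k = 1
    while True:
        cand = base.with_name(f"{base.name}.{k}")
        if not cand.exists():
            cand.mkdir(parents=True)
            return cand
        k += 1


def write_outputs(result: RunResult, out_dir: str | Path, cfg: RunConfig | None = None) -> Path:
    """Write node table, event log, snapshots, metrics and a run log.

    Node tables and event logs are CSV; snapshots are JSON; the metrics
    table has one row per snapshot.  An existing non-empty directory gets
    a versioned suffix instead of being overwritten.
    """
    from . import analysis

    out = _versioned_dir(Path(out_dir))
    result.community.node_table().to_csv(out / "nodes.csv", index=False)
    pd.DataFrame(
        [
            {"t": ev.t, "species_id": ev.species_id, "kind": ev.kind,
             "avalanche": ev.avalanche}
            for ev in result.event_log
        ]
    ).to_csv(out / "events.csv", index=False)
    pd.DataFrame(
        [
            {"t_start": a.t_start, "t_end": a.t_end, "size": a.size,
             "fraction": a.fraction}
            for a in result.avalanches
        ]
    ).to_csv(out / "avalanches.csv", index=False)

    rows = []
    for k, snap in enumerate(result.snapshots):
        (out / f"snapshot_{k:04d}.json").write_text(snap.to_json())
        if snap.n_consumers:
            web = analysis.cutoff_relative_to_average(snap)
            rows.append(analysis.compute_metrics(web).to_series().rename(k))
    if rows:
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index_label="snapshot")

    if cfg is not None:
        save_config(cfg, out / "config.yaml")
    log = {
        "seed": result.seed,
        "python": sys.version,
        "platform": platform.platform(),
        "numpy": np.__version__,
        "global_extinction_time": result.global_extinction_time,
        "n_snapshots": len(result.snapshots),
        "n_events": len(result.event_log),
    }
    (out / "run.log").write_text(json.dumps(log, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# checkpointing (restartable long runs)
# ---------------------------------------------------------------------------

def save_checkpoint(com: Community, rng: np.random.Generator, path: str | Path) -> None:
    payload = {
        "t": com.t,
        "resource": dataclasses.asdict(com.resource),
        "species": [dataclasses.asdict(sp) for sp in com.species],
        "events": [dataclasses.asdict(ev) for ev in com.event_log],
        "rng_state": rng.bit_generator.state,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[Community, np.random.Generator]:
    from .community import Event

    d = json.loads(Path(path).read_text())
    com = Community(
        t=d["t"],
        resource=Resource(**d["resource"]),
        species=[Species(**sp) for sp in d["species"]],
        event_log=[Event(**ev) for ev in d["events"]],
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = d["rng_state"]
    return com, rng
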