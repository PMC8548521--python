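"""File formats, configuration and run manifests.

All artefacts are plain text: per-run trajectory CSVs (columns ``t_s, x_cm,
y_cm, heading_deg, locked, fix_plus, fix_minus``), YAML sidecars carrying
the configuration snapshot, seed, contingency and per-trial outcomes, and a
YAML manifest tying a whole cohort directory together. Positions are cm,
angles degrees, time seconds; tick indexing is 0-based. See
``docs/formats.md`` for the full format reference.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional

import pandas as pd
import yaml

from . import __version__
from .geometry import ArenaConfig, Background, Pose
from .protocol import (
    BeeLog,
    Choice,
    ExperimentLog,
    Phase,
    ProtocolConfig,
    TrialLog,
)

__all__ = [
    "trial_log_to_frame",
    "write_trial_log",
    "read_trial_log",
    "arena_to_dict",
    "arena_from_dict",
    "protocol_to_dict",
    "protocol_from_dict",
    "write_config",
    "read_config",
    "write_experiment",
    "read_experiment",
]

LOG_COLUMNS = ["t_s", "x_cm", "y_cm", "heading_deg", "locked", "fix_plus", "fix_minus"]


def trial_log_to_frame(log: TrialLog) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": log.t,
            "x_cm": log.x,
            "y_cm": log.y,
            "heading_deg": log.heading,
            "locked": [int(v) for v in log.locked],
            "fix_plus": [int(v) for v in log.fix_plus],
            "fix_minus": [int(v) for v in log.fix_minus],
        }
    )


def write_trial_log(log: TrialLog, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trial_log_to_frame(log).to_csv(path, index=False, float_format="%.6f")


def read_trial_log(
    path: Path, phase: Phase, trial_index: int, meta: Optional[dict] = None
) -> TrialLog:
    df = pd.read_csv(path)
    meta = meta or {}
    log = TrialLog(
        phase=phase,
        trial_index=trial_index,
        t=df["t_s"].tolist(),
        x=df["x_cm"].tolist(),
        y=df["y_cm"].tolist(),
        heading=df["heading_deg"].tolist(),
        locked=[bool(v) for v in df["locked"]],
        fix_plus=[bool(v) for v in df["fix_plus"]],
        fix_minus=[bool(v) for v in df["fix_minus"]],
        choice=Choice(meta.get("choice", "nc")),
        latency=meta.get("latency"),
        reinforcement=meta.get("reinforcement"),
        cs_plus_side=meta.get("cs_plus_side"),
    )
    return log


def arena_to_dict(arena: ArenaConfig) -> dict:
    d = dataclasses.asdict(arena)
    d["start_pose"] = [arena.start_pose.x, arena.start_pose.y, arena.start_pose.heading]
    d["background"] = arena.background.value
    return d


def arena_from_dict(d: dict) -> ArenaConfig:
    d = dict(d)
    sp = d.pop("start_pose", [0.0, 0.0, 0.0])
    return ArenaConfig(
        start_pose=Pose(*sp), background=Background(d.pop("background", "transparent")), **d
    )


def protocol_to_dict(protocol: ProtocolConfig) -> dict:
    return dataclasses.asdict(protocol)


def protocol_from_dict(d: dict) -> ProtocolConfig:
    return ProtocolConfig(**d)


def write_config(arena: ArenaConfig, protocol: ProtocolConfig, path: Path) -> None:
    """Write the shipped baseline configuration as a flat two-section YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"arena": arena_to_dict(arena), "protocol": protocol_to_dict(protocol)}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


def read_config(path: Path) -> tuple[ArenaConfig, ProtocolConfig]:
    payload = yaml.safe_load(Path(path).read_text())
    return (
        arena_from_dict(payload.get("arena", {})),
        protocol_from_dict(payload.get("protocol", {})),
    )


def _trial_meta(log: TrialLog) -> dict:
    return {
        "phase": log.phase.value,
        "trial_index": log.trial_index,
        "choice": log.choice.value,
        "latency": log.latency,
        "reinforcement": log.reinforcement,
        "cs_plus_side": log.cs_plus_side,
    }


def write_experiment(log: ExperimentLog, out_dir: Path, condition: str = "run") -> Path:
    """Write a cohort to ``out_dir``: one trajectory CSV per bee per run plus
    a YAML manifest with the config snapshot, seeds and per-trial outcomes.
    Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bees_meta = []
    for bee in log.bees:
        files = {}
        for tr in bee.trials:
            rel = f"bee{bee.bee_id:03d}_train{tr.trial_index:02d}.csv"
            write_trial_log(tr, out_dir / rel)
            files[rel] = _trial_meta(tr)
        if bee.test is not None:
            rel = f"bee{bee.bee_id:03d}_test.csv"
            write_trial_log(bee.test, out_dir / rel)
            files[rel] = _trial_meta(bee.test)
        bees_meta.append(
            {
                "bee_id": bee.bee_id,
                "cs_plus_color": bee.cs_plus_color,
                "cs_minus_color": bee.cs_minus_color,
                "seed": bee.seed,
                "files": files,
            }
        )
    manifest = {
        "package_version": __version__,
        "condition": condition,
        "seed": log.seed,
        "arena": arena_to_dict(log.arena),
        "protocol": protocol_to_dict(log.protocol),
        "bees": bees_meta,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_experiment(out_dir: Path) -> ExperimentLog:
    """Reload a cohort from its manifest; write -> read -> write round-trips
    byte-identically."""
    out_dir = Path(out_dir)
    manifest = yaml.safe_load((out_dir / "manifest.yaml").read_text())
    arena = arena_from_dict(manifest["arena"])
    protocol = protocol_from_dict(manifest["protocol"])
    bees: List[BeeLog] = []
    for bm in manifest["bees"]:
        trials: List[TrialLog] = []
        test = None
        for rel, meta in bm["files"].items():
            log = read_trial_log(
                out_dir / rel, Phase(meta["phase"]), meta["trial_index"], meta
            )
            if log.phase is Phase.TRAIN:
                trials.append(log)
            else:
                test = log
        trials.sort(key=lambda t: t.trial_index)
        bees.append(
            BeeLog(
                bee_id=bm["bee_id"],
                cs_plus_color=bm["cs_plus_color"],
                cs_minus_color=bm["cs_minus_color"],
                trials=trials,
                test=test,
                seed=bm["seed"],
            )
        )
    bees.sort(key=lambda b: b.bee_id)
    return ExperimentLog(arena=arena, protocol=protocol, bees=bees, seed=manifest["seed"])
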