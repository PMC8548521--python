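"""End-to-end reproduction runs for the three experiments.

``reproduce`` executes every condition of one experiment at the published
cohort sizes with the shipped agent defaults, writes trajectory logs,
metrics tables, learning curves and heat-map data, and emits a YAML summary
comparing the simulated category proportions against the expected
qualitative pattern (clear CS+/CS- separation only when frontal background
motion is absent; slower, shorter walks under ventral optic flow; graded
phototaxis across red intensities).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import yaml

from .agents import (
    PhototaxisAgent,
    RWLearningAgent,
    learning_params_for_condition,
    phototaxis_params,
)
from .geometry import ArenaConfig, Background
from .io import write_experiment
from .metrics import learning_curves, metrics_table, occupancy_heatmap
from .protocol import (
    PALETTE,
    Choice,
    ProtocolConfig,
    apply_exclusion,
    run_phototaxis_tests,
)
from .protocol import run_experiment as _run_experiment

__all__ = ["EXP1_COHORTS", "EXP2_COHORTS", "EXP3_COHORTS", "reproduce"]

#: published cohort sizes per condition
EXP1_COHORTS = {"red10": 19, "red50": 19, "red100": 20}
EXP2_COHORTS = {
    "transparent": 24,
    "grating_closed_loop": 17,
    "grating_gaze_fixed": 17,
    "grating_rotating": 17,
}
EXP3_COHORTS = {"no_ventral_flow": 29, "ventral_flow": 38}

_EXP1_STIMULI = {"red10": "red_10", "red50": "red_50", "red100": "red_100"}


def _scaled(n: int, scale: float) -> int:
    return max(2, int(round(n * scale)))


def _phototaxis_condition(
    name: str, n_bees: int, seed: int, out_dir: Path
) -> Dict[str, float]:
    arena = ArenaConfig()
    stim = PALETTE[_EXP1_STIMULI[name]]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = {Choice.RED: 0, Choice.NO_STIMULUS: 0, Choice.NC: 0}
    rows = []
    for b in range(n_bees):
        agent = PhototaxisAgent(phototaxis_params())
        logs = run_phototaxis_tests(agent, arena, stim, rng)
        for log in logs:
            counts[log.choice] += 1
            rows.append({"bee_id": b, "test": log.trial_index, "choice": log.choice.value})
    total = sum(counts.values())
    out_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    pd.DataFrame(rows).to_csv(out_dir / "choices.csv", index=False)
    return {
        "n_bees": n_bees,
        "n_tests": total,
        "pct_red": 100.0 * counts[Choice.RED] / total,
        "pct_no_stimulus": 100.0 * counts[Choice.NO_STIMULUS] / total,
        "pct_nc": 100.0 * counts[Choice.NC] / total,
    }


def _learning_condition(
    name: str,
    background: Background,
    ventral_flow: bool,
    n_bees: int,
    seed: int,
    out_dir: Path,
    protocol: ProtocolConfig,
) -> Dict[str, object]:
    arena = ArenaConfig(background=background, ventral_flow=ventral_flow)
    params = learning_params_for_condition(background, ventral_flow)
    log = _run_experiment(
        lambda: RWLearningAgent(params), arena, protocol, n_bees, seed
    )
    write_experiment(log, out_dir, condition=name)
    kept, excluded = apply_exclusion(log)
    summary: Dict[str, object] = {
        "n_bees": n_bees,
        "n_kept": len(kept),
        "n_excluded": len(excluded),
    }
    if kept:
        curves = learning_curves(kept, n_boot=2000, seed=seed)
        curves.to_csv(out_dir / "learning_curves.csv", index=False)
        metrics_table(kept, arena.tick).to_csv(out_dir / "metrics.csv", index=False)
        last = curves[curves["trial"] == curves["trial"].max()]
        summary["final_trial"] = {
            row["category"]: round(float(row["proportion"]), 3)
            for _, row in last.iterrows()
        }
        grid = occupancy_heatmap([tr for b in kept for tr in b.trials])
        np.savetxt(out_dir / "occupancy_train.csv", grid.counts, fmt="%d", delimiter=",")
    return summary


def reproduce(
    experiment_id: str, out_dir: Path, scale_factor: float = 1.0, seed: int = 0
) -> dict:
    """Run all conditions of ``experiment_id`` ("exp1" | "exp2" | "exp3") at
    cohort sizes scaled by ``scale_factor``; returns (and writes) the
    summary report."""
    out_dir = Path(out_dir)
    report: dict = {
        "experiment": experiment_id,
        "seed": seed,
        "scale_factor": scale_factor,
        "conditions": {},
    }
    if scale_factor < 1.0:
        report["note"] = "cohorts scaled below published sizes; reduced statistical power"
    if experiment_id == "exp1":
        for i, (name, n) in enumerate(EXP1_COHORTS.items()):
            report["conditions"][name] = _phototaxis_condition(
                name, _scaled(n, scale_factor), seed + i, out_dir / name
            )
    elif experiment_id == "exp2":
        backgrounds = {
            "transparent": Background.TRANSPARENT,
            "grating_closed_loop": Background.GRATING_CLOSED_LOOP,
            "grating_gaze_fixed": Background.GRATING_GAZE_FIXED,
            "grating_rotating": Background.GRATING_ROTATING,
        }
        protocol = ProtocolConfig(reinforcer_minus="quinine 60 mM")
        for i, (name, n) in enumerate(EXP2_COHORTS.items()):
            report["conditions"][name] = _learning_condition(
                name,
                backgrounds[name],
                False,
                _scaled(n, scale_factor),
                seed + i,
                out_dir / name,
                protocol,
            )
    elif experiment_id == "exp3":
        protocol = ProtocolConfig(reinforcer_minus="NaCl 3 M")
        for i, (name, n) in enumerate(EXP3_COHORTS.items()):
            report["conditions"][name] = _learning_condition(
                name,
                Background.TRANSPARENT,
                name == "ventral_flow",
                _scaled(n, scale_factor),
                seed + i,
                out_dir / name,
                protocol,
            )
    else:
        raise ValueError("experiment_id must be one of exp1, exp2, exp3")
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
    return report
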