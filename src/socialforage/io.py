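"""Reading and writing the delimited-text tables of a simulated experiment.

A round directory holds ``trajectories.csv`` (25 Hz or 1 Hz stream),
``events.csv``, ``patches.csv``, ``truth_states.csv`` and a
``config.yaml`` echo of the environment settings and seed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .config import AgentPolicy, EnvironmentConfig, SwitchCoefficients
from .sim import SimOutput

TRAJ_FILE = "trajectories.csv"
EVENTS_FILE = "events.csv"
PATCHES_FILE = "patches.csv"
TRUTH_FILE = "truth_states.csv"
CONFIG_FILE = "config.yaml"


def write_sim_output(out: SimOutput, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    out.trajectories.to_csv(d / TRAJ_FILE, index=False)
    out.events.to_csv(d / EVENTS_FILE, index=False)
    out.patches.to_csv(d / PATCHES_FILE, index=False)
    out.truth_states.to_csv(d / TRUTH_FILE, index=False)
    cfg = {
        "environment": {
            "arena_side": out.config.arena_side,
            "n_patches": out.config.n_patches,
            "coins_per_patch": out.config.coins_per_patch,
            "patch_radius": out.config.patch_radius,
            "mode": out.config.mode,
        },
        "n_agents": len(out.policies),
        "seed": out.seed,
        "group_id": out.group_id,
        "round_id": out.round_id,
        "policy": {
            "speed_max": out.policies[0].speed_max,
            "fov_horizontal": out.policies[0].fov_horizontal,
            "turn_noise_kappa": out.policies[0].turn_noise_kappa,
            "revert_prob": out.policies[0].revert_prob,
            "switch_coefficients": vars(out.policies[0].switch_coefficients),
        },
    }
    with open(d / CONFIG_FILE, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return d


def read_round_dir(directory) -> dict:
    """Load a round directory back into DataFrames (+ config dict)."""
    d = Path(directory)
    out = {
        "trajectories": pd.read_csv(d / TRAJ_FILE),
        "events": pd.read_csv(d / EVENTS_FILE),
        "patches": pd.read_csv(d / PATCHES_FILE),
    }
    if (d / TRUTH_FILE).exists():
        out["truth_states"] = pd.read_csv(d / TRUTH_FILE)
    if (d / CONFIG_FILE).exists():
        with open(d / CONFIG_FILE) as fh:
            out["config"] = yaml.safe_load(fh)
    return out


def environment_from_config(cfg: dict) -> EnvironmentConfig:
    env = cfg["environment"]
    return EnvironmentConfig(
        arena_side=env["arena_side"],
        n_patches=env["n_patches"],
        coins_per_patch=env["coins_per_patch"],
        patch_radius=env["patch_radius"],
        mode=env.get("mode", "custom"),
    )
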