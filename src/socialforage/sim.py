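"""Synthetic collective-foraging data generators.

Two generators make every downstream stage testable without any
external data:

* :func:`simulate_round` — a mechanistic agent-based simulation of the
  virtual foraging round: four avatars with forward-only movement and a
  bounded turn rate roam a walled square arena containing
  non-overlapping circular coin patches.  Avatars alternate between a
  correlated random walk (individual exploration, I), straight-line
  pursuit of an exploiting group member entered via a per-second
  logistic switch rule (social relocation, S), and immobile coin
  extraction at one coin per two seconds (exploitation, E).  Depleted
  patches respawn at random non-overlapping locations, so the task
  structure stays constant within a round.  Ground-truth latent states
  are recorded per second.

* :func:`simulate_from_model` — the exact generative twin of the
  statistical model: latent states are sampled from the
  covariate-dependent switching chain and observation channels from the
  state-dependent emission laws, for parameter-recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AgentPolicy, EnvironmentConfig, default_policies
from .features import BEARING_EPS, wrap_angle
from .hmm import ShmdmParams, inv_logit, switch_logit

MAX_PACKING_RETRIES = 10_000


@dataclass
class Patch:
    """One circular coin patch and its lifetime."""

    patch_id: int
    x: float
    y: float
    radius: float
    coins_remaining: int
    coins_initial: int
    t_created: float
    t_depleted: float | None = None

    @property
    def active(self) -> bool:
        return self.t_depleted is None

    def center(self) -> np.ndarray:
        return np.array([self.x, self.y])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_patch_center(
    config: EnvironmentConfig,
    existing_centers: np.ndarray,
    avoid_points: np.ndarray,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Rejection-sample a center fully inside the arena, >= 2r from every
    existing patch center and >= r from every avoid point (avatars)."""
    r = config.patch_radius
    lo, hi = r, config.arena_side - r
    if hi <= lo:
        raise ValueError("arena too small for the patch radius")
    for _ in range(MAX_PACKING_RETRIES):
        x = rng.uniform(lo, hi)
        y = rng.uniform(lo, hi)
        if existing_centers.size and np.min(np.hypot(existing_centers[:, 0] - x, existing_centers[:, 1] - y)) < 2 * r:
            continue
        if avoid_points.size and np.min(np.hypot(avoid_points[:, 0] - x, avoid_points[:, 1] - y)) < r:
            continue
        return x, y
    raise RuntimeError(
        f"could not place a non-overlapping patch after {MAX_PACKING_RETRIES} attempts"
    )


def make_environment(
    config: EnvironmentConfig,
    rng,
    avoid_points: Sequence | None = None,
    t: float = 0.0,
) -> list[Patch]:
    """Randomly place the configured number of non-overlapping patches.

    Patches lie fully inside the arena, pairwise center distance is at
    least twice the radius, and centers keep at least one radius from
    every point in ``avoid_points`` (initial avatar positions).
    """
    rng = _rng(rng)
    avoid = np.asarray(avoid_points, dtype=float).reshape(-1, 2) if avoid_points is not None else np.empty((0, 2))
    patches: list[Patch] = []
    centers = np.empty((0, 2))
    for k in range(config.n_patches):
        x, y = _sample_patch_center(config, centers, avoid, rng)
        patches.append(
            Patch(k, x, y, config.patch_radius, config.coins_per_patch, config.coins_per_patch, t)
        )
        centers = np.vstack([centers, [x, y]])
    return patches


def respawn_patch(
    patches: list[Patch],
    config: EnvironmentConfig,
    rng,
    avatar_positions: Sequence | None = None,
    t: float = 0.0,
    next_id: int | None = None,
) -> Patch:
    """Create a replacement patch after a depletion.

    The new patch holds a fresh complement of coins and does not
    overlap any surviving active patch or any current avatar position;
    it is appended to ``patches`` and returned.
    """
    rng = _rng(rng)
    centers = np.array([[p.x, p.y] for p in patches if p.active]).reshape(-1, 2)
    avoid = (
        np.asarray(avatar_positions, dtype=float).reshape(-1, 2)
        if avatar_positions is not None
        else np.empty((0, 2))
    )
    x, y = _sample_patch_center(config, centers, avoid, rng)
    if next_id is None:
        next_id = max(p.patch_id for p in patches) + 1 if patches else 0
    patch = Patch(next_id, x, y, config.patch_radius, config.coins_per_patch, config.coins_per_patch, t)
    patches.append(patch)
    return patch


@dataclass
class SimOutput:
    """Everything one simulated round produces.

    ``trajectories`` is the raw 25 Hz stream (per tick: position,
    heading, exploiting flag, cumulative coins, instantaneous state);
    ``truth_states`` the per-second ground-truth labels in {I, S, E}
    where the label at second t is the state in effect during (t-1, t]
    with exploitation read off the flag at t.
    """

    trajectories: pd.DataFrame
    events: pd.DataFrame
    patches: pd.DataFrame
    truth_states: pd.DataFrame
    config: EnvironmentConfig
    policies: list[AgentPolicy]
    seed: int | None
    group_id: int = 0
    round_id: int = 0
    covariates: pd.DataFrame | None = None  # per-second V/D/N/T the switch rule saw


_STATE_I, _STATE_S, _STATE_E = 0, 1, 2
_STATE_CHR = np.array(["I", "S", "E"])


def simulate_round(
    env_config: EnvironmentConfig,
    policies: Sequence[AgentPolicy] | None = None,
    duration: int = 720,
    tick_hz: int = 25,
    rng=None,
    group_id: int = 0,
    round_id: int = 0,
) -> SimOutput:
    """Simulate one foraging round with ground-truth latent states.

    The per-second decision loop mirrors the statistical model: an
    exploring avatar switches to social relocation with probability
    ``logit^-1`` of the policy's switch rule evaluated on the current
    V/D/N/T (D in meters, T in minutes), pursuing the nearest currently
    exploiting player; a relocating avatar reverts with its policy's
    per-second probability (and immediately when no one exploits).
    Entering an active patch starts extraction at one coin per two
    seconds; depletion respawns the patch elsewhere and releases the
    extractors into individual exploration.
    """
    if duration <= 0 or tick_hz <= 0:
        raise ValueError("duration and tick_hz must be positive")
    if policies is None:
        policies = default_policies(4)
    policies = list(policies)
    n_agents = len(policies)
    if n_agents < 1:
        raise ValueError("need at least one agent")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = _rng(rng)
    side = env_config.arena_side
    dt = 1.0 / tick_hz
    extraction_ticks = int(round(2.0 * tick_hz))  # one coin per two seconds

    pos = gen.uniform(0.0, side, size=(n_agents, 2))
    heading = gen.uniform(-math.pi, math.pi, size=n_agents)
    state = np.full(n_agents, _STATE_I, dtype=int)
    target = np.full(n_agents, -1, dtype=int)
    coins = np.zeros(n_agents, dtype=int)
    ticks_in_patch = np.zeros(n_agents, dtype=int)
    agent_patch = np.full(n_agents, -1, dtype=int)

    patches = make_environment(env_config, gen, avoid_points=pos)
    events: list[tuple] = []
    covariate_rows: list[tuple] = []  # the V/D/N/T the switch rule saw
    for p in patches:
        events.append((0.0, "patch_created", -1, p.patch_id, p.x, p.y))

    speed = np.array([pol.speed_max for pol in policies])
    sd_tick = np.array(
        [
            (1.0 / math.sqrt(pol.turn_noise_kappa) if pol.turn_noise_kappa > 0 else math.pi)
            / math.sqrt(tick_hz)
            for pol in policies
        ]
    )
    sd_pursuit = np.array(
        [
            (1.0 / math.sqrt(pol.pursuit_kappa) if pol.pursuit_kappa > 0 else math.pi)
            / math.sqrt(tick_hz)
            for pol in policies
        ]
    )
    turn_cap = np.array([pol.turn_rate_max * dt for pol in policies])
    half_fov = np.array([math.radians(pol.fov_horizontal) / 2.0 for pol in policies])

    n_ticks = duration * tick_hz
    traj_t = np.empty(n_ticks * n_agents)
    traj_x = np.empty_like(traj_t)
    traj_y = np.empty_like(traj_t)
    traj_h = np.empty_like(traj_t)
    traj_e = np.empty(n_ticks * n_agents, dtype=int)
    traj_c = np.empty(n_ticks * n_agents, dtype=int)
    traj_s = np.empty(n_ticks * n_agents, dtype=int)
    truth = np.empty((duration, n_agents), dtype=int)
    time_last_coin = np.zeros(n_agents)

    next_patch_id = len(patches)

    def active_patch_arrays():
        act = [p for p in patches if p.active]
        return act, np.array([[p.x, p.y] for p in act]).reshape(-1, 2)

    act_list, act_centers = active_patch_arrays()

    row = 0
    for s in range(duration):
        t_now = float(s)
        exploiting_now = state == _STATE_E
        # ground-truth label for second s: state in effect during (s-1, s]
        truth[s] = np.where(exploiting_now, _STATE_E, state)

        # --- per-second switching decisions for the coming second ---
        exploiters = np.flatnonzero(exploiting_now)
        for a in range(n_agents):
            if state[a] == _STATE_E:
                continue
            if exploiters.size == 0:
                state[a] = _STATE_I
                target[a] = -1
                continue
            dvec = pos[exploiters] - pos[a]
            dist = np.hypot(dvec[:, 0], dvec[:, 1])
            nearest = exploiters[int(np.argmin(dist))]
            bearings = np.abs(wrap_angle(np.arctan2(dvec[:, 1], dvec[:, 0]) - heading[a]))
            visible = (bearings <= half_fov[a]) & (dist > 0)
            if visible.any():
                v = 1.0
                vis_idx = np.flatnonzero(visible)
                closest = vis_idx[int(np.argmin(dist[visible]))]
                d_raw = float(dist[closest])
                closest_patch = agent_patch[exploiters[closest]]
                n_others = int(np.sum(agent_patch[exploiters] == closest_patch)) - 1
            else:
                v, d_raw, n_others = 0.0, np.nan, np.nan
            t_raw = t_now - time_last_coin[a]
            covariate_rows.append((t_now, a, v, d_raw, n_others, t_raw))
            if state[a] == _STATE_S:
                if gen.random() < policies[a].revert_prob:
                    state[a] = _STATE_I
                    target[a] = -1
                else:
                    target[a] = nearest  # retarget the nearest exploiter
                    continue
            if state[a] == _STATE_I:
                p_switch = policies[a].switch_coefficients.probability(
                    v, d_raw if v else 0.0, n_others if v else 0.0, t_raw / 60.0
                )
                if gen.random() < p_switch:
                    state[a] = _STATE_S
                    target[a] = nearest

        # --- 25 Hz movement within the second ---
        for k in range(tick_hz):
            t_tick = t_now + k * dt
            sl = slice(row, row + n_agents)
            traj_t[sl] = t_tick
            traj_x[sl] = pos[:, 0]
            traj_y[sl] = pos[:, 1]
            traj_h[sl] = heading
            traj_e[sl] = (state == _STATE_E).astype(int)
            traj_c[sl] = coins
            traj_s[sl] = state
            row += n_agents

            noise = gen.normal(0.0, 1.0, size=n_agents)
            for a in range(n_agents):
                if state[a] == _STATE_E:
                    ticks_in_patch[a] += 1
                    if ticks_in_patch[a] % extraction_ticks == 0:
                        pid = agent_patch[a]
                        patch = next(p for p in patches if p.patch_id == pid)
                        if patch.coins_remaining > 0:
                            patch.coins_remaining -= 1
                            coins[a] += 1
                            time_last_coin[a] = t_tick
                            events.append((t_tick, "coin_extracted", a, pid, pos[a, 0], pos[a, 1]))
                            if patch.coins_remaining == 0:
                                patch.t_depleted = t_tick
                                events.append((t_tick, "patch_depleted", -1, pid, patch.x, patch.y))
                                for b in np.flatnonzero(agent_patch == pid):
                                    state[b] = _STATE_I
                                    target[b] = -1
                                    agent_patch[b] = -1
                                    ticks_in_patch[b] = 0
                                new = respawn_patch(
                                    patches, env_config, gen, avatar_positions=pos, t=t_tick, next_id=next_patch_id
                                )
                                next_patch_id += 1
                                events.append((t_tick, "patch_created", -1, new.patch_id, new.x, new.y))
                                act_list, act_centers = active_patch_arrays()
                    continue

                if state[a] == _STATE_S and target[a] >= 0 and state[target[a]] == _STATE_E:
                    desired = math.atan2(pos[target[a], 1] - pos[a, 1], pos[target[a], 0] - pos[a, 0])
                    turn = wrap_angle(desired - heading[a]) + noise[a] * sd_pursuit[a]
                else:
                    turn = noise[a] * sd_tick[a]
                turn = float(np.clip(turn, -turn_cap[a], turn_cap[a]))
                h = wrap_angle(heading[a] + turn)
                nx = pos[a, 0] + speed[a] * dt * math.cos(h)
                ny = pos[a, 1] + speed[a] * dt * math.sin(h)
                if nx < 0.0:
                    nx, h = -nx, wrap_angle(math.pi - h)
                elif nx > side:
                    nx, h = 2 * side - nx, wrap_angle(math.pi - h)
                if ny < 0.0:
                    ny, h = -ny, wrap_angle(-h)
                elif ny > side:
                    ny, h = 2 * side - ny, wrap_angle(-h)
                pos[a] = (nx, ny)
                heading[a] = h

                if act_centers.size:
                    d2 = np.hypot(act_centers[:, 0] - nx, act_centers[:, 1] - ny)
                    hit = int(np.argmin(d2))
                    if d2[hit] <= act_list[hit].radius:
                        patch = act_list[hit]
                        state[a] = _STATE_E
                        target[a] = -1
                        agent_patch[a] = patch.patch_id
                        ticks_in_patch[a] = 0
                        events.append((t_tick, "patch_joined", a, patch.patch_id, nx, ny))

    agent_ids = np.tile(np.arange(n_agents), n_ticks)
    trajectories = pd.DataFrame(
        {
            "group_id": group_id,
            "round_id": round_id,
            "player_id": agent_ids,
            "t_sec": traj_t,
            "x_m": traj_x,
            "y_m": traj_y,
            "heading_rad": traj_h,
            "exploiting": traj_e,
            "coins_cum": traj_c,
            "truth_state": _STATE_CHR[traj_s],
        }
    )
    events_df = pd.DataFrame(
        events, columns=["t_sec", "event_type", "player_id", "patch_id", "x_m", "y_m"]
    )
    events_df.insert(0, "round_id", round_id)
    events_df.insert(0, "group_id", group_id)
    patches_df = pd.DataFrame(
        {
            "group_id": group_id,
            "round_id": round_id,
            "patch_id": [p.patch_id for p in patches],
            "x_m": [p.x for p in patches],
            "y_m": [p.y for p in patches],
            "radius": [p.radius for p in patches],
            "coins_initial": [p.coins_initial for p in patches],
            "coins_remaining": [p.coins_remaining for p in patches],
            "t_created": [p.t_created for p in patches],
            "t_depleted": [p.t_depleted if p.t_depleted is not None else np.nan for p in patches],
        }
    )
    covariates_df = pd.DataFrame(
        covariate_rows, columns=["t_sec", "player_id", "V", "D_raw", "N", "T_raw"]
    )
    covariates_df.insert(0, "round_id", round_id)
    covariates_df.insert(0, "group_id", group_id)
    truth_df = pd.DataFrame(
        {
            "group_id": group_id,
            "round_id": round_id,
            "player_id": np.tile(np.arange(n_agents), duration),
            "t_sec": np.repeat(np.arange(duration, dtype=float), n_agents),
            "truth_state": _STATE_CHR[truth.ravel()],
        }
    )
    return SimOutput(
        trajectories=trajectories,
        events=events_df,
        patches=patches_df,
        truth_states=truth_df,
        config=env_config,
        policies=policies,
        seed=seed,
        group_id=group_id,
        round_id=round_id,
        covariates=covariates_df,
    )


# ---------------------------------------------------------------------------
# Generative twin of the statistical model
# ---------------------------------------------------------------------------

_GROUP_COLS = ["group_id", "round_id", "player_id", "incentive", "environment"]


def recovery_study_params() -> ShmdmParams:
    """Ground-truth parameters of the canonical parameter-recovery study.

    Emissions are well separated (straight, approaching, target-facing
    relocation vs. diffuse exploration); switch coefficients echo the
    qualitative empirical pattern — higher baseline switching under
    concentrated resources and individual incentives, negative distance
    and crowding effects.  The S -> I intercept keeps relocation bouts
    short (about two seconds) so many transitions are observed, which
    makes the recovery study well-posed.
    """
    from .hmm import CellTransition, EmissionParams, StateEmissions, TransitionParams

    emissions = EmissionParams(
        explore=StateEmissions(0.0, 1.0, 0.5, 0.9, 0.1, 0.8),
        relocate=StateEmissions(0.0, 10.0, -1.6, 0.5, -1.8, 0.7),
    )
    cells = {
        ("group", "concentrated"): CellTransition(-2.2, 1.0, -0.5, -0.3, 0.15, -0.2),
        ("group", "distributed"): CellTransition(-2.6, 0.8, -0.6, -0.1, 0.10, -0.2),
        ("individual", "concentrated"): CellTransition(-1.9, 1.2, -0.4, -0.4, 0.20, -0.2),
        ("individual", "distributed"): CellTransition(-2.4, 0.9, -0.5, -0.2, 0.10, -0.2),
    }
    return ShmdmParams(emissions=emissions, transitions=TransitionParams(cells=cells))


def simulate_from_model(params: ShmdmParams, covariates: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Sample latent states and emissions from the generative model.

    ``covariates`` holds per-second predictors (columns V, D, N, T,
    optionally minute) and a ``valid`` mask; maximal valid runs within
    each player-round form segments and the chain restarts in
    individual exploration at every segment start.  Social channels
    (ddist, bearing) are emitted as missing wherever V = 0.  Returns a
    copy with ``state`` ("I"/"S"), theta, ddist, bearing columns.
    """
    params.emissions.validate(ordered=False)
    for cell in params.transitions.cells.values():
        for mc in cell.tv.values():
            _ = mc.delta  # construction already validated the simplex
    gen = _rng(rng)
    out = covariates.copy().reset_index(drop=True)
    n = len(out)
    state = np.full(n, -1, dtype=int)
    theta = np.full(n, np.nan)
    ddist = np.full(n, np.nan)
    bearing = np.full(n, np.nan)

    group_cols = [c for c in _GROUP_COLS if c in out.columns]
    groups = out.groupby(group_cols, sort=False).groups.values() if group_cols else [out.index]
    emis = (params.emissions.explore, params.emissions.relocate)
    for idx in groups:
        idx = np.asarray(idx)
        sub = out.loc[idx]
        incentive = sub["incentive"].iloc[0] if "incentive" in sub else "all"
        environment = sub["environment"].iloc[0] if "environment" in sub else "all"
        cell = params.transitions.cell(incentive, environment)
        valid = sub["valid"].to_numpy().astype(bool)
        v = sub["V"].to_numpy(dtype=float)
        d = sub["D"].to_numpy(dtype=float)
        ncol = sub["N"].to_numpy(dtype=float)
        tcol = sub["T"].to_numpy(dtype=float)
        minute = sub["minute"].to_numpy() if "minute" in sub else None
        if np.any(valid & ~np.isfinite(v + np.where(v == 1, d + ncol, 0) + tcol)):
            raise ValueError("covariates must be finite on valid steps")
        eta = switch_logit(
            cell,
            np.where(valid, v, 0.0),
            np.where(valid, d, 0.0),
            np.where(valid, ncol, 0.0),
            np.where(valid, tcol, 0.0),
            minute if cell.tv else None,
        )
        p = inv_logit(eta)
        q = inv_logit(cell.gamma)
        prev_valid = np.concatenate(([False], valid[:-1]))
        cur = 0
        for k in range(valid.size):
            if not valid[k]:
                continue
            if not prev_valid[k]:
                cur = 0  # segment start: individual exploration
            else:
                if cur == 0:
                    cur = 1 if gen.random() < p[k] else 0
                else:
                    cur = 0 if gen.random() < q else 1
            state[idx[k]] = cur
            st = emis[cur]
            theta[idx[k]] = wrap_angle(gen.vonmises(st.vm_mu, st.vm_kappa))
            if v[k] == 1:
                ddist[idx[k]] = gen.normal(st.dd_mu, st.dd_sigma)
                bearing[idx[k]] = max(gen.lognormal(st.lb_mu, st.lb_sigma), BEARING_EPS)

    out["state"] = np.where(state >= 0, _STATE_CHR[np.clip(state, 0, 1)], None)
    out["theta"] = theta
    out["ddist"] = ddist
    out["bearing"] = bearing
    return out


def simulate_covariates(
    n_players: int = 40,
    incentives: Sequence[str] = ("group", "individual"),
    environments: Sequence[str] = ("concentrated", "distributed"),
    round_length: int = 720,
    players_per_group: int = 4,
    seg_mean: float = 30.0,
    gap_mean: float = 25.0,
    rng=None,
) -> pd.DataFrame:
    """Generate per-second state-predictor series for recovery studies.

    Incentive is a between-subjects factor (players split evenly);
    every player completes one round per environment.  Predictors mimic
    the empirical structure: persistent exploiter visibility (two-state
    Markov chain), AR(1) distance to the closest visible exploiter,
    mostly-single exploiters (N in {0,1,2} with probabilities
    0.83/0.14/0.03), and a time-since-success ramp with random resets.
    D and T are z-scored over the steps where they enter the model.
    """
    gen = _rng(rng)
    rows = []
    per_inc = n_players // len(incentives)
    for pi in range(n_players):
        incentive = incentives[min(pi // per_inc, len(incentives) - 1)]
        group = pi // players_per_group
        for ri, env in enumerate(environments):
            valid = np.zeros(round_length, dtype=bool)
            t = int(gen.integers(0, 10))
            while t < round_length:
                seg = 1 + int(gen.geometric(1.0 / seg_mean))
                valid[t : min(t + seg, round_length)] = True
                t += seg + 1 + int(gen.geometric(1.0 / gap_mean))
            v = np.zeros(round_length)
            v[0] = gen.random() < 0.5
            for k in range(1, round_length):
                p_one = 0.70 if v[k - 1] == 1 else 0.30
                v[k] = gen.random() < p_one
            d = np.empty(round_length)
            d[0] = gen.normal()
            for k in range(1, round_length):
                d[k] = 0.9 * d[k - 1] + math.sqrt(1 - 0.81) * gen.normal()
            n_col = gen.choice([0.0, 1.0, 2.0], size=round_length, p=[0.83, 0.14, 0.03])
            t_raw = np.empty(round_length)
            clock = 0.0
            for k in range(round_length):
                t_raw[k] = clock
                clock = 0.0 if gen.random() < 0.05 else clock + 1.0
            seconds = np.arange(round_length)
            rows.append(
                pd.DataFrame(
                    {
                        "group_id": group,
                        "round_id": ri,
                        "player_id": pi,
                        "incentive": incentive,
                        "environment": env,
                        "t_sec": seconds.astype(float),
                        "minute": seconds // 60 + 1,
                        "V": v,
                        "D": d,
                        "N": n_col,
                        "T_raw": t_raw,
                        "valid": valid.astype(int),
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    valid = out["valid"].to_numpy().astype(bool)
    v1 = valid & (out["V"].to_numpy() == 1)
    d = out["D"].to_numpy(dtype=float)
    out["D"] = (d - d[v1].mean()) / d[v1].std()
    t_raw = out["T_raw"].to_numpy(dtype=float)
    out["T"] = (t_raw - t_raw[valid].mean()) / t_raw[valid].std()
    return out
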