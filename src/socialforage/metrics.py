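"""Behavioral outcome measures for collective foraging rounds.

Scrounging is quantified as a conditional probability: among the patch
lifetimes at which a focal player observed at least one exploiting
group member (while free to move), the proportion the focal
subsequently joined before depletion.  Success time-courses model the
per-second probability of exploiting with a monotonic
(ordered-categorical) minute-of-round effect per condition.  Simple
spatial/visual summaries (mean distance to others and mean number of
players in view while not exploiting, patch discoveries and joins) and
trajectory descriptors (straightness, turning-angle dispersion)
complete the picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._optim import map_laplace
from .features import wrap_angle
from .hmm import N_MINUTES
from .posterior import hpdi

_ROUND_KEY = ["group_id", "round_id"]
_PLAYER_KEY = _ROUND_KEY + ["player_id"]


# ---------------------------------------------------------------------------
# Scrounging
# ---------------------------------------------------------------------------


@dataclass
class ScroungeLedger:
    """One row per (focal, patch-lifetime) observation episode.

    ``episodes`` columns: group_id, round_id, player_id, patch_id,
    first_seen (s), joined (bool).  An episode exists when the focal,
    while not exploiting, had an exploiting group member at that patch
    in their field of view for at least one second; it counts as joined
    when the focal started extracting there afterwards, before the
    patch was depleted.
    """

    episodes: pd.DataFrame

    def per_player_round(self) -> pd.DataFrame:
        if self.episodes.empty:
            return pd.DataFrame(columns=_PLAYER_KEY + ["n_observed", "n_joined"])
        g = self.episodes.groupby(_PLAYER_KEY)
        out = g.agg(n_observed=("joined", "size"), n_joined=("joined", "sum")).reset_index()
        out["n_joined"] = out["n_joined"].astype(int)
        return out


def scrounging_ledger(
    traj_1hz: pd.DataFrame,
    events: pd.DataFrame,
    patches: pd.DataFrame,
    fov_deg: float = 108.0,
) -> ScroungeLedger:
    """Build the scrounging episode ledger for one or more rounds."""
    known = set(patches["patch_id"])
    bad = set(events["patch_id"].unique()) - known - {-1}
    if bad:
        raise ValueError(f"events reference unknown patch ids: {sorted(bad)}")
    half = math.radians(fov_deg) / 2.0
    episodes = []
    for (g, r), traj in traj_1hz.groupby(_ROUND_KEY):
        ev = events[(events["group_id"] == g) & (events["round_id"] == r)]
        pat = patches[(patches["group_id"] == g) & (patches["round_id"] == r)]
        players = np.sort(traj["player_id"].unique())
        piv = traj.set_index(["t_sec", "player_id"]).sort_index()
        seconds = np.sort(traj["t_sec"].unique())
        T, P = seconds.size, players.size
        xy = np.empty((T, P, 2))
        heading = np.empty((T, P))
        exploiting = np.empty((T, P), dtype=bool)
        for pi, p in enumerate(players):
            sub = piv.xs(p, level="player_id").reindex(seconds)
            xy[:, pi, 0] = sub["x_m"].to_numpy(dtype=float)
            xy[:, pi, 1] = sub["y_m"].to_numpy(dtype=float)
            heading[:, pi] = sub["heading_rad"].to_numpy(dtype=float)
            exploiting[:, pi] = sub["exploiting"].to_numpy().astype(bool)

        # exploiting player -> patch, via the containing active patch
        from .features import _assign_patches

        patch_of = _assign_patches(xy, exploiting, pat, seconds)

        ends = {}
        for _, prow in pat.iterrows():
            t_end = prow["t_depleted"]
            ends[prow["patch_id"]] = float(t_end) if np.isfinite(t_end) else float(seconds[-1]) + 1.0

        joins = ev[ev["event_type"] == "patch_joined"]
        join_times = {
            (int(row["player_id"]), int(row["patch_id"])): float(row["t_sec"])
            for _, row in joins.sort_values("t_sec").groupby(["player_id", "patch_id"]).head(1).iterrows()
        }

        for pi, p in enumerate(players):
            others = [j for j in range(P) if j != pi]
            delta = xy[:, others, :] - xy[:, pi : pi + 1, :]
            brg = np.abs(wrap_angle(np.arctan2(delta[..., 1], delta[..., 0]) - heading[:, pi : pi + 1]))
            dist = np.hypot(delta[..., 0], delta[..., 1])
            vis = exploiting[:, others] & (brg <= half) & (dist > 0) & ~exploiting[:, pi : pi + 1]
            seen: dict[int, float] = {}
            for ti in np.flatnonzero(vis.any(axis=1)):
                for k in np.flatnonzero(vis[ti]):
                    pid = patch_of[ti, others[k]]
                    if pid >= 0 and pid not in seen:
                        seen[pid] = float(seconds[ti])
            for pid, first_seen in seen.items():
                jt = join_times.get((int(p), int(pid)))
                joined = jt is not None and first_seen < jt <= ends.get(pid, np.inf)
                episodes.append((g, r, int(p), int(pid), first_seen, bool(joined)))
    cols = _PLAYER_KEY + ["patch_id", "first_seen", "joined"]
    return ScroungeLedger(pd.DataFrame(episodes, columns=cols))


def scrounging_rate(ledger: ScroungeLedger, pooling: str = "player") -> pd.DataFrame | float:
    """Empirical scrounging rate n_joined / n_observed at a pooling level.

    ``pooling`` is "player" (per player-round), "round" (per
    group-round) or "overall" (single proportion).  A unit with no
    observation episodes has an undefined rate and is reported as NaN,
    never as zero.
    """
    per = ledger.per_player_round()
    if pooling == "player":
        out = per.copy()
        out["rate"] = np.where(out["n_observed"] > 0, out["n_joined"] / out["n_observed"], np.nan)
        return out
    if pooling == "round":
        g = per.groupby(_ROUND_KEY)[["n_observed", "n_joined"]].sum().reset_index()
        g["rate"] = np.where(g["n_observed"] > 0, g["n_joined"] / g["n_observed"], np.nan)
        return g
    if pooling == "overall":
        n_obs = int(per["n_observed"].sum()) if not per.empty else 0
        if n_obs == 0:
            return float("nan")
        return float(per["n_joined"].sum() / n_obs)
    raise ValueError(f"unknown pooling {pooling!r}")


# ---------------------------------------------------------------------------
# Success time-course (monotonic minute effect)
# ---------------------------------------------------------------------------


@dataclass
class TimecourseFit:
    """Posterior for the per-minute exploitation-probability model."""

    draws: pd.DataFrame  # alpha[c], beta_max[c], delta[c,m] columns
    conditions: list
    converged: bool

    def curve(self, condition) -> np.ndarray:
        """(draws, 12) posterior P(exploiting) per minute for one condition."""
        c = self._key(condition)
        alpha = self.draws[f"alpha[{c}]"].to_numpy()
        beta = self.draws[f"beta_max[{c}]"].to_numpy()
        delta = np.column_stack(
            [self.draws[f"delta[{c},{m + 1}]"].to_numpy() for m in range(N_MINUTES)]
        )
        eta = alpha[:, None] + beta[:, None] * np.cumsum(delta, axis=1)
        return 1.0 / (1.0 + np.exp(-eta))

    def difference_curve(self, condition_a, condition_b) -> np.ndarray:
        """(draws, 12) posterior difference P_a - P_b per minute."""
        return self.curve(condition_a) - self.curve(condition_b)

    def curve_summary(self, condition) -> pd.DataFrame:
        p = self.curve(condition)
        rows = []
        for m in range(N_MINUTES):
            lo, hi = hpdi(p[:, m], 0.9)
            rows.append((m + 1, p[:, m].mean(), lo, hi))
        return pd.DataFrame(rows, columns=["minute", "mean", "hpdi_5", "hpdi_95"])

    def _key(self, condition) -> str:
        if isinstance(condition, tuple):
            return ",".join(map(str, condition))
        return str(condition)


def exploitation_timecourse_fit(
    exploiting: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | None = 0,
    prior_sd_alpha: float = 1.5,
    prior_sd_beta: float = 1.0,
) -> TimecourseFit:
    """Fit the monotonic success time-course model.

    ``exploiting`` needs per-second rows with columns ``exploiting``
    (0/1), ``minute`` (1..12) and optional condition labels
    ``incentive``/``environment``.  The per-second indicator follows a
    Bernoulli law whose logit is a condition intercept plus a total
    minute effect times the cumulative simplex increments.
    """
    df = exploiting.copy()
    if "incentive" not in df.columns:
        df["incentive"] = "all"
    if "environment" not in df.columns:
        df["environment"] = "all"
    agg = (
        df.groupby(["incentive", "environment", "minute"])["exploiting"]
        .agg(["sum", "size"])
        .reset_index()
    )
    conditions = sorted(set(zip(agg["incentive"], agg["environment"])))
    n_cond = len(conditions)
    cmap = {c: i for i, c in enumerate(conditions)}
    y = np.zeros((n_cond, N_MINUTES))
    n = np.zeros((n_cond, N_MINUTES))
    for _, row in agg.iterrows():
        ci = cmap[(row["incentive"], row["environment"])]
        m = int(row["minute"]) - 1
        if not (0 <= m < N_MINUTES):
            raise ValueError("minute index out of 1..12")
        y[ci, m] = row["sum"]
        n[ci, m] = row["size"]

    dim_per = 1 + 1 + (N_MINUTES - 1)  # alpha, beta_max, 11 simplex logits
    prior_mean = np.zeros(n_cond * dim_per)
    prior_sd = np.ones(n_cond * dim_per)
    for ci in range(n_cond):
        prior_sd[ci * dim_per + 0] = prior_sd_alpha
        prior_sd[ci * dim_per + 1] = prior_sd_beta

    def unpack(x):
        blk = x.reshape(n_cond, dim_per)
        alpha = blk[:, 0]
        beta = blk[:, 1]
        logits = np.concatenate([blk[:, 2:], np.zeros((n_cond, 1))], axis=1)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        delta = e / e.sum(axis=1, keepdims=True)
        return alpha, beta, delta

    def neglogpost(x):
        alpha, beta, delta = unpack(x)
        eta = alpha[:, None] + beta[:, None] * np.cumsum(delta, axis=1)
        ll = np.sum(y * (-np.logaddexp(0.0, -eta)) + (n - y) * (-np.logaddexp(0.0, eta)))
        z = (x - prior_mean) / prior_sd
        return -(ll - 0.5 * np.dot(z, z))

    res = map_laplace(
        neglogpost,
        prior_mean.copy(),
        n_draws=n_draws,
        rng=np.random.default_rng(seed),
        min_curvature=1.0 / max(prior_sd_alpha, prior_sd_beta, 1.0) ** 2,
    )
    cols = {}
    for ci, cond in enumerate(conditions):
        key = ",".join(map(str, cond))
        blk = res.draws.reshape(n_draws, n_cond, dim_per)
        cols[f"alpha[{key}]"] = blk[:, ci, 0]
        cols[f"beta_max[{key}]"] = blk[:, ci, 1]
        logits = np.concatenate([blk[:, ci, 2:], np.zeros((n_draws, 1))], axis=1)
        zz = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(zz)
        delta = e / e.sum(axis=1, keepdims=True)
        for m in range(N_MINUTES):
            cols[f"delta[{key},{m + 1}]"] = delta[:, m]
    return TimecourseFit(draws=pd.DataFrame(cols), conditions=conditions, converged=res.success)


# ---------------------------------------------------------------------------
# Spatial / visual summaries and trajectory descriptors
# ---------------------------------------------------------------------------


def spatial_social_summaries(
    traj_1hz: pd.DataFrame, events: pd.DataFrame, fov_deg: float = 108.0
) -> pd.DataFrame:
    """Per player-round spatial/visual summaries and patch counts.

    Mean distance to the other players and mean number of players in
    the focal's field of view, both computed over seconds at which the
    focal was not exploiting (NaN for solitary runs); plus the number
    of patches the focal discovered (first extractor) and joined
    (extracted at a patch another player had already extracted at).
    """
    half = math.radians(fov_deg) / 2.0
    rows = []
    for (g, r), traj in traj_1hz.groupby(_ROUND_KEY):
        players = np.sort(traj["player_id"].unique())
        piv = traj.set_index(["t_sec", "player_id"]).sort_index()
        seconds = np.sort(traj["t_sec"].unique())
        T, P = seconds.size, players.size
        xy = np.empty((T, P, 2))
        heading = np.empty((T, P))
        exploiting = np.empty((T, P), dtype=bool)
        for pi, p in enumerate(players):
            sub = piv.xs(p, level="player_id").reindex(seconds)
            xy[:, pi, 0] = sub["x_m"].to_numpy(dtype=float)
            xy[:, pi, 1] = sub["y_m"].to_numpy(dtype=float)
            heading[:, pi] = sub["heading_rad"].to_numpy(dtype=float)
            exploiting[:, pi] = sub["exploiting"].to_numpy().astype(bool)

        ev = events[(events["group_id"] == g) & (events["round_id"] == r)]
        arrivals = ev[ev["event_type"] == "patch_joined"].sort_values("t_sec")
        discovered = {p: 0 for p in players}
        joined = {p: 0 for p in players}
        seen_patches: set[int] = set()
        for _, row in arrivals.iterrows():
            p, pid = int(row["player_id"]), int(row["patch_id"])
            if pid not in seen_patches:
                discovered[p] = discovered.get(p, 0) + 1
                seen_patches.add(pid)
            else:
                joined[p] = joined.get(p, 0) + 1

        for pi, p in enumerate(players):
            free = ~exploiting[:, pi]
            if P >= 2:
                others = [j for j in range(P) if j != pi]
                delta = xy[:, others, :] - xy[:, pi : pi + 1, :]
                dist = np.hypot(delta[..., 0], delta[..., 1])
                brg = np.abs(
                    wrap_angle(np.arctan2(delta[..., 1], delta[..., 0]) - heading[:, pi : pi + 1])
                )
                in_fov = (brg <= half) & (dist > 0)
                mean_dist = float(dist[free].mean()) if free.any() else np.nan
                mean_fov = float(in_fov[free].sum(axis=1).mean()) if free.any() else np.nan
            else:
                mean_dist = mean_fov = np.nan
            rows.append(
                (g, r, int(p), mean_dist, mean_fov, discovered.get(p, 0), joined.get(p, 0))
            )
    return pd.DataFrame(
        rows,
        columns=_PLAYER_KEY
        + ["mean_dist_others", "mean_players_in_fov", "patches_discovered", "patches_joined"],
    )


def trajectory_descriptors(traj_1hz: pd.DataFrame) -> pd.DataFrame:
    """Straightness and turning-angle dispersion per player-round.

    Straightness is net displacement over path length (in [0, 1];
    NaN for zero path length); dispersion is the circular standard
    deviation sqrt(-2 ln R) of the per-second turning angles.
    """
    rows = []
    for (g, r, p), df in traj_1hz.groupby(_PLAYER_KEY):
        df = df.sort_values("t_sec")
        x = df["x_m"].to_numpy(dtype=float)
        y = df["y_m"].to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError("trajectory descriptors need at least two positions")
        steps = np.hypot(np.diff(x), np.diff(y))
        path = float(steps.sum())
        net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
        straightness = net / path if path > 0 else np.nan
        h = df["heading_rad"].to_numpy(dtype=float)
        theta = wrap_angle(np.diff(h))
        if theta.size:
            rbar = float(np.hypot(np.cos(theta).mean(), np.sin(theta).mean()))
            dispersion = math.sqrt(max(-2.0 * math.log(max(rbar, 1e-12)), 0.0))
        else:
            dispersion = np.nan
        rows.append((g, r, int(p), straightness, dispersion))
    return pd.DataFrame(rows, columns=_PLAYER_KEY + ["straightness", "turn_dispersion"])
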