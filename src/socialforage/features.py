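"""Feature construction: from raw trajectories to model-ready state series.

Raw trajectories (25 Hz samples of position, heading and the exploiting
flag per player) are resampled to 1 Hz and transformed into

* three *state-dependent variables* whose distributions differ between
  the latent behavioral states: the turning angle ``theta`` (rad), the
  smallest change in distance to visible exploiting players ``ddist``
  (m), and the smallest absolute relative bearing to visible exploiting
  players ``bearing`` (rad, strictly positive);
* four *state predictors* entering the logit of the switch probability:
  exploiter visibility ``V`` (0/1), z-scored distance to the closest
  visible exploiter ``D``, the number of other players extracting at
  that exploiter's patch ``N`` (0 = a single exploiter), and z-scored
  time since the focal's last coin ``T``;
* a validity mask and its maximal-run *segments*: only seconds at which
  the focal is free to move and at least one group member is exploiting
  are modeled, and the latent chain restarts in individual exploration
  at every segment start.

Angles are radians in (-pi, pi], 0 along +x; coordinates are meters
with the origin at an arena corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Strictly positive floor for bearings of exactly zero (log-normal support).
BEARING_EPS = 1e-6

TRAJ_KEY = ["group_id", "round_id", "player_id"]


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def turning_angle(heading_prev: float, heading_curr: float) -> float:
    """Change in movement direction between successive seconds, wrapped to (-pi, pi]."""
    if not (np.isfinite(heading_prev) and np.isfinite(heading_curr)):
        raise ValueError("headings must be finite")
    return wrap_angle(heading_curr - heading_prev)


def relative_bearing(pos_a, heading_a: float, pos_b) -> float:
    """Signed angle from a's heading to the line of sight a -> b, in (-pi, pi]."""
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    dx, dy = pos_b - pos_a
    if dx == 0.0 and dy == 0.0:
        raise ValueError("bearing undefined for coincident positions")
    return wrap_angle(np.arctan2(dy, dx) - heading_a)


def fov_visible(pos_a, heading_a: float, pos_b, fov_deg: float = 108.0) -> bool:
    """True iff b lies within a's horizontal field-of-view cone.

    There is no distance cutoff: the arena is small and walled, so the
    angular cone is the binding constraint.  Visibility is directional
    (a seeing b does not imply b seeing a).
    """
    half = np.deg2rad(fov_deg) / 2.0
    return bool(abs(relative_bearing(pos_a, heading_a, pos_b)) <= half)


def standardize(x, ddof: int = 0):
    """Z-score ``x`` over its non-missing entries (population SD by default).

    Raises on fewer than two defined values or zero variance.
    """
    arr = np.asarray(x, dtype=float)
    mask = np.isfinite(arr)
    if mask.sum() < 2:
        raise ValueError("standardize needs at least two defined values")
    mu = arr[mask].mean()
    sd = arr[mask].std(ddof=ddof)
    if sd == 0.0:
        raise ValueError("standardize undefined for zero-variance input")
    out = np.full(arr.shape, np.nan)
    out[mask] = (arr[mask] - mu) / sd
    return out


def time_since_success(extraction_times, t):
    """Seconds since the focal's most recent coin extraction at or before ``t``.

    Before any extraction the clock runs from the round start (time 0),
    so the value at ``t`` with no history is ``t`` itself.
    """
    ev = np.asarray(extraction_times, dtype=float)
    if ev.size and np.any(np.diff(ev) < 0):
        raise ValueError("extraction times must be ordered")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(ev, t_arr, side="right") - 1
    last = np.where(idx >= 0, ev[np.clip(idx, 0, None)] if ev.size else 0.0, 0.0)
    out = t_arr - last
    return out if np.ndim(t) else float(out[0])


@dataclass(frozen=True)
class Segment:
    """A maximal run of modeled (valid) seconds, half-open [start, end).

    The latent chain restarts in individual exploration at ``start``.
    """

    group_id: int
    round_id: int
    player_id: int
    start: int
    end: int
    reason_closed: str  # own_exploitation | no_social_info | round_end

    def __len__(self) -> int:
        return self.end - self.start


def build_segments(valid, exploiting=None, group_id=0, round_id=0, player_id=0):
    """Decompose a per-second validity mask into maximal-run segments.

    ``exploiting`` (same length) is only used to label why a segment
    closed; if omitted, every interior closure is labeled
    ``no_social_info``.
    """
    valid = np.asarray(valid).astype(bool)
    n = valid.size
    segments: list[Segment] = []
    start = None
    for t in range(n + 1):
        on = valid[t] if t < n else False
        if on and start is None:
            start = t
        elif not on and start is not None:
            if t == n:
                reason = "round_end"
            elif exploiting is not None and bool(np.asarray(exploiting)[t]):
                reason = "own_exploitation"
            else:
                reason = "no_social_info"
            segments.append(Segment(group_id, round_id, player_id, start, t, reason))
            start = None
    return segments


def resample_to_1hz(raw: pd.DataFrame) -> pd.DataFrame:
    """Resample a 25 Hz trajectory table to one row per integer second.

    Sample-and-hold at the tick nearest each second boundary; the
    exploiting flag is the flag at that tick.  Raises if the raw stream
    has a gap exceeding one second for any player.
    """
    out = []
    for key, df in raw.groupby(TRAJ_KEY, sort=True):
        t = df["t_sec"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"trajectory for {key} is not strictly time-ordered")
        gaps = np.diff(t)
        if gaps.size and gaps.max() > 1.0 + 1e-9:
            i = int(np.argmax(gaps))
            raise ValueError(
                f"gap of {gaps.max():.3f} s in trajectory for {key} "
                f"between t={t[i]:.3f} and t={t[i + 1]:.3f}"
            )
        seconds = np.arange(0, int(np.floor(t[-1] + 1e-9)) + 1)
        pos = np.searchsorted(t, seconds)
        pos = np.clip(pos, 0, t.size - 1)
        left = np.clip(pos - 1, 0, t.size - 1)
        nearest = np.where(np.abs(t[left] - seconds) <= np.abs(t[pos] - seconds), left, pos)
        sub = df.iloc[nearest].copy()
        sub["t_sec"] = seconds.astype(float)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class SocialChannels:
    """Per-second social observation channels for one focal player."""

    ddist: float
    bearing: float
    v: int
    d_raw: float
    n: float


def social_channels(
    focal_pos,
    focal_pos_prev,
    focal_heading: float,
    other_pos,
    other_pos_prev,
    other_exploiting,
    other_patch_id,
    fov_deg: float = 108.0,
) -> SocialChannels:
    """Compute the social channels for one focal player at one second.

    Over the set of players currently exploiting *and* inside the
    focal's FOV: ``ddist`` is the smallest change in distance since the
    previous second, ``bearing`` the smallest absolute relative bearing
    (floored at a strictly positive epsilon), ``d_raw`` the distance to
    the closest member, and ``n`` the number of *other* players
    extracting at that member's patch (0 = single exploiter).  All
    social outputs are missing (NaN) when no exploiter is visible.
    """
    focal_pos = np.asarray(focal_pos, dtype=float)
    focal_pos_prev = np.asarray(focal_pos_prev, dtype=float)
    other_pos = np.atleast_2d(np.asarray(other_pos, dtype=float))
    other_pos_prev = np.atleast_2d(np.asarray(other_pos_prev, dtype=float))
    exploiting = np.asarray(other_exploiting).astype(bool)
    patch_id = np.asarray(other_patch_id)

    half = np.deg2rad(fov_deg) / 2.0
    delta = other_pos - focal_pos
    dist = np.hypot(delta[:, 0], delta[:, 1])
    bearings = np.abs(wrap_angle(np.arctan2(delta[:, 1], delta[:, 0]) - focal_heading))
    visible = exploiting & (bearings <= half) & (dist > 0)
    if not visible.any():
        return SocialChannels(np.nan, np.nan, 0, np.nan, np.nan)

    delta_prev = other_pos_prev - focal_pos_prev
    dist_prev = np.hypot(delta_prev[:, 0], delta_prev[:, 1])
    ddist = np.min((dist - dist_prev)[visible])
    bearing = max(float(np.min(bearings[visible])), BEARING_EPS)
    closest = int(np.flatnonzero(visible)[np.argmin(dist[visible])])
    d_raw = float(dist[closest])
    n_at_patch = int(np.sum(exploiting & (patch_id == patch_id[closest]))) - 1
    return SocialChannels(float(ddist), bearing, 1, d_raw, float(n_at_patch))


def _active_patch_ids(patches: pd.DataFrame, t: float) -> pd.DataFrame:
    # inclusive upper bound: a patch depleted exactly at t still owns the
    # players whose exploiting flag was sampled at that instant
    depleted = patches["t_depleted"].to_numpy(dtype=float)
    open_ended = ~np.isfinite(depleted)
    active = (patches["t_created"].to_numpy(dtype=float) <= t) & (open_ended | (depleted >= t))
    return patches.loc[active]


def _assign_patches(xy: np.ndarray, exploiting: np.ndarray, patches: pd.DataFrame, seconds: np.ndarray) -> np.ndarray:
    """Patch id for every exploiting (t, player) entry, -1 elsewhere.

    An exploiting player is assigned the active patch containing their
    position (nearest center as a fallback against float round-off).
    """
    T, P = exploiting.shape
    out = np.full((T, P), -1, dtype=int)
    for ti in range(T):
        if not exploiting[ti].any():
            continue
        act = _active_patch_ids(patches, float(seconds[ti]))
        if act.empty:
            continue
        centers = act[["x_m", "y_m"]].to_numpy(dtype=float)
        ids = act["patch_id"].to_numpy()
        for p in np.flatnonzero(exploiting[ti]):
            d = np.hypot(centers[:, 0] - xy[ti, p, 0], centers[:, 1] - xy[ti, p, 1])
            out[ti, p] = int(ids[np.argmin(d)])
    return out


def build_state_series(
    traj_1hz: pd.DataFrame,
    patches: pd.DataFrame,
    events: pd.DataFrame | None = None,
    fov_deg: float = 108.0,
) -> pd.DataFrame:
    """Per-player-second state variables and raw predictors for one group-round.

    ``traj_1hz`` must hold all players of one group-round at 1 Hz.
    Returns a tidy frame with theta/ddist/bearing, V/D_raw/N/T_raw, the
    validity mask and the minute-of-round index.  Z-scoring and segment
    ids are added by :func:`standardize_features` / :func:`add_segment_ids`.
    """
    group_id = int(traj_1hz["group_id"].iloc[0])
    round_id = int(traj_1hz["round_id"].iloc[0])
    players = np.sort(traj_1hz["player_id"].unique())
    piv = traj_1hz.set_index(["t_sec", "player_id"]).sort_index()
    seconds = np.sort(traj_1hz["t_sec"].unique())
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

    patch_id = _assign_patches(xy, exploiting, patches, seconds)

    if events is not None:
        ev = events[events["event_type"] == "coin_extracted"]
        extraction = {
            p: np.sort(ev.loc[ev["player_id"] == p, "t_sec"].to_numpy(dtype=float))
            for p in players
        }
    else:
        extraction = {}
        for pi, p in enumerate(players):
            coins = piv.xs(p, level="player_id").reindex(seconds)["coins_cum"].to_numpy(dtype=float)
            inc = np.flatnonzero(np.diff(coins) > 0) + 1
            extraction[p] = seconds[inc].astype(float)

    half = np.deg2rad(fov_deg) / 2.0
    rows = []
    any_other_exploiting = exploiting.sum(axis=1)
    for pi, p in enumerate(players):
        others = [j for j in range(P) if j != pi]
        delta = xy[:, others, :] - xy[:, pi : pi + 1, :]  # (T, P-1, 2)
        dist = np.hypot(delta[..., 0], delta[..., 1])
        brg = np.abs(wrap_angle(np.arctan2(delta[..., 1], delta[..., 0]) - heading[:, pi : pi + 1]))
        visible = exploiting[:, others] & (brg <= half) & (dist > 0)
        ddist_pair = np.full_like(dist, np.nan)
        ddist_pair[1:] = dist[1:] - dist[:-1]

        theta = np.full(T, np.nan)
        theta[1:] = wrap_angle(heading[1:, pi] - heading[:-1, pi])

        t_raw = time_since_success(extraction[p], seconds)

        others_exploiting_ct = any_other_exploiting - exploiting[:, pi].astype(int)
        for ti in range(T):
            vis = visible[ti]
            v = int(vis.any())
            if v:
                dd = float(np.nanmin(np.where(vis, ddist_pair[ti], np.nan))) if ti > 0 else np.nan
                bearing = max(float(np.min(brg[ti][vis])), BEARING_EPS)
                vis_idx = np.flatnonzero(vis)
                closest = int(vis_idx[np.argmin(dist[ti][vis])])
                d_raw = float(dist[ti, closest])
                closest_pid = patch_id[ti, others[closest]]
                n = int(np.sum(exploiting[ti] & (patch_id[ti] == closest_pid))) - 1
            else:
                dd = bearing = d_raw = n = np.nan
            valid = (
                ti >= 1
                and not exploiting[ti, pi]
                and others_exploiting_ct[ti] > 0
                and np.isfinite(theta[ti])
            )
            rows.append(
                (
                    group_id,
                    round_id,
                    p,
                    float(seconds[ti]),
                    int(seconds[ti] // 60) + 1,
                    theta[ti],
                    dd,
                    bearing,
                    v,
                    d_raw,
                    n,
                    float(t_raw[ti]),
                    int(exploiting[ti, pi]),
                    int(valid),
                )
            )
    cols = [
        "group_id",
        "round_id",
        "player_id",
        "t_sec",
        "minute",
        "theta",
        "ddist",
        "bearing",
        "V",
        "D_raw",
        "N",
        "T_raw",
        "exploiting",
        "valid",
    ]
    return pd.DataFrame(rows, columns=cols)


def standardize_features(features: pd.DataFrame, scope: str = "pooled") -> pd.DataFrame:
    """Add z-scored predictors D and T to a (possibly multi-round) feature table.

    D is standardized over the valid seconds where it is defined (V=1);
    T over all valid seconds.  ``scope`` is "pooled" (one scale for the
    whole table, the default, keeping condition contrasts comparable)
    or "round" (within each group-round).
    """
    out = features.copy()
    out["D"] = np.nan
    out["T"] = np.nan

    def _z(df):
        valid = df["valid"].to_numpy().astype(bool)
        d = np.where(valid, df["D_raw"].to_numpy(dtype=float), np.nan)
        t = np.where(valid, df["T_raw"].to_numpy(dtype=float), np.nan)
        return standardize(d), standardize(t)

    if scope == "pooled":
        d, t = _z(out)
        out["D"], out["T"] = d, t
    elif scope == "round":
        for _, idx in out.groupby(["group_id", "round_id"]).groups.items():
            d, t = _z(out.loc[idx])
            out.loc[idx, "D"] = d
            out.loc[idx, "T"] = t
    else:
        raise ValueError(f"unknown z-scoring scope {scope!r}")
    return out


def add_segment_ids(features: pd.DataFrame) -> pd.DataFrame:
    """Assign a dataset-wide segment id to every valid second (NaN elsewhere)."""
    out = features.sort_values(TRAJ_KEY + ["t_sec"]).reset_index(drop=True)
    seg_id = np.full(len(out), -1, dtype=int)
    counter = 0
    for _, idx in out.groupby(TRAJ_KEY, sort=True).groups.items():
        valid = out.loc[idx, "valid"].to_numpy().astype(bool)
        runs = np.flatnonzero(np.diff(np.concatenate(([0], valid.astype(int)))) == 1)
        ends = np.flatnonzero(np.diff(np.concatenate((valid.astype(int), [0]))) == -1) + 1
        pos = np.asarray(idx)
        for s, e in zip(runs, ends):
            seg_id[pos[s:e]] = counter
            counter += 1
    out["segment_id"] = np.where(seg_id >= 0, seg_id, np.nan)
    return out


def features_pipeline(
    traj: pd.DataFrame,
    patches: pd.DataFrame,
    events: pd.DataFrame | None = None,
    fov_deg: float = 108.0,
    z_scope: str = "pooled",
    already_1hz: bool = True,
) -> pd.DataFrame:
    """Full pipeline: (resample ->) state series -> z-scores -> segment ids.

    ``traj`` may span several group-rounds; ``patches`` / ``events``
    must carry matching group_id/round_id columns when they do.
    """
    if not already_1hz:
        traj = resample_to_1hz(traj)
    parts = []
    for (g, r), sub in traj.groupby(["group_id", "round_id"]):
        pmask = (patches["group_id"] == g) & (patches["round_id"] == r) if "group_id" in patches else slice(None)
        psub = patches.loc[pmask] if not isinstance(pmask, slice) else patches
        if events is not None and "group_id" in events:
            esub = events[(events["group_id"] == g) & (events["round_id"] == r)]
        else:
            esub = events
        parts.append(build_state_series(sub, psub, esub, fov_deg=fov_deg))
    feats = pd.concat(parts, ignore_index=True)
    feats = standardize_features(feats, scope=z_scope)
    return add_segment_ids(feats)
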