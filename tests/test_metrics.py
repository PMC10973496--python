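"""Behavioral-metric tests: scrounging, time-courses, spatial summaries."""

import numpy as np
import pandas as pd
import pytest

import socialforage as sf
from socialforage.metrics import (
    ScroungeLedger,
    exploitation_timecourse_fit,
    scrounging_ledger,
    scrounging_rate,
    spatial_social_summaries,
    trajectory_descriptors,
)


def _toy_round(join: bool):
    """Two players: B digs at a patch from t=5; focal A watches from t=10
    and (optionally) walks over and joins at t=25."""
    seconds = np.arange(0, 40, dtype=float)
    rows = []
    for t in seconds:
        # B sits on the patch at (30, 0) exploiting from t=5
        rows.append((0, 0, 1, t, 30.0, 0.0, 0.0, int(t >= 5), 0))
        # A at (10+progress, 0), facing +x so B is dead ahead
        if join and t >= 12:
            x = min(10.0 + 2.0 * (t - 12), 27.5)
        else:
            x = 10.0
        rows.append((0, 0, 0, t, x, 0.0, 0.0, int(join and x >= 27.5), 0))
    traj = pd.DataFrame(
        rows,
        columns=["group_id", "round_id", "player_id", "t_sec", "x_m", "y_m",
                 "heading_rad", "exploiting", "coins_cum"],
    )
    events = [(0, 0, 0.0, "patch_created", -1, 7, 30.0, 0.0), (0, 0, 5.0, "patch_joined", 1, 7, 30.0, 0.0)]
    if join:
        t_join = float(seconds[(10.0 + 2.0 * (seconds - 12) >= 27.5) & (seconds >= 12)][0])
        events.append((0, 0, t_join, "patch_joined", 0, 7, 27.5, 0.0))
    events = pd.DataFrame(
        events, columns=["group_id", "round_id", "t_sec", "event_type", "player_id", "patch_id", "x_m", "y_m"]
    )
    patches = pd.DataFrame(
        {
            "group_id": [0], "round_id": [0], "patch_id": [7],
            "x_m": [30.0], "y_m": [0.0], "radius": [3.0],
            "coins_initial": [48], "coins_remaining": [40],
            "t_created": [0.0], "t_depleted": [np.nan],
        }
    )
    return traj, events, patches


class TestScrounging:
    def test_observed_and_joined_episode(self):
        traj, events, patches = _toy_round(join=True)
        ledger = scrounging_ledger(traj, events, patches)
        per = ledger.per_player_round()
        focal = per[per["player_id"] == 0].iloc[0]
        assert (focal["n_observed"], focal["n_joined"]) == (1, 1)

    def test_observed_but_never_joined(self):
        traj, events, patches = _toy_round(join=False)
        per = scrounging_ledger(traj, events, patches).per_player_round()
        focal = per[per["player_id"] == 0].iloc[0]
        assert (focal["n_observed"], focal["n_joined"]) == (1, 0)

    def test_discovery_without_observation_is_not_scrounging(self):
        # B (the digger) never observed anyone dig before arriving first
        traj, events, patches = _toy_round(join=True)
        per = scrounging_ledger(traj, events, patches).per_player_round()
        assert not (per["player_id"] == 1).any()

    def test_unknown_patch_id_errors(self):
        traj, events, patches = _toy_round(join=True)
        events.loc[len(events)] = (0, 0, 9.0, "patch_joined", 0, 99, 0.0, 0.0)
        with pytest.raises(ValueError):
            scrounging_ledger(traj, events, patches)

    def test_rates(self):
        ep = pd.DataFrame(
            {
                "group_id": 0, "round_id": 0, "player_id": [0, 0, 0],
                "patch_id": [1, 2, 3], "first_seen": [1.0, 2.0, 3.0],
                "joined": [True, True, False],
            }
        )
        per = scrounging_rate(ScroungeLedger(ep), pooling="player")
        assert per["rate"].iloc[0] == pytest.approx(2 / 3, abs=1e-9)
        all_joined = ScroungeLedger(ep.assign(joined=True))
        assert scrounging_rate(all_joined, pooling="overall") == 1.0

    def test_rate_undefined_without_episodes(self):
        empty = ScroungeLedger(pd.DataFrame(columns=["group_id", "round_id", "player_id", "patch_id", "first_seen", "joined"]))
        assert np.isnan(scrounging_rate(empty, pooling="overall"))

    def test_bernoulli_simulation_matches_binomial_ci(self):
        rng = np.random.default_rng(0)
        n = 1000
        ep = pd.DataFrame(
            {
                "group_id": 0, "round_id": 0,
                "player_id": np.repeat(np.arange(20), n // 20),
                "patch_id": np.arange(n), "first_seen": 0.0,
                "joined": rng.random(n) < 0.5,
            }
        )
        rate = scrounging_rate(ScroungeLedger(ep), pooling="overall")
        assert abs(rate - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_episodes_match_brute_force_on_simulated_round(self):
        """Cross-check the vectorized ledger against a direct per-second
        re-derivation using the scalar geometry primitives."""
        out = sf.simulate_round(sf.EnvironmentConfig.preset("concentrated"), duration=240, rng=55)
        traj = sf.resample_to_1hz(out.trajectories)
        ledger = scrounging_ledger(traj, out.events, out.patches)

        from socialforage.features import fov_visible

        piv = traj.set_index(["t_sec", "player_id"]).sort_index()
        players = sorted(traj["player_id"].unique())
        seconds = sorted(traj["t_sec"].unique())
        pat = out.patches.set_index("patch_id")
        expected = set()
        first_seen = {}
        for t in seconds:
            snap = piv.xs(t, level="t_sec")
            for f in players:
                if snap.loc[f, "exploiting"]:
                    continue
                for o in players:
                    if o == f or not snap.loc[o, "exploiting"]:
                        continue
                    a = (snap.loc[f, "x_m"], snap.loc[f, "y_m"])
                    b = (snap.loc[o, "x_m"], snap.loc[o, "y_m"])
                    if not fov_visible(a, snap.loc[f, "heading_rad"], b):
                        continue
                    # patch of o: containing patch whose lifetime covers t
                    d = np.hypot(pat["x_m"] - b[0], pat["y_m"] - b[1])
                    alive = (pat["t_created"] <= t) & (pat["t_depleted"].isna() | (pat["t_depleted"] >= t))
                    cand = d[alive & (d <= pat["radius"])]
                    if cand.empty:
                        continue
                    pid = int(cand.idxmin())
                    if (f, pid) not in first_seen:
                        first_seen[(f, pid)] = t
                        expected.add((f, pid))
        got = {(int(r.player_id), int(r.patch_id)) for r in ledger.episodes.itertuples()}
        assert got == expected
        for r in ledger.episodes.itertuples():
            assert r.first_seen == first_seen[(int(r.player_id), int(r.patch_id))]


class TestTimecourse:
    def test_flat_probability_recovered(self):
        rng = np.random.default_rng(1)
        n = 30 * 720
        df = pd.DataFrame(
            {
                "exploiting": rng.random(n) < 0.3,
                "minute": np.tile(np.arange(720) // 60 + 1, 30),
            }
        )
        tc = exploitation_timecourse_fit(df, n_draws=800, seed=2)
        curve = tc.curve(("all", "all")).mean(axis=0)
        assert np.all(np.abs(curve - 0.3) < 0.03)
        assert np.ptp(curve) < 0.04

    def test_zero_total_effect_gives_identical_minutes(self):
        from socialforage.metrics import TimecourseFit

        cols = {"alpha[all,all]": np.full(200, -0.5), "beta_max[all,all]": np.zeros(200)}
        for m in range(12):
            cols[f"delta[all,all,{m + 1}]"] = np.full(200, 1 / 12)
        tc = TimecourseFit(pd.DataFrame(cols), [("all", "all")], True)
        curve = tc.curve(("all", "all"))
        assert np.ptp(curve, axis=1).max() == 0.0

    def test_increasing_probability_recovered(self):
        rng = np.random.default_rng(3)
        minutes = np.tile(np.arange(720) // 60 + 1, 30)
        p_true = 0.1 + 0.3 * (minutes - 1) / 11
        df = pd.DataFrame({"exploiting": rng.random(minutes.size) < p_true, "minute": minutes})
        tc = exploitation_timecourse_fit(df, n_draws=600, seed=4)
        curve = tc.curve(("all", "all")).mean(axis=0)
        assert np.all(np.diff(curve) > -1e-6)
        assert curve[-1] - curve[0] > 0.2

    def test_difference_curve_shape(self):
        rng = np.random.default_rng(5)
        minutes = np.tile(np.arange(720) // 60 + 1, 20)
        frames = []
        for inc, p in (("group", 0.35), ("individual", 0.25)):
            frames.append(
                pd.DataFrame(
                    {
                        "exploiting": rng.random(minutes.size) < p,
                        "minute": minutes,
                        "incentive": inc,
                        "environment": "concentrated",
                    }
                )
            )
        tc = exploitation_timecourse_fit(pd.concat(frames), n_draws=500, seed=6)
        diff = tc.difference_curve(("group", "concentrated"), ("individual", "concentrated"))
        assert diff.mean() == pytest.approx(0.10, abs=0.03)


class TestSpatialSummaries:
    def test_two_stationary_players(self):
        rows = []
        for t in np.arange(0, 20, dtype=float):
            rows.append((0, 0, 0, t, 0.0, 0.0, 0.0, 0, 0))
            rows.append((0, 0, 1, t, 10.0, 0.0, np.pi, 0, 0))
        traj = pd.DataFrame(
            rows, columns=["group_id", "round_id", "player_id", "t_sec", "x_m", "y_m",
                           "heading_rad", "exploiting", "coins_cum"],
        )
        events = pd.DataFrame(columns=["group_id", "round_id", "t_sec", "event_type", "player_id", "patch_id", "x_m", "y_m"])
        out = spatial_social_summaries(traj, events)
        assert np.allclose(out["mean_dist_others"], 10.0)
        # facing each other: exactly one player in view for each
        assert np.allclose(out["mean_players_in_fov"], 1.0)

    def test_solitary_run_undefined_social_but_counts_discoveries(self):
        out = sf.simulate_round(
            sf.EnvironmentConfig.preset("concentrated"),
            policies=sf.default_policies(1), duration=300, rng=77,
        )
        traj = sf.resample_to_1hz(out.trajectories)
        summ = spatial_social_summaries(traj, out.events)
        assert summ["mean_dist_others"].isna().all()
        n_arrivals = (out.events["event_type"] == "patch_joined").sum()
        assert summ["patches_discovered"].iloc[0] + summ["patches_joined"].iloc[0] == n_arrivals
        assert summ["patches_joined"].iloc[0] == 0  # no one to join

    def test_discoveries_and_joins_from_toy_events(self):
        traj, events, patches = _toy_round(join=True)
        out = spatial_social_summaries(traj, events)
        a = out[out["player_id"] == 0].iloc[0]
        b = out[out["player_id"] == 1].iloc[0]
        assert (b["patches_discovered"], b["patches_joined"]) == (1, 0)
        assert (a["patches_discovered"], a["patches_joined"]) == (0, 1)

    def test_each_extracted_patch_has_one_discoverer(self, abm_round, abm_round_1hz):
        summ = spatial_social_summaries(abm_round_1hz, abm_round.events)
        arrivals = abm_round.events[abm_round.events["event_type"] == "patch_joined"]
        assert summ["patches_discovered"].sum() == arrivals["patch_id"].nunique()
        assert summ["patches_discovered"].sum() + summ["patches_joined"].sum() == len(arrivals)


class TestTrajectoryDescriptors:
    def _frame(self, x, y, heading):
        return pd.DataFrame(
            {
                "group_id": 0, "round_id": 0, "player_id": 0,
                "t_sec": np.arange(len(x), dtype=float),
                "x_m": x, "y_m": y, "heading_rad": heading,
                "exploiting": 0, "coins_cum": 0,
            }
        )

    def test_straight_line(self):
        n = 50
        d = trajectory_descriptors(self._frame(np.arange(n, dtype=float), np.zeros(n), np.zeros(n)))
        assert d["straightness"].iloc[0] == pytest.approx(1.0)
        assert d["turn_dispersion"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_closed_loop(self):
        ang = np.linspace(0, 2 * np.pi, 101)
        d = trajectory_descriptors(self._frame(np.cos(ang) * 10, np.sin(ang) * 10, ang + np.pi / 2))
        assert d["straightness"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_path_length_undefined(self):
        d = trajectory_descriptors(self._frame(np.zeros(10), np.zeros(10), np.zeros(10)))
        assert np.isnan(d["straightness"].iloc[0])

    def test_random_walk_straightness_decays_with_duration(self):
        rng = np.random.default_rng(8)
        vals = {n: [] for n in (60, 600)}
        for _ in range(12):
            for n in vals:
                h = np.cumsum(rng.normal(0, 0.4, n))
                x = np.cumsum(np.cos(h))
                y = np.cumsum(np.sin(h))
                d = trajectory_descriptors(self._frame(x, y, h))
                vals[n].append(d["straightness"].iloc[0])
        assert np.mean(vals[60]) > np.mean(vals[600])
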