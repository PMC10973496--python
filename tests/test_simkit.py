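"""Simulator tests: environment packing, round physics, generative twin."""

import numpy as np
import pandas as pd
import pytest

import socialforage as sf
from socialforage.config import EnvironmentConfig
from socialforage.hmm import inv_logit
from socialforage.sim import make_environment, recovery_study_params, respawn_patch


def pairwise_min_dist(patches):
    c = np.array([[p.x, p.y] for p in patches])
    d = np.hypot(c[:, 0, None] - c[None, :, 0], c[:, 1, None] - c[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return d.min()


class TestEnvironment:
    def test_presets(self):
        conc = EnvironmentConfig.preset("concentrated")
        dist = EnvironmentConfig.preset("distributed")
        assert (conc.n_patches, conc.coins_per_patch) == (5, 48)
        assert (dist.n_patches, dist.coins_per_patch) == (15, 16)
        for cfg in (conc, dist):
            assert cfg.arena_side == 90.0 and cfg.patch_radius == 3.0
        # equal total resources by design
        assert conc.n_patches * conc.coins_per_patch == dist.n_patches * dist.coins_per_patch

    def test_unknown_preset_and_bad_config(self):
        with pytest.raises(ValueError):
            EnvironmentConfig.preset("sparse")
        with pytest.raises(ValueError):
            EnvironmentConfig(arena_side=-1)
        with pytest.raises(ValueError):
            EnvironmentConfig(coins_per_patch=0)

    def test_make_environment_counts_and_packing(self):
        rng = np.random.default_rng(0)
        cfg = EnvironmentConfig.preset("concentrated")
        patches = make_environment(cfg, rng)
        assert len(patches) == 5
        assert all(p.coins_remaining == 48 for p in patches)
        assert pairwise_min_dist(patches) >= 2 * cfg.patch_radius
        for p in patches:
            assert cfg.patch_radius <= p.x <= cfg.arena_side - cfg.patch_radius
            assert cfg.patch_radius <= p.y <= cfg.arena_side - cfg.patch_radius

    def test_zero_patches(self):
        cfg = EnvironmentConfig(n_patches=0)
        assert make_environment(cfg, np.random.default_rng(1)) == []

    def test_avoid_points_respected(self):
        cfg = EnvironmentConfig.preset("distributed")
        rng = np.random.default_rng(2)
        avoid = rng.uniform(0, 90, size=(4, 2))
        patches = make_environment(cfg, rng, avoid_points=avoid)
        c = np.array([[p.x, p.y] for p in patches])
        d = np.hypot(c[:, None, 0] - avoid[None, :, 0], c[:, None, 1] - avoid[None, :, 1])
        assert d.min() >= cfg.patch_radius

    def test_packing_infeasible_raises(self):
        cfg = EnvironmentConfig(arena_side=14.0, n_patches=10, patch_radius=3.0)
        with pytest.raises(RuntimeError, match="attempts"):
            make_environment(cfg, np.random.default_rng(3))

    def test_respawn_restores_count_and_non_overlap(self):
        cfg = EnvironmentConfig.preset("concentrated")
        rng = np.random.default_rng(4)
        patches = make_environment(cfg, rng)
        for k in range(1000):
            victim = patches[int(rng.integers(0, len(patches)))]
            while not victim.active:
                victim = patches[int(rng.integers(0, len(patches)))]
            victim.coins_remaining = 0
            victim.t_depleted = float(k)
            new = respawn_patch(patches, cfg, rng, t=float(k))
            active = [p for p in patches if p.active]
            assert len(active) == cfg.n_patches
            assert new.coins_remaining == cfg.coins_per_patch
            survivors = [p for p in active if p.patch_id != new.patch_id]
            dmin = min(np.hypot(p.x - new.x, p.y - new.y) for p in survivors)
            assert dmin >= 2 * cfg.patch_radius


class TestSimulateRound:
    def test_tick_and_second_displacement_bounds(self, abm_round, abm_round_1hz):
        tick_cap = 2.0 / 25 + 1e-9
        for _, df in abm_round.trajectories.groupby("player_id"):
            d = np.hypot(df["x_m"].diff(), df["y_m"].diff()).dropna()
            assert d.max() <= tick_cap
        for _, df in abm_round_1hz.groupby("player_id"):
            d = np.hypot(df["x_m"].diff(), df["y_m"].diff()).dropna()
            assert d.max() <= 2.0 + 1e-9

    def test_coin_conservation_exact(self, abm_round):
        ev = abm_round.events
        injected = int((ev["event_type"] == "patch_created").sum()) * abm_round.config.coins_per_patch
        extracted = int((ev["event_type"] == "coin_extracted").sum())
        remaining = int(
            abm_round.patches.loc[abm_round.patches["t_depleted"].isna(), "coins_remaining"].sum()
        )
        assert injected == extracted + remaining
        # per-player coin count equals extraction-event count
        per_player = ev[ev["event_type"] == "coin_extracted"].groupby("player_id").size()
        final = abm_round.trajectories.groupby("player_id")["coins_cum"].max()
        for p, c in final.items():
            assert per_player.get(p, 0) == c

    def test_extraction_interval_is_two_seconds(self, abm_round):
        ev = abm_round.events
        coins = ev[ev["event_type"] == "coin_extracted"]
        for (_, _), grp in coins.groupby(["player_id", "patch_id"]):
            dt = np.diff(np.sort(grp["t_sec"].to_numpy()))
            assert np.allclose(dt, 2.0)

    def test_extractions_inside_patch_radius(self, abm_round):
        coins = abm_round.events[abm_round.events["event_type"] == "coin_extracted"]
        pat = abm_round.patches.set_index("patch_id")
        for _, row in coins.iterrows():
            p = pat.loc[row["patch_id"]]
            assert np.hypot(row["x_m"] - p["x_m"], row["y_m"] - p["y_m"]) <= p["radius"] + 1e-9

    def test_truth_labels_consistent(self, abm_round, abm_round_1hz):
        m = abm_round.truth_states.merge(
            abm_round_1hz, on=["group_id", "round_id", "player_id", "t_sec"]
        )
        assert ((m["truth_state_x"] == "E") == (m["exploiting"] == 1)).all()
        # S only while someone else is exploiting (at the label's second or the one before)
        expl = abm_round_1hz.pivot_table(index="t_sec", columns="player_id", values="exploiting")
        any_other = expl.sum(axis=1)
        for _, row in abm_round.truth_states[abm_round.truth_states["truth_state"] == "S"].iterrows():
            t, p = row["t_sec"], row["player_id"]
            others_now = any_other.get(t, 0) - expl.loc[t, p] if t in expl.index else 0
            others_prev = (
                any_other.get(t - 1, 0) - expl.loc[t - 1, p] if (t - 1) in expl.index else 0
            )
            assert others_now > 0 or others_prev > 0

    def test_same_seed_bit_identical(self):
        cfg = EnvironmentConfig.preset("distributed")
        a = sf.simulate_round(cfg, duration=90, rng=7)
        b = sf.simulate_round(cfg, duration=90, rng=7)
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.patches, b.patches)
        pd.testing.assert_frame_equal(a.truth_states, b.truth_states)

    def test_solitary_agent_never_relocates_socially(self):
        cfg = EnvironmentConfig.preset("concentrated")
        out = sf.simulate_round(cfg, policies=sf.default_policies(1), duration=300, rng=8)
        assert not (out.truth_states["truth_state"] == "S").any()

    def test_bad_args(self):
        cfg = EnvironmentConfig.preset("concentrated")
        with pytest.raises(ValueError):
            sf.simulate_round(cfg, duration=0, rng=0)
        with pytest.raises(ValueError):
            sf.simulate_round(cfg, policies=[], rng=0)


class TestSimulateFromModel:
    def _constant_covariates(self, n, v, d, n_expl, t):
        return pd.DataFrame(
            {
                "player_id": 0,
                "t_sec": np.arange(n, dtype=float),
                "minute": np.minimum(np.arange(n) // 60 + 1, 12),
                "V": float(v),
                "D": float(d),
                "N": float(n_expl),
                "T": float(t),
                "valid": 1,
            }
        )

    def test_logistic_limits(self, recovery_truth):
        em = recovery_truth.emissions
        strong = sf.ShmdmParams(
            em, sf.TransitionParams.single(sf.CellTransition(alpha=0.0, beta_v=8.0, gamma=-8.0))
        )
        cov = self._constant_covariates(4000, 1, 0, 0, 0)
        out = sf.simulate_from_model(strong, cov, rng=np.random.default_rng(0))
        assert (out["state"] == "S").mean() > 0.95
        never = sf.ShmdmParams(
            em, sf.TransitionParams.single(sf.CellTransition(alpha=-12.0, gamma=0.0))
        )
        cov0 = self._constant_covariates(4000, 0, np.nan, np.nan, 0)
        out0 = sf.simulate_from_model(never, cov0, rng=np.random.default_rng(1))
        assert (out0["state"] == "S").mean() < 0.01

    def test_neutral_rule_switches_half_the_time(self, recovery_truth):
        params = sf.ShmdmParams(
            recovery_truth.emissions,
            sf.TransitionParams.single(sf.CellTransition(alpha=0.0, gamma=0.0)),
        )
        cov = self._constant_covariates(20000, 0, np.nan, np.nan, 0)
        out = sf.simulate_from_model(params, cov, rng=np.random.default_rng(2))
        s = (out["state"] == "S").to_numpy()
        from_i = ~s[:-1]
        switch_freq = s[1:][from_i].mean()
        assert abs(switch_freq - 0.5) < 0.02

    def test_transition_frequencies_match_closed_form(self, recovery_truth):
        cell = sf.CellTransition(alpha=-1.2, beta_v=0.8, beta_d=-0.5, beta_n=-0.3, beta_t=0.2, gamma=-0.4)
        params = sf.ShmdmParams(recovery_truth.emissions, sf.TransitionParams.single(cell))
        v, d, n_expl, t = 1, 0.7, 1, -0.5
        cov = self._constant_covariates(100_000, v, d, n_expl, t)
        out = sf.simulate_from_model(params, cov, rng=np.random.default_rng(3))
        s = (out["state"] == "S").to_numpy()
        p_true = inv_logit(cell.alpha + cell.beta_v + cell.beta_d * d + cell.beta_n * n_expl + cell.beta_t * t)
        q_true = inv_logit(cell.gamma)
        p_hat = s[1:][~s[:-1]].mean()
        q_hat = (~s[1:])[s[:-1]].mean()
        n_i = (~s[:-1]).sum()
        n_s = s[:-1].sum()
        assert abs(p_hat - p_true) < 4 * np.sqrt(p_true * (1 - p_true) / n_i)
        assert abs(q_hat - q_true) < 4 * np.sqrt(q_true * (1 - q_true) / n_s)

    def test_social_channels_missing_when_invisible(self, recovery_truth):
        cov = self._constant_covariates(200, 0, np.nan, np.nan, 0.0)
        out = sf.simulate_from_model(recovery_truth_single(recovery_truth), cov, rng=np.random.default_rng(4))
        assert out["ddist"].isna().all() and out["bearing"].isna().all()
        assert out["theta"].notna().all()

    def test_invalid_params_raise(self, recovery_truth):
        from socialforage.hmm import StateEmissions, EmissionParams

        bad = sf.ShmdmParams(
            EmissionParams(
                explore=StateEmissions(0, 1, 0, -1.0, 0, 1),  # sigma <= 0
                relocate=recovery_truth.emissions.relocate,
            ),
            sf.TransitionParams.single(sf.CellTransition(alpha=0.0)),
        )
        cov = self._constant_covariates(10, 0, np.nan, np.nan, 0)
        with pytest.raises(ValueError):
            sf.simulate_from_model(bad, cov, rng=np.random.default_rng(5))

    def test_segment_restart_in_exploration(self, recovery_truth):
        # an always-switch rule: every step after the first in a segment is S,
        # while every segment's first step must be I
        params = sf.ShmdmParams(
            recovery_truth.emissions,
            sf.TransitionParams.single(sf.CellTransition(alpha=12.0, gamma=-12.0)),
        )
        cov = self._constant_covariates(100, 0, np.nan, np.nan, 0)
        cov.loc[cov.index % 10 == 0, "valid"] = 0  # break into segments
        out = sf.simulate_from_model(params, cov, rng=np.random.default_rng(6))
        valid = out[out["valid"] == 1]
        starts = valid["t_sec"].to_numpy() % 10 == 1
        assert (valid.loc[starts, "state"] == "I").all()
        assert (valid.loc[~starts, "state"] == "S").all()


def recovery_truth_single(truth):
    """Single-condition view of the canonical truth parameters."""
    cell = truth.transitions.cells[("group", "concentrated")]
    return sf.ShmdmParams(truth.emissions, sf.TransitionParams.single(cell))
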