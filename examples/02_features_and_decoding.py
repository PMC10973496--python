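"""Build model-ready features from a simulated round and decode states.

The feature pipeline turns raw trajectories into per-second turning
angles, distance changes and bearings toward visible exploiting
players, plus the switch predictors V/D/N/T; the model is then fitted
unsupervised and the Viterbi path compared with the simulator's
ground-truth states.
"""

import pandas as pd

import socialforage as sf

frames = []
for r in range(2):
    out = sf.simulate_round(
        sf.EnvironmentConfig.preset("concentrated"), duration=720, rng=60 + r, round_id=r
    )
    frames.append(out)

traj = pd.concat([sf.resample_to_1hz(o.trajectories) for o in frames], ignore_index=True)
feats = sf.features_pipeline(
    traj,
    pd.concat([o.patches for o in frames], ignore_index=True),
    pd.concat([o.events for o in frames], ignore_index=True),
)
print("player-seconds:", len(feats), "| modeled (valid):", int(feats["valid"].sum()))

fit = sf.fit(feats, kind="fixed", n_draws=1000, seed=1)
em = fit.params_at_mode().emissions
print(f"fitted distance-change means  I: {em.explore.dd_mu:.2f} m/s, S: {em.relocate.dd_mu:.2f} m/s")
print(f"fitted turning concentrations I: {em.explore.vm_kappa:.1f},  S: {em.relocate.vm_kappa:.1f}")

decoded = sf.decode(fit, feats)
truth = pd.concat([o.truth_states for o in frames], ignore_index=True)
merged = decoded.merge(truth, on=["group_id", "round_id", "player_id", "t_sec"])
valid = merged[merged["valid"] == 1]
acc = (valid["state_decoded"] == valid["truth_state"]).mean()
print(f"state recovery on modeled seconds: {acc:.1%}")

# Social relocation shows up as straighter motion (larger kappa),
# shrinking distance (negative mean change) and small bearings; the
# decoded path recovers the simulator's hidden states well above chance.
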