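"""Simulate one collective-foraging round and summarize what happened.

Four avatars forage for 12 minutes in a 90 m arena with 5 rich coin
patches (the "concentrated" layout).  The simulator logs trajectories
at 25 Hz, every patch/coin event, and the ground-truth behavioral state
of each avatar per second.
"""

import numpy as np

import socialforage as sf

out = sf.simulate_round(sf.EnvironmentConfig.preset("concentrated"), duration=720, rng=7)

coins = out.trajectories.groupby("player_id")["coins_cum"].max()
print("coins per avatar:", coins.to_dict())
print("events logged:", out.events["event_type"].value_counts().to_dict())

states = out.truth_states["truth_state"].value_counts(normalize=True)
print("time shares  I/S/E:", {k: round(v, 3) for k, v in states.items()})

traj = sf.resample_to_1hz(out.trajectories)
step = traj.sort_values("t_sec").groupby("player_id").apply(
    lambda df: np.hypot(df["x_m"].diff(), df["y_m"].diff()).max(), include_groups=False
)
print("max per-second displacement (m):", round(float(step.max()), 3), "<= 2 m/s cap")

# The I share is time spent searching independently, S the share spent
# approaching a successful group member, E the share spent extracting;
# coin counts are conserved exactly against the event log.
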