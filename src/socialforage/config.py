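"""Experiment configuration: arena, resource layout, and agent policies.

The virtual foraging arena is a flat square "courtyard" containing
non-overlapping circular coin patches.  Two named resource layouts are
used throughout: a *concentrated* environment (few rich patches) and a
*distributed* environment (many poor patches); both hold the same total
number of coins (240).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

ARENA_SIDE_M = 90.0
PATCH_RADIUS_M = 3.0
SPEED_MAX_MS = 2.0
FOV_HORIZONTAL_DEG = 108.0
TICK_HZ = 25
ROUND_DURATION_S = 720
EXTRACTION_INTERVAL_S = 2.0

#: (n_patches, coins_per_patch) for the named environment presets.
ENVIRONMENT_PRESETS = {
    "concentrated": (5, 48),
    "distributed": (15, 16),
}


@dataclass(frozen=True)
class EnvironmentConfig:
    """Resource layout for one round.

    Parameters
    ----------
    arena_side : float
        Side length of the square arena in meters.
    n_patches : int
        Number of simultaneously active circular patches.
    coins_per_patch : int
        Coins placed in each fresh patch.
    patch_radius : float
        Patch radius in meters.
    mode : str
        Preset name ("concentrated", "distributed") or "custom".
    """

    arena_side: float = ARENA_SIDE_M
    n_patches: int = 5
    coins_per_patch: int = 48
    patch_radius: float = PATCH_RADIUS_M
    mode: str = "custom"

    def __post_init__(self) -> None:
        if self.arena_side <= 0:
            raise ValueError("arena_side must be positive")
        if self.n_patches < 0:
            raise ValueError("n_patches must be non-negative")
        if self.coins_per_patch < 1:
            raise ValueError("coins_per_patch must be at least 1")
        if self.patch_radius <= 0:
            raise ValueError("patch_radius must be positive")

    @classmethod
    def preset(cls, mode: str) -> "EnvironmentConfig":
        """Build a named environment preset ("concentrated" or "distributed")."""
        try:
            n_patches, coins = ENVIRONMENT_PRESETS[mode]
        except KeyError:
            raise ValueError(
                f"unknown environment preset {mode!r}; "
                f"expected one of {sorted(ENVIRONMENT_PRESETS)}"
            ) from None
        return cls(
            arena_side=ARENA_SIDE_M,
            n_patches=n_patches,
            coins_per_patch=coins,
            patch_radius=PATCH_RADIUS_M,
            mode=mode,
        )


@dataclass(frozen=True)
class SwitchCoefficients:
    """Logit-scale coefficients of the per-second social switch rule.

    ``p_switch = logit^-1(alpha + beta_v*V + beta_d*V*D + beta_n*V*N + beta_t*T)``
    where V is the exploiter-visibility indicator, D the distance to the
    closest visible exploiter, N the number of *other* extractors at that
    exploiter's patch, and T the focal's time since last success.  The
    units of D and T are set by the consumer (the agent policy feeds raw
    meters and minutes; the statistical model feeds z-scores).
    """

    alpha: float = -3.0
    beta_v: float = 1.5
    beta_d: float = -0.05
    beta_n: float = -0.2
    beta_t: float = 0.3

    def logit(self, v: float, d: float, n: float, t: float) -> float:
        eta = self.alpha + self.beta_t * t
        if v:
            eta += self.beta_v + self.beta_d * d + self.beta_n * n
        return eta

    def probability(self, v: float, d: float, n: float, t: float) -> float:
        return 1.0 / (1.0 + math.exp(-self.logit(v, d, n, t)))


@dataclass(frozen=True)
class AgentPolicy:
    """Behavioral policy of one simulated avatar.

    Movement is forward-only at ``speed_max`` with a bounded turn rate,
    mirroring keyboard (forward / turn-left / turn-right) controls.
    While exploring the avatar performs a correlated random walk whose
    per-second heading persistence is a von Mises concentration
    ``turn_noise_kappa``; while relocating socially it steers toward its
    target with small heading jitter ``pursuit_kappa``.
    """

    speed_max: float = SPEED_MAX_MS
    fov_horizontal: float = FOV_HORIZONTAL_DEG
    turn_noise_kappa: float = 4.0
    pursuit_kappa: float = 400.0
    turn_rate_max: float = math.pi / 2  # rad/s
    switch_coefficients: SwitchCoefficients = field(default_factory=SwitchCoefficients)
    revert_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.speed_max <= 0:
            raise ValueError("speed_max must be positive")
        if not (0.0 < self.fov_horizontal <= 360.0):
            raise ValueError("fov_horizontal must be in (0, 360] degrees")
        if not (0.0 <= self.revert_prob <= 1.0):
            raise ValueError("revert_prob must be a probability")
        if self.turn_noise_kappa < 0 or self.pursuit_kappa < 0:
            raise ValueError("turn concentrations must be non-negative")


def default_policies(n_agents: int = 4) -> list[AgentPolicy]:
    """One default policy per avatar (homogeneous group)."""
    return [AgentPolicy() for _ in range(n_agents)]


def with_coefficients(policy: AgentPolicy, **kwargs) -> AgentPolicy:
    """Return a policy whose switch coefficients are updated with ``kwargs``."""
    return replace(policy, switch_coefficients=replace(policy.switch_coefficients, **kwargs))
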