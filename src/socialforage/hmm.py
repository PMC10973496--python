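"""Core of the social hidden Markov decision model.

Two latent behavioral states are modeled per player-second:
*individual exploration* (I, index 0) and *social relocation*
(S, index 1); *exploitation* is observed directly and masked out of the
chain.  Emissions per second are a turning angle (von Mises), the
smallest change in distance to visible exploiting players (normal) and
the smallest absolute relative bearing to them (log-normal); the social
channels are missing whenever no exploiting player is visible and then
simply drop out of the likelihood (marginalization, not imputation).

The I -> S switch probability follows a logistic regression in the
state predictors,

    P(I->S at t) = logit^-1(alpha_ij + bV_ij V_t + bD_ij V_t D_t
                            + bN_ij V_t N_t + bT_ij T_t),

with coefficients specific to the incentive condition i and resource
environment j; D and N are gated by the visibility indicator V.  The
reverse switch S -> I is a condition-specific intercept gamma_ij.
Coefficients may additionally carry a monotonic (ordered-categorical)
minute-of-round effect: a total effect times the cumulative sum of a
length-12 simplex.

Likelihood evaluation uses the forward algorithm; state decoding uses
the Viterbi algorithm with ties broken toward individual exploration.
Every segment of modeled seconds starts in state I with probability 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import i0e

N_MINUTES = 12
STATE_NAMES = ("I", "S")

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateEmissions:
    """Emission distribution parameters for one latent state."""

    vm_mu: float  # von Mises location of turning angle (rad)
    vm_kappa: float  # von Mises concentration (>= 0)
    dd_mu: float  # normal mean of distance change (m)
    dd_sigma: float  # normal sd (> 0)
    lb_mu: float  # log-normal location of bearing (log-rad)
    lb_sigma: float  # log-normal scale (> 0)

    def validate(self) -> None:
        if self.vm_kappa < 0:
            raise ValueError("von Mises concentration must be >= 0")
        if self.dd_sigma <= 0 or self.lb_sigma <= 0:
            raise ValueError("emission scales must be positive")


@dataclass(frozen=True)
class EmissionParams:
    """Emissions of both states, ordered so S is the approach state.

    Identification: relative to exploration, social relocation has the
    smaller mean distance change (stronger approach), the larger
    turning-angle concentration (straighter motion) and the smaller
    median bearing (orientation toward the target).
    """

    explore: StateEmissions
    relocate: StateEmissions

    def validate(self, ordered: bool = True) -> None:
        self.explore.validate()
        self.relocate.validate()
        if ordered:
            if not (self.relocate.dd_mu < self.explore.dd_mu):
                raise ValueError("ordering violated: dd_mu_S must be < dd_mu_I")
            if not (self.relocate.vm_kappa > self.explore.vm_kappa):
                raise ValueError("ordering violated: vm_kappa_S must be > vm_kappa_I")
            if not (self.relocate.lb_mu < self.explore.lb_mu):
                raise ValueError("ordering violated: bearing median_S must be < median_I")


@dataclass(frozen=True)
class MonotonicCoeff:
    """Monotonic (ordered-categorical) minute-of-round effect.

    The coefficient at minute ``m`` (1..12) is ``beta_max`` times the
    cumulative sum of the first ``m`` entries of the length-12 simplex
    ``delta``; at minute 12 the full ``beta_max`` is reached.
    """

    beta_max: float
    delta: np.ndarray

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", delta)
        if delta.shape != (N_MINUTES,):
            raise ValueError(f"delta must have length {N_MINUTES}")
        if np.any(delta < 0) or not math.isclose(delta.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("delta must be a simplex (non-negative, summing to 1)")

    def value(self, minute: int) -> float:
        return monotonic_coeff(self.beta_max, self.delta, minute)

    def profile(self) -> np.ndarray:
        """Coefficient value at every minute 1..12."""
        return self.beta_max * np.cumsum(self.delta)


def monotonic_coeff(beta_max: float, delta, minute) -> float:
    """Evaluate a monotonic minute effect: ``beta_max * sum(delta[:minute])``."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (N_MINUTES,):
        raise ValueError(f"delta must have length {N_MINUTES}")
    minute_arr = np.atleast_1d(np.asarray(minute))
    if np.any((minute_arr < 1) | (minute_arr > N_MINUTES)):
        raise ValueError(f"minute must be in 1..{N_MINUTES}")
    cum = np.concatenate(([0.0], np.cumsum(delta)))
    out = beta_max * cum[minute_arr]
    return out if np.ndim(minute) else float(out[0])


_COEF_NAMES = ("alpha", "beta_v", "beta_d", "beta_n", "beta_t")


@dataclass(frozen=True)
class CellTransition:
    """Switch-rule coefficients for one (incentive, environment) cell.

    Static coefficients plus optional monotonic minute effects keyed by
    coefficient name; the effective coefficient at minute m is the
    static value plus the monotonic term (a purely time-varying
    coefficient is obtained with static value 0).
    """

    alpha: float
    beta_v: float = 0.0
    beta_d: float = 0.0
    beta_n: float = 0.0
    beta_t: float = 0.0
    gamma: float = 0.0  # logit intercept of P(S -> I)
    tv: dict = field(default_factory=dict)

    def coefficient(self, name: str, minute=None):
        base = getattr(self, name)
        if name in self.tv:
            if minute is None:
                raise ValueError(f"minute required for time-varying coefficient {name!r}")
            return base + monotonic_coeff(self.tv[name].beta_max, self.tv[name].delta, minute)
        if minute is not None and np.ndim(minute):
            return np.full(np.shape(minute), float(base))
        return float(base)


@dataclass(frozen=True)
class TransitionParams:
    """Transition coefficients per experimental cell, keyed (incentive, environment)."""

    cells: dict

    def cell(self, incentive="all", environment="all") -> CellTransition:
        try:
            return self.cells[(incentive, environment)]
        except KeyError:
            raise KeyError(f"no transition cell for condition {(incentive, environment)!r}") from None

    @classmethod
    def single(cls, cell: CellTransition) -> "TransitionParams":
        return cls(cells={("all", "all"): cell})


@dataclass(frozen=True)
class ShmdmParams:
    """Full parameter set: emissions plus condition-specific transitions."""

    emissions: EmissionParams
    transitions: TransitionParams


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------


def vonmises_logpdf(theta, mu: float, kappa: float):
    """Log density of the von Mises distribution on (-pi, pi].

    At kappa=0 this is the uniform circular density 1/(2 pi).
    """
    theta = np.asarray(theta, dtype=float)
    # log I0(kappa) = log(i0e(kappa)) + kappa, stable for large kappa
    out = kappa * np.cos(theta - mu) - math.log(2.0 * math.pi) - (np.log(i0e(kappa)) + kappa)
    return out if out.ndim else float(out)


def normal_logpdf(x, mu: float, sigma: float):
    x = np.asarray(x, dtype=float)
    out = -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2.0 * math.pi)
    return out if out.ndim else float(out)


def lognormal_logpdf(x, mu: float, sigma: float):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(x)
        out = -0.5 * ((lx - mu) / sigma) ** 2 - lx - math.log(sigma) - 0.5 * math.log(2.0 * math.pi)
    return out if out.ndim else float(out)


def emission_logdensity(theta: float, ddist: float, bearing: float, state: StateEmissions) -> float:
    """Joint log density of one second's observation channels under one state.

    Channels are independent given the state; missing (NaN) social
    channels contribute nothing.  The turning angle must be present on
    every modeled step; a non-positive bearing violates the log-normal
    support and raises.
    """
    if not np.isfinite(theta):
        raise ValueError("turning angle must be present on every modeled step")
    total = vonmises_logpdf(theta, state.vm_mu, state.vm_kappa)
    if np.isfinite(ddist):
        total += normal_logpdf(ddist, state.dd_mu, state.dd_sigma)
    if np.isfinite(bearing):
        if bearing <= 0:
            raise ValueError("bearing must be strictly positive (log-normal support)")
        total += lognormal_logpdf(bearing, state.lb_mu, state.lb_sigma)
    return float(total)


def emission_loglik_matrix(theta, ddist, bearing, emissions: EmissionParams) -> np.ndarray:
    """(n, 2) matrix of per-step emission log densities for states (I, S)."""
    theta = np.asarray(theta, dtype=float)
    ddist = np.asarray(ddist, dtype=float)
    bearing = np.asarray(bearing, dtype=float)
    if np.any(~np.isfinite(theta)):
        raise ValueError("turning angle missing on a modeled step")
    present_b = np.isfinite(bearing)
    if np.any(present_b & (bearing <= 0)):
        raise ValueError("bearings must be strictly positive where present")
    out = np.empty((theta.size, 2))
    for s, st in enumerate((emissions.explore, emissions.relocate)):
        ll = vonmises_logpdf(theta, st.vm_mu, st.vm_kappa)
        dd = np.where(np.isfinite(ddist), ddist, st.dd_mu)
        ll = ll + np.where(np.isfinite(ddist), normal_logpdf(dd, st.dd_mu, st.dd_sigma), 0.0)
        bb = np.where(present_b, bearing, 1.0)
        ll = ll + np.where(present_b, lognormal_logpdf(bb, st.lb_mu, st.lb_sigma), 0.0)
        out[:, s] = ll
    return out


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------


def switch_logit(cell: CellTransition, v, d, n, t, minute=None):
    """Linear predictor of P(I->S) per step; D and N are gated by V.

    Missing D/N are only tolerated where V = 0 (the gate removes them).
    """
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((v == 1) & (~np.isfinite(d) | ~np.isfinite(n))):
        raise ValueError("D and N must be supplied wherever V = 1")
    d0 = np.where(v == 1, d, 0.0)
    n0 = np.where(v == 1, n, 0.0)
    eta = (
        cell.coefficient("alpha", minute)
        + cell.coefficient("beta_v", minute) * v
        + cell.coefficient("beta_d", minute) * v * d0
        + cell.coefficient("beta_n", minute) * v * n0
        + cell.coefficient("beta_t", minute) * t
    )
    return eta


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out if out.ndim else float(out)


def transition_matrix(
    params: ShmdmParams | TransitionParams,
    incentive="all",
    environment="all",
    v=0,
    d=np.nan,
    n=np.nan,
    t=0.0,
    minute=None,
) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix over (I, S) at one second."""
    trans = params.transitions if isinstance(params, ShmdmParams) else params
    cell = trans.cell(incentive, environment)
    p = inv_logit(switch_logit(cell, v, d, n, t, minute))
    q = inv_logit(cell.gamma)
    return np.array([[1.0 - p, p], [q, 1.0 - q]])


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------


@dataclass
class SegmentData:
    """Observations and predictors for one modeled segment.

    All arrays share one length; the latent chain starts in state I at
    the first step.  ``minute`` is the minute-of-round (1..12) used by
    time-varying coefficients.
    """

    theta: np.ndarray
    ddist: np.ndarray
    bearing: np.ndarray
    v: np.ndarray
    d: np.ndarray
    n: np.ndarray
    t: np.ndarray
    minute: np.ndarray | None = None
    incentive: str = "all"
    environment: str = "all"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.ddist = np.asarray(self.ddist, dtype=float)
        self.bearing = np.asarray(self.bearing, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.minute is not None:
            self.minute = np.asarray(self.minute)
        lengths = {a.size for a in (self.theta, self.ddist, self.bearing, self.v, self.d, self.n, self.t)}
        if len(lengths) != 1:
            raise ValueError("segment arrays must share one length")

    def __len__(self) -> int:
        return self.theta.size


def _segment_step_terms(seg: SegmentData, params: ShmdmParams):
    logf = emission_loglik_matrix(seg.theta, seg.ddist, seg.bearing, params.emissions)
    cell = params.transitions.cell(seg.incentive, seg.environment)
    minute = seg.minute if cell.tv else None
    eta = np.asarray(switch_logit(cell, seg.v, seg.d, seg.n, seg.t, minute), dtype=float)
    if eta.ndim == 0:
        eta = np.full(len(seg), float(eta))
    g = float(cell.gamma)
    # stable log p / log(1-p)
    log_p = -np.logaddexp(0.0, -eta)
    log_1mp = -np.logaddexp(0.0, eta)
    log_q = -np.logaddexp(0.0, -g) * np.ones_like(eta)
    log_1mq = -np.logaddexp(0.0, g) * np.ones_like(eta)
    return logf, log_p, log_1mp, log_q, log_1mq


def _pack(segments: Sequence[SegmentData], params: ShmdmParams):
    parts = [_segment_step_terms(s, params) for s in segments]
    logf = np.concatenate([p[0] for p in parts], axis=0)
    log_p = np.concatenate([p[1] for p in parts])
    log_1mp = np.concatenate([p[2] for p in parts])
    log_q = np.concatenate([p[3] for p in parts])
    log_1mq = np.concatenate([p[4] for p in parts])
    seg_start = np.zeros(logf.shape[0], dtype=np.bool_)
    pos = 0
    for s in segments:
        seg_start[pos] = True
        pos += len(s)
    return logf, log_p, log_1mp, log_q, log_1mq, seg_start


def _forward_flat_py(logf, log_p, log_1mp, log_q, log_1mq, seg_start):
    total = 0.0
    a_i = a_s = -np.inf
    n = logf.shape[0]
    for t in range(n):
        if seg_start[t]:
            if t > 0:
                total += np.logaddexp(a_i, a_s)
            a_i = logf[t, 0]
            a_s = -np.inf
        else:
            new_i = np.logaddexp(a_i + log_1mp[t], a_s + log_q[t]) + logf[t, 0]
            new_s = np.logaddexp(a_i + log_p[t], a_s + log_1mq[t]) + logf[t, 1]
            a_i, a_s = new_i, new_s
    if n:
        total += np.logaddexp(a_i, a_s)
    return total


def _viterbi_flat_py(logf, log_p, log_1mp, log_q, log_1mq, seg_start):
    n = logf.shape[0]
    path = np.zeros(n, dtype=np.int8)
    back = np.zeros((n, 2), dtype=np.int8)
    score_i = np.full(n, -np.inf)
    score_s = np.full(n, -np.inf)
    starts = [t for t in range(n) if seg_start[t]] + [n]
    for k in range(len(starts) - 1):
        s0, s1 = starts[k], starts[k + 1]
        score_i[s0] = logf[s0, 0]
        score_s[s0] = -np.inf
        for t in range(s0 + 1, s1):
            from_i = score_i[t - 1] + log_1mp[t]
            from_s = score_s[t - 1] + log_q[t]
            if from_i >= from_s:  # tie-break: prefer predecessor I
                score_i[t], back[t, 0] = from_i + logf[t, 0], 0
            else:
                score_i[t], back[t, 0] = from_s + logf[t, 0], 1
            from_i = score_i[t - 1] + log_p[t]
            from_s = score_s[t - 1] + log_1mq[t]
            if from_i >= from_s:
                score_s[t], back[t, 1] = from_i + logf[t, 1], 0
            else:
                score_s[t], back[t, 1] = from_s + logf[t, 1], 1
        last = s1 - 1
        state = 0 if score_i[last] >= score_s[last] else 1  # tie-break: prefer I
        path[last] = state
        for t in range(last, s0, -1):
            state = back[t, state]
            path[t - 1] = state
    return path


if _HAVE_NUMBA:
    _forward_flat = numba.njit(cache=True)(_forward_flat_py)
    _viterbi_flat = numba.njit(cache=True)(_viterbi_flat_py)
else:  # pragma: no cover
    _forward_flat = _forward_flat_py
    _viterbi_flat = _viterbi_flat_py


def forward_loglik(segments: Sequence[SegmentData] | SegmentData, params: ShmdmParams) -> float:
    """Log marginal likelihood of the segments via the forward algorithm.

    Each segment starts in state I with probability 1; segments are
    independent so their log likelihoods add (order does not matter).
    """
    if isinstance(segments, SegmentData):
        segments = [segments]
    segments = [s for s in segments if len(s) > 0]
    if not segments:
        warnings.warn("forward_loglik called with no non-empty segments", stacklevel=2)
        return 0.0
    return float(_forward_flat(*_pack(segments, params)))


def viterbi(segments: Sequence[SegmentData] | SegmentData, params: ShmdmParams) -> list[np.ndarray]:
    """Most likely state path per segment (0 = I, 1 = S), ties toward I."""
    single = isinstance(segments, SegmentData)
    if single:
        segments = [segments]
    segments = list(segments)
    nonempty = [s for s in segments if len(s) > 0]
    if not nonempty:
        warnings.warn("viterbi called with no non-empty segments", stacklevel=2)
        return [np.zeros(0, dtype=np.int8) for _ in segments]
    flat = _viterbi_flat(*_pack(nonempty, params))
    out, pos = [], 0
    it = iter(nonempty)
    for s in segments:
        if len(s) == 0:
            out.append(np.zeros(0, dtype=np.int8))
        else:
            next(it)
            out.append(flat[pos : pos + len(s)].copy())
            pos += len(s)
    return out[0] if single else out
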