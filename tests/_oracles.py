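"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's recursive implementations:
likelihoods are computed by explicit enumeration over all latent-state
paths, densities by direct formula evaluation, so any bug in the
forward/Viterbi code cannot cancel out.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from socialforage.hmm import SegmentData, ShmdmParams


def _emission_logpdf(theta, ddist, bearing, st):
    """Direct formula evaluation (von Mises / normal / log-normal)."""
    from scipy.special import i0

    total = st.vm_kappa * math.cos(theta - st.vm_mu) - math.log(2 * math.pi * i0(st.vm_kappa))
    if np.isfinite(ddist):
        total += -0.5 * ((ddist - st.dd_mu) / st.dd_sigma) ** 2 - math.log(
            st.dd_sigma * math.sqrt(2 * math.pi)
        )
    if np.isfinite(bearing):
        total += -0.5 * ((math.log(bearing) - st.lb_mu) / st.lb_sigma) ** 2 - math.log(
            bearing * st.lb_sigma * math.sqrt(2 * math.pi)
        )
    return total


def _path_logprob(seg: SegmentData, params: ShmdmParams, path) -> float:
    """Joint log probability of one latent path and the observations."""
    cell = params.transitions.cell(seg.incentive, seg.environment)
    emis = (params.emissions.explore, params.emissions.relocate)
    minute = seg.minute if cell.tv else None

    def switch_p(t):
        m = None if minute is None else int(minute[t])
        eta = (
            cell.coefficient("alpha", m)
            + cell.coefficient("beta_v", m) * seg.v[t]
            + cell.coefficient("beta_d", m) * seg.v[t] * (seg.d[t] if seg.v[t] == 1 else 0.0)
            + cell.coefficient("beta_n", m) * seg.v[t] * (seg.n[t] if seg.v[t] == 1 else 0.0)
            + cell.coefficient("beta_t", m) * seg.t[t]
        )
        return 1.0 / (1.0 + math.exp(-eta))

    q = 1.0 / (1.0 + math.exp(-cell.gamma))
    if path[0] != 0:
        return -math.inf
    lp = _emission_logpdf(seg.theta[0], seg.ddist[0], seg.bearing[0], emis[0])
    for t in range(1, len(seg)):
        p = switch_p(t)
        if path[t - 1] == 0:
            lp += math.log(p) if path[t] == 1 else math.log1p(-p)
        else:
            lp += math.log(q) if path[t] == 0 else math.log1p(-q)
        lp += _emission_logpdf(seg.theta[t], seg.ddist[t], seg.bearing[t], emis[path[t]])
    return lp


def brute_force_loglik(seg: SegmentData, params: ShmdmParams) -> float:
    """Log marginal likelihood by summing over all 2^(T-1) paths."""
    T = len(seg)
    total = -math.inf
    for tail in itertools.product([0, 1], repeat=T - 1):
        total = np.logaddexp(total, _path_logprob(seg, params, (0,) + tail))
    return float(total)


def brute_force_viterbi(seg: SegmentData, params: ShmdmParams) -> np.ndarray:
    """Most likely path by enumeration; ties resolved toward state I.

    Candidate paths are enumerated in lexicographic order with I < S,
    so the first path attaining the maximum is the I-preferring one —
    matching the tie-break contract of the dynamic program.
    """
    T = len(seg)
    best, best_lp = None, -math.inf
    for tail in itertools.product([0, 1], repeat=T - 1):
        path = (0,) + tail
        lp = _path_logprob(seg, params, path)
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return np.array(best, dtype=np.int8)


def random_segment(rng: np.random.Generator, length: int, incentive="all", environment="all", minutes=False) -> SegmentData:
    """A random observation segment with realistic missingness structure."""
    v = rng.integers(0, 2, length).astype(float)
    present = v == 1
    return SegmentData(
        theta=rng.vonmises(0.0, 1.0, length),
        ddist=np.where(present, rng.normal(0, 1, length), np.nan),
        bearing=np.where(present, rng.lognormal(0, 0.7, length), np.nan),
        v=v,
        d=np.where(present, rng.normal(0, 1, length), np.nan),
        n=np.where(present, rng.integers(0, 3, length).astype(float), np.nan),
        t=rng.normal(0, 1, length),
        minute=rng.integers(1, 13, length) if minutes else None,
        incentive=incentive,
        environment=environment,
    )
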