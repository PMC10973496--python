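"""Hierarchical Bayesian estimation of the social HMM.

All coefficients live on an unconstrained scale with Gaussian priors
(order-enforcing transforms identify the states: relative to
exploration, the relocation state has a strictly smaller mean distance
change, strictly larger turning concentration and strictly smaller
bearing median, so labels cannot switch in any retained draw).  The
default backend maximizes the log posterior (penalized likelihood) and
draws from the Laplace approximation at the mode — fast and exact for
the Gaussian-prior, data-rich settings used here; an ensemble-MCMC
(emcee) backend is available as a sampling cross-check.  Convergence
diagnostics (split-chain R-hat <= 1.01, effective sample sizes) are
computed on the retained draws and non-convergence flags the result.

Model kinds
-----------
``fixed``
    Condition-specific emission and transition coefficients only.
``re``
    Adds individual- and group-level offsets on the five switch
    coefficients (independent Gaussian priors of scale ``re_sd``).
``tv``
    Adds a monotonic (ordered-categorical) minute-of-round effect to
    each switch coefficient: a total effect times the cumulative sum of
    a length-12 simplex.
``re-tv``
    Both; random offsets attach to the average (static) effects only.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import i0e

from . import hmm
from ._optim import emcee_draws, map_laplace, split_rhat_ess
from .hmm import (
    N_MINUTES,
    CellTransition,
    EmissionParams,
    MonotonicCoeff,
    SegmentData,
    ShmdmParams,
    StateEmissions,
    TransitionParams,
    _forward_flat,
)

_LOG2PI = math.log(2.0 * math.pi)
_COEFS = ("alpha", "beta_v", "beta_d", "beta_n", "beta_t")

#: Unconstrained emission parameters: (name, prior mean, prior sd).
#: Informative enough to anchor the state labels (gap transforms force
#: the ordering; the priors keep the gaps away from zero).
EMISSION_PRIOR = (
    ("vm_mu_I", 0.0, 0.5),
    ("vm_mu_S", 0.0, 0.5),
    ("log_vm_kappa_I", 0.0, 1.0),
    ("log_vm_kappa_gap", 1.0, 1.0),
    ("dd_mu_I", 0.0, 1.0),
    ("log_dd_gap", 0.5, 1.0),
    ("log_dd_sigma_I", -0.3, 1.0),
    ("log_dd_sigma_S", -0.3, 1.0),
    ("lb_mu_I", 0.0, 1.0),
    ("log_lb_gap", 0.5, 1.0),
    ("log_lb_sigma_I", -0.3, 1.0),
    ("log_lb_sigma_S", -0.3, 1.0),
)

#: Weakly informative priors for transition coefficients (logit scale).
TRANSITION_PRIOR = {
    "alpha": (-2.0, 1.5),
    "beta_v": (0.0, 1.5),
    "beta_d": (0.0, 1.5),
    "beta_n": (0.0, 1.5),
    "beta_t": (0.0, 1.5),
    "gamma": (-1.0, 1.5),
    "tv_max": (0.0, 1.0),
    "tv_logit": (0.0, 1.0),
}


def _softmax_simplex(logits11: np.ndarray) -> np.ndarray:
    """Length-12 simplex from 11 free logits (last entry pinned at 0)."""
    z = np.concatenate([logits11, [0.0]]) if logits11.ndim == 1 else np.concatenate(
        [logits11, np.zeros(logits11.shape[:-1] + (1,))], axis=-1
    )
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Packed data
# ---------------------------------------------------------------------------


@dataclass
class ModelData:
    """Flat, segment-packed arrays over the modeled (valid) seconds."""

    theta: np.ndarray
    dd: np.ndarray
    dd_mask: np.ndarray
    lb_log: np.ndarray
    lb_mask: np.ndarray
    V: np.ndarray
    VD: np.ndarray
    VN: np.ndarray
    T: np.ndarray
    cond_idx: np.ndarray
    minute_idx: np.ndarray
    player_idx: np.ndarray
    group_idx: np.ndarray
    seg_start: np.ndarray
    conditions: list
    players: list
    groups: list
    row_index: np.ndarray  # original row labels of the source frame
    fingerprint: str = ""

    @property
    def n(self) -> int:
        return self.theta.size

    @classmethod
    def empty(cls, conditions: Sequence[tuple] = (("all", "all"),)) -> "ModelData":
        z = np.zeros(0)
        zi = np.zeros(0, dtype=int)
        zb = np.zeros(0, dtype=bool)
        return cls(z, z, zb, z, zb, z, z, z, z, zi, zi, zi, zi, zb, list(conditions), [], [], zi, "empty")

    @classmethod
    def from_features(cls, features: pd.DataFrame) -> "ModelData":
        df = features.loc[features["valid"].astype(bool)].copy()
        if df.empty:
            raise ValueError("no valid rows in the feature table")
        if "incentive" not in df.columns:
            df["incentive"] = "all"
        if "environment" not in df.columns:
            df["environment"] = "all"
        key = ["group_id", "round_id", "player_id"]
        df = df.sort_values(key + ["t_sec"], kind="mergesort")

        theta = df["theta"].to_numpy(dtype=float)
        if np.any(~np.isfinite(theta)):
            raise ValueError("turning angle missing on a valid step")
        dd = df["ddist"].to_numpy(dtype=float)
        lb = df["bearing"].to_numpy(dtype=float)
        dd_mask = np.isfinite(dd)
        lb_mask = np.isfinite(lb)
        if np.any(lb_mask & (lb <= 0)):
            raise ValueError("bearings must be strictly positive where present")
        v = df["V"].to_numpy(dtype=float)
        d = df["D"].to_numpy(dtype=float)
        n_col = df["N"].to_numpy(dtype=float)
        t_col = df["T"].to_numpy(dtype=float)
        if np.any((v == 1) & (~np.isfinite(d) | ~np.isfinite(n_col))):
            raise ValueError("D and N must be defined wherever V = 1")
        if np.any(~np.isfinite(t_col)):
            raise ValueError("T must be defined on every valid step")

        conditions = sorted(set(zip(df["incentive"], df["environment"])))
        cond_map = {c: i for i, c in enumerate(conditions)}
        cond_idx = np.array([cond_map[c] for c in zip(df["incentive"], df["environment"])])
        players = sorted(df["player_id"].unique())
        groups = sorted(df["group_id"].unique())
        pmap = {p: i for i, p in enumerate(players)}
        gmap = {g: i for i, g in enumerate(groups)}
        player_idx = df["player_id"].map(pmap).to_numpy(dtype=int)
        group_idx = df["group_id"].map(gmap).to_numpy(dtype=int)
        minute = df["minute"].to_numpy(dtype=int) if "minute" in df.columns else np.ones(len(df), dtype=int)
        minute_idx = np.clip(minute - 1, 0, N_MINUTES - 1)

        same_unit = np.zeros(len(df), dtype=bool)
        unit = df[key].to_numpy()
        same_unit[1:] = (unit[1:] == unit[:-1]).all(axis=1)
        tsec = df["t_sec"].to_numpy(dtype=float)
        contiguous = np.zeros(len(df), dtype=bool)
        contiguous[1:] = np.isclose(np.diff(tsec), 1.0)
        seg_start = ~(same_unit & contiguous)

        fp = hashlib.sha1(
            np.ascontiguousarray(np.column_stack([theta, v, t_col])).tobytes()
        ).hexdigest()[:12]
        return cls(
            theta=theta,
            dd=np.where(dd_mask, dd, 0.0),
            dd_mask=dd_mask,
            lb_log=np.where(lb_mask, np.log(np.where(lb_mask, lb, 1.0)), 0.0),
            lb_mask=lb_mask,
            V=v,
            VD=np.where(v == 1, d, 0.0) * v,
            VN=np.where(v == 1, n_col, 0.0) * v,
            T=t_col,
            cond_idx=cond_idx,
            minute_idx=minute_idx,
            player_idx=player_idx,
            group_idx=group_idx,
            seg_start=seg_start,
            conditions=conditions,
            players=players,
            groups=groups,
            row_index=df.index.to_numpy(),
            fingerprint=f"n={len(df)} sha1={fp}",
        )


def segments_from_features(features: pd.DataFrame) -> tuple[list[SegmentData], list[np.ndarray]]:
    """Build per-segment observation bundles (and their source row labels)."""
    data = ModelData.from_features(features)
    bounds = np.flatnonzero(data.seg_start).tolist() + [data.n]
    segments, rows = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        inc, env = data.conditions[data.cond_idx[a]]
        segments.append(
            SegmentData(
                theta=data.theta[a:b],
                ddist=np.where(data.dd_mask[a:b], data.dd[a:b], np.nan),
                bearing=np.where(data.lb_mask[a:b], np.exp(data.lb_log[a:b]), np.nan),
                v=data.V[a:b],
                d=np.where(data.V[a:b] == 1, data.VD[a:b], np.nan),
                n=np.where(data.V[a:b] == 1, data.VN[a:b], np.nan),
                t=data.T[a:b],
                minute=data.minute_idx[a:b] + 1,
                incentive=inc,
                environment=env,
            )
        )
        rows.append(data.row_index[a:b])
    return segments, rows


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class ShmdmModel:
    """Parameter layout, likelihood and prior for one model configuration."""

    def __init__(
        self,
        data: ModelData,
        kind: str = "fixed",
        re_sd: float = 0.5,
        priors: dict | None = None,
    ):
        if kind not in ("fixed", "re", "tv", "re-tv"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.data = data
        self.kind = kind
        self.re = kind in ("re", "re-tv")
        self.tv = kind in ("tv", "re-tv")
        self.re_sd = float(re_sd)
        tp = dict(TRANSITION_PRIOR)
        if priors:
            tp.update(priors)
        self.n_cond = len(data.conditions)
        self.n_players = max(len(data.players), 1)
        self.n_groups = max(len(data.groups), 1)

        names: list[str] = []
        mean: list[float] = []
        sd: list[float] = []
        for nm, m, s in EMISSION_PRIOR:
            names.append(nm)
            mean.append(m)
            sd.append(s)
        self.i_trans = len(names)
        for inc, env in data.conditions:
            for coef in _COEFS + ("gamma",):
                names.append(f"{coef}[{inc},{env}]")
                m, s = tp[coef]
                mean.append(m)
                sd.append(s)
        self.i_tv = len(names)
        if self.tv:
            for inc, env in data.conditions:
                for coef in _COEFS:
                    names.append(f"tv_max_{coef}[{inc},{env}]")
                    m, s = tp["tv_max"]
                    mean.append(m)
                    sd.append(s)
                    for k in range(N_MINUTES - 1):
                        names.append(f"tv_logit_{coef}[{inc},{env},{k}]")
                        m, s = tp["tv_logit"]
                        mean.append(m)
                        sd.append(s)
        self.i_re = len(names)
        if self.re:
            for p in range(self.n_players):
                for coef in _COEFS:
                    names.append(f"re_ind_{coef}[{p}]")
                    mean.append(0.0)
                    sd.append(self.re_sd)
            for g in range(self.n_groups):
                for coef in _COEFS:
                    names.append(f"re_grp_{coef}[{g}]")
                    mean.append(0.0)
                    sd.append(self.re_sd)
        self.names = names
        self.prior_mean = np.array(mean)
        self.prior_sd = np.array(sd)
        self.dim = len(names)

    # -- unpacking ---------------------------------------------------------

    def _emissions_nat(self, x: np.ndarray) -> dict:
        # clipped exponentials keep line-search excursions finite
        def _exp(v: float) -> float:
            return math.exp(min(max(v, -30.0), 30.0))

        e = x[:12]
        return {
            "vm_mu": (e[0], e[1]),
            "vm_kappa": (_exp(e[2]), _exp(e[2]) + _exp(e[3])),
            "dd_mu": (e[4], e[4] - _exp(e[5])),
            "dd_sigma": (_exp(e[6]), _exp(e[7])),
            "lb_mu": (e[8], e[8] - _exp(e[9])),
            "lb_sigma": (_exp(e[10]), _exp(e[11])),
        }

    def _trans_block(self, x: np.ndarray) -> np.ndarray:
        return x[self.i_trans : self.i_tv].reshape(self.n_cond, 6)

    def _tv_blocks(self, x: np.ndarray):
        per = 5 * N_MINUTES  # 5 coefficients x (1 max + 11 logits)
        raw = x[self.i_tv : self.i_re].reshape(self.n_cond, 5, N_MINUTES)
        tv_max = raw[:, :, 0]
        logits = raw[:, :, 1:]
        delta = _softmax_simplex(logits)
        cum = np.cumsum(delta, axis=-1)  # (n_cond, 5, 12)
        return tv_max, delta, cum

    def _re_blocks(self, x: np.ndarray):
        n_ind = self.n_players * 5
        blk = x[self.i_re :]
        ind = blk[:n_ind].reshape(self.n_players, 5)
        grp = blk[n_ind:].reshape(self.n_groups, 5)
        return ind, grp

    # -- likelihood --------------------------------------------------------

    def _emission_logf(self, x: np.ndarray) -> np.ndarray:
        d = self.data
        nat = self._emissions_nat(x)
        logf = np.empty((d.n, 2))
        for s in range(2):
            k = nat["vm_kappa"][s]
            ll = k * np.cos(d.theta - nat["vm_mu"][s]) - _LOG2PI - (math.log(i0e(k)) + k)
            mu, sig = nat["dd_mu"][s], nat["dd_sigma"][s]
            ll = ll + d.dd_mask * (
                -0.5 * ((d.dd - mu) / sig) ** 2 - math.log(sig) - 0.5 * _LOG2PI
            )
            mu, sig = nat["lb_mu"][s], nat["lb_sigma"][s]
            ll = ll + d.lb_mask * (
                -0.5 * ((d.lb_log - mu) / sig) ** 2 - d.lb_log - math.log(sig) - 0.5 * _LOG2PI
            )
            logf[:, s] = ll
        return logf

    def _step_coefs(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-step values of the five switch coefficients and gamma."""
        d = self.data
        tb = self._trans_block(x)
        coefs = tb[d.cond_idx, :5]  # (n, 5)
        if self.tv:
            tv_max, _, cum = self._tv_blocks(x)
            coefs = coefs + tv_max[d.cond_idx] * cum[d.cond_idx, :, :][
                np.arange(d.n)[:, None], np.arange(5)[None, :], d.minute_idx[:, None]
            ]
        if self.re:
            ind, grp = self._re_blocks(x)
            coefs = coefs + ind[d.player_idx] + grp[d.group_idx]
        gamma = tb[d.cond_idx, 5]
        return coefs, gamma

    def loglik(self, x: np.ndarray) -> float:
        d = self.data
        if d.n == 0:
            return 0.0
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            logf = self._emission_logf(x)
            if not np.isfinite(logf).all():
                return -1e15  # line-search excursion; reject smoothly
            coefs, gamma = self._step_coefs(x)
            eta = (
                coefs[:, 0]
                + coefs[:, 1] * d.V
                + coefs[:, 2] * d.VD
                + coefs[:, 3] * d.VN
                + coefs[:, 4] * d.T
            )
            log_p = -np.logaddexp(0.0, -eta)
            log_1mp = -np.logaddexp(0.0, eta)
            log_q = -np.logaddexp(0.0, -gamma)
            log_1mq = -np.logaddexp(0.0, gamma)
            out = float(_forward_flat(logf, log_p, log_1mp, log_q, log_1mq, d.seg_start))
        return out if np.isfinite(out) else -1e15

    def logprior(self, x: np.ndarray) -> float:
        z = (x - self.prior_mean) / self.prior_sd
        return float(-0.5 * np.dot(z, z))

    def neglogpost(self, x: np.ndarray) -> float:
        return -(self.loglik(x) + self.logprior(x))

    # -- natural-scale views ------------------------------------------------

    def params_from_x(self, x: np.ndarray) -> ShmdmParams:
        nat = self._emissions_nat(x)
        emissions = EmissionParams(
            explore=StateEmissions(
                nat["vm_mu"][0], nat["vm_kappa"][0], nat["dd_mu"][0], nat["dd_sigma"][0],
                nat["lb_mu"][0], nat["lb_sigma"][0],
            ),
            relocate=StateEmissions(
                nat["vm_mu"][1], nat["vm_kappa"][1], nat["dd_mu"][1], nat["dd_sigma"][1],
                nat["lb_mu"][1], nat["lb_sigma"][1],
            ),
        )
        tb = self._trans_block(x)
        cells = {}
        if self.tv:
            tv_max, delta, _ = self._tv_blocks(x)
        for ci, cond in enumerate(self.data.conditions):
            tv = {}
            if self.tv:
                for k, coef in enumerate(_COEFS):
                    tv[coef] = MonotonicCoeff(float(tv_max[ci, k]), delta[ci, k])
            cells[cond] = CellTransition(
                alpha=float(tb[ci, 0]),
                beta_v=float(tb[ci, 1]),
                beta_d=float(tb[ci, 2]),
                beta_n=float(tb[ci, 3]),
                beta_t=float(tb[ci, 4]),
                gamma=float(tb[ci, 5]),
                tv=tv,
            )
        return ShmdmParams(emissions=emissions, transitions=TransitionParams(cells=cells))

    def natural_frame(self, draws_unc: np.ndarray) -> pd.DataFrame:
        """Posterior draws mapped to interpretable natural-scale columns."""
        x = np.atleast_2d(draws_unc)
        cols: dict[str, np.ndarray] = {}
        cols["vm_mu[I]"], cols["vm_mu[S]"] = x[:, 0], x[:, 1]
        cols["vm_kappa[I]"] = np.exp(x[:, 2])
        cols["vm_kappa[S]"] = np.exp(x[:, 2]) + np.exp(x[:, 3])
        cols["dd_mu[I]"] = x[:, 4]
        cols["dd_mu[S]"] = x[:, 4] - np.exp(x[:, 5])
        cols["dd_sigma[I]"], cols["dd_sigma[S]"] = np.exp(x[:, 6]), np.exp(x[:, 7])
        cols["lb_mu[I]"] = x[:, 8]
        cols["lb_mu[S]"] = x[:, 8] - np.exp(x[:, 9])
        cols["lb_sigma[I]"], cols["lb_sigma[S]"] = np.exp(x[:, 10]), np.exp(x[:, 11])
        tb = x[:, self.i_trans : self.i_tv].reshape(x.shape[0], self.n_cond, 6)
        for ci, (inc, env) in enumerate(self.data.conditions):
            for k, coef in enumerate(_COEFS + ("gamma",)):
                cols[f"{coef}[{inc},{env}]"] = tb[:, ci, k]
        if self.tv:
            raw = x[:, self.i_tv : self.i_re].reshape(x.shape[0], self.n_cond, 5, N_MINUTES)
            for ci, (inc, env) in enumerate(self.data.conditions):
                for k, coef in enumerate(_COEFS):
                    cols[f"tv_max_{coef}[{inc},{env}]"] = raw[:, ci, k, 0]
                    delta = _softmax_simplex(raw[:, ci, k, 1:])
                    for m in range(N_MINUTES):
                        cols[f"delta_{coef}[{inc},{env},{m + 1}]"] = delta[:, m]
        if self.re:
            blk = x[:, self.i_re :]
            n_ind = self.n_players * 5
            ind = blk[:, :n_ind].reshape(x.shape[0], self.n_players, 5)
            grp = blk[:, n_ind:].reshape(x.shape[0], self.n_groups, 5)
            for pi, p in enumerate(self.data.players):
                for k, coef in enumerate(_COEFS):
                    cols[f"re_ind_{coef}[{p}]"] = ind[:, pi, k]
            for gi, g in enumerate(self.data.groups):
                for k, coef in enumerate(_COEFS):
                    cols[f"re_grp_{coef}[{g}]"] = grp[:, gi, k]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Fit driver and results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Posterior draws plus diagnostics for one fitted model."""

    draws: pd.DataFrame
    unconstrained: np.ndarray
    mode_x: np.ndarray
    cov: np.ndarray
    model: ShmdmModel
    loglik_hat: float
    diagnostics: dict
    converged: bool
    backend: str
    seed: int | None
    fingerprint: str

    def get(self, name: str) -> np.ndarray:
        """Draw vector of one natural-scale parameter."""
        return self.draws[name].to_numpy()

    def params_at_mode(self) -> ShmdmParams:
        return self.model.params_from_x(self.mode_x)

    def summary(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        from .posterior import hpdi

        names = list(names) if names is not None else list(self.draws.columns)
        rows = []
        for nm in names:
            d = self.draws[nm].to_numpy()
            lo, hi = hpdi(d, 0.9)
            rows.append((nm, d.mean(), d.std(), lo, hi))
        return pd.DataFrame(rows, columns=["param", "mean", "sd", "hpdi_5", "hpdi_95"]).set_index("param")


def fit(
    features: pd.DataFrame | None,
    kind: str = "fixed",
    priors: dict | None = None,
    re_sd: float = 0.5,
    n_draws: int = 1000,
    seed: int | None = 0,
    backend: str = "laplace",
    hessian: str = "exact",
    conditions: Sequence[tuple] | None = None,
    maxiter: int = 3000,
    emcee_steps: int = 600,
) -> FitResult:
    """Fit the social HMM to a feature table.

    ``features`` needs the columns produced by the feature pipeline
    (theta/ddist/bearing, V/D/N/T, valid, minute, player_id, group_id,
    plus incentive/environment labels when fitting condition-specific
    coefficients).  Passing ``features=None`` fits the prior alone
    (prior-predictive mode); then ``conditions`` lists the cells to
    parameterize.  Non-convergence (optimizer failure or split R-hat
    above 1.01) flags the result and warns, it never silently passes.
    """
    if features is None:
        data = ModelData.empty(conditions or [("all", "all")])
    else:
        data = ModelData.from_features(features)
    model = ShmdmModel(data, kind=kind, re_sd=re_sd, priors=priors)
    rng = np.random.default_rng(seed)
    res = map_laplace(
        model.neglogpost,
        x0=model.prior_mean.copy(),
        n_draws=n_draws,
        rng=rng,
        hessian=hessian,
        maxiter=maxiter,
        min_curvature=float(1.0 / model.prior_sd.max() ** 2),
    )
    if backend == "laplace":
        draws_unc = res.draws
    elif backend == "emcee":
        draws_unc = emcee_draws(
            model.neglogpost, res.x, res.cov, n_draws=n_draws, rng=rng, steps=emcee_steps,
            burn=emcee_steps // 2,
        )
    else:
        raise ValueError("backend must be 'laplace' or 'emcee'")
    rhat, ess = split_rhat_ess(draws_unc)
    converged = bool(res.success and rhat <= 1.01)
    if not converged:
        warnings.warn(
            f"fit flagged as non-converged (success={res.success}, max R-hat={rhat:.3f})",
            stacklevel=2,
        )
    return FitResult(
        draws=model.natural_frame(draws_unc),
        unconstrained=draws_unc,
        mode_x=res.x,
        cov=res.cov,
        model=model,
        loglik_hat=model.loglik(res.x),
        diagnostics={"rhat_max": rhat, "ess_min": ess, "optimizer": res.message},
        converged=converged,
        backend=backend,
        seed=seed,
        fingerprint=data.fingerprint,
    )


def switch_probability_surface(
    fit_result: FitResult,
    incentive="all",
    environment="all",
    grid: pd.DataFrame | None = None,
    max_grid: int = 2000,
    population_level: bool = True,
) -> np.ndarray:
    """Posterior draws of the average P(I->S) over a covariate grid.

    The default grid is the fitted data's empirical distribution of
    situations with a visible exploiter (V = 1) in that condition — the
    baseline switching probability.  Random-effect offsets are excluded
    at the population level.
    """
    model = fit_result.model
    d = model.data
    cond = (incentive, environment)
    if cond not in d.conditions:
        raise KeyError(f"condition {cond!r} not in fitted data")
    ci = d.conditions.index(cond)
    if grid is None:
        sel = (d.cond_idx == ci) & (d.V == 1)
        if not sel.any():
            raise ValueError("empty default grid: no V=1 steps for this condition")
        g_v = d.V[sel]
        g_vd = d.VD[sel]
        g_vn = d.VN[sel]
        g_t = d.T[sel]
        g_min = d.minute_idx[sel]
    else:
        if len(grid) == 0:
            raise ValueError("empty covariate grid")
        g_v = grid["V"].to_numpy(dtype=float)
        g_vd = g_v * grid["D"].fillna(0.0).to_numpy(dtype=float)
        g_vn = g_v * grid["N"].fillna(0.0).to_numpy(dtype=float)
        g_t = grid["T"].to_numpy(dtype=float)
        g_min = (
            np.clip(grid["minute"].to_numpy(dtype=int) - 1, 0, N_MINUTES - 1)
            if "minute" in grid
            else np.zeros(len(grid), dtype=int)
        )
    if g_v.size > max_grid:
        step = int(np.ceil(g_v.size / max_grid))
        g_v, g_vd, g_vn, g_t, g_min = (a[::step] for a in (g_v, g_vd, g_vn, g_t, g_min))

    x = fit_result.unconstrained
    tb = x[:, model.i_trans : model.i_tv].reshape(x.shape[0], model.n_cond, 6)
    coefs = tb[:, ci, :5]  # (draws, 5)
    if model.tv:
        raw = x[:, model.i_tv : model.i_re].reshape(x.shape[0], model.n_cond, 5, N_MINUTES)
        tv_max = raw[:, ci, :, 0]  # (draws, 5)
        cum = np.cumsum(_softmax_simplex(raw[:, ci, :, 1:]), axis=-1)  # (draws, 5, 12)
        coef_t = coefs[:, :, None] + tv_max[:, :, None] * cum  # (draws, 5, 12)
        eta = (
            coef_t[:, 0, g_min]
            + coef_t[:, 1, g_min] * g_v
            + coef_t[:, 2, g_min] * g_vd
            + coef_t[:, 3, g_min] * g_vn
            + coef_t[:, 4, g_min] * g_t
        )
    else:
        eta = (
            coefs[:, [0]]
            + coefs[:, [1]] * g_v
            + coefs[:, [2]] * g_vd
            + coefs[:, [3]] * g_vn
            + coefs[:, [4]] * g_t
        )
    if not population_level and model.re:
        raise NotImplementedError("per-individual surfaces are not implemented")
    p = 1.0 / (1.0 + np.exp(-eta))
    return p.mean(axis=1)


def decode(fit_result: FitResult, features: pd.DataFrame) -> pd.DataFrame:
    """Viterbi-decode the most likely state per second, for display.

    Valid seconds get the decoded latent state (I or S); omitted
    seconds are re-inserted as E while the focal was exploiting and as
    I otherwise (the player's state is known in both cases).
    """
    params = fit_result.params_at_mode()
    segments, rows = segments_from_features(features)
    paths = hmm.viterbi(segments, params)
    out = features.copy()
    state = np.where(out["exploiting"].to_numpy().astype(bool), "E", "I") if "exploiting" in out else np.full(len(out), "I")
    decoded = pd.Series(state, index=out.index, dtype=object)
    for path, idx in zip(paths, rows):
        decoded.loc[idx] = np.where(np.asarray(path) == 1, "S", "I")
    out["state_decoded"] = decoded
    return out
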