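"""Time-lagged Gaussian-process regression for collective dynamics.

Relates a group's past visual-spatial organization to its current
collective foraging success: the number of players exploiting at time
t (binomial out of group size) is regressed on a z-scored group
predictor (mean pairwise distance, or the number of directed
visibility links among members) evaluated at a grid of past lags
t - tau.  The regression weight at lag tau is an average effect plus a
lag-specific offset, and the offsets follow a zero-mean multivariate
Gaussian whose covariance between lags tau_x and tau_y is a squared-
exponential (RBF) kernel: the maximum covariance eta decays at rate
rho with the squared lag distance relative to the largest lag.  The
kernel pools information across neighboring lags, so similar lags get
similar weights while the lag grid remains fully flexible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from ._optim import map_laplace
from .features import standardize, wrap_angle
from .posterior import hpdi

_ROUND_KEY = ["group_id", "round_id"]


def default_lag_grid() -> np.ndarray:
    """Every second up to half a minute, then 5 s steps up to three minutes."""
    return np.unique(np.concatenate([np.arange(1, 31), np.arange(35, 181, 5)]))


def rbf_cov(tau_x, tau_y, eta: float, rho: float, tau_max: float):
    """Squared-exponential covariance between lags.

    ``eta * exp(-rho * (tau_y - tau_x)^2 / tau_max^2)``: stationary and
    symmetric, depending only on the lag distance.
    """
    if eta < 0 or rho < 0:
        raise ValueError("eta and rho must be non-negative")
    if tau_max <= 0:
        raise ValueError("tau_max must be positive")
    tau_x = np.asarray(tau_x, dtype=float)
    tau_y = np.asarray(tau_y, dtype=float)
    out = eta * np.exp(-rho * (tau_y - tau_x) ** 2 / tau_max**2)
    return out if out.ndim else float(out)


def rbf_gram(lags, eta: float, rho: float, tau_max: float | None = None) -> np.ndarray:
    """Kernel matrix over a lag grid."""
    lags = np.asarray(lags, dtype=float)
    if tau_max is None:
        tau_max = float(lags.max())
    return rbf_cov(lags[:, None], lags[None, :], eta, rho, tau_max)


# ---------------------------------------------------------------------------
# Group-level series and lag design
# ---------------------------------------------------------------------------


def group_series(traj_1hz: pd.DataFrame, fov_deg: float = 108.0) -> pd.DataFrame:
    """Per group-round-second collective state.

    Columns: n_exploiting, group_size, mean_dist (mean pairwise
    distance, m), visibility_edges (directed looking-at links; an
    exploiting player sees no one, so the count ranges 0..g*(g-1)).
    Condition labels (incentive/environment) are carried through when
    present.
    """
    half = math.radians(fov_deg) / 2.0
    rows = []
    extra = [c for c in ("incentive", "environment") if c in traj_1hz.columns]
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
        n_expl = exploiting.sum(axis=1)
        dists = np.zeros(T)
        edges = np.zeros(T, dtype=int)
        npairs = P * (P - 1) // 2
        for i in range(P):
            for j in range(P):
                if i == j:
                    continue
                delta = xy[:, j, :] - xy[:, i, :]
                dist = np.hypot(delta[:, 0], delta[:, 1])
                if j > i:
                    dists += dist
                brg = np.abs(wrap_angle(np.arctan2(delta[:, 1], delta[:, 0]) - heading[:, i]))
                edges += (~exploiting[:, i]) & (brg <= half) & (dist > 0)
        labels = {c: traj[c].iloc[0] for c in extra}
        for ti in range(T):
            rows.append(
                (g, r, float(seconds[ti]), int(n_expl[ti]), P,
                 dists[ti] / npairs if npairs else np.nan, int(edges[ti]),
                 *[labels[c] for c in extra])
            )
    cols = _ROUND_KEY + ["t_sec", "n_exploiting", "group_size", "mean_dist", "visibility_edges"] + extra
    return pd.DataFrame(rows, columns=cols)


@dataclass
class LagDesign:
    """Stacked outcome/predictor pairs for the lag regression.

    ``X[t, k]`` is the z-scored predictor at lag ``lags[k]`` before the
    outcome row t; outcomes are counts out of ``group_size``.
    """

    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    lags: np.ndarray
    condition: np.ndarray  # per-row (incentive, environment) labels
    predictor: str


def build_lag_design(
    series: pd.DataFrame, predictor: str = "distance", lags=None
) -> LagDesign:
    """Build the time-lagged design from a group series table.

    Rows exist only for t >= max(lags) within each group-round; the
    predictor ("distance" -> mean_dist, "visibility" ->
    visibility_edges) is z-scored pooled within condition.
    """
    col = {"distance": "mean_dist", "visibility": "visibility_edges"}.get(predictor)
    if col is None:
        raise ValueError("predictor must be 'distance' or 'visibility'")
    lags = np.unique(np.asarray(lags if lags is not None else default_lag_grid(), dtype=int))
    if lags.min() < 1:
        raise ValueError("lags must be >= 1 second")
    max_lag = int(lags.max())

    df = series.copy()
    if "incentive" not in df.columns:
        df["incentive"] = "all"
    if "environment" not in df.columns:
        df["environment"] = "all"
    df["_z"] = np.nan
    for _, idx in df.groupby(["incentive", "environment"]).groups.items():
        df.loc[idx, "_z"] = standardize(df.loc[idx, col].to_numpy(dtype=float))

    ys, ns, Xs, conds = [], [], [], []
    for (g, r), sub in df.groupby(_ROUND_KEY):
        sub = sub.sort_values("t_sec")
        x = sub["_z"].to_numpy(dtype=float)
        y = sub["n_exploiting"].to_numpy(dtype=float)
        gs = sub["group_size"].to_numpy(dtype=float)
        T = x.size
        if T <= max_lag:
            raise ValueError(
                f"group-round {(g, r)} has {T} s of data, shorter than max lag {max_lag}"
            )
        t_idx = np.arange(max_lag, T)
        Xs.append(x[t_idx[:, None] - lags[None, :]])
        ys.append(y[t_idx])
        ns.append(gs[t_idx])
        conds.extend([(sub["incentive"].iloc[0], sub["environment"].iloc[0])] * t_idx.size)
    return LagDesign(
        y=np.concatenate(ys),
        n=np.concatenate(ns),
        X=np.vstack(Xs),
        lags=lags,
        condition=np.array(conds, dtype=object),
        predictor=predictor,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class LagGpFit:
    """Posterior lag-effect curves per condition.

    For each condition the draws table holds the intercept ``a``, the
    average effect ``beta_bar``, kernel hyperparameters ``eta`` and
    ``rho``, and the per-lag weights ``beta[tau]`` (= average effect
    plus lag offset).
    """

    draws: dict
    lags: np.ndarray
    predictor: str
    converged: bool

    def conditions(self) -> list:
        return list(self.draws)

    def lag_curve(self, condition) -> np.ndarray:
        """(draws, n_lags) posterior of the per-lag regression weights."""
        df = self.draws[condition]
        return np.column_stack([df[f"beta[{tau}]"].to_numpy() for tau in self.lags])

    def curve_summary(self, condition) -> pd.DataFrame:
        curve = self.lag_curve(condition)
        rows = []
        for k, tau in enumerate(self.lags):
            lo, hi = hpdi(curve[:, k], 0.9)
            rows.append((int(tau), curve[:, k].mean(), lo, hi))
        return pd.DataFrame(rows, columns=["lag", "mean", "hpdi_5", "hpdi_95"])


def fit_laggp(
    design: LagDesign,
    n_draws: int = 1000,
    seed: int | None = 0,
    jitter: float = 1e-8,
) -> LagGpFit:
    """Fit the binomial lag-GP model, one condition at a time.

    The linear predictor of the exploiting count at time t is an
    intercept plus the sum over lags of (average effect + lag offset)
    times the lagged predictor; offsets carry the RBF-kernel Gaussian
    prior, and the kernel amplitude/decay are estimated jointly with
    weakly informative log-normal priors.
    """
    lags = design.lags.astype(float)
    K = lags.size
    tau_max = float(lags.max())
    dist2 = (lags[:, None] - lags[None, :]) ** 2 / tau_max**2
    conditions = sorted({tuple(c) for c in design.condition})
    draws_by_cond = {}
    ok = True
    rng = np.random.default_rng(seed)

    # unconstrained layout: a, beta_bar, log_eta, log_rho, d (K)
    prior_mean = np.concatenate([[0.0, 0.0, -2.5, 0.5], np.zeros(K)])
    prior_sd_head = np.array([1.5, 1.0, 1.5, 1.5])

    for cond in conditions:
        sel = np.array([tuple(c) == cond for c in design.condition])
        y = design.y[sel]
        n = design.n[sel]
        X = design.X[sel]

        def neglogpost(x):
            a, beta_bar, log_eta, log_rho = x[:4]
            d = x[4:]
            eta_k = math.exp(log_eta)
            rho_k = math.exp(log_rho)
            Kmat = eta_k * np.exp(-rho_k * dist2) + jitter * (1.0 + eta_k) * np.eye(K)
            try:
                L = np.linalg.cholesky(Kmat)
            except np.linalg.LinAlgError:
                return 1e12
            alpha_v = solve_triangular(L, d, lower=True)
            quad = float(alpha_v @ alpha_v)
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
            lp_d = -0.5 * (quad + logdet)
            z = (x[:4] - prior_mean[:4]) / prior_sd_head
            lp_head = -0.5 * float(z @ z)
            eta_lin = a + X @ (beta_bar + d)
            ll = float(np.sum(y * (-np.logaddexp(0.0, -eta_lin)) + (n - y) * (-np.logaddexp(0.0, eta_lin))))
            return -(ll + lp_d + lp_head)

        res = map_laplace(
            neglogpost, prior_mean.copy(), n_draws=n_draws, rng=rng,
            min_curvature=0.05, maxiter=20000,
        )
        ok = ok and res.success
        cols = {
            "a": res.draws[:, 0],
            "beta_bar": res.draws[:, 1],
            "eta": np.exp(res.draws[:, 2]),
            "rho": np.exp(res.draws[:, 3]),
        }
        for k, tau in enumerate(design.lags):
            cols[f"beta[{tau}]"] = res.draws[:, 1] + res.draws[:, 4 + k]
            cols[f"d[{tau}]"] = res.draws[:, 4 + k]
        draws_by_cond[cond] = pd.DataFrame(cols)
    return LagGpFit(draws=draws_by_cond, lags=design.lags, predictor=design.predictor, converged=ok)


def simulate_lag_series(
    lag_profile: dict | None,
    n_rounds: int = 4,
    duration: int = 720,
    group_size: int = 4,
    alpha: float = -0.5,
    ar: float = 0.95,
    rng=None,
    incentive: str = "all",
    environment: str = "all",
) -> pd.DataFrame:
    """Simulate group series with a known lag-effect profile.

    The predictor is a stationary AR(1) (unit marginal variance); the
    exploiting count at t is binomial with logit equal to ``alpha``
    plus the sum over the profile's lags of weight times the lagged
    predictor.  ``lag_profile`` maps lag (s) to weight; None or empty
    means no dependence (the null model).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lag_profile = lag_profile or {}
    lags = np.array(sorted(lag_profile), dtype=int)
    weights = np.array([lag_profile[int(k)] for k in lags])
    rows = []
    for r in range(n_rounds):
        x = np.empty(duration)
        x[0] = gen.normal()
        s = math.sqrt(1.0 - ar**2)
        for t in range(1, duration):
            x[t] = ar * x[t - 1] + s * gen.normal()
        eta = np.full(duration, alpha)
        for k, w in zip(lags, weights):
            eta[k:] += w * x[:-k] if k else w * x
        p = 1.0 / (1.0 + np.exp(-eta))
        y = gen.binomial(group_size, p)
        for t in range(duration):
            rows.append((0, r, float(t), int(y[t]), group_size, x[t], 0, incentive, environment))
    return pd.DataFrame(
        rows,
        columns=_ROUND_KEY
        + ["t_sec", "n_exploiting", "group_size", "mean_dist", "visibility_edges", "incentive", "environment"],
    )
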