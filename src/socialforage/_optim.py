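"""Penalized-likelihood optimization with Laplace posterior draws.

Shared backend for the hierarchical models in this package: maximize a
log posterior (all priors are Gaussian on the unconstrained scale),
approximate the posterior by a Gaussian centered at the mode with
covariance the inverse Hessian, and draw from it.  An ensemble-MCMC
(emcee) refinement is available where a sampling check is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize


def fd_hessian(f, x: np.ndarray, h_scale: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of ``f`` at ``x`` with per-coordinate steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = h_scale * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            val = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)) / (
                4.0 * h[i] * h[j]
            )
            H[i, j] = H[j, i] = val
    return H


def _psd_cov_from_hessian(H: np.ndarray, min_curvature: float = 0.0) -> np.ndarray:
    """Invert a Hessian of a negative log posterior, repairing tiny
    non-PSD eigenvalues that finite differences can introduce.

    ``min_curvature`` is a lower bound on the true curvature (for a
    log-concave likelihood with Gaussian priors, at least the smallest
    prior precision); flat or negative FD eigenvalues are raised to it.
    """
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    floor = max(vals.max(), 1.0) * 1e-10
    floor = max(floor, min_curvature)
    if np.any(vals <= 0):
        warnings.warn(
            "Hessian not positive definite at the mode; clipping "
            f"{int(np.sum(vals <= 0))} eigenvalues",
            stacklevel=2,
        )
    vals = np.clip(vals, floor, None)
    return (vecs / vals) @ vecs.T


@dataclass
class MapLaplaceResult:
    """Mode, Gaussian covariance and unconstrained posterior draws."""

    x: np.ndarray
    cov: np.ndarray
    draws: np.ndarray  # (n_draws, dim), unconstrained scale
    neglogpost: float
    success: bool
    message: str
    hess_method: str


def map_laplace(
    neglogpost,
    x0: np.ndarray,
    n_draws: int = 1000,
    rng=None,
    hessian: str = "exact",
    maxiter: int = 3000,
    h_scale: float = 1e-3,
    min_curvature: float = 0.0,
) -> MapLaplaceResult:
    """Maximize ``-neglogpost`` and draw from the Laplace approximation.

    ``hessian='exact'`` uses central finite differences (preferred up to
    a few hundred parameters); ``'bfgs'`` reuses the optimizer's inverse
    Hessian estimate (cheap, cruder tails).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x0 = np.asarray(x0, dtype=float)
    res = optimize.minimize(
        neglogpost, x0, method="L-BFGS-B", options={"maxiter": maxiter, "maxfun": 10 * maxiter}
    )
    if not res.success:
        warnings.warn(f"optimizer did not report success: {res.message}", stacklevel=2)
    x_hat = np.asarray(res.x, dtype=float)
    if hessian == "exact":
        H = fd_hessian(neglogpost, x_hat, h_scale=h_scale)
        cov = _psd_cov_from_hessian(H, min_curvature=min_curvature)
    elif hessian == "bfgs":
        cov = np.asarray(res.hess_inv.todense())
        cov = 0.5 * (cov + cov.T)
    else:
        raise ValueError("hessian must be 'exact' or 'bfgs'")
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]) * max(1.0, np.trace(cov) / cov.shape[0]))
    z = rng.standard_normal((n_draws, x_hat.size))
    draws = x_hat + z @ L.T
    return MapLaplaceResult(
        x=x_hat,
        cov=cov,
        draws=draws,
        neglogpost=float(res.fun),
        success=bool(res.success),
        message=str(res.message),
        hess_method=hessian,
    )


def emcee_draws(
    neglogpost,
    x_init: np.ndarray,
    cov_init: np.ndarray,
    n_draws: int = 1000,
    rng=None,
    steps: int = 600,
    burn: int = 300,
) -> np.ndarray:
    """Refine a Laplace approximation with an affine-invariant ensemble sampler."""
    import emcee

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    dim = x_init.size
    nwalkers = max(2 * dim + 2, 8)
    scale = np.sqrt(np.clip(np.diag(cov_init), 1e-12, None))
    p0 = x_init + 0.5 * scale * rng.standard_normal((nwalkers, dim))

    def logpost(x):
        return -neglogpost(x)

    sampler = emcee.EnsembleSampler(nwalkers, dim, logpost)
    state = sampler.run_mcmc(p0, steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=burn)  # (steps-burn, nwalkers, dim)
    flat = chain.reshape(-1, dim)
    idx = rng.choice(flat.shape[0], size=min(n_draws, flat.shape[0]), replace=False)
    return flat[idx]


def split_rhat_ess(draws: np.ndarray, n_chains: int = 4) -> tuple[float, float]:
    """Max split-chain R-hat and min bulk ESS over parameters (via arviz)."""
    import arviz as az

    n, dim = draws.shape
    m = (n // n_chains) * n_chains
    reshaped = draws[:m].reshape(n_chains, -1, dim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(reshaped)
        rhat = float(az.rhat(ds)["x"].max())
        ess = float(az.ess(ds)["x"].min())
    return rhat, ess
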