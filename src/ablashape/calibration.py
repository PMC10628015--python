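"""Calibration of the width model from (power, velocity, width) observations.

The observation model is heteroscedastic Gaussian regression on log
covariates:

    mu_i    = alpha + beta_power * ln(P_i) + beta_velocity * ln(v_i)
    sigma_i = eps + eps_power * P_i + eps_velocity * v_i
    w_i ~ Normal(mu_i, sigma_i)

with Normal priors on the mean coefficients and Exponential priors on the
(non-negative) noise coefficients.  The posterior is sampled with an
affine-invariant ensemble sampler (emcee), initialised at the MAP point;
convergence is summarised with split-R-hat and effective sample size
(ArviZ).  A scikit-learn-compatible estimator, :class:`WidthRegressor`,
wraps the same fit for pipeline use.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from ablashape.width_model import (
    CalibrationCoefficients,
    PosteriorCoefficients,
    width_mean,
    width_sd,
)

__all__ = [
    "CalibrationObservation",
    "CalibrationDesign",
    "PriorSpec",
    "MCMCSettings",
    "CalibrationFit",
    "simulate_calibration",
    "fit_calibration",
    "summarize_posterior",
    "WidthRegressor",
    "read_observations_csv",
    "write_observations_csv",
]


@dataclass(frozen=True)
class CalibrationObservation:
    """One measured cylindrical ablation: settings and resulting width."""

    power: float
    velocity: float
    width: float
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.power <= 0 or self.velocity <= 0 or self.width <= 0:
            raise ValueError("power, velocity and width must be positive")


@dataclass(frozen=True)
class CalibrationDesign:
    """Factorial calibration design: powers x velocities x replicates.

    Defaults are four power levels (60-120 W) crossed with eight velocities
    evenly spaced in [0.05, 0.12] mm/s, each run over a 35 mm travel
    distance.
    """

    powers: tuple[float, ...] = (60.0, 80.0, 100.0, 120.0)
    velocities: tuple[float, ...] = tuple(np.linspace(0.05, 0.12, 8).round(6))
    travel_distance: float = 35.0
    replicates: int = 1

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.powers) or any(v <= 0 for v in self.velocities):
            raise ValueError("design levels must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self) -> list[tuple[float, float]]:
        return [(p, v) for p in self.powers for v in self.velocities]


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales: Normal(0, scale) for mean coefficients, Exponential(rate)
    for noise coefficients.  Defaults are weakly informative at the mm scale
    of the calibration data."""

    alpha_scale: float = 50.0
    beta_power_scale: float = 10.0
    beta_velocity_scale: float = 10.0
    eps_rate: float = 1.0
    eps_power_rate: float = 1.0
    eps_velocity_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_scale", "beta_power_scale", "beta_velocity_scale",
                     "eps_rate", "eps_power_rate", "eps_velocity_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    walkers_per_chain: int = 16
    seed: int | None = None


@dataclass
class CalibrationFit:
    """Posterior draws plus convergence diagnostics and warnings."""

    posterior: PosteriorCoefficients
    rhat: dict
    ess: dict
    converged: bool
    warnings: list = field(default_factory=list)
    map_estimate: CalibrationCoefficients | None = None


def simulate_calibration(
    truth: CalibrationCoefficients,
    design: CalibrationDesign | None = None,
    seed: int | None = None,
) -> list[CalibrationObservation]:
    """Draw synthetic calibration observations from the generative model.

    One observation per design cell per replicate; widths are sampled from
    ``Normal(mu, sigma)`` and resampled (truncation at zero, with a
    warning) in the rare event a non-positive width is drawn.
    """
    design = design or CalibrationDesign()
    rng = np.random.default_rng(seed)
    obs: list[CalibrationObservation] = []
    n_resampled = 0
    for rep in range(design.replicates):
        for p, v in design.cells():
            mu = width_mean(truth, p, v)
            sd = width_sd(truth, p, v)
            w = mu if sd == 0 else rng.normal(mu, sd)
            while w <= 0:
                n_resampled += 1
                w = rng.normal(mu, sd)
            obs.append(CalibrationObservation(power=p, velocity=v, width=float(w), replicate=rep))
    if n_resampled:
        warnings.warn(
            f"resampled {n_resampled} non-positive width draws (truncation at 0)",
            stacklevel=2,
        )
    return obs


def _design_matrices(obs: Sequence[CalibrationObservation]):
    P = np.array([o.power for o in obs])
    V = np.array([o.velocity for o in obs])
    W = np.array([o.width for o in obs])
    return P, V, W


def _ols_start(P, V, W, fix_intercept_zero: bool):
    """Least squares on (1, ln P, ln v) regressors; the zero-noise oracle."""
    cols = [np.log(P), np.log(V)]
    if not fix_intercept_zero:
        cols.insert(0, np.ones_like(P))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, W, rcond=None)
    if fix_intercept_zero:
        alpha, bp, bv = 0.0, beta[0], beta[1]
    else:
        alpha, bp, bv = beta
    resid_sd = float(np.std(W - X @ beta))
    return float(alpha), float(bp), float(bv), resid_sd


def _log_posterior_factory(P, V, W, priors: PriorSpec, fix_intercept_zero: bool,
                           sigma_floor: float):
    lnP, lnV = np.log(P), np.log(V)
    prior_scales = np.array(
        [priors.alpha_scale, priors.beta_power_scale, priors.beta_velocity_scale]
    )
    prior_rates = np.array([priors.eps_rate, priors.eps_power_rate, priors.eps_velocity_rate])

    def log_post(theta: np.ndarray) -> np.ndarray:
        # theta: (nwalkers, 6) -> (nwalkers,)
        theta = np.atleast_2d(theta)
        mean_c, noise_c = theta[:, :3], theta[:, 3:]
        if fix_intercept_zero:
            mean_c = mean_c.copy()
            mean_c[:, 0] = 0.0
        bad = np.any(noise_c < 0, axis=1)
        mu = mean_c[:, 0:1] + mean_c[:, 1:2] * lnP[None, :] + mean_c[:, 2:3] * lnV[None, :]
        sigma = noise_c[:, 0:1] + noise_c[:, 1:2] * P[None, :] + noise_c[:, 2:3] * V[None, :]
        sigma = np.maximum(sigma, sigma_floor)
        loglik = -0.5 * np.sum(((W[None, :] - mu) / sigma) ** 2 + 2 * np.log(sigma), axis=1)
        logprior = (
            -0.5 * np.sum((mean_c / prior_scales[None, :]) ** 2, axis=1)
            - np.sum(noise_c * prior_rates[None, :], axis=1)
        )
        out = loglik + logprior
        out[bad] = -np.inf
        return out

    return log_post


def _map_estimate(log_post, start: np.ndarray) -> np.ndarray:
    def neg(theta_free):
        th = theta_free.copy()
        th[3:] = np.abs(th[3:])  # noise coefficients live on [0, inf)
        return -float(log_post(th[None, :])[0])

    res = optimize.minimize(neg, start, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
    th = res.x.copy()
    th[3:] = np.abs(th[3:])
    return th


def fit_calibration(
    obs: Sequence[CalibrationObservation],
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    fix_intercept_zero: bool = False,
    sigma_floor: float = 1e-6,
) -> CalibrationFit:
    """Fit the heteroscedastic width model by ensemble MCMC.

    Requires at least 7 observations spanning at least two power and two
    velocity levels (otherwise the six coefficients are not identifiable).
    Each chain is an independent, seeded ensemble run; retained draws from
    all chains form the returned :class:`PosteriorCoefficients`.
    Non-convergence (split-R-hat > 1.05) sets ``converged = False`` and a
    warning entry, never an exception.
    """
    import arviz as az
    import emcee

    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCSettings()
    P, V, W = _design_matrices(obs)
    if len(obs) < 7:
        raise ValueError(f"need >= 7 observations, got {len(obs)}")
    if len(np.unique(P)) < 2 and len(np.unique(V)) < 2:
        raise ValueError(
            "degenerate design: need at least 2 power or 2 velocity levels "
            "(single power AND single velocity is unidentifiable)"
        )
    if len(np.unique(P)) < 2 or len(np.unique(V)) < 2:
        raise ValueError("need >= 2 distinct power levels and >= 2 distinct velocity levels")

    log_post = _log_posterior_factory(P, V, W, priors, fix_intercept_zero, sigma_floor)
    alpha0, bp0, bv0, resid_sd = _ols_start(P, V, W, fix_intercept_zero)
    start = np.array([alpha0, bp0, bv0, max(resid_sd, 1e-3), 1e-3, 1e-3])
    theta_map = _map_estimate(log_post, start)
    map_coeffs = CalibrationCoefficients(*theta_map)

    nw = mcmc.walkers_per_chain
    kept_steps = max(math.ceil(mcmc.draws / nw), 2)
    seed_seq = np.random.SeedSequence(mcmc.seed)
    chain_seeds = seed_seq.spawn(mcmc.chains)
    all_chains = []
    ball_scale = np.maximum(1e-3 * np.abs(theta_map), 1e-4)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        p0 = theta_map[None, :] + ball_scale[None, :] * rng.standard_normal((nw, 6))
        p0[:, 3:] = np.abs(p0[:, 3:])
        sampler = emcee.EnsembleSampler(nw, 6, log_post, vectorize=True)
        # emcee's move RNG otherwise inherits the (unseeded) global state
        sampler._random = np.random.mtrand.RandomState(int(rng.integers(2**31)))
        state = sampler.run_mcmc(
            p0, mcmc.warmup + kept_steps, progress=False,
            skip_initial_state_check=True,
        )
        chain = sampler.get_chain(discard=mcmc.warmup)  # (kept_steps, nw, 6)
        all_chains.append(chain.reshape(-1, 6)[: mcmc.draws])

    draws = np.concatenate(all_chains, axis=0)
    draws[:, 3:] = np.maximum(draws[:, 3:], 0.0)
    if fix_intercept_zero:
        draws[:, 0] = 0.0
    chain_idx = np.repeat(np.arange(mcmc.chains), mcmc.draws)
    draw_idx = np.tile(np.arange(mcmc.draws), mcmc.chains)
    posterior = PosteriorCoefficients(draws, chain=chain_idx, draw=draw_idx)

    stacked = draws.reshape(mcmc.chains, mcmc.draws, 6)
    idata = az.from_dict(
        posterior={name: stacked[:, :, i] for i, name in enumerate(posterior.coef_names)}
    )
    import logging

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        az_logger = getattr(az, "_log", logging.getLogger("arviz"))
        level = az_logger.level
        az_logger.setLevel(logging.ERROR)  # single-chain shape notices
        try:
            rhat_ds = az.rhat(idata)
            ess_ds = az.ess(idata)
        finally:
            az_logger.setLevel(level)
    rhat = {k: float(rhat_ds[k].values) for k in posterior.coef_names}
    ess = {k: float(ess_ds[k].values) for k in posterior.coef_names}
    fit_warnings = []
    # R-hat of a coefficient pinned at a constant (e.g. zero-noise data) is NaN
    finite_rhat = [r for r in rhat.values() if np.isfinite(r)]
    converged = all(r <= 1.05 for r in finite_rhat)
    if not converged:
        fit_warnings.append(
            f"non-convergence: max split-R-hat = {max(finite_rhat):.3f} > 1.05"
        )
    return CalibrationFit(
        posterior=posterior,
        rhat=rhat,
        ess=ess,
        converged=converged,
        warnings=fit_warnings,
        map_estimate=map_coeffs,
    )


def summarize_posterior(post: PosteriorCoefficients, level: float = 0.95):
    """Per-coefficient mean, sd and central credible interval as a DataFrame."""
    import pandas as pd

    if len(post) < 2:
        raise ValueError("need at least 2 draws to summarize")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = {}
    for name in post.coef_names:
        d = post[name]
        rows[name] = {
            "mean": float(np.mean(d)),
            "sd": float(np.std(d, ddof=1)),
            f"ci_{lo_q*100:g}%": float(np.quantile(d, lo_q)),
            f"ci_{hi_q*100:g}%": float(np.quantile(d, hi_q)),
        }
    return pd.DataFrame(rows).T


class WidthRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for the heteroscedastic log-linear width model.

    Parameters
    ----------
    priors : PriorSpec, optional
        Prior scales/rates for the Bayesian fit.
    chains, draws, warmup : int
        MCMC schedule (independent ensemble chains, retained draws per
        chain, discarded warmup steps).
    fix_intercept_zero : bool
        Pin the intercept at zero (the model-block variant of the
        calibration model).
    seed : int, optional
        Seed for the sampler.

    Attributes
    ----------
    posterior_ : PosteriorCoefficients
        Retained posterior draws.
    coefficients_ : CalibrationCoefficients
        Posterior-mean coefficients.
    diagnostics_ : dict
        Split-R-hat and effective sample size per coefficient.
    """

    def __init__(self, priors: PriorSpec | None = None, chains: int = 4,
                 draws: int = 1000, warmup: int = 500,
                 fix_intercept_zero: bool = False, seed: int | None = None):
        self.priors = priors
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.fix_intercept_zero = fix_intercept_zero
        self.seed = seed

    def fit(self, X, y):
        """Fit from ``X = [[power, velocity], ...]`` and widths ``y`` [mm]."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns power [W], velocity [mm/s]")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        obs = [
            CalibrationObservation(power=p, velocity=v, width=w)
            for (p, v), w in zip(X, y)
        ]
        fit = fit_calibration(
            obs,
            priors=self.priors,
            mcmc=MCMCSettings(chains=self.chains, draws=self.draws,
                              warmup=self.warmup, seed=self.seed),
            fix_intercept_zero=self.fix_intercept_zero,
        )
        self.posterior_ = fit.posterior
        self.coefficients_ = fit.posterior.mean_coefficients()
        self.diagnostics_ = {"rhat": fit.rhat, "ess": fit.ess, "converged": fit.converged}
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        """Posterior-mean width [mm] for ``X = [[power, velocity], ...]``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coefficients_")
        X = np.asarray(X, dtype=float)
        return np.array([width_mean(self.coefficients_, p, v) for p, v in X])

    def predict_interval(self, X, level: float = 0.95):
        """Posterior-predictive central intervals, one (lo, hi) row per input."""
        from sklearn.utils.validation import check_is_fitted

        from ablashape.width_model import predictive_interval

        check_is_fitted(self, "posterior_")
        X = np.asarray(X, dtype=float)
        return np.array([predictive_interval(self.posterior_, p, v, level=level) for p, v in X])


def write_observations_csv(obs: Sequence[CalibrationObservation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["power_w", "velocity_mm_s", "width_mm", "replicate"])
        for o in obs:
            writer.writerow([o.power, o.velocity, o.width, "" if o.replicate is None else o.replicate])


def read_observations_csv(path: str | Path) -> list[CalibrationObservation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rep = row.get("replicate")
            out.append(
                CalibrationObservation(
                    power=float(row["power_w"]),
                    velocity=float(row["velocity_mm_s"]),
                    width=float(row["width_mm"]),
                    replicate=int(rep) if rep not in (None, "") else None,
                )
            )
    return out
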