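"""Trip success, fuel-vs-harvest regression, and failed-trip inference.

Fitted to trip records (Tooniktoyok-style: fuel litres, edible kg, mode,
participants): the probability a trip succeeds is Bernoulli with
probability theta; for successful trips log fuel is linear in log edible
weight (a power law on the natural scale); for failed trips log fuel is
normal with its own mean and SD.  The three blocks are a priori
independent, so they are sampled as separate MCMC blocks and draws are
aligned by index.

Priors are weakly informative: Beta(1, 1) on theta, Normal(0, 1) on the
regression intercept and slope (log scale), Normal(0, 5) on the failed-trip
log-fuel mean, and half-Normal(1) on both SDs.

The unobserved-failure construction: if every harvest report is one
successful trip, the number of failed trips accompanying ``n`` observed
successes under a Bernoulli(theta) trip process is negative-binomial with
mean ``n (1 - theta) / theta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import rw_metropolis, split_rhat, ess_mean

logger = logging.getLogger("harvestcarbon")

__all__ = [
    "TripModelSettings",
    "TripModelPosterior",
    "fit_trip_model",
    "predict_fuel",
    "expected_failures",
    "simulate_failures",
]


@dataclass(frozen=True)
class TripModelSettings:
    chains: int = 3
    iterations: int = 6000  # random-walk chains need more steps than HMC would
    seed: int = 0
    n_keep: int = 100
    theta_prior: tuple[float, float] = (1.0, 1.0)  # Beta(alpha, beta)
    rhat_threshold: float = 1.01


@dataclass
class TripModelPosterior:
    """Aligned posterior draws for the trip process.

    All arrays share one draw index so joint uncertainty propagates when
    the posterior is pushed through downstream accounting.
    """

    theta: np.ndarray
    intercept: np.ndarray
    slope: np.ndarray
    resid_sd: np.ndarray
    failed_log_mean: np.ndarray
    failed_log_sd: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    n_success: int
    n_failed: int
    converged: bool = True

    def __post_init__(self) -> None:
        if np.any((self.theta <= 0) | (self.theta >= 1)):
            raise ValueError("TripModelPosterior: theta draws must lie in (0, 1)")
        if np.any(self.failed_log_sd <= 0):
            raise ValueError("TripModelPosterior: failed_log_sd draws must be > 0")

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "theta": self.theta,
                "intercept": self.intercept,
                "slope": self.slope,
                "resid_sd": self.resid_sd,
                "failed_log_mean": self.failed_log_mean,
                "failed_log_sd": self.failed_log_sd,
            }
        )


def _thin(flat: np.ndarray, n_keep: int) -> np.ndarray:
    idx = np.linspace(0, flat.shape[0] - 1, n_keep).round().astype(int)
    return flat[idx]


def fit_trip_model(
    trips: pd.DataFrame,
    settings: TripModelSettings = TripModelSettings(),
) -> TripModelPosterior:
    """Joint posterior for (theta, intercept, slope, resid SD, failed-fuel
    log mean/SD) from a trip table.

    Requires at least one success and one failure; an all-success or
    all-failure table cannot identify theta away from the boundary — pass a
    stronger ``theta_prior`` (pseudo-counts, e.g. ``(2, 2)``) and split the
    data if that is really what you have.  Records with fuel <= 0 are
    excluded from the fuel blocks (and logged); they still count for theta.
    """
    success = trips["edible_kg"].to_numpy() > 0
    n_s, n_f = int(success.sum()), int((~success).sum())
    if n_s == 0 or n_f == 0:
        raise ValueError(
            "fit_trip_model: need at least one success and one failure; "
            "for degenerate tables use a theta_prior with pseudo-counts, "
            "e.g. TripModelSettings(theta_prior=(2, 2))"
        )
    fuel_ok = trips["fuel_l"].to_numpy() > 0
    n_excluded = int((~fuel_ok).sum())
    if n_excluded:
        logger.warning("fit_trip_model: excluding %d record(s) with fuel <= 0", n_excluded)

    a0, b0 = settings.theta_prior
    # theta block: logit-scale random walk, Beta prior with Jacobian
    k, n = n_s, n_s + n_f

    def lp_theta(x: np.ndarray) -> np.ndarray:
        lam = x[:, 0]
        theta = 1.0 / (1.0 + np.exp(-lam))
        return (k + a0) * np.log(theta) + (n - k + b0) * np.log1p(-theta)

    theta_chains = rw_metropolis(
        lp_theta,
        np.array([np.log(k + 0.5) - np.log(n - k + 0.5)]),
        n_chains=settings.chains,
        n_iter=settings.iterations,
        seed=settings.seed,
        init_step=0.5,
    )
    theta_draws = 1.0 / (1.0 + np.exp(-theta_chains[..., 0]))

    # regression block on successful trips with positive fuel, with the
    # log-kg covariate centred to decorrelate intercept and slope
    reg = trips[success & fuel_ok]
    x_log = np.log(reg["edible_kg"].to_numpy(dtype=float))
    y_log = np.log(reg["fuel_l"].to_numpy(dtype=float))
    xbar = float(x_log.mean())
    xc = x_log - xbar
    m = x_log.size

    def lp_reg(p: np.ndarray) -> np.ndarray:
        ac, b, log_s = p[:, 0], p[:, 1], p[:, 2]
        s = np.exp(log_s)
        resid = y_log[None, :] - (ac[:, None] + b[:, None] * xc[None, :])
        loglik = -m * log_s - 0.5 * np.sum(resid**2, axis=1) / s**2
        a = ac - b * xbar  # prior applies to the uncentred intercept
        logprior = -0.5 * a**2 - 0.5 * b**2 - 0.5 * s**2 + log_s  # N(0,1)^2, halfN(1)+Jacobian
        return loglik + logprior

    ls_init = np.log(max(np.std(y_log), 1e-2))
    reg_chains = rw_metropolis(
        lp_reg,
        np.array([float(y_log.mean()), 0.0, ls_init]),
        n_chains=settings.chains,
        n_iter=settings.iterations,
        seed=settings.seed + 1,
        init_step=0.2,
    )

    # failed-trip fuel block
    failed = trips[~success & fuel_ok]
    z = np.log(failed["fuel_l"].to_numpy(dtype=float))
    mz = z.size

    def lp_failed(p: np.ndarray) -> np.ndarray:
        mu, log_s = p[:, 0], p[:, 1]
        s = np.exp(log_s)
        loglik = -mz * log_s - 0.5 * np.sum((z[None, :] - mu[:, None]) ** 2, axis=1) / s**2
        logprior = -0.5 * (mu / 5.0) ** 2 - 0.5 * s**2 + log_s  # N(0,5), halfN(1)+Jacobian
        return loglik + logprior

    failed_chains = rw_metropolis(
        lp_failed,
        np.array([float(z.mean()), np.log(max(np.std(z), 1e-2))]),
        n_chains=settings.chains,
        n_iter=settings.iterations,
        seed=settings.seed + 2,
        init_step=0.2,
    )

    rhat = {
        "theta": float(split_rhat(theta_draws)),
        "intercept": float(split_rhat(reg_chains[..., 0] - reg_chains[..., 1] * xbar)),
        "slope": float(split_rhat(reg_chains[..., 1])),
        "resid_sd": float(split_rhat(np.exp(reg_chains[..., 2]))),
        "failed_log_mean": float(split_rhat(failed_chains[..., 0])),
        "failed_log_sd": float(split_rhat(np.exp(failed_chains[..., 1]))),
    }
    ess = {
        "theta": float(ess_mean(theta_draws)),
        "slope": float(ess_mean(reg_chains[..., 1])),
        "failed_log_mean": float(ess_mean(failed_chains[..., 0])),
    }
    converged = all(v <= settings.rhat_threshold for v in rhat.values())
    if not converged:
        logger.warning("fit_trip_model: split-R-hat above threshold: %s", rhat)

    flat_reg = reg_chains.reshape(-1, 3)
    flat_failed = failed_chains.reshape(-1, 2)
    flat_theta = theta_draws.reshape(-1)
    nk = settings.n_keep
    a_draws = _thin(flat_reg[:, 0] - flat_reg[:, 1] * xbar, nk)
    return TripModelPosterior(
        theta=_thin(flat_theta, nk),
        intercept=a_draws,
        slope=_thin(flat_reg[:, 1], nk),
        resid_sd=np.exp(_thin(flat_reg[:, 2], nk)),
        failed_log_mean=_thin(flat_failed[:, 0], nk),
        failed_log_sd=np.exp(_thin(flat_failed[:, 1], nk)),
        rhat=rhat,
        ess=ess,
        n_success=n_s,
        n_failed=n_f,
        converged=converged,
    )


def predict_fuel(edible_kg: float, posterior: TripModelPosterior) -> np.ndarray:
    """Per-draw expected fuel (L) to harvest ``edible_kg`` on one trip."""
    if not edible_kg > 0:
        raise ValueError("predict_fuel: edible_kg must be > 0")
    return np.exp(posterior.intercept + posterior.slope * np.log(edible_kg))


def expected_failures(n_success, theta):
    """Expected unobserved failed trips accompanying ``n_success`` successes.

    Negative-binomial expectation ``n_success * (1 - theta) / theta``.
    Accepts scalar or array theta.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0) | (theta > 1)):
        raise ValueError("expected_failures: theta must be in (0, 1]")
    out = n_success * (1.0 - theta) / theta
    return float(out) if out.ndim == 0 else out


def simulate_failures(
    n_success: int,
    posterior: TripModelPosterior,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw failed-trip count and total failed-trip fuel (L).

    For each posterior draw, the failed-trip count is negative-binomial
    (failures before the ``n_success``-th success at rate theta) and each
    failed trip burns lognormal fuel with that draw's failed-trip
    parameters.
    """
    if not n_success >= 1:
        raise ValueError("simulate_failures: n_success must be >= 1")
    rng = np.random.default_rng(seed)
    n_failed = np.empty(posterior.n_draws, dtype=int)
    fuel = np.empty(posterior.n_draws)
    for d in range(posterior.n_draws):
        nf = int(stats.nbinom.rvs(n_success, posterior.theta[d], random_state=rng))
        n_failed[d] = nf
        fuel[d] = (
            np.exp(
                posterior.failed_log_mean[d]
                + posterior.failed_log_sd[d] * rng.standard_normal(nf)
            ).sum()
            if nf
            else 0.0
        )
    return n_failed, fuel
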