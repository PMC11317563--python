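"""Gasoline inputs of local harvesting: litres, dollars, and CO2e.

Treats each harvest report as one successful trip and pushes the aligned
latent-harvest and trip-model draws through the fuel regression, then adds
the fuel of the unobserved failed trips implied by the Bernoulli trip
process.  Gasoline emissions combine combustion (kg CO2e per litre burned)
with the shipping of the fuel itself to the region (density times route
distance times per-mode factors at a low or high endpoint).

Draw alignment matters and is preserved throughout: kg draws and
regression-parameter draws are indexed by the same posterior draw, so a
heavy-harvest draw is costed with that same draw's fuel curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config_io import FuelEmissionConfig, ValidationError
from .trip_model import TripModelPosterior, simulate_failures

__all__ = [
    "FuelDraws",
    "harvest_fuel_draws",
    "total_fuel_with_failures",
    "gasoline_cost",
    "gasoline_emissions",
]


@dataclass(frozen=True)
class FuelDraws:
    """Per-draw fuel totals (L): successful trips, failed trips, and both."""

    successful: np.ndarray
    failed: np.ndarray
    n_failed: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.successful + self.failed


def harvest_fuel_draws(kg_draws: np.ndarray, posterior: TripModelPosterior) -> np.ndarray:
    """Per-draw total fuel (L) over all successful (reported) trips.

    ``kg_draws`` has shape ``(n_draws, n_reports)`` and must be aligned by
    draw index with the trip posterior: fuel for draw d is
    ``sum_i exp(a_d + b_d log kg_{d,i})`` so kg and regression uncertainty
    propagate jointly.
    """
    kg_draws = np.asarray(kg_draws, dtype=float)
    if kg_draws.ndim != 2:
        raise ValidationError("harvest_fuel_draws: kg_draws must be (n_draws, n_reports)")
    if kg_draws.shape[1] == 0:
        return np.zeros(kg_draws.shape[0])
    if kg_draws.shape[0] != posterior.n_draws:
        raise ValidationError(
            f"harvest_fuel_draws: draw-count mismatch ({kg_draws.shape[0]} kg draws vs "
            f"{posterior.n_draws} trip-model draws)"
        )
    if np.any(kg_draws <= 0):
        raise ValidationError("harvest_fuel_draws: kg draws must be positive")
    log_kg = np.log(kg_draws)
    return np.exp(posterior.intercept[:, None] + posterior.slope[:, None] * log_kg).sum(axis=1)


def total_fuel_with_failures(
    success_fuel_draws: np.ndarray,
    n_reports: int,
    posterior: TripModelPosterior,
    seed: int = 0,
) -> FuelDraws:
    """Add the fuel of unobserved failed trips to the successful-trip fuel.

    Per draw: the failed-trip count accompanying ``n_reports`` observed
    successes is negative-binomial at that draw's theta, and each failed
    trip burns lognormal fuel at that draw's failed-trip parameters.
    """
    success_fuel_draws = np.asarray(success_fuel_draws, dtype=float)
    if success_fuel_draws.shape[0] != posterior.n_draws:
        raise ValidationError("total_fuel_with_failures: draw-count mismatch")
    n_failed, failed_fuel = simulate_failures(n_reports, posterior, seed=seed)
    return FuelDraws(successful=success_fuel_draws, failed=failed_fuel, n_failed=n_failed)


def gasoline_cost(fuel_draws: np.ndarray, price_cad_per_l: float) -> np.ndarray:
    """Per-draw gasoline cost (CAD)."""
    if not price_cad_per_l > 0:
        raise ValidationError("gasoline_cost: price must be > 0")
    return np.asarray(fuel_draws, dtype=float) * price_cad_per_l


def gasoline_emissions(
    fuel_draws: np.ndarray,
    config: FuelEmissionConfig,
    endpoint: str,
    community: str | None = None,
) -> np.ndarray:
    """Per-draw CO2e (kg) from burning and shipping the gasoline.

    Per litre: the combustion factor plus density times the summed
    distance x per-mode shipping factor at the chosen endpoint.  Failed
    and successful fuel are attributed at the regional level, so a single
    route is used: the given ``community``'s, or the only configured route
    when there is exactly one.
    """
    fuel = np.asarray(fuel_draws, dtype=float)
    if community is None:
        if len(config.route_legs) == 1:
            community = next(iter(config.route_legs))
        else:
            raise ValidationError(
                "gasoline_emissions: specify a community (several gasoline routes configured)"
            )
    shipping = config.shipping_intensity(community, endpoint)  # kg CO2e per kg fuel
    per_litre = config.combustion_ef_kg_per_l + config.gasoline_density_kg_per_l * shipping
    return fuel * per_litre
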