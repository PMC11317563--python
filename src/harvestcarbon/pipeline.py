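"""End-to-end orchestration: reports + trips + config -> summary tables.

Chains the four analysis components — deheaping, the trip model, the
weight/value/emissions propagation, and the gasoline accounting — keeping
draw alignment so uncertainty propagates jointly, and returns both the raw
draw vectors and table-shaped summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config_io import ConfigBundle, SCENARIO_LABELS
from .deheap import DeheapConfig, DeheapPosterior, fit_deheap
from .trip_model import TripModelPosterior, TripModelSettings, fit_trip_model
from .valuation import (
    PosteriorSummary,
    aggregate_by_class,
    edible_weight_draws,
    replacement_emissions,
    substitution_value,
    summarize,
    summarize_by_class,
)
from .fuel_carbon import (
    FuelDraws,
    gasoline_cost,
    gasoline_emissions,
    harvest_fuel_draws,
    total_fuel_with_failures,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    deheap_posterior: DeheapPosterior
    trip_posterior: TripModelPosterior | None
    weight_draws: dict[str, np.ndarray]
    value_draws: dict[str, np.ndarray]
    emissions_draws: dict[str, dict[str, np.ndarray]]  # scenario -> class -> draws
    fuel: FuelDraws | None
    summaries: dict[str, list[PosteriorSummary]] = field(default_factory=dict)


def run_pipeline(
    reports: pd.DataFrame,
    bundle: ConfigBundle,
    trips: pd.DataFrame | None = None,
    *,
    seed: int = 0,
    n_keep: int = 100,
    chains: int = 3,
    iterations: int = 4000,
    pooling_mode: str = "species_type_pooled",
) -> PipelineResult:
    """Run the full estimation chain on validated inputs.

    ``trips`` is optional: without it the fuel component is skipped.  All
    samplers are seeded deterministically from ``seed``.
    """
    deheap_post = fit_deheap(
        reports,
        bundle.species,
        DeheapConfig(
            pooling_mode=pooling_mode,
            chains=chains,
            iterations=iterations,
            seed=seed,
            n_keep=n_keep,
        ),
    )
    kg = edible_weight_draws(deheap_post, reports, bundle.species)
    weight = aggregate_by_class(kg, reports, bundle.species)
    value = substitution_value(
        kg, bundle.prices, reports, bundle.species, default_community=bundle.default_community
    )
    emissions = {
        label: replacement_emissions(
            kg,
            bundle.scenarios[label],
            reports,
            bundle.species,
            default_community=bundle.default_community,
        )
        for label in SCENARIO_LABELS
    }

    summaries: dict[str, list[PosteriorSummary]] = {
        "weight": summarize_by_class(weight, "kg"),
        "value": summarize_by_class(value, "CAD"),
    }
    for label in SCENARIO_LABELS:
        summaries[f"emissions_{label}"] = summarize_by_class(emissions[label], "kg CO2e")

    trip_post = None
    fuel = None
    if trips is not None:
        trip_post = fit_trip_model(
            trips, TripModelSettings(chains=chains, iterations=iterations, seed=seed + 10, n_keep=n_keep)
        )
        success_fuel = harvest_fuel_draws(kg, trip_post)
        fuel = total_fuel_with_failures(success_fuel, len(reports), trip_post, seed=seed + 20)
        cost = gasoline_cost(fuel.total, bundle.fuel.fuel_price_cad_per_l)
        fuel_rows = [
            summarize(fuel.successful, "successful_trip_fuel", "L"),
            summarize(fuel.failed, "failed_trip_fuel", "L"),
            summarize(fuel.n_failed.astype(float), "failed_trips", "trips"),
            summarize(fuel.total, "total_fuel", "L"),
            summarize(cost, "gasoline_cost", "CAD"),
        ]
        for endpoint in ("low", "high"):
            co2 = gasoline_emissions(
                fuel.total, bundle.fuel, endpoint, community=bundle.default_community
            )
            fuel_rows.append(summarize(co2, f"gasoline_emissions_{endpoint}", "kg CO2e"))
        summaries["fuel"] = fuel_rows

    return PipelineResult(
        deheap_posterior=deheap_post,
        trip_posterior=trip_post,
        weight_draws=weight,
        value_draws=value,
        emissions_draws=emissions,
        fuel=fuel,
        summaries=summaries,
    )
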