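"""Edible weight, market-replacement value, and replacement-food emissions.

Latent-harvest draws are pushed through deterministic per-report
conversions — edible weight per animal, community replacement price (CPI
adjusted), and scenario emission intensity (production factor plus route
transport factors) — then aggregated per posterior draw by taxon class
(bird / fish / mammal) and in total, so every summary carries the full
posterior uncertainty.  Prices, weights, and emission factors themselves
carry no error model; the low/high scenario endpoints express that
uncertainty instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config_io import (
    EmissionScenario,
    PriceTable,
    TAXON_CLASSES,
    ValidationError,
)
from .deheap import DeheapPosterior

logger = logging.getLogger("harvestcarbon")

__all__ = [
    "PosteriorSummary",
    "edible_weight_draws",
    "aggregate_by_class",
    "substitution_value",
    "replacement_emissions",
    "hpdi",
    "summarize",
    "summarize_by_class",
]

CLASS_KEYS = list(TAXON_CLASSES) + ["total"]


@dataclass(frozen=True)
class PosteriorSummary:
    label: str
    mean: float
    sd: float
    hpdi_low: float
    hpdi_high: float
    units: str


def _resolve(reports: pd.DataFrame, species: pd.DataFrame, column: str) -> np.ndarray:
    mapped = reports["species_code"].map(species.set_index("species_code")[column])
    if mapped.isna().any():
        bad = sorted(reports.loc[mapped.isna(), "species_code"].unique())
        raise ValidationError(f"unresolved species codes {bad}")
    return mapped.to_numpy()


def edible_weight_draws(
    deheap_post: DeheapPosterior,
    reports: pd.DataFrame,
    species: pd.DataFrame,
) -> np.ndarray:
    """Per-draw, per-report edible kilograms.

    Each latent count draw is multiplied by the edible weight of the
    species actually reported (per species, not pooled by species type).
    Shape ``(n_draws, n_reports)``, aligned with ``deheap_post.draws``.
    """
    reports = reports.reset_index(drop=True)
    if len(reports) != deheap_post.draws.shape[1]:
        raise ValidationError("edible_weight_draws: reports do not match posterior width")
    per_animal = _resolve(reports, species, "edible_weight_kg_per_animal").astype(float)
    return deheap_post.draws * per_animal[None, :]


def aggregate_by_class(
    per_report_draws: np.ndarray,
    reports: pd.DataFrame,
    species: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Sum per-report draws into per-draw taxon-class totals plus the grand
    total; additive by construction in every draw."""
    reports = reports.reset_index(drop=True)
    classes = _resolve(reports, species, "taxon_class")
    out = {}
    for cls in TAXON_CLASSES:
        mask = classes == cls
        out[cls] = per_report_draws[:, mask].sum(axis=1)
    out["total"] = per_report_draws.sum(axis=1)
    return out


def _community_of(reports: pd.DataFrame, known: set[str], default: str) -> pd.Series:
    comm = reports["community"].astype(str)
    unknown = ~comm.isin(known)
    if unknown.any():
        if not default or default not in known:
            raise ValidationError(
                f"reports reference unknown communities {sorted(comm[unknown].unique())} "
                "and no valid default_community is configured"
            )
        logger.warning(
            "%d report(s) lack a configured community; falling back to %r",
            int(unknown.sum()),
            default,
        )
        comm = comm.where(~unknown, default)
    return comm


def substitution_value(
    kg_draws: np.ndarray,
    prices: PriceTable,
    reports: pd.DataFrame,
    species: pd.DataFrame,
    *,
    default_community: str = "",
) -> dict[str, np.ndarray]:
    """Per-draw market-replacement value (CAD), by taxon class and total.

    value = kg x community price for the report's replacement category x
    CPI factor.
    """
    reports = reports.reset_index(drop=True)
    categories = _resolve(reports, species, "replacement_category")
    known = set(prices.prices["community"])
    comm = _community_of(reports, known, default_community)
    price = np.array(
        [prices.lookup(c, cat) for c, cat in zip(comm, categories)], dtype=float
    )
    value = kg_draws * (price * prices.cpi_factor)[None, :]
    return aggregate_by_class(value, reports, species)


def replacement_emissions(
    kg_draws: np.ndarray,
    scenario: EmissionScenario,
    reports: pd.DataFrame,
    species: pd.DataFrame,
    *,
    default_community: str = "",
) -> dict[str, np.ndarray]:
    """Per-draw replacement-food emissions (kg CO2e), by class and total.

    Per kilogram: the category production factor plus the summed
    distance x mode factor over the route legs to the report's community.
    """
    reports = reports.reset_index(drop=True)
    categories = _resolve(reports, species, "replacement_category")
    comm = _community_of(reports, set(scenario.route_legs), default_community)
    transport = np.array([scenario.transport_intensity(c) for c in comm])
    production = np.array([scenario.production_ef[cat] for cat in categories])
    co2e = kg_draws * (production + transport)[None, :]
    return aggregate_by_class(co2e, reports, species)


def hpdi(draws: np.ndarray, mass: float = 0.90) -> tuple[float, float]:
    """Highest posterior density interval from samples.

    The shortest contiguous window over the sorted draws spanning
    ``floor(mass * n)`` inter-point gaps (``floor(mass * n) + 1`` points),
    ties broken by the lowest start index — the standard sample-HDI
    convention.  Requires at least 10 draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError(f"hpdi: need at least 10 draws, got {n}")
    if not 0 < mass < 1:
        raise ValueError("hpdi: mass must be in (0, 1)")
    span = int(np.floor(mass * n))
    widths = x[span:] - x[: n - span]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + span])


def summarize(draws: np.ndarray, label: str, units: str, mass: float = 0.90) -> PosteriorSummary:
    """Mean, sample SD, and HPDI of a draw vector."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("summarize: empty draws")
    low, high = hpdi(x, mass) if x.size >= 10 else (float(x.min()), float(x.max()))
    return PosteriorSummary(
        label=label,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        hpdi_low=low,
        hpdi_high=high,
        units=units,
    )


def summarize_by_class(
    class_draws: dict[str, np.ndarray], units: str, mass: float = 0.90
) -> list[PosteriorSummary]:
    """One summary row per taxon class plus the total (table-shaped)."""
    return [summarize(class_draws[k], k, units, mass) for k in CLASS_KEYS if k in class_draws]
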