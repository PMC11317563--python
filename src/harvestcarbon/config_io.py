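"""Tabular input/output and the shared configuration model.

All tables are UTF-8 CSV with a header row; scenario definitions and scalar
constants live in a YAML config file.  Validation is total: every malformed
input is rejected with a :class:`ValidationError` naming the offending row
and field.  Units are carried in field names (kg, CAD, L, kg CO2e); there is
no unit system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("harvestcarbon")

TAXON_CLASSES = ("bird", "fish", "mammal")
REPLACEMENT_CATEGORIES = ("poultry", "fish_mix", "beef_pork_mix")
TRIP_MODES = ("boat", "snowmobile", "atv")
SCENARIO_LABELS = ("barge_low", "barge_high", "foodmail_low", "foodmail_high")

SPECIES_COLUMNS = [
    "species_code",
    "species_type",
    "taxon_class",
    "edible_weight_kg_per_animal",
    "replacement_category",
]
PRICE_COLUMNS = ["community", "replacement_category", "price_cad_per_kg"]
HARVEST_COLUMNS = ["report_id", "community", "month", "species_code", "reported_count", "missing_flag"]
TRIP_COLUMNS = ["trip_id", "mode", "participants", "fuel_l", "edible_kg", "success"]


class ValidationError(ValueError):
    """Raised when an input table or config violates an invariant."""


@dataclass(frozen=True)
class PriceTable:
    """Replacement-food prices (CAD/kg) per community and category."""

    prices: pd.DataFrame  # columns: community, replacement_category, price_cad_per_kg
    cpi_factor: float

    def lookup(self, community: str, category: str) -> float:
        sel = self.prices[
            (self.prices["community"] == community)
            & (self.prices["replacement_category"] == category)
        ]
        if sel.empty:
            raise ValidationError(
                f"no price for community={community!r}, replacement_category={category!r}"
            )
        return float(sel["price_cad_per_kg"].iloc[0])


@dataclass(frozen=True)
class EmissionScenario:
    """One replacement-food transport scenario.

    ``production_ef`` maps replacement category to kg CO2e per kg edible;
    ``route_legs`` maps community to an ordered list of (mode, km) legs;
    ``transport_ef`` maps transport mode to kg CO2e per kg per km at the
    endpoint (low or high) this scenario uses.
    """

    label: str
    production_ef: Mapping[str, float]
    route_legs: Mapping[str, Sequence[tuple[str, float]]]
    transport_ef: Mapping[str, float]

    def transport_intensity(self, community: str) -> float:
        """kg CO2e per kg edible shipped to ``community`` (transport only)."""
        if community not in self.route_legs:
            raise ValidationError(f"scenario {self.label!r}: no route for community {community!r}")
        return sum(km * self.transport_ef[mode] for mode, km in self.route_legs[community])


@dataclass(frozen=True)
class FuelEmissionConfig:
    """Gasoline constants and the gasoline shipping route."""

    gasoline_density_kg_per_l: float = 0.749
    combustion_ef_kg_per_l: float = 2.319
    fuel_price_cad_per_l: float = 1.76
    route_legs: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    transport_ef: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def shipping_intensity(self, community: str, endpoint: str) -> float:
        """kg CO2e per kg of gasoline shipped to ``community``."""
        if endpoint not in ("low", "high"):
            raise ValidationError(f"unknown endpoint {endpoint!r}; expected 'low' or 'high'")
        if community not in self.route_legs:
            raise ValidationError(f"no gasoline route for community {community!r}")
        return sum(km * self.transport_ef[mode][endpoint] for mode, km in self.route_legs[community])


@dataclass(frozen=True)
class ConfigBundle:
    species: pd.DataFrame
    prices: PriceTable
    scenarios: Mapping[str, EmissionScenario]
    fuel: FuelEmissionConfig
    default_community: str

    def species_map(self, column: str) -> pd.Series:
        return self.species.set_index("species_code")[column]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")


def validate_species(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SPECIES_COLUMNS, "species table")
    dup = df["species_code"][df["species_code"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"species table: duplicate species_code {sorted(set(dup))}")
    for idx, row in df.iterrows():
        if row["taxon_class"] not in TAXON_CLASSES:
            raise ValidationError(
                f"species table row {idx}: field taxon_class has unknown token "
                f"{row['taxon_class']!r} (expected one of {TAXON_CLASSES})"
            )
        if row["replacement_category"] not in REPLACEMENT_CATEGORIES:
            raise ValidationError(
                f"species table row {idx}: field replacement_category has unknown token "
                f"{row['replacement_category']!r}"
            )
        if not row["edible_weight_kg_per_animal"] > 0:
            raise ValidationError(
                f"species table row {idx}: field edible_weight_kg_per_animal must be > 0, "
                f"got {row['edible_weight_kg_per_animal']!r}"
            )
    return df.reset_index(drop=True)


def validate_prices(df: pd.DataFrame, cpi_factor: float) -> PriceTable:
    _require_columns(df, PRICE_COLUMNS, "price table")
    if not cpi_factor > 0:
        raise ValidationError(f"config: cpi_factor must be > 0, got {cpi_factor!r}")
    dup = df[df.duplicated(["community", "replacement_category"])]
    if not dup.empty:
        raise ValidationError(
            "price table: duplicate (community, replacement_category) rows at index "
            f"{list(dup.index)}"
        )
    for idx, row in df.iterrows():
        if row["replacement_category"] not in REPLACEMENT_CATEGORIES:
            raise ValidationError(
                f"price table row {idx}: field replacement_category has unknown token "
                f"{row['replacement_category']!r}"
            )
        if not row["price_cad_per_kg"] > 0:
            raise ValidationError(
                f"price table row {idx}: field price_cad_per_kg must be > 0, "
                f"got {row['price_cad_per_kg']!r}"
            )
    return PriceTable(prices=df.reset_index(drop=True), cpi_factor=float(cpi_factor))


def _validate_routes(routes: Mapping, transport_ef: Mapping, context: str) -> dict:
    out: dict[str, list[tuple[str, float]]] = {}
    for community, legs in routes.items():
        out[community] = []
        for i, leg in enumerate(legs):
            mode, km = leg[0], float(leg[1])
            if mode not in transport_ef:
                raise ValidationError(
                    f"{context}: route for {community!r} leg {i}: unknown transport mode {mode!r}"
                )
            if not km > 0:
                raise ValidationError(
                    f"{context}: route for {community!r} leg {i}: field distance_km must be > 0, got {km}"
                )
            out[community].append((mode, km))
    return out


def build_scenarios(config: Mapping) -> dict[str, EmissionScenario]:
    """Materialize the four replacement-transport scenarios from one config."""
    production_ef = {k: float(v) for k, v in config["production_ef"].items()}
    for cat, ef in production_ef.items():
        if ef < 0:
            raise ValidationError(f"config: field production_ef[{cat!r}] must be >= 0, got {ef}")
    transport_ef = config["transport_ef"]
    for mode, ends in transport_ef.items():
        for endpoint in ("low", "high"):
            if float(ends[endpoint]) < 0:
                raise ValidationError(
                    f"config: field transport_ef[{mode!r}][{endpoint!r}] must be >= 0"
                )
    scenarios = {}
    for route_name in ("barge", "foodmail"):
        legs = _validate_routes(config["routes"][route_name], transport_ef, "config routes")
        for endpoint in ("low", "high"):
            label = f"{route_name}_{endpoint}"
            scenarios[label] = EmissionScenario(
                label=label,
                production_ef=production_ef,
                route_legs=legs,
                transport_ef={m: float(e[endpoint]) for m, e in transport_ef.items()},
            )
    return scenarios


def build_fuel_config(config: Mapping) -> FuelEmissionConfig:
    fuel = config["fuel"]
    for key in ("gasoline_density_kg_per_l", "combustion_ef_kg_per_l", "fuel_price_cad_per_l"):
        if not float(fuel[key]) > 0:
            raise ValidationError(f"config: field fuel.{key} must be > 0, got {fuel[key]!r}")
    transport_ef = config["transport_ef"]
    routes = _validate_routes(fuel.get("routes", {}), transport_ef, "config fuel routes")
    return FuelEmissionConfig(
        gasoline_density_kg_per_l=float(fuel["gasoline_density_kg_per_l"]),
        combustion_ef_kg_per_l=float(fuel["combustion_ef_kg_per_l"]),
        fuel_price_cad_per_l=float(fuel["fuel_price_cad_per_l"]),
        route_legs=routes,
        transport_ef={m: {k: float(v) for k, v in e.items()} for m, e in transport_ef.items()},
    )


def load_tables(
    species_path: str | Path,
    prices_path: str | Path,
    config_path: str | Path,
    harvest_path: str | Path | None = None,
) -> ConfigBundle:
    """Load and validate species, price, and scenario configuration.

    If ``harvest_path`` is given, additionally checks that every species
    code referenced by the harvest table resolves in the species table.
    """
    species = validate_species(pd.read_csv(species_path))
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    prices = validate_prices(pd.read_csv(prices_path), float(config["cpi_factor"]))
    bundle = ConfigBundle(
        species=species,
        prices=prices,
        scenarios=build_scenarios(config),
        fuel=build_fuel_config(config),
        default_community=str(config.get("default_community", "")),
    )
    if harvest_path is not None:
        harvest = load_harvest_reports(harvest_path)
        check_species_resolvable(harvest, species)
    return bundle


def check_species_resolvable(harvest: pd.DataFrame, species: pd.DataFrame) -> None:
    unresolved = sorted(set(harvest["species_code"]) - set(species["species_code"]))
    if unresolved:
        raise ValidationError(f"harvest table: unresolved species codes {unresolved}")


def load_harvest_reports(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, HARVEST_COLUMNS, "harvest table")
    df["missing_flag"] = df["missing_flag"].astype(bool)
    bad = df[~df["missing_flag"] & ~(df["reported_count"] > 0)]
    if not bad.empty:
        raise ValidationError(
            f"harvest table row {bad.index[0]}: field reported_count must be > 0 "
            "for non-missing reports"
        )
    return df


def load_trips(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRIP_COLUMNS, "trip table")
    for idx, row in df.iterrows():
        if row["mode"] not in TRIP_MODES:
            raise ValidationError(f"trip table row {idx}: field mode has unknown token {row['mode']!r}")
        if not row["participants"] >= 1:
            raise ValidationError(f"trip table row {idx}: field participants must be >= 1")
    df["success"] = df["success"].astype(bool)
    mismatch = df[df["success"] != (df["edible_kg"] > 0)]
    if not mismatch.empty:
        raise ValidationError(
            f"trip table row {mismatch.index[0]}: field success must equal (edible_kg > 0)"
        )
    return df


def write_summary_tables(summaries: Mapping[str, Sequence], out_dir: str | Path) -> dict[str, Path]:
    """Write one CSV per estimand from posterior summaries.

    ``summaries`` maps an estimand name (``weight``, ``value``,
    ``emissions_<scenario>``, ``fuel`` ...) to a sequence of
    :class:`~harvestcarbon.valuation.PosteriorSummary`.  Output is
    bit-stable given identical draws.
    """
    if not summaries:
        raise ValidationError("write_summary_tables: empty summary mapping")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, rows in summaries.items():
        if not rows:
            raise ValidationError(f"write_summary_tables: empty summary for {name!r}")
        df = pd.DataFrame(
            [
                {
                    "estimand": s.label,
                    "mean": s.mean,
                    "sd": s.sd,
                    "hpdi_low": s.hpdi_low,
                    "hpdi_high": s.hpdi_high,
                    "units": s.units,
                }
                for s in rows
            ]
        )
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path
    return paths
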