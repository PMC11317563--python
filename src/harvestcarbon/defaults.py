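"""Default study configuration for the Inuvialuit Settlement Region setting.

The real harvest-survey and trip datasets are access-restricted, so the
package ships a self-contained default configuration: a species table with
edible-weight conversion factors, per-community replacement prices, food
production and transport emission factors, shipping routes, and gasoline
constants.  Route distances and emission factors are illustrative values on
the scale reported in the transport and food life-cycle literature; they are
configuration inputs, not package claims.

All defaults are plain Python structures written to CSV/YAML on demand, so a
bare ``harvestcarbon simulate`` produces a complete, runnable data directory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

COMMUNITIES = [
    "Aklavik",
    "Inuvik",
    "Paulatuk",
    "Sachs Harbour",
    "Tuktoyaktuk",
    "Ulukhaktok",
]

# Share of harvest reports attributed to each community (Inuvik largest).
COMMUNITY_WEIGHTS = {
    "Aklavik": 0.17,
    "Inuvik": 0.28,
    "Paulatuk": 0.10,
    "Sachs Harbour": 0.07,
    "Tuktoyaktuk": 0.21,
    "Ulukhaktok": 0.17,
}

# species_code, species_type, taxon_class, edible_weight_kg_per_animal,
# replacement_category.  Edible weights follow published conversion-factor
# compilations for northern game and fish.
DEFAULT_SPECIES = [
    ("caribou", "caribou", "mammal", 41.0, "beef_pork_mix"),
    ("muskox", "muskox", "mammal", 92.0, "beef_pork_mix"),
    ("ringed_seal", "seals", "mammal", 22.0, "beef_pork_mix"),
    ("bearded_seal", "seals", "mammal", 94.0, "beef_pork_mix"),
    ("beluga", "whales", "mammal", 181.0, "beef_pork_mix"),
    ("broad_whitefish", "whitefish", "fish", 2.2, "fish_mix"),
    ("lake_whitefish", "whitefish", "fish", 1.3, "fish_mix"),
    ("inconnu", "inconnu", "fish", 4.5, "fish_mix"),
    ("arctic_char", "char", "fish", 2.0, "fish_mix"),
    ("lake_trout", "trout", "fish", 2.5, "fish_mix"),
    ("snow_goose", "geese", "bird", 1.8, "poultry"),
    ("canada_goose", "geese", "bird", 2.4, "poultry"),
    ("mallard", "ducks", "bird", 0.8, "poultry"),
    ("eider", "ducks", "bird", 1.0, "poultry"),
    ("ptarmigan", "ptarmigan", "bird", 0.35, "poultry"),
]

SPECIES_COLUMNS = [
    "species_code",
    "species_type",
    "taxon_class",
    "edible_weight_kg_per_animal",
    "replacement_category",
]

# Probability that a harvest report concerns each species.
DEFAULT_SPECIES_WEIGHTS = {
    "caribou": 0.18,
    "muskox": 0.05,
    "ringed_seal": 0.05,
    "bearded_seal": 0.01,
    "beluga": 0.01,
    "broad_whitefish": 0.14,
    "lake_whitefish": 0.05,
    "inconnu": 0.08,
    "arctic_char": 0.10,
    "lake_trout": 0.04,
    "snow_goose": 0.08,
    "canada_goose": 0.07,
    "mallard": 0.05,
    "eider": 0.04,
    "ptarmigan": 0.05,
}

# Per species_type (log_mean, log_sd) of the true-count distribution:
# single large mammals are taken in ones and twos, fish and birds in
# batches, which is what makes recalled counts heap on round numbers.
DEFAULT_TYPE_LOG_PARAMS = {
    "caribou": (0.6, 0.7),
    "muskox": (0.3, 0.6),
    "seals": (0.7, 0.8),
    "whales": (0.0, 0.4),
    "whitefish": (2.3, 1.0),
    "inconnu": (2.0, 1.0),
    "char": (2.2, 1.0),
    "trout": (1.8, 0.9),
    "geese": (2.0, 1.0),
    "ducks": (1.8, 0.9),
    "ptarmigan": (1.5, 0.8),
}

# CAD per kg of market replacement food, by community and category
# (lowest regular prices for preferred purchase volumes; remoter
# communities pay more).
DEFAULT_PRICES = {
    "Aklavik": {"poultry": 13.6, "fish_mix": 32.5, "beef_pork_mix": 25.5},
    "Inuvik": {"poultry": 12.0, "fish_mix": 29.5, "beef_pork_mix": 23.5},
    "Paulatuk": {"poultry": 14.5, "fish_mix": 34.5, "beef_pork_mix": 27.0},
    "Sachs Harbour": {"poultry": 15.0, "fish_mix": 35.5, "beef_pork_mix": 28.0},
    "Tuktoyaktuk": {"poultry": 13.0, "fish_mix": 31.5, "beef_pork_mix": 25.0},
    "Ulukhaktok": {"poultry": 15.0, "fish_mix": 35.0, "beef_pork_mix": 27.5},
}

DEFAULT_CONFIG = {
    "cpi_factor": 0.989,
    "default_community": "Inuvik",
    # to-the-retail production emission factors, kg CO2e per kg edible
    "production_ef": {
        "poultry": 2.8,
        "fish_mix": 3.5,  # 70/30 whitefish/salmonid blend folded into one factor
        "beef_pork_mix": 12.5,  # 50/50 beef-pork blend
    },
    # kg CO2e per kg freight per km, low/high endpoints by transport mode
    "transport_ef": {
        "road": {"low": 0.00008, "high": 0.00018},
        "rail": {"low": 0.00001, "high": 0.00005},
        "barge": {"low": 0.00001, "high": 0.00006},
        "air": {"low": 0.00060, "high": 0.00160},
    },
    # replacement-food shipping: road south to the railhead/river then barge
    # down the Mackenzie, versus road up the Dempster then air to the
    # fly-in communities
    "routes": {
        "barge": {
            "Aklavik": [["road", 980], ["barge", 1860]],
            "Inuvik": [["road", 980], ["barge", 1800]],
            "Paulatuk": [["road", 980], ["barge", 2300]],
            "Sachs Harbour": [["road", 980], ["barge", 2400]],
            "Tuktoyaktuk": [["road", 980], ["barge", 1940]],
            "Ulukhaktok": [["road", 980], ["barge", 2600]],
        },
        "foodmail": {
            "Aklavik": [["road", 3500], ["air", 60]],
            "Inuvik": [["road", 3500]],
            "Paulatuk": [["road", 3500], ["air", 400]],
            "Sachs Harbour": [["road", 3500], ["air", 520]],
            "Tuktoyaktuk": [["road", 3650]],
            "Ulukhaktok": [["road", 3500], ["air", 560]],
        },
    },
    "fuel": {
        "gasoline_density_kg_per_l": 0.749,
        "combustion_ef_kg_per_l": 2.319,
        "fuel_price_cad_per_l": 1.76,
        # gasoline travels by rail to the river port then by barge
        "routes": {
            "Aklavik": [["rail", 2700], ["barge", 1860]],
            "Inuvik": [["rail", 2700], ["barge", 1800]],
            "Paulatuk": [["rail", 2700], ["barge", 2300]],
            "Sachs Harbour": [["rail", 2700], ["barge", 2400]],
            "Tuktoyaktuk": [["rail", 2700], ["barge", 1940]],
            "Ulukhaktok": [["rail", 2700], ["barge", 2600]],
        },
    },
}

# Trip-process truth used by the synthetic generator: success probability,
# log-log fuel regression, and the failed-trip log-fuel distribution.
DEFAULT_TRIP_TRUTH = {
    "theta_true": 0.75,
    "intercept_true": 2.0,
    "slope_true": 0.5,
    "resid_sd_true": 0.5,
    "failed_fuel_log_mean": 3.8,
    "failed_fuel_log_sd": 0.5,
    "kg_log_mean": 3.0,
    "kg_log_sd": 0.9,
}

N_REPORTS_DEFAULT = 2388
N_MISSING_DEFAULT = 64
N_TRIPS_DEFAULT = 132


def species_frame() -> pd.DataFrame:
    return pd.DataFrame(DEFAULT_SPECIES, columns=SPECIES_COLUMNS)


def prices_frame() -> pd.DataFrame:
    rows = [
        (community, category, price)
        for community, cats in DEFAULT_PRICES.items()
        for category, price in cats.items()
    ]
    return pd.DataFrame(rows, columns=["community", "replacement_category", "price_cad_per_kg"])


def write_default_inputs(out_dir: str | Path) -> dict[str, Path]:
    """Write species.csv, prices.csv and config.yaml into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": out / "species.csv",
        "prices": out / "prices.csv",
        "config": out / "config.yaml",
    }
    species_frame().to_csv(paths["species"], index=False)
    prices_frame().to_csv(paths["prices"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)
    return paths
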