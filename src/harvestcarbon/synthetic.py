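"""Synthetic harvest-report and trip generators with known ground truth.

The generators reproduce the statistical structure the estimation pipeline
assumes: recall-survey counts drawn lognormally per species type and then
*heaped* onto round numbers (multiples of 5, 10, or 50, with coarser
rounding for larger counts), a completely-at-random missingness mechanism
emulating data-entry errors, and harvesting trips with Bernoulli success,
a log-log fuel-vs-harvest relationship for successful trips, and lognormal
fuel on failed trips.  Every generated dataset carries its ground truth so
recovery and calibration tests have an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .config_io import TRIP_MODES, validate_species

__all__ = [
    "HeapRule",
    "SyntheticTruth",
    "heap",
    "simulate_harvest_reports",
    "simulate_trips",
    "divide_group_harvests",
]


@dataclass(frozen=True)
class HeapRule:
    """Graded rounding rule for recalled counts.

    Counts below ``threshold_small`` are reported exactly (nearest integer,
    minimum 1); above it, counts round to the nearest multiple of 5, then
    10 from ``band_10`` up, then 50 from ``band_50`` up — so larger
    estimates are more heaped than smaller ones.  The real mechanism is
    unobserved; this rule is a fixture convention, which is why ground
    truth is always retained.
    """

    threshold_small: float = 5.0
    band_10: float = 100.0
    band_50: float = 250.0


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside a generated dataset."""

    seed: int
    true_counts: dict[int, float] = field(default_factory=dict)  # report_id -> true count
    type_log_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    theta_true: float | None = None
    intercept_true: float | None = None
    slope_true: float | None = None
    resid_sd_true: float | None = None
    failed_fuel_log_mean: float | None = None
    failed_fuel_log_sd: float | None = None

    def __post_init__(self) -> None:
        for name, (_, sd) in self.type_log_params.items():
            if not sd > 0:
                raise ValueError(f"type_log_params[{name!r}]: log_sd must be > 0")
        if self.theta_true is not None and not 0 < self.theta_true < 1:
            raise ValueError(f"theta_true must be in (0, 1), got {self.theta_true}")

    def total_true_weight(self, reports: pd.DataFrame, species: pd.DataFrame) -> float:
        """True total edible weight (kg) of a generated harvest table."""
        weights = species.set_index("species_code")["edible_weight_kg_per_animal"]
        per_animal = reports["species_code"].map(weights).to_numpy()
        counts = reports["report_id"].map(self.true_counts).to_numpy()
        return float(np.sum(per_animal * counts))

    def save(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["true_counts"] = {int(k): float(v) for k, v in self.true_counts.items()}
        payload["type_log_params"] = {
            k: [float(a), float(b)] for k, (a, b) in self.type_log_params.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["type_log_params"] = {
            k: (float(a), float(b)) for k, (a, b) in payload.get("type_log_params", {}).items()
        }
        return cls(**payload)


def heap(count, rule: HeapRule = HeapRule()):
    """Report a true count the way a recall survey would: heaped.

    Scalar or array input; scalars return a Python int.
    """
    x = np.asarray(count, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("heap: count must be > 0")
    exact = np.maximum(1, np.floor(x + 0.5))
    mult = np.where(x < rule.band_10, 5.0, np.where(x < rule.band_50, 10.0, 50.0))
    rounded = mult * np.floor(x / mult + 0.5)
    out = np.where(x < rule.threshold_small, exact, rounded)
    if np.isscalar(count) or np.ndim(count) == 0:
        return int(out)
    return out.astype(int)


def simulate_harvest_reports(
    species: pd.DataFrame,
    n_reports: int = defaults.N_REPORTS_DEFAULT,
    *,
    type_log_params: dict[str, tuple[float, float]] | None = None,
    species_weights: dict[str, float] | None = None,
    missing_frac: float = defaults.N_MISSING_DEFAULT / defaults.N_REPORTS_DEFAULT,
    seed: int = 0,
    heap_rule: HeapRule = HeapRule(),
    communities: list[str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a heaped recall-survey table plus its ground truth.

    True counts are lognormal per species type; reported counts are
    ``heap(true)``; exactly ``round(missing_frac * n_reports)`` reports are
    blanked and flagged missing (chosen completely at random, emulating
    data-entry errors unrelated to harvest size).
    """
    if species.empty:
        raise ValueError("simulate_harvest_reports: species table is empty")
    if not n_reports > 0:
        raise ValueError("simulate_harvest_reports: n_reports must be > 0")
    if not 0 <= missing_frac < 1:
        raise ValueError("simulate_harvest_reports: missing_frac must be in [0, 1)")
    species = validate_species(species)
    type_log_params = dict(type_log_params or defaults.DEFAULT_TYPE_LOG_PARAMS)
    species_weights = dict(species_weights or defaults.DEFAULT_SPECIES_WEIGHTS)
    communities = communities or defaults.COMMUNITIES

    rng = np.random.default_rng(seed)
    codes = [c for c in species["species_code"] if species_weights.get(c, 0) > 0]
    probs = np.array([species_weights[c] for c in codes])
    probs = probs / probs.sum()
    chosen = rng.choice(len(codes), size=n_reports, p=probs)
    code_arr = np.array(codes)[chosen]
    type_of = species.set_index("species_code")["species_type"]
    types = type_of.loc[code_arr].to_numpy()

    mu = np.array([type_log_params[t][0] for t in types])
    sd = np.array([type_log_params[t][1] for t in types])
    true_counts = np.exp(mu + sd * rng.standard_normal(n_reports))
    reported = heap(true_counts, heap_rule).astype(float)

    comm_names = [c for c in communities]
    comm_probs = np.array([defaults.COMMUNITY_WEIGHTS.get(c, 1.0) for c in comm_names])
    comm_probs = comm_probs / comm_probs.sum()
    community = rng.choice(comm_names, size=n_reports, p=comm_probs)
    month = rng.integers(1, 13, size=n_reports)

    n_missing = int(round(missing_frac * n_reports))
    missing_idx = rng.permutation(n_reports)[:n_missing]
    missing_flag = np.zeros(n_reports, dtype=bool)
    missing_flag[missing_idx] = True
    reported[missing_flag] = np.nan

    report_ids = np.arange(1, n_reports + 1)
    df = pd.DataFrame(
        {
            "report_id": report_ids,
            "community": community,
            "month": month,
            "species_code": code_arr,
            "reported_count": reported,
            "missing_flag": missing_flag,
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        true_counts={int(i): float(t) for i, t in zip(report_ids, true_counts)},
        type_log_params={k: tuple(v) for k, v in type_log_params.items()},
    )
    return df, truth


def simulate_trips(
    n_trips: int = defaults.N_TRIPS_DEFAULT,
    *,
    theta_true: float = defaults.DEFAULT_TRIP_TRUTH["theta_true"],
    intercept_true: float = defaults.DEFAULT_TRIP_TRUTH["intercept_true"],
    slope_true: float = defaults.DEFAULT_TRIP_TRUTH["slope_true"],
    resid_sd_true: float = defaults.DEFAULT_TRIP_TRUTH["resid_sd_true"],
    failed_fuel_log_mean: float = defaults.DEFAULT_TRIP_TRUTH["failed_fuel_log_mean"],
    failed_fuel_log_sd: float = defaults.DEFAULT_TRIP_TRUTH["failed_fuel_log_sd"],
    kg_log_mean: float = defaults.DEFAULT_TRIP_TRUTH["kg_log_mean"],
    kg_log_sd: float = defaults.DEFAULT_TRIP_TRUTH["kg_log_sd"],
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a trip table with Bernoulli success and log-log fuel scaling.

    ``theta_true = 1`` is allowed (no failed trips); otherwise theta must be
    in (0, 1].
    """
    if not n_trips > 0:
        raise ValueError("simulate_trips: n_trips must be > 0")
    if not 0 < theta_true <= 1:
        raise ValueError(f"simulate_trips: theta_true must be in (0, 1], got {theta_true}")
    rng = np.random.default_rng(seed)
    success = rng.random(n_trips) < theta_true
    kg = np.where(
        success,
        np.exp(kg_log_mean + kg_log_sd * rng.standard_normal(n_trips)),
        0.0,
    )
    noise = resid_sd_true * rng.standard_normal(n_trips)
    fuel_success = np.exp(intercept_true + slope_true * np.log(np.where(kg > 0, kg, 1.0)) + noise)
    fuel_failed = np.exp(failed_fuel_log_mean + failed_fuel_log_sd * rng.standard_normal(n_trips))
    fuel = np.where(success, fuel_success, fuel_failed)
    mode = rng.choice(TRIP_MODES, size=n_trips, p=[0.3, 0.5, 0.2])
    participants = 1 + rng.poisson(0.8, size=n_trips)
    df = pd.DataFrame(
        {
            "trip_id": np.arange(1, n_trips + 1),
            "mode": mode,
            "participants": participants,
            "fuel_l": fuel,
            "edible_kg": kg,
            "success": success,
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        # theta=1 (no failures) is stored as None: the truth invariant keeps
        # theta strictly inside (0, 1)
        theta_true=theta_true if theta_true < 1 else None,
        intercept_true=intercept_true,
        slope_true=slope_true,
        resid_sd_true=resid_sd_true,
        failed_fuel_log_mean=failed_fuel_log_mean,
        failed_fuel_log_sd=failed_fuel_log_sd,
    )
    return df, truth


def divide_group_harvests(trips: pd.DataFrame) -> pd.DataFrame:
    """Convert group-reported harvests to per-machine harvests.

    Snowmobile and ATV trips report the group's harvest but individual
    expenses, so the harvest is divided by the participant count (as if
    each participant ran their own machine).  Boat trips keep the total
    harvest: one boat carries the whole party.
    """
    if (trips["participants"] < 1).any():
        bad = trips.index[trips["participants"] < 1][0]
        raise ValueError(f"divide_group_harvests: row {bad}: participants must be >= 1")
    out = trips.copy()
    shared = out["mode"].isin(["snowmobile", "atv"])
    out.loc[shared, "edible_kg"] = out.loc[shared, "edible_kg"] / out.loc[shared, "participants"]
    return out
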