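import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harvestcarbon.config_io import EmissionScenario, PriceTable, ValidationError
from harvestcarbon.deheap import DeheapConfig, DeheapPosterior, fit_deheap
from harvestcarbon.valuation import (
    aggregate_by_class,
    edible_weight_draws,
    hpdi,
    replacement_emissions,
    substitution_value,
    summarize,
    summarize_by_class,
)


def brute_force_hpdi(x, mass=0.9):
    """Independent oracle: try every window of floor(mass*n)+1 sorted points."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    span = int(np.floor(mass * n))
    best = None
    for j in range(n - span):
        width = x[j + span] - x[j]
        if best is None or width < best[0]:
            best = (width, x[j], x[j + span])
    return best[1], best[2]


def _reports(codes, communities=None):
    n = len(codes)
    return pd.DataFrame(
        {
            "report_id": np.arange(1, n + 1),
            "community": communities or ["Inuvik"] * n,
            "month": [1] * n,
            "species_code": codes,
            "reported_count": [2.0] * n,
            "missing_flag": [False] * n,
        }
    )


def _posterior(draws, report_ids):
    n_draws, n_rep = draws.shape
    return DeheapPosterior(
        report_ids=np.asarray(report_ids),
        draws=draws,
        log_mean=np.log(draws).mean(axis=0),
        log_sd=np.log(draws).std(axis=0),
        rhat=np.ones(n_rep),
        ess=np.full(n_rep, 1000.0),
        missing_mask=np.zeros(n_rep, dtype=bool),
        moments=None,
        config=DeheapConfig(),
    )


class TestEdibleWeight:
    def test_count_times_per_animal_weight(self, tiny_species):
        reports = _reports(["caribou", "goose"])
        post = _posterior(np.array([[2.0, 3.0], [1.0, 5.0]]), [1, 2])
        kg = edible_weight_draws(post, reports, tiny_species)
        np.testing.assert_allclose(kg, [[80.0, 6.0], [40.0, 10.0]])

    def test_class_totals_sum_to_grand_total_every_draw(self, species, small_survey):
        reports, _ = small_survey
        post = fit_deheap(reports, species, DeheapConfig(seed=21, iterations=1000))
        kg = edible_weight_draws(post, reports, species)
        agg = aggregate_by_class(kg, reports, species)
        np.testing.assert_allclose(
            agg["bird"] + agg["fish"] + agg["mammal"], agg["total"], rtol=1e-12
        )

    def test_unresolved_species_is_an_error(self, tiny_species):
        reports = _reports(["caribou", "walrus"])
        post = _posterior(np.ones((3, 2)), [1, 2])
        with pytest.raises(ValidationError, match="walrus"):
            edible_weight_draws(post, reports, tiny_species)


class TestSubstitutionValue:
    def _prices(self, cpi=0.989):
        rows = [
            ("Inuvik", "poultry", 12.0),
            ("Inuvik", "fish_mix", 26.0),
            ("Inuvik", "beef_pork_mix", 24.0),
        ]
        return PriceTable(
            prices=pd.DataFrame(
                rows, columns=["community", "replacement_category", "price_cad_per_kg"]
            ),
            cpi_factor=cpi,
        )

    def test_kg_times_price_times_cpi(self, tiny_species):
        reports = _reports(["char"])
        kg = np.array([[10.0]])
        out = substitution_value(kg, self._prices(), reports, tiny_species)
        assert out["total"][0] == pytest.approx(10 * 26.0 * 0.989)  # 257.14

    def test_unit_cpi_is_plain_product(self, tiny_species):
        reports = _reports(["char"])
        out = substitution_value(np.array([[10.0]]), self._prices(cpi=1.0), reports, tiny_species)
        assert out["total"][0] == pytest.approx(260.0)

    def test_price_scale_equivariance(self, tiny_species):
        reports = _reports(["char", "goose", "caribou"])
        kg = np.abs(np.random.default_rng(0).normal(5, 1, (20, 3)))
        base = substitution_value(kg, self._prices(), reports, tiny_species)
        doubled_prices = self._prices()
        doubled = PriceTable(
            prices=doubled_prices.prices.assign(
                price_cad_per_kg=doubled_prices.prices["price_cad_per_kg"] * 2
            ),
            cpi_factor=0.989,
        )
        out2 = substitution_value(kg, doubled, reports, tiny_species)
        np.testing.assert_allclose(out2["total"], 2 * base["total"])

    def test_missing_price_cell_is_an_error(self, tiny_species):
        reports = _reports(["char"], communities=["Inuvik"])
        prices = PriceTable(
            prices=pd.DataFrame(
                [("Inuvik", "poultry", 12.0)],
                columns=["community", "replacement_category", "price_cad_per_kg"],
            ),
            cpi_factor=1.0,
        )
        with pytest.raises(ValidationError, match="fish_mix"):
            substitution_value(np.ones((2, 1)), prices, reports, tiny_species)


class TestReplacementEmissions:
    def _scenario(self, label="barge_low", production=15.0, road_ef=0.0001, km=3000):
        return EmissionScenario(
            label=label,
            production_ef={c: production for c in ("poultry", "fish_mix", "beef_pork_mix")},
            route_legs={"Inuvik": [("road", km)]} if km else {"Inuvik": []},
            transport_ef={"road": road_ef},
        )

    def test_production_plus_route_arithmetic(self, tiny_species):
        reports = _reports(["char"])
        out = replacement_emissions(np.array([[1.0]]), self._scenario(), reports, tiny_species)
        assert out["total"][0] == pytest.approx(15.3)  # 15 + 3000*0.0001

    def test_zero_length_route_leaves_production_only(self, tiny_species):
        reports = _reports(["char"])
        out = replacement_emissions(
            np.array([[1.0]]), self._scenario(km=0), reports, tiny_species
        )
        assert out["total"][0] == pytest.approx(15.0)

    def test_scenario_monotone_in_emission_factors(self, bundle, species, small_survey):
        """With every food-mail-high leg factor >= its barge-low counterpart
        (true of the shipped config), totals are ordered."""
        reports, _ = small_survey
        kg = np.abs(np.random.default_rng(1).normal(5, 1, (10, len(reports))))
        low = replacement_emissions(kg, bundle.scenarios["barge_low"], reports, species)
        high = replacement_emissions(kg, bundle.scenarios["foodmail_high"], reports, species)
        assert (high["total"] >= low["total"]).all()

    def test_missing_route_is_an_error(self, tiny_species):
        reports = _reports(["char"], communities=["Paulatuk"])
        with pytest.raises(ValidationError, match="Paulatuk"):
            replacement_emissions(np.ones((2, 1)), self._scenario(), reports, tiny_species)


class TestHpdi:
    def test_uniform_grid_shortest_window(self):
        lo, hi = hpdi(np.arange(1, 101), 0.9)
        assert (lo, hi) == (1.0, 91.0)

    def test_constant_draws_degenerate_interval(self):
        lo, hi = hpdi(np.full(50, 3.3), 0.9)
        assert lo == hi == 3.3

    def test_matches_brute_force_on_corpus(self):
        rng = np.random.default_rng(42)
        corpus = [
            rng.normal(size=11),
            rng.normal(size=200),
            rng.lognormal(1, 0.8, size=150),
            rng.uniform(-5, 5, size=57),
            np.concatenate([rng.normal(-3, 0.5, 60), rng.normal(3, 0.5, 40)]),
            rng.integers(0, 8, size=120).astype(float),  # heavy ties
        ]
        for x in corpus:
            for mass in (0.5, 0.9, 0.95):
                assert hpdi(x, mass) == brute_force_hpdi(x, mass)

    def test_near_central_interval_for_symmetric_samples(self):
        x = np.random.default_rng(3).normal(0, 1, 5000)
        lo, hi = hpdi(x, 0.9)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert lo == pytest.approx(qlo, abs=0.15)
        assert hi == pytest.approx(qhi, abs=0.15)

    def test_matches_arviz_convention(self):
        import arviz as az

        x = np.random.default_rng(9).normal(size=500)
        lo, hi = hpdi(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=1e-8)
        assert hi == pytest.approx(ref[1], abs=1e-8)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(5), 0.9)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=10, max_size=200),
        st.sampled_from([0.5, 0.8, 0.9, 0.95]),
    )
    def test_property_contains_required_mass(self, xs, mass):
        x = np.asarray(xs)
        lo, hi = hpdi(x, mass)
        assert lo <= hi
        inside = np.sum((x >= lo) & (x <= hi))
        assert inside >= int(np.floor(mass * x.size)) + 1
        assert (lo, hi) == brute_force_hpdi(x, mass)


class TestSummarize:
    def test_constant_draws(self):
        s = summarize(np.full(20, 7.0), "total", "kg")
        assert (s.mean, s.sd, s.hpdi_low, s.hpdi_high) == (7.0, 0.0, 7.0, 7.0)

    def test_total_mean_is_sum_of_class_means(self, species, small_survey):
        reports, _ = small_survey
        post = fit_deheap(reports, species, DeheapConfig(seed=22, iterations=1000))
        kg = edible_weight_draws(post, reports, species)
        rows = summarize_by_class(aggregate_by_class(kg, reports, species), "kg")
        by_label = {r.label: r for r in rows}
        assert by_label["total"].mean == pytest.approx(
            by_label["bird"].mean + by_label["fish"].mean + by_label["mammal"].mean
        )
        assert [r.label for r in rows] == ["bird", "fish", "mammal", "total"]

    def test_seeded_normal_mean_within_3_se(self):
        x = np.random.default_rng(17).normal(10, 2, 4000)
        s = summarize(x, "x", "u")
        assert abs(s.mean - 10) < 3 * 2 / np.sqrt(4000)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.array([]), "x", "u")


def test_linearity_weight_scaling_propagates(tiny_species):
    """Scaling every edible weight by c scales all downstream means by c."""
    reports = _reports(["caribou", "goose", "char"])
    draws = np.abs(np.random.default_rng(2).normal(3, 1, (30, 3)))
    post = _posterior(draws, [1, 2, 3])
    kg = edible_weight_draws(post, reports, tiny_species)
    scaled = tiny_species.assign(
        edible_weight_kg_per_animal=tiny_species["edible_weight_kg_per_animal"] * 2.5
    )
    kg2 = edible_weight_draws(post, reports, scaled)
    np.testing.assert_allclose(kg2, 2.5 * kg)
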