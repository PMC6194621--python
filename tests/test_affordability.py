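"""Affordability: treatment costing, grouped-income reconstruction, CDE incidence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from medaccess import (
    DrugDefinition,
    IncomeDistribution,
    IncomeGroupTable,
    annualize,
    cde_incidence,
    cde_table,
    daily_cost,
    fit_income_distribution,
)
from medaccess.affordability import lognormal_group_means

import pandas as pd


def lognormal_dist(mu, sigma, year=2013, sector="urban"):
    frozen = stats.lognorm(s=sigma, scale=np.exp(mu))
    return IncomeDistribution(year, sector, frozen.cdf, frozen.ppf,
                              {"mu": mu, "sigma": sigma})


def quintile_table(mu, sigma, year=2013, sector="urban"):
    shares = np.full(5, 0.2)
    means = lognormal_group_means(mu, sigma, shares)
    return IncomeGroupTable(year, sector, tuple(shares), tuple(float(m) for m in means))


class TestTreatmentCost:
    def test_two_units_per_day(self):
        d = DrugDefinition("metformin", "antidiabetic", "chronic", True,
                           250.0, "mg", 500.0, "mg")
        assert daily_cost(0.5, d) == pytest.approx(1.0)

    def test_ddd_equal_to_reference_strength_is_identity(self, amoxicillin):
        d = DrugDefinition("omeprazole", "gastro", "acute", True,
                           20.0, "mg", 20.0, "mg")
        assert daily_cost(3.7, d) == pytest.approx(3.7)

    def test_random_tuples_match_per_mg_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ref, ddd, price = rng.uniform(1, 1000), rng.uniform(1, 3000), rng.uniform(0.01, 20)
            d = DrugDefinition("x", "c", "chronic", True, ref, "mg", ddd, "mg")
            per_mg = price / ref
            assert daily_cost(price, d) == pytest.approx(per_mg * ddd, rel=1e-12)

    def test_unit_mismatch_handled_via_conversion(self):
        d = DrugDefinition("x", "c", "chronic", True, 500.0, "mg", 1.0, "g")
        assert daily_cost(2.0, d) == pytest.approx(4.0)

    def test_annualize(self):
        assert annualize(1.0) == 365.0
        assert annualize(0.0) == 0.0
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10)
        assert annualize(x) == pytest.approx(x * 365.0)
        with pytest.raises(ValueError):
            annualize(-1.0)


class TestIncomeFit:
    def test_lognormal_recovery_from_analytic_quintiles(self):
        table = quintile_table(9.2, 0.6)
        dist = fit_income_distribution(table, "lognormal")
        assert dist.params["mu"] == pytest.approx(9.2, abs=0.05)
        assert dist.params["sigma"] == pytest.approx(0.6, abs=0.05)
        assert dist.params["rms_relative_residual"] < 1e-4

    def test_single_group_fixed_sigma_median_identity(self):
        m, sigma = 20000.0, 0.5
        table = IncomeGroupTable(2013, "urban", (1.0,), (m,))
        dist = fit_income_distribution(table, "lognormal", sigma=sigma)
        # lognormal mean-median identity: median = mean * exp(-sigma^2/2)
        assert dist.quantile(0.5) == pytest.approx(m * np.exp(-sigma**2 / 2), rel=1e-9)

    def test_degenerate_small_sigma_approaches_step(self):
        m = 10000.0
        table = IncomeGroupTable(2013, "rural", (1.0,), (m,))
        dist = fit_income_distribution(table, "lognormal", sigma=1e-6)
        assert dist.cdf(m * 0.999) < 1e-6
        assert dist.cdf(m * 1.001) > 1 - 1e-6

    def test_non_increasing_group_means_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            IncomeGroupTable(2013, "urban", (0.5, 0.5), (100.0, 100.0))

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            IncomeGroupTable(2013, "urban", (0.5, 0.4), (100.0, 200.0))

    def test_cdf_quantile_round_trip_both_methods(self):
        table = quintile_table(9.0, 0.5)
        ps = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
        for method in ("lognormal", "piecewise"):
            dist = fit_income_distribution(table, method)
            xs = dist.quantile(ps)          # points on the fitted support
            np.testing.assert_allclose(dist.cdf(xs), ps, atol=1e-9)
            np.testing.assert_allclose(dist.quantile(dist.cdf(xs)), xs, rtol=1e-9)

    def test_piecewise_reproduces_group_means_exactly(self):
        table = quintile_table(9.0, 0.5)
        dist = fit_income_distribution(table, "piecewise")
        # uniform blocks are centered on the group means ...
        mids = [0.5 * (lo + hi) for lo, hi in dist.params["intervals"]]
        np.testing.assert_allclose(mids, table.means[:-1], rtol=1e-12)
        # ... the Pareto tail mean matches the top group mean ...
        a, xm = dist.params["pareto_alpha"], dist.params["pareto_xm"]
        assert a > 1.0
        assert a * xm / (a - 1) == pytest.approx(table.means[-1], rel=1e-12)
        # ... and the cdf reaches the cumulative shares at the block tops
        tops = np.array([hi for _, hi in dist.params["intervals"]])
        np.testing.assert_allclose(dist.cdf(tops), [0.2, 0.4, 0.6, 0.8], atol=1e-12)

    def test_fit_residual_warning_recorded_for_non_lognormal_table(self):
        table = IncomeGroupTable(2013, "urban", (0.25, 0.25, 0.25, 0.25),
                                 (100.0, 101.0, 102.0, 100000.0))
        dist = fit_income_distribution(table, "lognormal")
        assert "warning" in dist.params


class TestCDEIncidence:
    def test_zero_cost_is_zero(self):
        assert cde_incidence(0.0, lognormal_dist(9.0, 0.5), 0.10) == 0.0

    def test_cost_above_all_incomes_is_hundred(self):
        dist = lognormal_dist(np.log(10000.0), 1e-9)  # near-step at 10000
        assert cde_incidence(2000.0, dist, 0.10) == pytest.approx(100.0)

    def test_closed_form_symmetry_point(self):
        """cost 1000 at threshold 0.1 puts the cut at the median income
        e^mu = 10000, so exactly half the population crosses."""
        dist = lognormal_dist(np.log(10000.0), 0.5)
        assert cde_incidence(1000.0, dist, 0.10) == pytest.approx(50.0)

    def test_matches_lognormal_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            mu, sigma = rng.uniform(8, 11), rng.uniform(0.2, 1.0)
            c, tau = rng.uniform(10, 5000), rng.uniform(0.05, 0.3)
            expected = 100 * stats.norm.cdf((np.log(c / tau) - mu) / sigma)
            got = cde_incidence(c, lognormal_dist(mu, sigma), tau)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_cost_below_threshold_times_minimum_income_is_zero(self):
        """A cheap generic never triggers catastrophic spending when even the
        poorest group's income dwarfs cost/threshold (bounded-support
        reconstruction)."""
        table = quintile_table(10.0, 0.4)
        dist = fit_income_distribution(table, "piecewise")
        cheap_annual = 40.0   # cost/tau = 400 << all incomes
        assert cde_incidence(cheap_annual, dist, 0.10) == 0.0

    def test_invalid_threshold_errors(self):
        dist = lognormal_dist(9.0, 0.5)
        for tau in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="threshold"):
                cde_incidence(100.0, dist, tau)

    @given(
        cost=st.floats(1.0, 1e5),
        mu=st.floats(8.0, 11.0),
        sigma=st.floats(0.1, 1.2),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_nonincreasing_in_threshold(self, cost, mu, sigma):
        dist = lognormal_dist(mu, sigma)
        inc = [cde_incidence(cost, dist, tau) for tau in (0.075, 0.10, 0.125)]
        assert inc[0] >= inc[1] >= inc[2]

    @given(
        costs=st.tuples(st.floats(1.0, 1e5), st.floats(1.0, 1e5)),
        mu=st.floats(8.0, 11.0),
        sigma=st.floats(0.1, 1.2),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_nondecreasing_in_cost(self, costs, mu, sigma):
        dist = lognormal_dist(mu, sigma)
        lo, hi = sorted(costs)
        assert cde_incidence(lo, dist, 0.10) <= cde_incidence(hi, dist, 0.10)

    def test_rural_incidence_exceeds_urban_at_lower_mean_income(self):
        """With equal dispersion and lower rural mean income, rural incidence
        is at least urban incidence for any cost."""
        urban = fit_income_distribution(quintile_table(10.0, 0.5, sector="urban"))
        rural = fit_income_distribution(quintile_table(9.0, 0.5, sector="rural"))
        for cost in (100.0, 1000.0, 5000.0):
            assert (cde_incidence(cost, rural, 0.10)
                    >= cde_incidence(cost, urban, 0.10))


class TestCDETable:
    def test_equals_independent_composition(self):
        d = DrugDefinition("metformin", "antidiabetic", "chronic", True,
                           500.0, "mg", 2000.0, "mg")
        prices = pd.DataFrame({
            "drug_id": ["metformin"] * 2,
            "brand_status": ["generic", "innovator_brand"],
            "year": [2013, 2013],
            "median_unit_price": [0.4, 2.1],
        })
        dists = {
            (2013, "urban"): lognormal_dist(10.0, 0.5, 2013, "urban"),
            (2013, "rural"): lognormal_dist(9.0, 0.6, 2013, "rural"),
        }
        table = cde_table(prices, {"metformin": d}, dists)
        assert len(table) == 2 * 2 * 3
        for row in table.itertuples(index=False):
            price = prices.loc[
                prices.brand_status == row.brand_status, "median_unit_price"
            ].iloc[0]
            annual = annualize(daily_cost(price, d))
            expected = cde_incidence(annual, dists[(row.year, row.sector)], row.threshold)
            assert row.incidence_pct == pytest.approx(expected)
        # thresholds monotone within every (brand, sector) block
        for _, grp in table.groupby(["brand_status", "sector"]):
            inc = grp.sort_values("threshold")["incidence_pct"].to_numpy()
            assert (np.diff(inc) <= 1e-12).all()

    def test_household_multiplier_reduces_incidence(self):
        d = DrugDefinition("x", "c", "chronic", True, 100.0, "mg", 100.0, "mg")
        prices = pd.DataFrame({
            "drug_id": ["x"], "brand_status": ["generic"], "year": [2013],
            "median_unit_price": [1.0],
        })
        dists = {(2013, "urban"): lognormal_dist(9.0, 0.5, 2013, "urban")}
        solo = cde_table(prices, {"x": d}, dists)
        household = cde_table(prices, {"x": d}, dists, household_size=3.0)
        assert (household["incidence_pct"] <= solo["incidence_pct"] + 1e-12).all()
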