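"""Estimator: rates, geometric-mean summaries, extrapolation, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bycatchrisk import estimator
from bycatchrisk.errors import AlignmentError, DataError
from bycatchrisk.estimator import (
    RateSummary,
    annual_summary,
    assemble_observer_series,
    compute_rates,
    extrapolate_bycatch,
    geometric_mean,
    percent_of_population,
    rate_trend_check,
    risk_indices,
    risk_map,
    summarize_rates,
    trend_test,
)


def _tables(t_b, t_p, f, species="kemps_ridley", gear="shrimp_trawl", year=2000,
            bin_=(25, -90)):
    bycatch = pd.DataFrame(
        [{"species": species, "gear": gear, "year": year, "bin_lat": bin_[0],
          "bin_lon": bin_[1], "count": t_b}]
    )
    ab = pd.DataFrame(
        [{"species": species, "year": year, "bin_lat": bin_[0], "bin_lon": bin_[1],
          "t_p": t_p}]
    )
    eff = pd.DataFrame(
        [{"gear": gear, "year": year, "bin_lat": bin_[0], "bin_lon": bin_[1],
          "effort": f, "unit": "km"}]
    )
    return bycatch, ab, eff


class TestComputeRates:
    @pytest.mark.parametrize(
        "t_b,t_p,f,expected",
        [(1, 1000.0, 1000.0, 1e-6), (2, 5e4, 4e3, 1e-8)],
    )
    def test_rate_arithmetic(self, t_b, t_p, f, expected):
        rates, excluded = compute_rates(*_tables(t_b, t_p, f))
        assert excluded.empty
        assert rates["rate"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_counts_never_enter(self):
        rates, excluded = compute_rates(*_tables(0, 1000.0, 1000.0))
        assert rates.empty and excluded.empty

    def test_undefined_rate_flagged_not_dropped(self):
        rates, excluded = compute_rates(*_tables(3, 0.0, 1000.0))
        assert rates.empty
        assert len(excluded) == 1
        assert excluded["t_b"].iloc[0] == 3

    def test_area_level_record_needs_membership(self):
        bycatch, ab, eff = _tables(1, 1000.0, 1000.0)
        bycatch.loc[0, ["bin_lat", "bin_lon"]] = np.nan
        bycatch["area_label"] = "TX"
        with pytest.raises(AlignmentError):
            compute_rates(bycatch, ab, eff, membership=None)
        rates, _ = compute_rates(
            bycatch, ab, eff, membership={"TX": [(25, -90), (26, -90)]}
        )
        assert rates["rate"].iloc[0] == pytest.approx(1e-6, rel=1e-12)

    def test_construction_oracle_recovers_q(self, demo_bundle):
        """Deterministic counts T_b = round(q*T_p*F) give back q within
        rounding for every constructed cell."""
        q = 2e-7
        ab = demo_bundle.abundance.query("species == 'kemps_ridley'").copy()
        eff = demo_bundle.effort.query("gear == 'shrimp_trawl'")
        merged = ab.merge(eff, on=["year", "bin_lat", "bin_lon"])
        merged["count"] = np.rint(q * merged["t_p"] * merged["effort"]).astype(int)
        merged = merged[merged["count"] >= 1]
        bycatch = merged.assign(species="kemps_ridley", gear="shrimp_trawl")[
            ["species", "gear", "year", "bin_lat", "bin_lon", "count"]
        ]
        rates, excluded = compute_rates(bycatch, ab, eff)
        assert excluded.empty and len(rates) == len(merged)
        lam = q * merged["t_p"].to_numpy() * merged["effort"].to_numpy()
        rounding = 0.5 / lam  # relative error bound from count rounding
        assert (np.abs(rates["rate"].to_numpy() / q - 1) <= rounding + 1e-12).all()


class TestSummarizeRates:
    def _rates(self, values, species="s", gear="g"):
        return pd.DataFrame(
            {
                "species": species,
                "gear": gear,
                "year": 2000,
                "unit": [f"u{i}" for i in range(len(values))],
                "rate": values,
            }
        )

    def test_all_equal_rates_undefined_bounds(self):
        (s,) = summarize_rates(self._rates([1e-6, 1e-6, 1e-6]))
        assert s.gm == pytest.approx(1e-6, rel=1e-12)
        assert s.lower is None and s.upper is None
        row = estimator.summary_table([s]).iloc[0]
        assert row["lower"] == "--" and row["upper"] == "--"

    def test_two_point_geometric_mean(self):
        (s,) = summarize_rates(self._rates([1e-6, 1e-8]))
        assert s.gm == pytest.approx(1e-7, rel=1e-12)
        assert s.lower == pytest.approx(1e-8, rel=1e-12)
        assert s.upper == pytest.approx(1e-6, rel=1e-12)

    def test_singleton_has_no_bounds(self):
        (s,) = summarize_rates(self._rates([5e-10]))
        assert s.n == 1 and s.lower is None and s.upper is None

    def test_log_space_oracle_50_lognormal(self):
        """GM of 50 seeded lognormal rates equals exp(mean(log q)) to 1e-12
        relative."""
        rng = np.random.default_rng(123)
        q = np.exp(rng.normal(-16, 2, size=50))
        (s,) = summarize_rates(self._rates(q))
        assert s.gm == pytest.approx(np.exp(np.log(q).mean()), rel=1e-12)
        assert s.lower <= s.gm <= s.upper

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        q = np.exp(rng.normal(-10, 1, size=20))
        (s1,) = summarize_rates(self._rates(q))
        (s2,) = summarize_rates(self._rates(rng.permutation(q)))
        assert s1.gm == pytest.approx(s2.gm, rel=1e-12)
        assert s1.lower == pytest.approx(s2.lower, rel=1e-12)

    def test_empty_group_absent(self):
        assert summarize_rates(self._rates([])) == []

    def test_geometric_mean_rejects_nonpositive(self):
        with pytest.raises(DataError):
            geometric_mean([1.0, 0.0])


class TestRiskIndices:
    def test_product(self):
        _, ab, eff = _tables(1, 10.0, 5.0)
        risk = risk_indices(ab, eff)
        assert risk["risk"].iloc[0] == 50.0

    def test_zero_factor_zero_risk(self):
        _, ab, eff = _tables(1, 0.0, 5.0)
        assert risk_indices(ab, eff)["risk"].iloc[0] == 0.0

    def test_multi_year_mean_and_log10(self):
        ab = pd.DataFrame(
            {"species": "s", "year": [2000, 2001], "bin_lat": 25, "bin_lon": -90,
             "t_p": [10.0, 30.0]}
        )
        eff = pd.DataFrame(
            {"gear": "g", "year": [2000, 2001], "bin_lat": 25, "bin_lon": -90,
             "effort": [2.0, 2.0], "unit": "km"}
        )
        rm = risk_map(risk_indices(ab, eff))
        assert rm["risk"].iloc[0] == pytest.approx((20 + 60) / 2)
        assert rm["log10_risk"].iloc[0] == pytest.approx(np.log10(40))
        # zero risk renders as missing on the log scale
        ab["t_p"] = 0.0
        rm0 = risk_map(risk_indices(ab, eff))
        assert np.isnan(rm0["log10_risk"].iloc[0])


class TestExtrapolation:
    def test_single_bin_identity(self):
        """Rate from one bin extrapolated over that bin returns T_b exactly."""
        bycatch, ab, eff = _tables(7, 123.0, 45.6)
        rates, _ = compute_rates(bycatch, ab, eff)
        summaries = summarize_rates(rates)
        est = extrapolate_bycatch(summaries, risk_indices(ab, eff))
        assert est["bycatch"].iloc[0] == pytest.approx(7.0, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance_in_abundance(self, demo_bundle, demo_result, c):
        """T_p -> c*T_p scales rates by 1/c and risk by c: B_y unchanged."""
        b = demo_bundle
        ab = b.abundance.copy()
        ab["t_p"] *= c
        rates, _ = compute_rates(b.bycatch, ab, b.effort, b.world.membership)
        est = extrapolate_bycatch(summarize_rates(rates), risk_indices(ab, b.effort))
        base = demo_result.estimates.set_index(["species", "gear", "year"])["bycatch"]
        scaled = est.set_index(["species", "gear", "year"])["bycatch"]
        assert np.allclose(scaled.loc[base.index], base, rtol=1e-9)

    def test_scale_equivariance_in_effort(self, demo_bundle, demo_result):
        b = demo_bundle
        eff = b.effort.copy()
        eff["effort"] *= 3.0
        rates, _ = compute_rates(b.bycatch, b.abundance, eff, b.world.membership)
        est = extrapolate_bycatch(
            summarize_rates(rates), risk_indices(b.abundance, eff)
        )
        base = demo_result.estimates.set_index(["species", "gear", "year"])["bycatch"]
        scaled = est.set_index(["species", "gear", "year"])["bycatch"]
        assert np.allclose(scaled.loc[base.index], base, rtol=1e-9)

    def test_arithmetic_mean_rates_upper_bound_gm_totals(self, demo_bundle,
                                                         demo_result):
        """AM >= GM, so totals from arithmetic-mean rates bound the GM-based
        totals from above (the estimator's lower-bound character)."""
        rates = demo_result.rates
        risk = demo_result.risk
        for s in demo_result.summaries:
            am = rates.query("species == @s.species and gear == @s.gear")[
                "rate"
            ].mean()
            assert am >= s.gm * (1 - 1e-12)


class TestAnnualSummary:
    def _est(self, values, species="s", gear="g"):
        return pd.DataFrame(
            {"species": species, "gear": gear,
             "year": 2000 + np.arange(len(values)), "bycatch": values,
             "bycatch_lower": values, "bycatch_upper": values}
        )

    def test_constant_series(self):
        out = annual_summary(self._est([100.0] * 5))
        assert out["gm_annual_bycatch"].iloc[0] == pytest.approx(100.0, rel=1e-12)

    def test_two_point(self):
        out = annual_summary(self._est([10.0, 1000.0]))
        assert out["gm_annual_bycatch"].iloc[0] == pytest.approx(100.0, rel=1e-12)

    def test_zero_years_excluded_not_degenerate(self):
        out = annual_summary(self._est([10.0, 0.0, 1000.0]))
        assert out["n_years"].iloc[0] == 2
        assert out["gm_annual_bycatch"].iloc[0] == pytest.approx(100.0, rel=1e-12)

    def test_log_space_oracle(self):
        rng = np.random.default_rng(9)
        b = np.exp(rng.normal(5, 1, size=15))
        out = annual_summary(self._est(b))
        assert out["gm_annual_bycatch"].iloc[0] == pytest.approx(
            np.exp(np.log(b).mean()), rel=1e-12
        )


class TestPercentOfPopulation:
    def test_simple_ratio(self):
        est = pd.DataFrame(
            [{"species": "s", "gear": "g", "year": 2000, "bycatch": 5.0,
              "bycatch_lower": 5.0, "bycatch_upper": 5.0}]
        )
        ab = pd.DataFrame(
            [{"species": "s", "year": 2000, "bin_lat": 25, "bin_lon": -90,
              "t_p": 1000.0}]
        )
        out = percent_of_population(est, ab)
        assert out["percent"].iloc[0] == pytest.approx(0.5)

    def test_zero_bycatch_zero_percent(self):
        est = pd.DataFrame(
            [{"species": "s", "gear": "g", "year": 2000, "bycatch": 0.0,
              "bycatch_lower": 0.0, "bycatch_upper": 0.0}]
        )
        ab = pd.DataFrame(
            [{"species": "s", "year": 2000, "bin_lat": 25, "bin_lon": -90,
              "t_p": 1000.0}]
        )
        assert percent_of_population(est, ab)["percent"].iloc[0] == 0.0


class TestTrends:
    def test_perfect_linear_trend(self):
        s = pd.Series({2000 + i: 10.0 + 2 * i for i in range(10)})
        out = trend_test(s)
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 10

    def test_constant_series_undefined(self):
        out = trend_test(pd.Series({2000 + i: 5.0 for i in range(5)}))
        assert np.isnan(out["r"]) and np.isnan(out["p"])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        years = np.arange(2000, 2020)
        vals = years * 0.3 + rng.normal(0, 2, years.size)
        out = trend_test(pd.Series(vals, index=years))
        # closed-form Pearson r and t-based two-sided p
        xm, ym = years - years.mean(), vals - vals.mean()
        r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        t = r * np.sqrt((years.size - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), years.size - 2)
        assert out["r"] == pytest.approx(r, rel=1e-12)
        assert out["p"] == pytest.approx(p, rel=1e-9)

    def _rates(self, years, values):
        return pd.DataFrame(
            {"species": "s", "gear": "g", "year": years,
             "unit": [f"u{i}" for i in range(len(years))], "rate": values}
        )

    def test_rate_trend_constant_r2_zero(self):
        out = rate_trend_check(self._rates([2000, 2001, 2002], [1e-6] * 3))
        assert out["r2"].iloc[0] == 0.0

    def test_rate_trend_exact_exponential_r2_one(self):
        years = np.arange(2000, 2010)
        out = rate_trend_check(self._rates(years, 1e-6 * np.exp(0.2 * (years - 2000))))
        assert out["r2"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_rate_trend_matches_ols_oracle(self):
        rng = np.random.default_rng(3)
        years = np.tile(np.arange(2000, 2010), 3)
        q = np.exp(rng.normal(-14, 1, years.size))
        out = rate_trend_check(self._rates(years, q))
        x, y = years.astype(float), np.log(q)
        beta = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        alpha = y.mean() - beta * x.mean()
        ss_res = ((y - alpha - beta * x) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert out["r2"].iloc[0] == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)
        assert out["n"].iloc[0] == years.size


class TestConditioningBias:
    def test_small_lambda_inflates_gm(self):
        """Observed-only rates at lambda < 1 overestimate q: every observed
        count is >= 1 while the mean is < 1, so GM >= q_true."""
        rng = np.random.default_rng(21)
        q_true = 1e-6
        t_p = np.full(400, 1e3)
        f = np.full(400, 500.0)  # lambda = 0.5 everywhere
        counts = rng.poisson(q_true * t_p * f)
        obs = counts > 0
        rates = pd.DataFrame(
            {"species": "s", "gear": "g", "year": 2000,
             "unit": [f"u{i}" for i in range(obs.sum())],
             "rate": counts[obs] / (t_p[obs] * f[obs])}
        )
        (s,) = summarize_rates(rates)
        assert s.gm >= q_true


class TestObserverSeries:
    def _raw(self):
        rows = []
        for year, med in [(2013, 10.0), (2014, 20.0), (2015, 30.0)]:
            rows.append(("kemps_ridley", year, "gulf", "standard", med, med - 5,
                         med + 5))
        rows.append(("kemps_ridley", 2016, "atlantic", "standard", 5.0, 3.0, 8.0))
        for year in (2013, 2014, 2015):
            rows.append(("kemps_ridley", year, "atlantic", "standard", 2.0, 1.0, 4.0))
        return pd.DataFrame(
            rows,
            columns=["species", "year", "basin", "net_class", "median", "ci_low",
                     "ci_high"],
        )

    def test_fill_rule_mean_of_prior_three(self):
        """Missing final Gulf year = mean of its prior three years."""
        out = assemble_observer_series(self._raw()).set_index("year")
        assert out.loc[2016, "median"] == pytest.approx((10 + 20 + 30) / 3 + 5)

    def test_no_missing_years_plain_sums(self):
        out = assemble_observer_series(self._raw()).set_index("year")
        assert out.loc[2014, "median"] == pytest.approx(20.0 + 2.0)

    def test_ci_bounds_summed_like_medians(self):
        out = assemble_observer_series(self._raw()).set_index("year")
        # hand-summed fixture: gulf fill CI low = mean(5,15,25) = 15, + atl 3
        assert out.loc[2016, "ci_low"] == pytest.approx(15 + 3)
        assert out.loc[2016, "ci_high"] == pytest.approx(25 + 8)

    def test_net_classes_summed_within_basin(self):
        raw = self._raw()
        extra = raw[raw["year"] == 2014].head(1).copy()
        extra["net_class"] = "try"
        out = assemble_observer_series(pd.concat([raw, extra])).set_index("year")
        assert out.loc[2014, "median"] == pytest.approx(20 + 2 + 20)

    def test_insufficient_prior_years(self):
        raw = self._raw()
        raw = raw[~((raw["basin"] == "gulf") & (raw["year"] == 2013))]
        with pytest.raises(DataError):
            assemble_observer_series(raw)

    def test_ci_must_bracket_median(self):
        raw = self._raw()
        raw.loc[0, "ci_low"] = 99.0
        with pytest.raises(DataError):
            assemble_observer_series(raw)
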