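import numpy as np
import pandas as pd
import pytest
from scipy import stats

import genecea.analytics as an
from genecea.parameters import STRATEGIES


class TestIcerNmb:
    # printed incremental cells of the base-case comparison table
    @pytest.mark.parametrize(
        "dc,de,expected_icer,expected_nmb",
        [
            (1_431_259_534, 57_657, 24_824, 298_450_466),
            (424_789_072, 14_289, 29_728, 3_880_928),
            (1_290_310_134, 58_314, 22_127, 459_109_866),
            (1_205_349_097, 56_173, 21_458, 479_840_903),
        ],
    )
    def test_incremental_arithmetic(self, dc, de, expected_icer, expected_nmb):
        assert round(an.icer(dc, de)) == expected_icer
        assert an.nmb(dc, de, 30_000) == expected_nmb

    def test_zero_effect_difference_undefined(self):
        assert an.icer(123.0, 0.0) is None

    def test_break_even(self):
        assert an.nmb(30_000 * 5.0, 5.0, 30_000) == 0.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            an.nmb(1.0, 1.0, -1.0)


class TestIncrementalTable:
    def test_usd_twin_exact_factor(self, base_outcomes):
        costs = {k: v[0] for k, v in base_outcomes.items()}
        effects = {k: v[1] for k, v in base_outcomes.items()}
        tab = an.incremental_table(costs, effects, eur_usd=1.0875)
        assert len(tab) == 4
        for col in ("delta_cost", "icer", "nmb"):
            np.testing.assert_allclose(tab[f"{col}_usd"], tab[col] * 1.0875, rtol=1e-15)

    def test_dominance_annotation(self):
        tab = an.incremental_table(
            {"WGS": 50.0, "X": 100.0}, {"WGS": 2.0, "X": 1.0}, reference="WGS"
        )
        assert bool(tab.loc["X", "dominant"]) is True
        assert tab.loc["X", "icer"] < 0  # raw negative ICER is preserved

    def test_icer_ci_excludes_nonpositive_effect_draws(self, psa_factory):
        rng = np.random.default_rng(0)
        de = rng.normal(1.0, 0.1, 1_000)
        psa = psa_factory(
            costs={"WGS": np.full(1_000, 200.0), "SOC": np.zeros(1_000)},
            effects={"WGS": de, "SOC": np.zeros(1_000)},
        )
        tab = an.incremental_table(
            {"WGS": 200.0, "SOC": 0.0}, {"WGS": 1.0, "SOC": 0.0}, psa=psa
        )
        assert tab.loc["SOC", "icer_excluded_fraction"] < 0.01
        assert tab.loc["SOC", "icer_lo"] < 200.0 < tab.loc["SOC", "icer_hi"]


class TestQuadrants:
    def test_all_northeast(self, psa_factory):
        psa = psa_factory(
            costs={"WGS": np.full(100, 10.0), "SOC": np.zeros(100)},
            effects={"WGS": np.ones(100), "SOC": np.zeros(100)},
        )
        q = an.quadrant_proportions(psa, "WGS", "SOC")
        assert q["NE"] == 1.0 and sum(q.values()) == 1.0

    def test_symmetric_costs_split_north_south(self, psa_factory):
        rng = np.random.default_rng(1)
        n = 20_000
        psa = psa_factory(
            costs={"WGS": rng.normal(0, 1, n), "SOC": np.zeros(n)},
            effects={"WGS": np.ones(n), "SOC": np.zeros(n)},
        )
        q = an.quadrant_proportions(psa, "WGS", "SOC")
        assert q["NE"] == pytest.approx(0.5, abs=0.02)
        assert q["SE"] == pytest.approx(0.5, abs=0.02)
        assert sum(q.values()) == pytest.approx(1.0, abs=1e-12)


class TestCeac:
    def test_degenerate_psa_is_step_function(self, degenerate_psa, base_outcomes):
        grid = np.arange(0, 50_001, 100.0)
        curve = an.ceac(degenerate_psa, grid, reference="WGS")
        dc = base_outcomes["WGS"][0] - base_outcomes["SOC"][0]
        de = base_outcomes["WGS"][1] - base_outcomes["SOC"][1]
        switch = dc / de
        pair = curve.pairwise["SOC"].to_numpy()
        assert set(np.unique(pair)) <= {0.0, 1.0}
        np.testing.assert_array_equal(pair, (grid > switch).astype(float))

    def test_optimal_probabilities_sum_to_one(self, psa_default):
        grid = [0, 10_000, 30_000, 50_000]
        curve = an.ceac(psa_default, grid)
        np.testing.assert_allclose(curve.optimal.sum(axis=1), 1.0, atol=1e-12)
        assert ((curve.optimal >= 0) & (curve.optimal <= 1)).all().all()
        assert ((curve.pairwise >= 0) & (curve.pairwise <= 1)).all().all()

    def test_pairwise_probability_complement(self, psa_default):
        # continuous outcomes: P(ref wins) + P(comparator wins) = 1
        curve = an.ceac(psa_default, [25_000.0])
        p = curve.pairwise["SOC"].iloc[0]
        nmb_ref = 25_000 * psa_default.effects["WGS"] - psa_default.costs["WGS"]
        nmb_soc = 25_000 * psa_default.effects["SOC"] - psa_default.costs["SOC"]
        assert p + (nmb_soc > nmb_ref).mean() == pytest.approx(1.0, abs=1e-12)

    def test_huge_wtp_favours_highest_effect_strategy(self, psa_default):
        curve = an.ceac(psa_default, [1e9])
        best = curve.optimal.iloc[0].idxmax()
        mean_effects = {n: psa_default.effects[n].mean() for n in psa_default.strategies}
        assert best == max(mean_effects, key=mean_effects.get)
        # residual mass reflects per-draw yield uncertainty between the
        # two second-tier strategies, not cost considerations
        assert curve.optimal.iloc[0][best] > 0.8
        assert curve.optimal.iloc[0][["WGS after SOC", "WES after SOC"]].sum() > 0.99

    def test_zero_wtp_favours_cheapest_strategy(self, psa_default):
        curve = an.ceac(psa_default, [0.0])
        assert curve.optimal.iloc[0]["SOC"] > 0.95

    def test_exact_ties_split_equally(self, psa_factory):
        psa = psa_factory(
            costs={"WGS": np.full(10, 5.0), "CLONE": np.full(10, 5.0)},
            effects={"WGS": np.ones(10), "CLONE": np.ones(10)},
        )
        curve = an.ceac(psa, [1_000.0])
        assert curve.optimal.iloc[0]["WGS"] == pytest.approx(0.5)
        assert curve.optimal.iloc[0]["CLONE"] == pytest.approx(0.5)

    def test_empty_grid_rejected(self, degenerate_psa):
        with pytest.raises(ValueError):
            an.ceac(degenerate_psa, [])


class TestCeaf:
    def test_deterministic_frontier_switches_at_pairwise_icers(
        self, degenerate_psa, base_outcomes
    ):
        # restrict to the three single-tier strategies
        single = {"SOC", "WES", "WGS"}
        psa = degenerate_psa
        sub = type(psa)(
            parameters=psa.parameters,
            costs={k: v for k, v in psa.costs.items() if k in single},
            effects={k: v for k, v in psa.effects.items() if k in single},
            chain_id=psa.chain_id,
            seed=psa.seed,
        )
        o = base_outcomes
        icer_ws = (o["WES"][0] - o["SOC"][0]) / (o["WES"][1] - o["SOC"][1])
        icer_gw = (o["WGS"][0] - o["WES"][0]) / (o["WGS"][1] - o["WES"][1])
        grid = np.arange(0, 50_001, 100.0)
        curve = an.ceac(sub, grid)
        frontier = an.ceaf(curve, sub)
        lookup = frontier.set_index("wtp")["strategy"]
        assert lookup[icer_ws - 100 - icer_ws % 100] == "SOC"
        assert lookup[icer_ws + 200 - icer_ws % 100] == "WES"
        assert lookup[icer_gw - 100 - icer_gw % 100] == "WES"
        assert lookup[icer_gw + 200 - icer_gw % 100] == "WGS"
        assert frontier["probability"].between(0, 1).all()


class TestEib:
    def test_linearity_identity(self, psa_default):
        wtp = 30_000.0
        val = an.eib(psa_default, "WGS", "SOC", wtp)
        dc = psa_default.costs["WGS"] - psa_default.costs["SOC"]
        de = psa_default.effects["WGS"] - psa_default.effects["SOC"]
        assert val == pytest.approx(wtp * de.mean() - dc.mean(), rel=1e-9)

    def test_deterministic_limit_reproduces_nmb(self, psa_factory):
        # degenerate PSA pinned at the printed totals for WGS and SOC
        psa = psa_factory(
            costs={"WGS": np.full(8, 1_862_645_603.0), "SOC": np.full(8, 431_386_069.0)},
            effects={"WGS": np.full(8, 178_367.0), "SOC": np.full(8, 120_710.0)},
        )
        assert an.eib(psa, "WGS", "SOC", 30_000.0) == 298_450_466.0

    def test_zero_at_mean_icer(self, psa_default):
        dc = psa_default.costs["WGS"] - psa_default.costs["SOC"]
        de = psa_default.effects["WGS"] - psa_default.effects["SOC"]
        wtp = dc.mean() / de.mean()
        assert an.eib(psa_default, "WGS", "SOC", wtp) == pytest.approx(0.0, abs=1e-6)


class TestValueOfInformation:
    def test_degenerate_psa_has_zero_evpi(self, degenerate_psa):
        for wtp in (0.0, 30_000.0, 50_000.0):
            assert an.evpi(degenerate_psa, wtp) == pytest.approx(0.0, abs=1e-9)

    def test_evpi_nonnegative_on_grid(self, psa_default):
        for wtp in np.arange(0, 50_001, 5_000.0):
            assert an.evpi(psa_default, wtp) >= -1e-9

    def test_gaussian_closed_form(self, psa_factory):
        # two strategies whose NMB difference is N(mu, sigma^2):
        # EVPI = sigma*phi(mu/sigma) - |mu|*Phi(-|mu|/sigma)
        mu, sigma, n = 40.0, 120.0, 1_000_000
        rng = np.random.default_rng(12345)
        d = rng.normal(mu, sigma, n)
        psa = psa_factory(
            costs={"A": np.zeros(n), "B": -d}, effects={"A": np.zeros(n), "B": np.zeros(n)},
        )
        est = an.evpi(psa, wtp=0.0)
        closed = sigma * stats.norm.pdf(mu / sigma) - abs(mu) * stats.norm.cdf(-abs(mu) / sigma)
        mc_se = np.maximum(d, 0).std() / np.sqrt(n)
        assert abs(est - closed) < 4 * mc_se

    def test_population_scaling(self):
        pp = 12.5
        pop = an.population_evpi(pp, population=1_000, horizon_years=10, discount_rate=0.03)
        disc_pop = 1_000 * sum(1.03 ** -t for t in range(10))
        assert pop == pytest.approx(pp * disc_pop, rel=1e-12)

    def test_evpi_shrinks_as_yield_priors_tighten(
        self, defaults, all_strategies, psa_default
    ):
        import dataclasses

        import genecea as g

        params, priors, _, settings = defaults
        tight = dict(priors.specs)
        for k in ("soc", "wes", "wgs"):
            spec = priors.specs[f"yield_{k}"]
            a, b = spec.p["alpha"], spec.p["beta"]
            scale = 50.0  # same mean, 50x the effective sample size
            tight[f"yield_{k}"] = g.DistributionSpec.beta(a * scale, b * scale)
        psa_tight = g.run_psa(
            all_strategies, g.PriorSet(tight), params,
            dataclasses.replace(settings, n_draws=4_000, n_chains=2, seed=20240126),
        )
        assert an.evpi(psa_tight, 30_000.0) < an.evpi(psa_default, 30_000.0)

    def test_evppi_independent_parameter_is_null(self, psa_factory):
        rng = np.random.default_rng(2)
        n = 40_000
        x = rng.uniform(size=n)  # has no effect on outcomes
        d = rng.normal(10.0, 50.0, n)
        psa = psa_factory(
            costs={"A": np.zeros(n), "B": -d},
            effects={"A": np.zeros(n), "B": np.zeros(n)},
            parameters=pd.DataFrame({"odyssey_cost": x}),
        )
        total = an.evpi(psa, 0.0)
        partial = an.evppi(psa, "odyssey_cost", 0.0)
        assert partial <= 0.1 * total + 0.5

    def test_evppi_single_driver_captures_all_uncertainty(self, psa_factory):
        rng = np.random.default_rng(3)
        n = 40_000
        x = rng.normal(10.0, 50.0, n)
        psa = psa_factory(
            costs={"A": np.zeros(n), "B": -x},
            effects={"A": np.zeros(n), "B": np.zeros(n)},
            parameters=pd.DataFrame({"yield_wgs": x}),
        )
        total = an.evpi(psa, 0.0)
        partial = an.evppi(psa, "yield_wgs", 0.0)
        assert partial == pytest.approx(total, rel=0.05)

    def test_evppi_bounded_by_evpi(self, psa_default):
        wtp = 30_000.0
        total = an.evpi(psa_default, wtp)
        n = psa_default.n_draws
        for name in ("yield_wgs", "yield_soc", "care_cost_wgs", "change_cost_soc"):
            partial = an.evppi(psa_default, name, wtp)
            assert -1e-9 <= partial <= total + 3 * total / np.sqrt(n) + 1.0

    def test_evppi_constant_parameter_zero(self, psa_factory):
        psa = psa_factory(
            costs={"A": np.zeros(10), "B": np.ones(10)},
            effects={"A": np.zeros(10), "B": np.zeros(10)},
            parameters=pd.DataFrame({"odyssey_cost": np.full(10, 2375.0)}),
        )
        assert an.evppi(psa, "odyssey_cost", 0.0) == 0.0


class TestCredibleInterval:
    def test_constant_samples_zero_width(self):
        lo, hi = an.credible_interval([5.0, 5.0, 5.0])
        assert lo == hi == 5.0

    def test_uniform_quantiles(self):
        x = np.random.default_rng(4).uniform(size=1_000_000)
        lo, hi = an.credible_interval(x, 0.95)
        assert lo == pytest.approx(0.025, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)

    def test_contains_median(self):
        x = np.random.default_rng(5).normal(size=501)
        lo, hi = an.credible_interval(x, 0.5)
        assert lo <= np.median(x) <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            an.credible_interval([1.0], 0.95)
        with pytest.raises(ValueError):
            an.credible_interval([1.0, 2.0], 1.5)
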