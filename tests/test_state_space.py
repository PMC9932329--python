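import numpy as np
import pandas as pd
import pytest

from ecohealth import (
    CarryingAssessment,
    Subsystem,
    compute_weights,
    normalize,
)
from ecohealth.state_space import (
    IndicatorLoads,
    assess,
    compute_loads,
    contribution_rates,
    ideal_state,
    overall_modulus,
    subsystem_modulus,
    subsystem_shares,
)
from conftest import random_panel


class TestModuli:
    @pytest.mark.parametrize(
        "loads,expected",
        [
            ([0.03, 0.04], 0.05),  # 3-4-5 triangle
            ([0.0, 0.0, 0.0], 0.0),
            ([0.06], 0.06),
        ],
    )
    def test_subsystem_modulus(self, loads, expected):
        assert subsystem_modulus(loads) == pytest.approx(expected, abs=1e-15)

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            subsystem_modulus([-0.1, 0.2])

    @pytest.mark.parametrize(
        "moduli,printed,tol",
        [
            ((0.030, 0.045, 0.074), 0.092, 0.0015),  # published 2007 column
            ((0.082, 0.051, 0.098), 0.137, 0.0015),  # 2014
            ((0.065, 0.052, 0.100), 0.130, 0.0015),  # 2019
            ((0.0504, 0.0461, 0.0795), 0.1048, 0.001),  # ideal state
            ((0.0, 0.0, 0.0), 0.0, 1e-15),
        ],
    )
    def test_overall_modulus_reproduces_published_series(self, moduli, printed, tol):
        assert overall_modulus(*moduli) == pytest.approx(printed, abs=tol)

    @pytest.mark.parametrize("seed", range(15))
    def test_decomposition_and_oracle_equivalence(self, seed):
        """Per-subsystem RSS aggregation equals the single-shot Euclidean
        modulus of all loads — checked against a literal transcription."""
        panel = random_panel(seed, n_years=4, per_subsystem=2)
        weights, _ = compute_weights(panel)
        norm = normalize(panel)
        a = assess(norm, weights)
        loads = compute_loads(norm, weights)
        for year in a.years:
            direct = np.sqrt(
                sum(float(loads.values.loc[year, c]) ** 2 for c in loads.values.columns)
            )
            assert float(a.ecc.loc[year]) == pytest.approx(direct, abs=1e-12)
            subs = [float(a.subsystem_series(s).loc[year]) for s in Subsystem]
            assert float(a.ecc.loc[year]) == pytest.approx(
                overall_modulus(*subs), abs=1e-12
            )

    def test_monotonicity_in_normalized_values(self, small_panel):
        weights, _ = compute_weights(small_panel)
        norm = normalize(small_panel)
        a0 = assess(norm, weights)
        year = norm.years[2]
        col = "X_1"
        bumped = norm.values.copy()
        bumped.loc[year, col] = min(1.0, bumped.loc[year, col] + 0.1)
        assert bumped.loc[year, col] > norm.values.loc[year, col]
        from ecohealth import NormalizedPanel

        a1 = assess(NormalizedPanel(values=bumped, definitions=norm.definitions), weights)
        assert float(a1.subsystem_series(Subsystem.ECONOMIC).loc[year]) > float(
            a0.subsystem_series(Subsystem.ECONOMIC).loc[year]
        )
        assert float(a1.ecc.loc[year]) > float(a0.ecc.loc[year])

    @pytest.mark.parametrize("seed", range(10))
    def test_modulus_bounded_by_sqrt3(self, seed):
        panel = random_panel(seed, n_years=6, per_subsystem=3)
        weights, _ = compute_weights(panel)
        a = assess(normalize(panel), weights)
        assert (a.ecc <= np.sqrt(3) + 1e-12).all()


class TestIdealState:
    def test_mean_strategy_on_constant_panel_equals_yearly_ecc(self, small_definitions):
        from ecohealth import IndicatorPanel, WeightVector

        years = pd.Index(range(2000, 2004), name="year")
        values = pd.DataFrame(
            {d.id: [0.4] * 4 for d in small_definitions}, index=years
        )
        from ecohealth import NormalizedPanel

        norm = NormalizedPanel(values=values, definitions=small_definitions)
        weights = WeightVector(
            weights=pd.Series(0.5, index=values.columns),
            subsystems=norm.subsystem_of(),
        )
        a = assess(norm, weights, strategy="mean")
        for year in a.years:
            assert float(a.ecc.loc[year]) == pytest.approx(a.ecc_star, abs=1e-12)

    def test_single_year_mean_equals_that_year(self, small_definitions):
        from ecohealth import NormalizedPanel, WeightVector

        values = pd.DataFrame(
            {d.id: [0.3] for d in small_definitions},
            index=pd.Index([2010], name="year"),
        )
        norm = NormalizedPanel(values=values, definitions=small_definitions)
        weights = WeightVector(
            weights=pd.Series(0.5, index=values.columns), subsystems=norm.subsystem_of()
        )
        ideal = ideal_state(norm, weights, strategy="mean")
        pd.testing.assert_series_equal(
            ideal.ideal_values, values.iloc[0], check_names=False
        )

    def test_fixed_strategy_requires_all_indicators(self, small_panel):
        weights, _ = compute_weights(small_panel)
        norm = normalize(small_panel)
        with pytest.raises(ValueError, match="X_2"):
            ideal_state(norm, weights, strategy="fixed", fixed_values={"X_1": 0.5})

    def test_ideal_decomposition(self, small_panel):
        weights, _ = compute_weights(small_panel)
        ideal = ideal_state(normalize(small_panel), weights, strategy="max")
        rss = np.sqrt(sum(v**2 for v in ideal.subsystem_moduli.values()))
        assert ideal.modulus == pytest.approx(rss, abs=1e-12)


class TestContributionRates:
    def make_loads(self, data, subsystems):
        values = pd.DataFrame(data, index=pd.Index([2000], name="year"))
        return IndicatorLoads(values=values, subsystems=pd.Series(subsystems))

    def test_single_indicator_is_100(self):
        loads = self.make_loads({"X_1": [0.2]}, {"X_1": Subsystem.ECONOMIC})
        out = contribution_rates(loads)
        assert out.loc["X_1", "contribution_pct"] == pytest.approx(100.0, abs=1e-9)

    def test_equal_loads_split_evenly(self):
        loads = self.make_loads(
            {f"X_{i}": [0.1] for i in range(1, 5)},
            {f"X_{i}": Subsystem.ECONOMIC for i in range(1, 5)},
        )
        out = contribution_rates(loads)
        assert np.allclose(out["contribution_pct"], 25.0, atol=1e-9)

    def test_linear_shares_brute_force(self):
        loads = self.make_loads(
            {"X_1": [0.03], "X_2": [0.04]},
            {"X_1": Subsystem.ECONOMIC, "X_2": Subsystem.ECONOMIC},
        )
        out = contribution_rates(loads, definition="linear")
        assert out.loc["X_1", "contribution_pct"] == pytest.approx(100 * 0.03 / 0.07, abs=1e-9)
        assert out.loc["X_2", "contribution_pct"] == pytest.approx(100 * 0.04 / 0.07, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("definition", ["linear", "squared"])
    def test_percentages_sum_to_100_per_subsystem(self, seed, definition):
        panel = random_panel(seed, n_years=5, per_subsystem=3)
        weights, _ = compute_weights(panel)
        norm = normalize(panel)
        out = contribution_rates(compute_loads(norm, weights), definition=definition)
        sums = out.groupby("subsystem")["contribution_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_all_zero_subsystem_rejected(self):
        loads = self.make_loads({"X_1": [0.0]}, {"X_1": Subsystem.ECONOMIC})
        with pytest.raises(ValueError, match="economic"):
            contribution_rates(loads)


class TestSubsystemShares:
    def make_assessment(self, ec, es, ha):
        years = pd.Index(range(2000, 2000 + len(ec)), name="year")
        moduli = pd.DataFrame(
            {"ecc_economic": ec, "ecc_ecological": es, "ecc_human": ha}, index=years
        )
        moduli["ecc"] = np.sqrt((moduli**2).sum(axis=1))
        ideal = {c: 0.1 for c in moduli.columns}
        return CarryingAssessment(moduli=moduli, ideal=ideal)

    def test_published_subsystem_table_averages_to_45_28_27(self, shandong):
        a = self.make_assessment(
            shandong.subsystem_moduli["economic"].tolist(),
            shandong.subsystem_moduli["ecological"].tolist(),
            shandong.subsystem_moduli["human"].tolist(),
        )
        shares = subsystem_shares(a)
        assert round(shares[Subsystem.HUMAN]) == 45
        assert round(shares[Subsystem.ECONOMIC]) == 28
        assert round(shares[Subsystem.ECOLOGICAL]) == 27

    def test_equal_moduli_split_evenly(self):
        a = self.make_assessment([0.1] * 3, [0.1] * 3, [0.1] * 3)
        shares = subsystem_shares(a)
        for v in shares.values():
            assert v == pytest.approx(100 / 3, abs=1e-9)

    def test_zero_subsystem_share_is_zero(self):
        a = self.make_assessment([0.0, 0.0], [0.1, 0.2], [0.1, 0.2])
        assert subsystem_shares(a)[Subsystem.ECONOMIC] == 0.0

    def test_all_zero_year_rejected(self):
        a = self.make_assessment([0.0], [0.0], [0.0])
        with pytest.raises(ValueError, match="2000"):
            subsystem_shares(a)
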