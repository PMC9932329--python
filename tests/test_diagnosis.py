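import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecohealth import (
    CarryingAssessment,
    CarryingType,
    HealthLevel,
    PipelineConfig,
    Subsystem,
    Trend,
    WarningDegree,
    WarningLevel,
)
from ecohealth.diagnosis import (
    BandScheme,
    assess_trend,
    classify_carrying,
    diagnose_series,
    health_level,
    subsystem_diagnosis,
    warning_level,
)

SEVERITY = {
    HealthLevel.VERY_HEALTHY: 0,
    HealthLevel.HEALTHY: 1,
    HealthLevel.SUB_HEALTH: 2,
    HealthLevel.UNHEALTHY: 3,
    HealthLevel.MORBID: 4,
}


def make_assessment(ecc_values, ecc_star):
    years = pd.Index(range(2000, 2000 + len(ecc_values)), name="year")
    share = np.asarray(ecc_values) / np.sqrt(3)
    moduli = pd.DataFrame(
        {"ecc_economic": share, "ecc_ecological": share, "ecc_human": share},
        index=years,
    )
    moduli["ecc"] = np.sqrt((moduli**2).sum(axis=1))
    star = ecc_star / np.sqrt(3)
    ideal = {"ecc_economic": star, "ecc_ecological": star, "ecc_human": star,
             "ecc": np.sqrt(3) * star}
    return CarryingAssessment(moduli=moduli, ideal=ideal)


class TestClassifyCarrying:
    @pytest.mark.parametrize(
        "ecc,ecc_star,expected",
        [
            (0.092, 0.1048, CarryingType.LOADABLE),  # published 2007
            (0.137, 0.1048, CarryingType.OVERLOAD),  # published 2014
            (1.2, 1.0, CarryingType.CRITICAL_OVERLOAD),  # boundary inclusive
            (0.8, 1.0, CarryingType.LIGHT_LOAD),
            (1.0, 1.0, CarryingType.LOADABLE),  # exactly ideal
            (1.4, 1.0, CarryingType.OVERLOAD),
            (1.4000001, 1.0, CarryingType.SEVERE_OVERLOAD),
            (0.0, 1.0, CarryingType.LIGHT_LOAD),
        ],
    )
    def test_band_edges(self, ecc, ecc_star, expected):
        assert classify_carrying(ecc, ecc_star) is expected

    def test_nonpositive_ideal_rejected(self):
        with pytest.raises(ValueError):
            classify_carrying(0.5, 0.0)

    @given(ratio=st.floats(min_value=0, max_value=10, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_totality(self, ratio):
        """Every nonnegative modulus falls in exactly one band."""
        assert classify_carrying(ratio, 1.0) in CarryingType


class TestAssessTrend:
    @pytest.mark.parametrize(
        "current,previous,expected",
        [
            (0.137, 0.121, Trend.AGGRAVATED),  # published 2014 arrow
            (0.106, 0.127, Trend.SLOWING),  # published 2012 arrow
            (0.5, 0.5, Trend.SLOWING),  # tie -> lenient default
        ],
    )
    def test_examples(self, current, previous, expected):
        assert assess_trend(current, previous) is expected

    def test_first_year_defaults(self):
        assert assess_trend(0.5, None) is Trend.AGGRAVATED
        assert assess_trend(0.5, None, first_year_rule=Trend.UNDEFINED) is Trend.UNDEFINED
        assert assess_trend(0.5, 0.5, tie_rule=Trend.AGGRAVATED) is Trend.AGGRAVATED


class TestWarningAndHealth:
    @pytest.mark.parametrize(
        "ctype,trend,level,degree",
        [
            (CarryingType.LOADABLE, Trend.AGGRAVATED, WarningLevel.GREEN, WarningDegree.NO),
            (CarryingType.LOADABLE, Trend.SLOWING, WarningLevel.GREEN, WarningDegree.NO),
            (CarryingType.LIGHT_LOAD, Trend.SLOWING, WarningLevel.GREEN, WarningDegree.NO),
            (CarryingType.CRITICAL_OVERLOAD, Trend.SLOWING, WarningLevel.BLUE, WarningDegree.LIGHT),
            (CarryingType.CRITICAL_OVERLOAD, Trend.AGGRAVATED, WarningLevel.YELLOW, WarningDegree.MEDIUM),
            (CarryingType.OVERLOAD, Trend.SLOWING, WarningLevel.ORANGE, WarningDegree.HEAVY),
            (CarryingType.OVERLOAD, Trend.AGGRAVATED, WarningLevel.RED, WarningDegree.EXTREMELY_HEAVY),
            (CarryingType.SEVERE_OVERLOAD, Trend.SLOWING, WarningLevel.ORANGE, WarningDegree.HEAVY),
            (CarryingType.SEVERE_OVERLOAD, Trend.AGGRAVATED, WarningLevel.RED, WarningDegree.EXTREMELY_HEAVY),
        ],
    )
    def test_warning_table(self, ctype, trend, level, degree):
        assert warning_level(ctype, trend) == (level, degree)

    @pytest.mark.parametrize(
        "degree,health",
        [
            (WarningDegree.NO, HealthLevel.VERY_HEALTHY),
            (WarningDegree.LIGHT, HealthLevel.HEALTHY),
            (WarningDegree.MEDIUM, HealthLevel.SUB_HEALTH),
            (WarningDegree.HEAVY, HealthLevel.UNHEALTHY),
            (WarningDegree.EXTREMELY_HEAVY, HealthLevel.MORBID),
        ],
    )
    def test_health_mapping(self, degree, health):
        assert health_level(degree) is health

    def test_chain_total_over_all_pairs(self):
        """Every (type, trend) pair yields exactly one (level, degree,
        health) triple — the chain is total and deterministic."""
        for ctype in CarryingType:
            for trend in Trend:
                level, degree = warning_level(ctype, trend)
                assert isinstance(level, WarningLevel)
                assert health_level(degree) in HealthLevel

    def test_monotone_severity_across_bands(self):
        """For a fixed trend, health never improves as ECC crosses bands."""
        for trend in (Trend.AGGRAVATED, Trend.SLOWING):
            severities = []
            for ratio in (0.4, 0.9, 1.1, 1.3, 1.6):
                ctype = classify_carrying(ratio, 1.0)
                _, degree = warning_level(ctype, trend)
                severities.append(SEVERITY[health_level(degree)])
            assert severities == sorted(severities)


class TestDiagnoseSeries:
    def test_published_diagnosis_reproduced_from_printed_ecc(self, shandong):
        """Running the full chain on the printed overall-modulus series
        reproduces the published warning and health rows in every year
        except the documented 2011 band-edge printing artifact."""
        a = make_assessment(shandong.ecc.tolist(), shandong.ecc_star)
        records = diagnose_series(a)
        type_hits = sum(
            r.carrying_type is t for r, t in zip(records, shandong.ecc_types)
        )
        assert type_hits >= 12
        # 2011 (index 4): 0.127/0.1048 = 1.2118 crosses the printed band
        mismatch_years = [
            2000 + i
            for i, (r, t) in enumerate(zip(records, shandong.ecc_types))
            if r.carrying_type is not t
        ]
        assert mismatch_years == [2004]  # offset year index of 2011

    def test_constant_loadable_series_all_green(self):
        a = make_assessment([0.9] * 5, 1.0)
        records = diagnose_series(a)
        for r in records:
            assert r.carrying_type is CarryingType.LOADABLE
            assert r.warning_level is WarningLevel.GREEN
            assert r.warning_degree is WarningDegree.NO
            assert r.health_level is HealthLevel.VERY_HEALTHY

    def test_requires_two_years(self):
        a = make_assessment([0.9], 1.0)
        with pytest.raises(ValueError, match="two years"):
            diagnose_series(a)

    def test_trends_follow_series(self):
        a = make_assessment([1.1, 1.3, 1.25, 1.25], 1.0)
        records = diagnose_series(a)
        assert [r.trend for r in records] == [
            Trend.AGGRAVATED,  # first-year default
            Trend.AGGRAVATED,
            Trend.SLOWING,
            Trend.SLOWING,  # tie
        ]

    def test_subsystem_table_formatting(self):
        a = make_assessment([0.9, 1.1, 1.5], 1.0)
        table = subsystem_diagnosis(a)
        # moduli are equal across subsystems by construction
        col = table[Subsystem.ECONOMIC.value].tolist()
        assert col[0] == "loadable"  # green band: no arrow
        assert col[1] == "critical overload (↗)"
        assert col[2] == "severe overload"  # severe band printed bare

    @given(
        ratios=st.lists(
            st.floats(min_value=0.01, max_value=1.7, allow_nan=False),
            min_size=2,
            max_size=10,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_chain_always_produces_consistent_records(self, ratios):
        """Whatever the modulus path, every record satisfies the pairing
        invariants enforced by DiagnosisRecord itself."""
        a = make_assessment(ratios, 1.0)
        records = diagnose_series(a)
        assert len(records) == len(ratios)
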