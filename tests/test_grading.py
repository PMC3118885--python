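import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecosens as es
from ecosens.errors import ContractError, GradingError, SchemaError


class TestIndicatorSpec:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0, 1), (3, 1), (5, 3), (7.5, 3), (12, 5), (20, 7), (25, 9), (1000, 9)],
    )
    def test_numeric_bins_with_higher_tie(self, slope_spec, raw, expected):
        # a shared edge resolves to the more sensitive class
        assert slope_spec.grade(raw) == expected

    def test_lower_tie_resolves_shared_edge_down(self, slope_spec):
        assert slope_spec.grade(5, tie="lower") == 1
        assert slope_spec.grade(25, tie="lower") == 7

    def test_out_of_domain_numeric_raises(self, slope_spec):
        with pytest.raises(GradingError):
            slope_spec.grade(-1.0)

    def test_categorical_grade_and_unknown_category(self):
        spec = es.IndicatorSpec(
            id="veg", kind="categorical", categories={"water": 1, "forest": 3, "bare": 9}
        )
        assert spec.grade("forest") == 3
        with pytest.raises(GradingError):
            spec.grade("lava")

    def test_four_bins_rejected(self):
        spec = es.IndicatorSpec(
            id="bad", kind="numeric", direction="benefit",
            intervals=((0, 1), (1, 2), (2, 3), (3, 4)),
        )
        with pytest.raises(SchemaError, match="bad"):
            spec.validate()

    def test_gapped_bins_rejected_in_strict_mode(self):
        spec = es.IndicatorSpec(
            id="gap", kind="numeric", direction="benefit",
            intervals=((0, 1), (2, 3), (3, 4), (4, 5), (5, 6)),
        )
        with pytest.raises(SchemaError, match="gapped"):
            spec.validate(strict=True)
        spec2 = es.IndicatorSpec(
            id="gap", kind="numeric", direction="benefit",
            intervals=((0, 1), (2, 3), (3, 4), (4, 5), (5, 6)),
            flags=("printed-gaps",),
        )
        spec2.validate(strict=True)  # flagged as-printed rows are exempt

    def test_single_indicator_covering_reals_is_valid(self):
        spec = es.IndicatorSpec(
            id="solo", kind="numeric", direction="benefit",
            intervals=(
                (-math.inf, 0.0), (0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, math.inf)
            ),
        )
        scheme = es.GradingScheme(indicators=(spec,))
        scheme.validate(strict=True)
        assert scheme["solo"].grade(-5) == 1
        assert scheme["solo"].grade(100) == 9

    @given(x=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_totality_and_monotone_benefit(self, x):
        """Inside the domain exactly one grade; benefit grades non-decreasing."""
        spec = es.IndicatorSpec(
            id="t", kind="numeric", direction="benefit",
            intervals=(
                (-math.inf, -10.0), (-10.0, 0.0), (0.0, 10.0), (10.0, 100.0),
                (100.0, math.inf),
            ),
        )
        g = spec.grade(x)
        assert g in es.GRADE_INDICES
        assert spec.grade(x + 1.0) >= g

    def test_cost_direction_grades_non_increasing(self):
        spec = es.IndicatorSpec(
            id="depth", kind="numeric", direction="cost",
            intervals=(
                (200.0, math.inf), (100.0, 200.0), (60.0, 100.0), (40.0, 60.0),
                (-math.inf, 40.0),
            ),
        )
        values = [10, 50, 80, 150, 500]
        grades = [spec.grade(v) for v in values]
        assert grades == sorted(grades, reverse=True)

    def test_bin_midpoint_idempotence(self, slope_spec):
        for (lo, hi), g in zip(slope_spec.intervals, es.GRADE_INDICES):
            if math.isinf(hi):
                hi = lo + 10
            assert slope_spec.grade((lo + hi) / 2) == g


class TestYichengScheme:
    def test_forty_indicators_in_four_groups(self, scheme):
        assert len(scheme) == 40
        groups = scheme.groups(level=0)
        assert set(groups) == {
            "soil_conditions", "water_conditions", "atmospheric_conditions", "biodiversity",
        }

    @pytest.mark.parametrize(
        "indicator,raw,expected",
        [
            ("slope", 3, 1),        # flat terrain, insensitive
            ("ph", 7.0, 5),         # neutral soil, moderate
            ("slope", 25, 9),       # shared edge -> more sensitive class
            ("groundwater_depth", 30, 9),
            ("water_sort", "III", 5),
            ("vegetation_type", "forest", 3),
        ],
    )
    def test_published_grade_examples(self, scheme, indicator, raw, expected):
        assert scheme[indicator].grade(raw) == expected


class TestGradeTable:
    def test_grades_in_range_for_in_domain_values(self, slope_spec):
        scheme = es.GradingScheme(indicators=(slope_spec,))
        raw = pd.DataFrame({"slope": [1.0, 12.0, 30.0]}, index=["a", "b", "c"])
        out = es.grade_table(scheme, raw)
        assert out["slope"].tolist() == [1.0, 5.0, 9.0]

    def test_unknown_column_is_a_contract_error(self, slope_spec):
        scheme = es.GradingScheme(indicators=(slope_spec,))
        raw = pd.DataFrame({"slope": [1.0], "mystery": [2.0]})
        with pytest.raises(ContractError, match="mystery"):
            es.grade_table(scheme, raw)

    def test_missing_values_propagate_with_default_policy(self, slope_spec):
        scheme = es.GradingScheme(indicators=(slope_spec,))
        raw = pd.DataFrame({"slope": [1.0, np.nan]}, index=["a", "b"])
        out = es.grade_table(scheme, raw)
        assert out.loc["a", "slope"] == 1.0
        assert math.isnan(out.loc["b", "slope"])
        with pytest.raises(GradingError):
            es.grade_table(scheme, raw, missing="error")

    def test_zero_noise_generator_table_grades_to_target(self, scheme):
        cfg = es.SimulationConfig(rows=3, cols=3, sigma=0.0, eps=0.0, seed=7,
                                  mixture=(0.0, 0.0, 0.0, 1.0, 0.0))
        sim = es.generate_units(cfg, scheme)
        grades = es.grade_table(scheme, sim.raw)
        assert (grades.to_numpy() == 7.0).all()


def test_load_scheme_rejects_malformed_bins(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "name: bad\nindicators:\n"
        "  - id: x\n    kind: numeric\n    direction: benefit\n"
        "    intervals: [[0, 1], [1, 2], [2, 3], [3, 4]]\n"
    )
    with pytest.raises(SchemaError, match="'x'"):
        es.load_scheme(bad)


def test_load_scheme_roundtrip(tmp_path, slope_spec):
    import yaml

    scheme = es.GradingScheme(indicators=(slope_spec,), name="mini")
    p = tmp_path / "scheme.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh)
    loaded = es.load_scheme(p)
    assert loaded.ids == scheme.ids
    assert loaded["slope"].intervals == slope_spec.intervals
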