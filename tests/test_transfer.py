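import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenwallcba.errors import InvalidParameterError, ValidationError
from greenwallcba.transfer import (
    HedonicStudyRecord,
    IntervalUncertainty,
    NoUncertainty,
    TransferConfig,
    annuitize_record,
    greenery_annual_value,
    per_person,
    summarize_unit_values,
    to_unit_value,
)

# Published reference values per study:
# (annuity, greenery value, base-year EUR value, unit value per m²)
REFERENCE = {
    "peck_1999": (12_599, 1_323, 1_044, 20.88),
    "hunt_2008": (12_599, 1_134, 895, 17.90),
    "gao_asami_tokyo": (32_998, 8_400, 87, 3.46),
    "gao_asami_kitakyushu": (4_010, 1_980, 17, 0.69),
    "ichihara_cohen": (4_000, 648, 859, 17.18),
    "des_rosiers": (6_135, 239, 189, 3.78),
    "tomalty_recreational": (21_662, 4_332, 3_174, 63.47),
    "tomalty_productive": (21_662, 1_516, 1_111, 22.22),
}


class TestAnnuitizeRecord:
    def test_property_price_is_annuitized(self, records_by_id, config):
        assert annuitize_record(records_by_id["peck_1999"], config) == pytest.approx(
            12_599, abs=0.5
        )

    def test_annual_rent_passes_through(self, records_by_id, config):
        assert annuitize_record(records_by_id["ichihara_cohen"], config) == 4_000

    def test_kitakyushu_property(self, records_by_id, config):
        assert annuitize_record(
            records_by_id["gao_asami_kitakyushu"], config
        ) == pytest.approx(4_010, abs=0.5)


class TestGreeneryAnnualValue:
    def test_interval_midpoint_times_annuity(self, records_by_id, config):
        assert greenery_annual_value(records_by_id["peck_1999"], config) == pytest.approx(
            1_323, abs=0.5
        )

    def test_premium_on_raw_price(self, records_by_id, config):
        # the two land-price studies multiply the raw price, not the annuity
        value = greenery_annual_value(records_by_id["gao_asami_tokyo"], config)
        assert value == pytest.approx(8_400, rel=0.005)

    def test_recreational_roof(self, records_by_id, config):
        assert greenery_annual_value(
            records_by_id["tomalty_recreational"], config
        ) == pytest.approx(4_332, abs=0.5)


class TestToUnitValue:
    @pytest.mark.parametrize("study_id", sorted(REFERENCE))
    def test_reproduces_published_row(self, study_id, records_by_id, config):
        annuity, greenery, eur_base, unit = REFERENCE[study_id]
        rec = records_by_id[study_id]
        est = to_unit_value(rec, config)
        assert annuitize_record(rec, config) == pytest.approx(annuity, rel=0.005)
        assert greenery_annual_value(rec, config) == pytest.approx(greenery, rel=0.005)
        # small EUR amounts round coarsely in print; allow 0.5% or 1 EUR
        assert est.eur_base_value == pytest.approx(
            eur_base, rel=0.005, abs=1.0
        )
        assert est.unit_value == pytest.approx(unit, rel=0.005)

    def test_unit_value_is_base_value_over_area(self, estimates):
        for est in estimates:
            assert est.unit_value == pytest.approx(
                est.eur_base_value / est.area, rel=1e-12
            )

    def test_missing_fx_propagates(self, records_by_id, config, tables):
        from greenwallcba.errors import MissingRateError

        rec = dataclasses.replace(records_by_id["peck_1999"], currency="GBP")
        with pytest.raises(MissingRateError):
            to_unit_value(rec, config)


class TestPerPerson:
    def test_trimmed_mean_per_person(self, config):
        assert per_person(12.3, config) == pytest.approx(5.1, abs=0.05)

    def test_pooled_mean_per_person(self, config):
        assert per_person(5.8, config) == pytest.approx(2.4, abs=0.05)

    def test_single_person_household_identity(self, tables):
        config = TransferConfig(fx=tables.fx, cpi=tables.cpi, household_size=1.0)
        assert per_person(7.7, config) == 7.7

    def test_nonpositive_household_rejected(self, tables):
        with pytest.raises(InvalidParameterError):
            TransferConfig(fx=tables.fx, cpi=tables.cpi, household_size=0.0)


class TestSummarize:
    def test_mean_of_all_estimates(self, estimates):
        assert summarize_unit_values(estimates) == pytest.approx(18.7, abs=0.05)

    def test_mean_excluding_maximum(self, estimates):
        assert summarize_unit_values(estimates, exclude_max=True) == pytest.approx(
            12.3, abs=0.05
        )

    def test_single_estimate_is_itself(self, estimates):
        assert summarize_unit_values([estimates[0]]) == estimates[0].unit_value

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            summarize_unit_values([])

    @given(values=st.lists(st.floats(0.01, 100), min_size=2, max_size=12))
    @settings(max_examples=50)
    def test_trimmed_mean_never_larger(self, values):
        full = summarize_unit_values(values)
        trimmed = summarize_unit_values(values, exclude_max=True)
        assert trimmed <= full + 1e-12
        if len(set(values)) == 1:
            assert trimmed == pytest.approx(full)


class TestHomogeneity:
    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=25)
    def test_degree_one_in_price_and_premium(self, scale, records_by_id, config):
        rec = records_by_id["des_rosiers"]
        base = to_unit_value(rec, config).unit_value
        scaled_price = dataclasses.replace(rec, price=rec.price * scale)
        assert to_unit_value(scaled_price, config).unit_value == pytest.approx(
            base * scale, rel=1e-9
        )
        scaled_premium = dataclasses.replace(rec, premium_pct=rec.premium_pct * scale)
        assert to_unit_value(scaled_premium, config).unit_value == pytest.approx(
            base * scale, rel=1e-9
        )

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=25)
    def test_degree_minus_one_in_area(self, scale, records_by_id, config):
        rec = records_by_id["des_rosiers"]
        base = to_unit_value(rec, config).unit_value
        scaled = dataclasses.replace(rec, greenery_area=rec.greenery_area * scale)
        assert to_unit_value(scaled, config).unit_value == pytest.approx(
            base / scale, rel=1e-9
        )


class TestRecordValidation:
    def _make(self, **kwargs):
        defaults = dict(
            study_id="x",
            data_year=2010,
            location="",
            currency="EUR",
            price_kind="property-price",
            price=100_000.0,
            premium_pct=5.0,
            greenery_area=50.0,
        )
        defaults.update(kwargs)
        return HedonicStudyRecord(**defaults)

    def test_valid_record_accepted(self):
        assert self._make().uncertainty == NoUncertainty()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"price": 0.0},
            {"greenery_area": -1.0},
            {"premium_pct": 0.0},
            {"price_kind": "lease"},
            {"premium_base": "rent"},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            self._make(**kwargs)

    def test_interval_must_match_midpoint(self):
        with pytest.raises(ValidationError):
            self._make(premium_pct=5.0, uncertainty=IntervalUncertainty(2.0, 10.0))

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValidationError):
            IntervalUncertainty(5.0, 5.0)
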