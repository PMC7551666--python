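"""The exponent schedule and the power-law prediction engine."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adescale import (
    CANONICAL_SCHEDULE,
    AdultReference,
    DomainError,
    MaturityStatus,
    MissingMaturityError,
    exponent_for_age,
    fixed_exponent_ratio,
    predict_clearance,
    project_dose,
    round_half_away,
)

NA = MaturityStatus.NOT_APPLICABLE


class TestExponentSchedule:
    @pytest.mark.parametrize(
        "age, maturity, expected",
        [
            (0.1, MaturityStatus.PRETERM, 1.2),
            (0.1, MaturityStatus.TERM, 1.1),
            (0.25, MaturityStatus.PRETERM, 1.2),  # neonatal window is upper-inclusive
            (0.25, MaturityStatus.TERM, 1.1),
            (0.3, NA, 1.0),
            (1.5, NA, 1.0),
            (2.0, NA, 1.0),  # band boundaries are upper-inclusive
            (2.1, NA, 0.9),
            (3.5, NA, 0.9),
            (5.0, NA, 0.9),
            (5.01, NA, 0.75),
            (10.0, NA, 0.75),
            (17.9, NA, 0.75),
        ],
    )
    def test_canonical_lookup(self, age, maturity, expected):
        assert exponent_for_age(age, maturity) == expected

    @pytest.mark.parametrize("age", [-1.0, 0.0, 18.0, 25.0])
    def test_age_outside_pediatric_domain_rejected(self, age):
        with pytest.raises(DomainError):
            exponent_for_age(age, NA)

    def test_neonatal_age_requires_maturity(self):
        with pytest.raises(MissingMaturityError):
            exponent_for_age(0.2, NA)

    @given(age=st.floats(min_value=0.001, max_value=17.999))
    @settings(max_examples=300, derandomize=True)
    def test_lookup_is_total_over_pediatric_ages(self, age):
        """Every age in (0, 18) y maps to exactly one canonical exponent."""
        maturity = MaturityStatus.TERM if age <= 0.25 else NA
        assert exponent_for_age(age, maturity) in {1.1, 1.0, 0.9, 0.75}


class TestPredictClearance:
    def reference(self, cl=20.3, units="mL/h"):
        return AdultReference(
            drug_name="drug", adult_clearance=cl, clearance_units=units
        )

    def test_tocilizumab_worked_example(self):
        """20.3 mL/h adult CL scaled to a 20 kg child with exponent 0.75."""
        pred = predict_clearance(self.reference(), 20.0, 0.75)
        assert round_half_away(pred.predicted_clearance, 1) == 7.9

    def test_hand_evaluated_preschool_prediction(self):
        # independent oracle: 55 * (10/70)**0.9 = 9.5417... -> 9.5 at 1 dp
        pred = predict_clearance(self.reference(cl=55.0), 10.0, 0.9)
        assert pred.predicted_clearance == pytest.approx(55.0 * (10 / 70) ** 0.9)
        assert round_half_away(pred.predicted_clearance, 1) == 9.5

    @given(
        cl=st.floats(min_value=0.1, max_value=1e4),
        b=st.sampled_from([1.2, 1.1, 1.0, 0.9, 0.75]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_identity_at_reference_weight(self, cl, b):
        """At 70 kg the prediction equals the adult clearance exactly."""
        pred = predict_clearance(self.reference(cl=cl), 70.0, b)
        assert pred.predicted_clearance == pytest.approx(cl, rel=1e-14)

    @given(
        w1=st.floats(min_value=0.5, max_value=69.0),
        delta=st.floats(min_value=0.1, max_value=30.0),
        b=st.floats(min_value=0.1, max_value=1.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_weight(self, w1, delta, b):
        ref = self.reference()
        lo = predict_clearance(ref, w1, b).predicted_clearance
        hi = predict_clearance(ref, w1 + delta, b).predicted_clearance
        assert hi > lo

    def test_units_passed_through_verbatim(self):
        for units in ["mL/h", "mL/day", "L/h", "mL/min"]:
            pred = predict_clearance(self.reference(units=units), 12.0, 1.0)
            assert pred.clearance_units == units

    @pytest.mark.parametrize("weight, exponent", [(-5, 0.75), (0, 0.75), (20, 0)])
    def test_invalid_inputs_rejected(self, weight, exponent):
        with pytest.raises(DomainError):
            predict_clearance(self.reference(), weight, exponent)


class TestDoseProjection:
    def test_dose_is_clearance_times_auc(self):
        pred = predict_clearance(
            AdultReference("d", 55.3, "mL/h"), 20.0, 0.75
        )
        proj = project_dose(pred, 10.0)
        assert proj.projected_dose == pytest.approx(pred.predicted_clearance * 10.0)

    def test_nonpositive_auc_rejected(self):
        pred = predict_clearance(AdultReference("d", 10.0, "mL/h"), 20.0, 0.75)
        for auc in (0.0, -4.0):
            with pytest.raises(DomainError):
                project_dose(pred, auc)


class TestFixedExponentComparator:
    def test_identity_cases(self):
        assert fixed_exponent_ratio(70.0, 1.2) == pytest.approx(1.0)
        assert fixed_exponent_ratio(35.0, 0.75) == pytest.approx(1.0)

    def test_preterm_overprediction_factor(self):
        # hand oracle: (3.5/70)**(0.75-1.2) = 0.05**-0.45 = 3.8490...
        assert fixed_exponent_ratio(3.5, 1.2) == pytest.approx(
            0.05 ** (-0.45), rel=1e-12
        )
        assert fixed_exponent_ratio(3.5, 1.2) == pytest.approx(3.85, abs=0.005)

    @given(
        weight=st.floats(min_value=0.5, max_value=69.9),
        ade=st.sampled_from([1.2, 1.1, 1.0, 0.9]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_fixed_075_overpredicts_below_reference_weight(self, weight, ade):
        """The classical 0.75 exponent over-predicts whenever the true
        (age-dependent) exponent is larger and the child is lighter than
        the 70 kg adult; the factor grows as weight shrinks."""
        ratio = fixed_exponent_ratio(weight, ade)
        assert ratio > 1.0
        assert fixed_exponent_ratio(weight * 0.5, ade) > ratio

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(DomainError):
            fixed_exponent_ratio(0.0, 1.2)


@pytest.mark.parametrize(
    "value, decimals, expected",
    [(7.93, 1, 7.9), (-8.14, 0, -8.0), (2.5, 0, 3.0), (-2.5, 0, -3.0), (0.05, 1, 0.1)],
)
def test_round_half_away_from_zero(value, decimals, expected):
    assert round_half_away(value, decimals) == expected
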