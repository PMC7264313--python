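"""Normative prediction equations and the percent-predicted screening index.

Handgrip maximal voluntary contraction force (MVC, DaN) is predicted from
sex, age and forearm circumference by a linear reference equation; maximal
cycling power (MP, W) by sex-specific allometric equations in height (m)
and age (Jones).  Observed performances are expressed as percentages of
these predictions, and their quotient

    ratio = %Pred MVC / %Pred MP

is the screening index for metabolic myopathy: values well above 1 mean
short isometric performance is relatively preserved compared with aerobic
cycling power, the signature of impaired oxidative ATP supply.

The module also builds the individually-scaled incremental cycling
protocol (2-min warm-up at 20% of estimated maximal power, then +10% per
minute up to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .cohort import Sex

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SubjectRecord

__all__ = [
    "PercentPredicted",
    "ProtocolSchedule",
    "predict_mvc",
    "predict_mp",
    "estimated_mp",
    "incremental_protocol",
    "percent_predicted",
    "mvc_mp_ratio",
    "iso_line_class",
]

# Grip-strength reference equation coefficients (force in DaN; circumference
# in cm, age in years; male indicator 1/0).
_MVC_CIRC = 2.699
_MVC_MALE = 5.979
_MVC_AGE = -0.244
_MVC_INTERCEPT = -22.776

# Jones cycle-ergometer maximal power: coefficient, height exponent, age
# exponent, per sex.  Height in meters (a cm height makes the power blow up
# by ~10^5, hence the hard range guard below).
_MP_COEF = {
    Sex.MALE: (245.48, 2.7, -0.46),
    Sex.FEMALE: (157.95, 2.8, -0.43),
}


def predict_mvc(sex: Sex, age: float, forearm_circumference: float) -> float:
    """Predicted handgrip MVC (DaN) from sex, age (yr), forearm circumference (cm)."""
    if age <= 0:
        raise ValueError("age must be positive")
    if forearm_circumference <= 0:
        raise ValueError("forearm circumference must be positive")
    pred = (
        _MVC_CIRC * forearm_circumference
        + _MVC_MALE * (1.0 if Sex(sex) is Sex.MALE else 0.0)
        + _MVC_AGE * age
        + _MVC_INTERCEPT
    )
    if pred <= 0:
        raise ValueError(
            f"predicted MVC is non-positive ({pred:.2f} DaN) for sex={Sex(sex).value}, "
            f"age={age}, circumference={forearm_circumference} cm: inputs are outside "
            "the calibration range of the reference equation"
        )
    return pred


def predict_mp(sex: Sex, age: float, height: float) -> float:
    """Predicted maximal cycling power (W) from sex, age (yr) and height (m)."""
    if age <= 0:
        raise ValueError("age must be positive")
    if not 1.0 <= height <= 2.3:
        raise ValueError(
            f"height {height} outside [1.0, 2.3] m — pass meters, not centimeters"
        )
    coef, h_exp, a_exp = _MP_COEF[Sex(sex)]
    return coef * height**h_exp * age**a_exp


def estimated_mp(pred_mp: float, intolerance_factor: float = 1.0) -> float:
    """Estimated maximal power: predicted MP scaled by an exercise-intolerance factor.

    The factor is supplied by the user (fraction in (0, 1]); no adjustment
    model is built in.
    """
    if not 0 < intolerance_factor <= 1:
        raise ValueError("intolerance_factor must be in (0, 1]")
    if pred_mp <= 0:
        raise ValueError("pred_mp must be positive")
    return pred_mp * intolerance_factor


@dataclass(frozen=True)
class ProtocolSchedule:
    """Incremental cycling protocol scaled to an estimated maximal power (EMP)."""

    emp: float
    warmup_load: float
    warmup_duration: float  # minutes
    step_loads: tuple[float, ...]  # one load per minute after warm-up


def incremental_protocol(emp: float) -> ProtocolSchedule:
    """Build the ramp: 2-min warm-up at 20% EMP, then +10% EMP per minute.

    Steps run 30%, 40%, ..., 100% of EMP, so warm-up plus eight one-minute
    steps reach EMP at minute ten — a ten-minute test to exhaustion.
    """
    if emp <= 0:
        raise ValueError("emp must be positive")
    steps = tuple(emp * (0.20 + 0.10 * k) for k in range(1, 9))
    return ProtocolSchedule(
        emp=emp, warmup_load=0.20 * emp, warmup_duration=2.0, step_loads=steps
    )


def percent_predicted(observed: float, predicted: float) -> float:
    """Observed performance as a percentage of its normative prediction."""
    if predicted <= 0:
        raise ValueError("predicted value must be positive")
    if observed < 0:
        raise ValueError("observed value must be non-negative")
    return 100.0 * observed / predicted


def mvc_mp_ratio(pct_mvc: float, pct_mp: float) -> float:
    """The screening index: %Pred MVC divided by %Pred MP."""
    if pct_mp <= 0:
        raise ValueError("pct_mp must be positive")
    return pct_mvc / pct_mp


def iso_line_class(pct_mvc: float, pct_mp: float, tolerance: float = 0.0) -> str:
    """Position relative to the iso-line of equal percent-predicted values.

    Returns ``"above"`` (grip relatively preserved), ``"below"`` or ``"on"``
    (|ratio − 1| ≤ tolerance).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ratio = mvc_mp_ratio(pct_mvc, pct_mp)
    if ratio > 1 + tolerance:
        return "above"
    if ratio < 1 - tolerance:
        return "below"
    return "on"


@dataclass(frozen=True)
class PercentPredicted:
    """Predicted and percent-predicted performances for one subject."""

    pred_mvc: float  # DaN
    pred_mp: float  # W
    pct_mvc: float  # %
    pct_mp: float  # %
    ratio: float  # dimensionless, pct_mvc / pct_mp

    def __post_init__(self) -> None:
        if self.pred_mvc <= 0 or self.pred_mp <= 0:
            raise ValueError("predicted values must be positive")

    @classmethod
    def from_measurements(
        cls, sex: Sex, age: float, height: float, forearm_circumference: float,
        mvc: float, mp: float,
    ) -> "PercentPredicted":
        pred_mvc = predict_mvc(sex, age, forearm_circumference)
        pred_mp = predict_mp(sex, age, height)
        pct_mvc = percent_predicted(mvc, pred_mvc)
        pct_mp = percent_predicted(mp, pred_mp)
        return cls(pred_mvc, pred_mp, pct_mvc, pct_mp, mvc_mp_ratio(pct_mvc, pct_mp))

    @classmethod
    def from_record(cls, record: "SubjectRecord") -> "PercentPredicted":
        return cls.from_measurements(
            record.sex, record.age, record.height,
            record.forearm_circumference, record.mvc, record.mp,
        )

    def iso_class(self, tolerance: float = 0.0) -> str:
        return iso_line_class(self.pct_mvc, self.pct_mp, tolerance)
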