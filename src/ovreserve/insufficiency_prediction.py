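"""Propagation of an irradiated pool to the insufficiency threshold.

An exposure scenario is an (age at treatment, ovarian dose) pair. The
dose instantaneously reduces the pool; the residual pool then decays
under the same count-triggered rates as an unirradiated pool until it
reaches the insufficiency threshold ``n_menopause``.

The loss of ovarian function (LOF) of a scenario is the percentage
decrease in the remaining time to insufficiency relative to an
unirradiated woman of the same age:

    LOF = 100 * (T0 - T1) / T0,

with T0 = age_menopause - age and T1 the post-irradiation remaining
time. LOF is 0 at zero dose and 100 at (or beyond) the sterilizing dose.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError
from .radiation_response import RadiationParams, apply_dose
from .reserve_decay import DecayParams, oocyte_count, time_to_threshold

__all__ = [
    "ExposureScenario",
    "PredictionResult",
    "age_at_insufficiency",
    "remaining_years",
    "loss_of_function",
    "predict",
]


@dataclass(frozen=True)
class ExposureScenario:
    """One (age at treatment, total ovarian dose) exposure."""

    age_at_treatment: float
    dose: float

    def __post_init__(self) -> None:
        if self.age_at_treatment < 0:
            raise DomainError(f"age must be non-negative, got {self.age_at_treatment}")
        if self.dose < 0:
            raise DomainError(f"dose must be non-negative, got {self.dose}")


@dataclass(frozen=True)
class PredictionResult:
    """Mechanistic prediction for one exposure scenario."""

    residual_count: float
    age_insufficiency: float
    remaining_years_with_rx: float
    remaining_years_no_rx: float
    lof_percent: float


def remaining_years(age: float, decay: DecayParams) -> float:
    """Expected years of ovarian function left without irradiation."""
    if not (0 <= age < decay.age_menopause):
        raise DomainError(
            f"age must lie in [0, {decay.age_menopause}) years, got {age}"
        )
    return decay.age_menopause - age


def age_at_insufficiency(
    scenario: ExposureScenario, decay: DecayParams, rad: RadiationParams
) -> float:
    """Age at which the post-dose pool first reaches the threshold.

    The residual pool R = N(age)·f(dose) decays under the unirradiated,
    count-triggered rates; because the dynamics depend only on the
    current count, the remaining time is the closed-form
    :func:`ovreserve.reserve_decay.time_to_threshold` (no integration-grid
    artifacts). Equals ``age_menopause`` at zero dose and the treatment
    age itself at or beyond the sterilizing dose.
    """
    age = scenario.age_at_treatment
    if age >= decay.age_menopause:
        raise DomainError(f"treatment age {age} is past menopause")
    n = oocyte_count(age, decay)
    if n <= decay.n_menopause:
        raise DomainError(
            f"pool already at/below the insufficiency threshold at age {age}"
        )
    residual = apply_dose(n, scenario.dose, rad)
    return age + time_to_threshold(residual, decay)


def loss_of_function(
    scenario: ExposureScenario, decay: DecayParams, rad: RadiationParams
) -> float:
    """LOF (%) of a scenario; 0 at zero dose, 100 at the sterilizing dose."""
    return predict(scenario, decay, rad).lof_percent


def predict(
    scenario: ExposureScenario, decay: DecayParams, rad: RadiationParams
) -> PredictionResult:
    """Full mechanistic prediction for one scenario."""
    age = scenario.age_at_treatment
    t0 = remaining_years(age, decay)
    age_ins = age_at_insufficiency(scenario, decay, rad)
    t1 = age_ins - age
    lof = 100.0 * (t0 - t1) / t0
    # guard fp crumbs at the dose=0 / sterilizing endpoints
    lof = min(100.0, max(0.0, lof))
    n = oocyte_count(age, decay)
    return PredictionResult(
        residual_count=apply_dose(n, scenario.dose, rad),
        age_insufficiency=age_ins,
        remaining_years_with_rx=t1,
        remaining_years_no_rx=t0,
        lof_percent=lof,
    )
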