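"""Oocyte survival after ovarian irradiation.

Oocyte kill is modelled as log-linear in dose: the surviving fraction
after a total ovarian dose z (Gy, both ovaries receiving the same dose)
is

    f(z) = 10**(-alpha * z),

with ``alpha = 0.15`` per Gy by default, corresponding to an oocyte LD50
of log10(2)/0.15 ≈ 2.0 Gy. The dose reduces the pool instantaneously at
the age of treatment; no fractionation or repair correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError
from .reserve_decay import DecayParams, oocyte_count

__all__ = [
    "RadiationParams",
    "surviving_fraction",
    "apply_dose",
    "sterilizing_dose",
]


@dataclass(frozen=True)
class RadiationParams:
    """Dose-response constant.

    ``alpha`` is the decadic slope of the survival curve per Gy:
    log10(surviving fraction) = -alpha * dose.
    """

    alpha: float = 0.15

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DomainError(f"alpha must be positive, got {self.alpha}")


def surviving_fraction(dose: float, params: RadiationParams = RadiationParams()) -> float:
    """Fraction of oocytes surviving ``dose`` Gy; 1 at zero dose."""
    if dose < 0:
        raise DomainError(f"dose must be non-negative, got {dose}")
    return 10.0 ** (-params.alpha * dose)


def apply_dose(
    count: float, dose: float, params: RadiationParams = RadiationParams()
) -> float:
    """Pool size immediately after an instantaneous dose."""
    if count <= 0:
        raise DomainError(f"count must be positive, got {count}")
    return count * surviving_fraction(dose, params)


def sterilizing_dose(
    age: float, decay: DecayParams, params: RadiationParams = RadiationParams()
) -> float:
    """Smallest dose causing immediate ovarian insufficiency at ``age``.

    Solves ``oocyte_count(age) * 10**(-alpha*z) = n_menopause``:
    ``z = log10(N(age)/n_menopause) / alpha``. Zero exactly at
    ``age_menopause``, where the pool sits at the threshold; beyond that
    the pool is already below the threshold and a :class:`DomainError`
    is raised.
    """
    if age < 0 or age > decay.age_menopause:
        raise DomainError(
            f"age must lie in [0, {decay.age_menopause}] years, got {age}"
        )
    n = oocyte_count(age, decay)
    return math.log10(n / decay.n_menopause) / params.alpha
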