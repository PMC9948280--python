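"""Age-dependent decline of the ovarian primordial-follicle pool.

The human ovary holds a finite pool of primordial follicles that declines
from birth to menopause. The decline is biexponential: a slow phase from
birth and an accelerated phase late in reproductive life, the acceleration
setting in when roughly 25,000 follicles remain (around age 37). Menopause
corresponds to the pool falling below ~1,000 follicles, at a median age
of 51 years.

The model here is a count-triggered two-phase exponential,

    dN/dt = -k(N) * N,   k(N) = k1 if N > n_break else k2,

with ``k2 > k1``. The trigger is the *count*, not the age, so a pool
depleted by radiation below ``n_break`` immediately adopts the accelerated
rate. The two rates are calibrated so the unperturbed trajectory passes
exactly through three anchors: ``n0`` at birth, ``n_break`` at
``age_break`` and ``n_menopause`` at ``age_menopause``.

Because each phase is a pure exponential, the model has a closed form
(:func:`oocyte_count`, inverted by :func:`age_at_count`) which serves as
the analytical oracle for the fixed-step fourth-order Runge-Kutta
integrator (:func:`integrate_rk4`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import CalibrationError, DomainError, ParameterError

__all__ = [
    "DecayParams",
    "Trajectory",
    "calibrate_decay",
    "default_decay",
    "decline_rate",
    "oocyte_count",
    "age_at_count",
    "time_to_threshold",
    "integrate_rk4",
]

#: Published calibration anchors: oocytes at birth, count and age at the
#: onset of accelerated loss, count defining insufficiency, median age of
#: natural menopause.
DEFAULT_ANCHORS = dict(
    n0=701_200.0,
    n_break=25_000.0,
    age_break=37.0,
    n_menopause=1_000.0,
    age_menopause=51.0,
)


@dataclass(frozen=True)
class DecayParams:
    """Calibrated constants of the two-phase exponential decline model.

    Attributes
    ----------
    n0 : float
        Oocyte count at birth.
    n_break : float
        Count at which the decline accelerates (phase switch).
    age_break : float
        Age (years) at which an unperturbed pool reaches ``n_break``.
    n_menopause : float
        Count threshold defining ovarian insufficiency.
    age_menopause : float
        Age (years) at which an unperturbed pool reaches ``n_menopause``.
    k1, k2 : float
        First- and second-phase per-year fractional loss rates (1/yr),
        ``k2 > k1 > 0``.
    """

    n0: float
    n_break: float
    age_break: float
    n_menopause: float
    age_menopause: float
    k1: float = field(repr=True)
    k2: float = field(repr=True)

    def __post_init__(self) -> None:
        if not (self.n0 > self.n_break > self.n_menopause > 0):
            raise CalibrationError(
                "counts must satisfy n0 > n_break > n_menopause > 0, got "
                f"{self.n0} > {self.n_break} > {self.n_menopause}"
            )
        if not (0 < self.age_break < self.age_menopause):
            raise CalibrationError(
                "ages must satisfy 0 < age_break < age_menopause, got "
                f"{self.age_break}, {self.age_menopause}"
            )
        if not (self.k2 > self.k1 > 0):
            raise CalibrationError(
                f"rates must satisfy k2 > k1 > 0, got k1={self.k1}, k2={self.k2}"
            )


def calibrate_decay(
    n0: float,
    n_break: float,
    age_break: float,
    n_menopause: float,
    age_menopause: float,
) -> DecayParams:
    """Calibrate the two-phase rates from three (age, count) anchors.

    ``k1 = ln(n0/n_break)/age_break`` and
    ``k2 = ln(n_break/n_menopause)/(age_menopause - age_break)``, so the
    closed-form trajectory passes exactly through (0, n0),
    (age_break, n_break) and (age_menopause, n_menopause).

    Raises
    ------
    CalibrationError
        If counts are not strictly decreasing in the order given, or the
        ages are not ordered, or any quantity is non-positive.
    """
    if min(n0, n_break, n_menopause) <= 0 or not (n0 > n_break > n_menopause):
        raise CalibrationError(
            f"anchor counts must be positive and strictly decreasing: "
            f"{n0}, {n_break}, {n_menopause}"
        )
    if not (0 < age_break < age_menopause):
        raise CalibrationError(
            f"anchor ages must satisfy 0 < age_break < age_menopause: "
            f"{age_break}, {age_menopause}"
        )
    k1 = math.log(n0 / n_break) / age_break
    k2 = math.log(n_break / n_menopause) / (age_menopause - age_break)
    return DecayParams(
        n0=n0,
        n_break=n_break,
        age_break=age_break,
        n_menopause=n_menopause,
        age_menopause=age_menopause,
        k1=k1,
        k2=k2,
    )


def default_decay() -> DecayParams:
    """Decay model calibrated to the published anchors."""
    return calibrate_decay(
        DEFAULT_ANCHORS["n0"],
        DEFAULT_ANCHORS["n_break"],
        DEFAULT_ANCHORS["age_break"],
        DEFAULT_ANCHORS["n_menopause"],
        DEFAULT_ANCHORS["age_menopause"],
    )


def _phase_rate(count: float, params: DecayParams) -> float:
    # boundary N == n_break belongs to phase 2 (deterministic tie-break)
    return params.k1 if count > params.n_break else params.k2


def decline_rate(count: float, params: DecayParams) -> float:
    """Right-hand side of the decline ODE, dN/dt = -k(N)*N (oocytes/yr).

    Always negative. The boundary ``count == n_break`` uses the
    accelerated rate ``k2``.
    """
    if count <= 0:
        raise DomainError(f"oocyte count must be positive, got {count}")
    return -_phase_rate(count, params) * count


def oocyte_count(age, params: DecayParams):
    """Closed-form oocyte count of an unperturbed pool at ``age`` years.

    ``n0*exp(-k1*age)`` up to ``age_break``, then
    ``n_break*exp(-k2*(age-age_break))``; continuous at the break.
    Accepts a scalar or array; negative ages raise :class:`DomainError`.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise DomainError(f"age must be non-negative, got {age}")
    out = np.where(
        a <= params.age_break,
        params.n0 * np.exp(-params.k1 * a),
        params.n_break * np.exp(-params.k2 * (a - params.age_break)),
    )
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def age_at_count(count: float, params: DecayParams) -> float:
    """Exact inverse of :func:`oocyte_count` on (0, n0]."""
    if not (0 < count <= params.n0):
        raise DomainError(f"count must be in (0, {params.n0}], got {count}")
    if count > params.n_break:
        return math.log(params.n0 / count) / params.k1
    return params.age_break + math.log(params.n_break / count) / params.k2


def time_to_threshold(count: float, params: DecayParams) -> float:
    """Years for a pool of ``count`` oocytes to decay to ``n_menopause``.

    The dynamics depend only on the current count, so a pool of size N
    behaves exactly like an unperturbed pool observed at ``age_at_count(N)``;
    the answer is ``age_menopause - age_at_count(count)``, clamped at zero
    for pools already below the threshold.
    """
    if count <= 0:
        raise DomainError(f"count must be positive, got {count}")
    if count <= params.n_menopause:
        return 0.0
    return params.age_menopause - age_at_count(count, params)


@dataclass(frozen=True)
class Trajectory:
    """An integrated (ages, counts) trajectory; same length, counts > 0."""

    ages: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.ages.shape != self.counts.shape:
            raise ParameterError("ages and counts must have the same length")

    def __len__(self) -> int:
        return self.ages.size

    def final_count(self) -> float:
        return float(self.counts[-1])


def _rk4_step(n: float, h: float, k: float) -> float:
    # one classic RK4 step for dN/dt = -k*N with the rate frozen
    s1 = -k * n
    s2 = -k * (n + 0.5 * h * s1)
    s3 = -k * (n + 0.5 * h * s2)
    s4 = -k * (n + h * s3)
    return n + h / 6.0 * (s1 + 2.0 * s2 + 2.0 * s3 + s4)


def _advance(n: float, h: float, params: DecayParams) -> float:
    """Advance the pool by one step of length ``h``.

    The rate constant is frozen per phase. If the step crosses the phase
    boundary ``n_break``, the crossing instant is located to machine
    precision (root of the slow-phase RK4 sub-step) and the step is split
    there, so each sub-step integrates a smooth exponential and the
    integrator retains its fourth-order accuracy through the switch.
    """
    if h == 0.0:
        return n
    k = _phase_rate(n, params)
    cand = _rk4_step(n, h, k)
    if n > params.n_break and cand < params.n_break:
        # slow phase would cross the switch inside this step
        f = lambda d: _rk4_step(n, d, params.k1) - params.n_break
        d_cross = brentq(f, 0.0, h, xtol=1e-14, rtol=8.9e-16)
        return _rk4_step(params.n_break, h - d_cross, params.k2)
    return cand


def integrate_rk4(
    start_count: float,
    start_age: float,
    end_age: float,
    step: float,
    params: DecayParams,
) -> Trajectory:
    """Integrate the decline ODE with fixed-step fourth-order Runge-Kutta.

    Returns the trajectory sampled at ``start_age + i*step`` (the last
    interval is shortened to land exactly on ``end_age``). A zero-length
    interval returns a single-point trajectory.

    Raises
    ------
    ParameterError
        If ``step <= 0`` or ``end_age < start_age``.
    DomainError
        If ``start_count <= 0``.
    """
    if start_count <= 0:
        raise DomainError(f"start_count must be positive, got {start_count}")
    if step <= 0:
        raise ParameterError(f"step must be positive, got {step}")
    if end_age < start_age:
        raise ParameterError(
            f"end_age ({end_age}) must not precede start_age ({start_age})"
        )

    ages = [start_age]
    counts = [start_count]
    n = start_count
    t = start_age
    while t < end_age - 1e-12:
        h = min(step, end_age - t)
        n = _advance(n, h, params)
        t = t + h
        ages.append(t)
        counts.append(n)
    return Trajectory(np.array(ages), np.array(counts))
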