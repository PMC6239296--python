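"""Power-duration modelling of human running performance.

A runner's metabolic power is measured on a relative scale: zero at the
basal rate ``P_b`` and one at the crossover power ``P_m`` (close to the
power at maximal oxygen uptake), so that the *aerobic power reserve*
``P_m - P_b`` normalises all intensities.  The maximal average power that
can be sustained over a duration ``T`` declines logarithmically,

    p_max(T) = 1 - gamma_s * log(T / t_c)   for T <= t_c,
    p_max(T) = 1 - gamma_l * log(T / t_c)   for T >  t_c,

where ``t_c`` is the crossover time separating supra-maximal (short) from
sub-maximal (long) efforts and ``gamma_s``, ``gamma_l`` are dimensionless
endurance exponents.  This form is the exact solution of a
self-consistency relation: the nominal average power plus a supplemental
power (the slow drift in running economy plus anaerobic contributions)
equals the time average of the instantaneous power, which at time ``t`` of
a race of duration ``T`` equals the maximal power sustainable for the
remaining ``T - t``.

Because running economy is linear in velocity (``p = v / v_m`` with
crossover velocity ``v_m``), the fastest time over a distance ``d``
follows in closed form through the real branch ``W_-1`` of the Lambert W
function, and the four parameters ``(t_c, v_m, gamma_s, gamma_l)`` can be
recovered from a handful of race results by least squares on relative
time deviations.  Derived quantities include the endurance indices
``E_l = exp(0.1 / gamma_l)`` and ``E_s = exp(-0.1 / gamma_s)`` (multiples
of ``t_c`` over which 90% / 110% of crossover power can be held), the
crossover distance ``d_c = v_m * t_c``, the lactate-threshold intensity
``p_LT = 100 * [1 - gamma_l * log(60 / t_c)]`` and personalised training
paces at prescribed intensity for a prescribed duration or distance.

Internal units are fixed: distance in metres, time in minutes, velocity
in metres per minute.  Conversion to and from clock notation happens only
at the I/O boundary.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "MILE",
    "HALF_MARATHON",
    "MARATHON",
    "DISTANCE_ALIASES",
    "AthleteProfile",
    "PowerDurationPoint",
    "RescaledCoordinates",
    "EnduranceSummary",
    "RaceResult",
    "RaceSet",
    "FitOptions",
    "FitReport",
    "PaceQuery",
    "PaceEntry",
    "PaceTable",
    "ProfileVariant",
    "ModelDomainError",
    "ParseError",
    "InsufficientDataError",
    "lambert_w_m1",
    "relative_power",
    "economy_relative_power",
    "p_max",
    "supplemental_power_rel",
    "duration_at_relative_power",
    "duration_at_velocity",
    "race_time",
    "mean_race_velocity",
    "rescaled_coordinates",
    "approx_race_time",
    "supplemental_factor",
    "endurance_summary",
    "verify_self_consistency",
    "objective",
    "fit_profile",
    "generate_race_set",
    "velocity_at_intensity_duration",
    "velocity_at_intensity_distance",
    "pace_table",
    "threshold_intensity",
    "parse_time",
    "format_time",
    "format_pace",
    "parse_distance",
    "read_race_csv",
    "write_race_csv",
    "RecordFixture",
    "PaceFixture",
    "RECORD_FIXTURES",
    "ATHLETE_FIXTURES",
    "PACE_FIXTURES",
    "STANDARD_PACE_QUERIES",
    "ENDURANCE_VARIANTS",
    "TC_VARIANTS",
    "reproduce_tables",
    "TableIssue",
    "TableReport",
]

# --------------------------------------------------------------------------
# Configuration: units, bounds, named distances, logging
# --------------------------------------------------------------------------

LOG = logging.getLogger("runpower")

#: Default basal metabolic rate in W/kg, used only when an absolute power
#: scale is requested and the profile does not carry its own P_b.
BASAL_POWER_DEFAULT = 1.2

#: Lower bound on the endurance exponents; below this exp(1/gamma)
#: overflows and the model degenerates.
GAMMA_MIN = 1e-3

MILE = 1609.34
HALF_MARATHON = 21097.5
MARATHON = 42195.0

#: Named distance aliases accepted wherever a distance is parsed.
DISTANCE_ALIASES = {
    "mile": MILE,
    "half": HALF_MARATHON,
    "half-marathon": HALF_MARATHON,
    "marathon": MARATHON,
}

#: Sanity window for implied race velocities (m/min); results outside it
#: are accepted with a warning.
VELOCITY_SANITY = (50.0, 800.0)

#: Box bounds for the four fitted parameters (t_c min, v_m m/min, gammas).
FIT_BOUNDS = {
    "t_c": (2.0, 40.0),
    "v_m": (150.0, 700.0),
    "gamma_s": (GAMMA_MIN, 0.5),
    "gamma_l": (GAMMA_MIN, 0.5),
}

#: Multi-start grid for the fit; v_m is started from the observed velocity
#: at the result whose time is closest to six minutes.
TC_STARTS = (4.0, 6.0, 9.0, 13.0, 20.0)
GAMMA_L_STARTS = (0.04, 0.055, 0.08)
GAMMA_S_STARTS = (0.06, 0.10, 0.15)

_INV_E = 1.0 / math.e


class ModelDomainError(ValueError):
    """An input lies outside the region where the model is defined
    (negative duration, Lambert argument outside [-1/e, 0), ...)."""


class ParseError(ValueError):
    """A time string, distance token or CSV row could not be parsed."""


class InsufficientDataError(ValueError):
    """Too few race results for a four-parameter fit."""


# --------------------------------------------------------------------------
# Clock-time parsing and formatting (I/O boundary)
# --------------------------------------------------------------------------

def _round_half_up_centi(x: float) -> int:
    return math.floor(x * 100.0 + 0.5)


def parse_time(text: str) -> float:
    """Parse ``h:mm:ss.xx``, ``mm:ss.xx`` or bare seconds into minutes.

    >>> parse_time("58:23.00")
    58.38333333333333
    >>> parse_time("2:01:39.00") * 60
    7299.0
    >>> parse_time("90")
    1.5
    """
    token = str(text).strip()
    parts = token.split(":")
    if not token or any(p.strip() == "" for p in parts):
        raise ParseError(f"empty time component in {text!r}")
    try:
        values = [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"unparsable time {text!r}") from exc
    if any(v < 0 for v in values):
        raise ParseError(f"negative time component in {text!r}")
    if len(parts) == 1:
        return values[0] / 60.0  # bare seconds
    if len(parts) == 2:
        mm, ss = values
        if ss >= 60.0 or mm >= 60.0:
            raise ParseError(f"component out of range in {text!r} (mm, ss < 60)")
        return mm + ss / 60.0
    if len(parts) == 3:
        hh, mm, ss = values
        if ss >= 60.0 or mm >= 60.0:
            raise ParseError(f"component out of range in {text!r} (mm, ss < 60)")
        return hh * 60.0 + mm + ss / 60.0
    raise ParseError(f"too many ':' in time {text!r}")


def format_time(minutes: float) -> str:
    """Format minutes as ``mm:ss.xx`` below one hour, ``h:mm:ss.xx`` above,
    rounding half-up at 0.01 s."""
    if not math.isfinite(minutes) or minutes < 0:
        raise ValueError(f"cannot format time {minutes!r}")
    centi = _round_half_up_centi(minutes * 60.0)
    s, cs = divmod(centi, 100)
    m, s = divmod(s, 60)
    h, m = divmod(m, 60)
    if h:
        return f"{h}:{m:02d}:{s:02d}.{cs:02d}"
    return f"{m:02d}:{s:02d}.{cs:02d}"


def format_pace(seconds_per_km: float) -> str:
    """Format a pace in seconds per kilometre as ``mm:ss.xx``."""
    centi = _round_half_up_centi(seconds_per_km)
    s, cs = divmod(centi, 100)
    m, s = divmod(s, 60)
    return f"{m:02d}:{s:02d}.{cs:02d}"


def parse_distance(token: str | float) -> float:
    """A distance in metres, or one of the named aliases (mile, half, marathon)."""
    if isinstance(token, (int, float)):
        value = float(token)
    else:
        key = str(token).strip().lower()
        if key in DISTANCE_ALIASES:
            return DISTANCE_ALIASES[key]
        try:
            value = float(key)
        except ValueError as exc:
            raise ParseError(f"unknown distance {token!r}") from exc
    if value <= 0:
        raise ParseError(f"distance must be positive, got {token!r}")
    return value


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AthleteProfile:
    """The four physiological parameters of a runner.

    Parameters
    ----------
    t_c : float
        Crossover time in minutes, separating supra-maximal from
        sub-maximal efforts; roughly the time maximal aerobic power can
        be sustained (5-6 min for elite men, longer for many runners).
    v_m : float
        Crossover velocity in m/min, the smallest velocity nominally
        eliciting the crossover power.
    gamma_s, gamma_l : float
        Dimensionless endurance exponents for the short (supra-maximal)
        and long (sub-maximal) regime; smaller ``gamma_l`` and larger
        ``gamma_s`` both mean better endurance on the respective side.
    P_b, P_m : float, optional
        Absolute basal and crossover power in W/kg.  Race times and paces
        are determined by the four relative parameters alone; these are
        annotations used only when an absolute power scale is requested.
    """

    t_c: float
    v_m: float
    gamma_s: float
    gamma_l: float
    P_b: float | None = None
    P_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_c > 0 and math.isfinite(self.t_c)):
            raise ValueError(f"t_c must be positive, got {self.t_c}")
        if not (self.v_m > 0 and math.isfinite(self.v_m)):
            raise ValueError(f"v_m must be positive, got {self.v_m}")
        for name, g in (("gamma_s", self.gamma_s), ("gamma_l", self.gamma_l)):
            if not (GAMMA_MIN <= g < 1.0):
                raise ValueError(
                    f"{name} must lie in [{GAMMA_MIN}, 1), got {g}"
                )
        if self.P_b is not None and self.P_m is not None and self.P_m <= self.P_b:
            raise ValueError("P_m must exceed P_b")

    @property
    def d_c(self) -> float:
        """Crossover distance ``v_m * t_c`` in metres."""
        return self.v_m * self.t_c

    def as_dict(self) -> dict:
        d = {
            "t_c": self.t_c,
            "v_m": self.v_m,
            "gamma_s": self.gamma_s,
            "gamma_l": self.gamma_l,
        }
        if self.P_b is not None:
            d["P_b"] = self.P_b
        if self.P_m is not None:
            d["P_m"] = self.P_m
        return d


@dataclass(frozen=True)
class PowerDurationPoint:
    """A (duration, power) sample; ``p`` is relative power, ``P`` absolute
    W/kg (either may be carried)."""

    T: float
    p: float | None = None
    P: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class RescaledCoordinates:
    """Logarithmic race coordinates: ``tau = log(T/t_c)``,
    ``delta = log(d/d_c)``, ``upsilon = log(vbar/v_m)``; the identity
    ``tau = delta - upsilon`` holds exactly because ``vbar = d/T``."""

    tau: float
    delta: float
    upsilon: float


@dataclass(frozen=True)
class EnduranceSummary:
    """Endurance indices and threshold quantities of a profile."""

    E_s: float
    E_l: float
    d_c: float
    p_LT: float


# --------------------------------------------------------------------------
# Lambert W, real branch W_-1
# --------------------------------------------------------------------------

def _wm1_raw(z: np.ndarray) -> np.ndarray:
    """W_-1 on a float array assumed to lie inside [-1/e, 0).

    Initialised from the asymptotic expansion
    ``L1 - L2 + L2/L1 + (L2^2 - 2 L2)/(2 L1^2)`` with ``L1 = log(-z)``,
    ``L2 = log(-L1)`` (switching to the branch-point series in
    ``sqrt(2(1 + e z))`` near ``z = -1/e``), then polished by Halley
    iteration on ``w e^w - z``.
    """
    z = np.asarray(z, dtype=float)
    w = np.empty_like(z)
    ez1 = np.e * z + 1.0  # distance from the branch point, >= 0

    near = ez1 < 1e-3
    if np.any(near):
        p = -np.sqrt(2.0 * np.clip(ez1[near], 0.0, None))
        w[near] = -1.0 + p * (1.0 + p * (-1.0 / 3.0 + p * (11.0 / 72.0)))
    far = ~near
    if np.any(far):
        L1 = np.log(-z[far])
        L2 = np.log(-L1)
        w[far] = L1 - L2 + L2 / L1 + (L2 - 2.0) * L2 / (2.0 * L1 * L1)

    # So close to the branch point that the series is already at machine
    # precision and Halley's denominator would be ill-conditioned.
    active = ez1 >= 1e-12
    for _ in range(64):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        wa = w[idx]
        ew = np.exp(wa)
        f = wa * ew - z[idx]
        wp1 = wa + 1.0
        denom = ew * wp1 - (wp1 + 1.0) * f / (2.0 * wp1)
        step = np.where(denom != 0.0, f / np.where(denom != 0.0, denom, 1.0), 0.0)
        wa = wa - step
        w[idx] = wa
        done = np.abs(step) <= 1e-15 * (1.0 + np.abs(wa))
        active[idx[done]] = False
    return w


def lambert_w_m1(z):
    """Real branch ``W_-1(z)`` of the Lambert W function for
    ``z in [-1/e, 0)``; the solution ``w <= -1`` of ``w e^w = z``.

    Accepts a scalar or array.  Raises :class:`ModelDomainError` outside
    the domain -- when reached from the race-time formulas this signals a
    distance or velocity outside the model's validity.
    """
    arr = np.atleast_1d(np.asarray(z, dtype=float))
    if arr.size == 0:
        return arr
    if (not np.all(np.isfinite(arr))) or np.any(arr >= 0.0) or np.any(
        arr < -_INV_E * (1.0 + 1e-12)
    ):
        raise ModelDomainError(
            f"Lambert W_-1 argument outside [-1/e, 0): {np.asarray(z)!r}"
        )
    w = _wm1_raw(np.clip(arr, -_INV_E, None))
    if np.ndim(z) == 0:
        return float(w[0])
    return w


def _wm1_series(z):
    """Truncated asymptotic expansion of W_-1 (no Halley polish); accurate
    to better than 0.4% for |z| <= 0.1."""
    z = np.asarray(z, dtype=float)
    L1 = np.log(-z)
    L2 = np.log(-L1)
    return L1 - L2 + L2 / L1 + (L2 - 2.0) * L2 / (2.0 * L1 * L1)


# --------------------------------------------------------------------------
# Closed-form model equations
# --------------------------------------------------------------------------

def _shape_like(x, template) -> float | np.ndarray:
    return float(x[0]) if np.ndim(template) == 0 else x


def relative_power(P, P_b: float, P_m: float):
    """Map absolute power (W/kg) to the relative scale
    ``p = (P - P_b) / (P_m - P_b)``; 0 at basal, 1 at crossover."""
    if P_m <= P_b:
        raise ValueError("P_m must exceed P_b")
    return (np.asarray(P, dtype=float) - P_b) / (P_m - P_b) if np.ndim(P) else (
        (float(P) - P_b) / (P_m - P_b)
    )


def economy_relative_power(v, profile: AthleteProfile):
    """Nominal (short-duration, laboratory) intensity to run at velocity
    ``v``: running economy is linear, ``p = v / v_m``."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("velocity must be non-negative")
    out = arr / profile.v_m
    return float(out) if np.ndim(v) == 0 else out


def p_max(T, profile: AthleteProfile, relative: bool = True):
    """Maximal average power sustainable over duration ``T`` (minutes).

    Relative form: ``1 - gamma * log(T/t_c)`` with ``gamma_s`` below the
    crossover time and ``gamma_l`` above; continuous at ``t_c`` with value
    1 (i.e. ``P_m``), non-increasing in ``T``.  With ``relative=False``
    the profile must carry ``P_m`` (``P_b`` defaults to 1.2 W/kg).
    """
    arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(arr <= 0):
        raise ModelDomainError("duration must be positive")
    gamma = np.where(arr < profile.t_c, profile.gamma_s, profile.gamma_l)
    rel = 1.0 - gamma * np.log(arr / profile.t_c)
    if np.any(rel <= 0):
        warnings.warn(
            "p_max fell to or below the basal level; duration outside the "
            "model's useful range",
            stacklevel=2,
        )
    if relative:
        return _shape_like(rel, T)
    if profile.P_m is None:
        raise ValueError("absolute p_max requires P_m on the profile")
    P_b = profile.P_b if profile.P_b is not None else BASAL_POWER_DEFAULT
    return _shape_like(P_b + rel * (profile.P_m - P_b), T)


def supplemental_power_rel(T, profile: AthleteProfile):
    """Supplemental power (drift in running economy plus anaerobic
    contribution) as a fraction of the aerobic power reserve:
    ``gamma_s`` for ``T <= t_c``, ``(gamma_s - gamma_l) t_c/T + gamma_l``
    beyond; continuous at ``t_c``, tending to ``gamma_l`` as T grows."""
    arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(arr <= 0):
        raise ModelDomainError("duration must be positive")
    gs, gl, tc = profile.gamma_s, profile.gamma_l, profile.t_c
    out = np.where(arr < tc, gs, (gs - gl) * tc / arr + gl)
    return _shape_like(out, T)


def duration_at_relative_power(p, profile: AthleteProfile):
    """Longest duration (minutes) over which relative power ``p`` can be
    sustained: ``t_c * exp(-(p-1)/gamma)``, ``gamma_l`` for ``p <= 1`` and
    ``gamma_s`` for ``p > 1``.  Inverse of the relative ``p_max``."""
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(arr <= 0):
        raise ModelDomainError("relative power must be positive")
    gamma = np.where(arr > 1.0, profile.gamma_s, profile.gamma_l)
    out = profile.t_c * np.exp(-(arr - 1.0) / gamma)
    return _shape_like(out, p)


def duration_at_velocity(v, profile: AthleteProfile):
    """Longest duration (minutes) over which an average velocity ``v``
    (m/min) can be sustained.  Warns below one minute, where oxygen-uptake
    kinetics (not modelled) dominate."""
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if np.any(arr <= 0):
        raise ModelDomainError("velocity must be positive")
    out = duration_at_relative_power(arr / profile.v_m, profile)
    out = np.atleast_1d(out)
    if np.any(out < 1.0):
        warnings.warn(
            "predicted duration below 1 minute: oxygen-kinetics regime "
            "outside the model",
            stacklevel=2,
        )
    return _shape_like(out, v)


def _race_lambert_parts(d, profile: AthleteProfile, intensity: float = 1.0):
    """Branch exponent and Lambert argument for a distance query."""
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(arr <= 0):
        raise ModelDomainError("distance must be positive")
    gamma = np.where(arr < profile.d_c, profile.gamma_s, profile.gamma_l)
    z = -(arr / profile.d_c) / (intensity * gamma) * np.exp(-1.0 / gamma)
    if np.any(z >= 0.0) or np.any(z < -_INV_E * (1.0 + 1e-12)):
        raise ModelDomainError(
            "distance outside model validity for the given profile "
            "(Lambert argument leaves [-1/e, 0))"
        )
    return arr, gamma, np.clip(z, -_INV_E, None)


def race_time(d, profile: AthleteProfile):
    """Fastest time (minutes) over distance ``d`` (metres):

        T(d) = -d / (gamma * v_m * W_-1[-(d/d_c)/gamma * exp(-1/gamma)])

    with ``gamma_l`` for ``d >= d_c`` and ``gamma_s`` below; continuous
    and strictly increasing, with ``T(d_c) = t_c``.
    """
    arr, gamma, z = _race_lambert_parts(d, profile)
    w = _wm1_raw(z)
    out = -arr / (gamma * profile.v_m * w)
    return _shape_like(out, d)


def mean_race_velocity(d, profile: AthleteProfile):
    """Mean velocity ``d / T(d)`` (m/min) of a maximal effort over ``d``;
    equals ``v_m`` at the crossover distance and decreases with ``d``."""
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    out = arr / np.atleast_1d(race_time(arr, profile))
    return _shape_like(out, d)


def rescaled_coordinates(d: float, profile: AthleteProfile) -> RescaledCoordinates:
    """Exact logarithmic coordinates of the maximal effort over ``d``."""
    T = race_time(float(d), profile)
    delta = math.log(float(d) / profile.d_c)
    tau = math.log(T / profile.t_c)
    return RescaledCoordinates(tau=tau, delta=delta, upsilon=delta - tau)


def approx_race_time(d: float, profile: AthleteProfile) -> RescaledCoordinates:
    """Asymptotic (series) approximation of the race-time relation.

    In rescaled variables ``tau(delta) = delta - upsilon(delta)`` with
    ``upsilon = L(1/gamma, delta - log gamma)`` where

        L(x, y) = -log x + log[ x - y + log(x-y) + log(x-y)/(x-y)
                                - log(x-y)(log(x-y) - 2) / (2 (x-y)^2) ],

    using ``gamma_l`` at and above the crossover distance, ``gamma_s``
    below.  ``t_c * exp(tau)`` approximates :func:`race_time` to better
    than 0.4% while the Lambert argument stays within [-0.1, 0); a warning
    is issued when it does not.
    """
    dd = float(d)
    if dd <= 0:
        raise ModelDomainError("distance must be positive")
    gamma = profile.gamma_l if dd >= profile.d_c else profile.gamma_s
    delta = math.log(dd / profile.d_c)
    z = -(dd / profile.d_c) / gamma * math.exp(-1.0 / gamma)
    if abs(z) > 0.1:
        warnings.warn(
            f"Lambert argument {z:.3g} beyond 0.1 in magnitude; series "
            "accuracy degrades",
            stacklevel=2,
        )
    x = 1.0 / gamma
    y = delta - math.log(gamma)
    t = x - y  # equals -log(-z) > 1 inside the domain
    lt = math.log(t)
    upsilon = -math.log(x) + math.log(
        t + lt + lt / t - lt * (lt - 2.0) / (2.0 * t * t)
    )
    return RescaledCoordinates(tau=delta - upsilon, delta=delta, upsilon=upsilon)


def supplemental_factor(T, profile: AthleteProfile):
    """Multiplicative excess of total over nominal running power at race
    duration ``T``: the total mean power is
    ``P_b + (vbar/v_m) * factor * (P_m - P_b)``.

    ``factor = 1 + 1/(1/gamma_s - log(T/t_c))`` for ``T <= t_c`` and
    ``1 + (1 + (gamma_s/gamma_l - 1) t_c/T)/(1/gamma_l - log(T/t_c))``
    beyond; it peaks at ``1 + gamma_s`` at the crossover time (a cusp) and
    exceeds 1 for every valid duration.
    """
    arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(arr <= 0):
        raise ModelDomainError("duration must be positive")
    gs, gl, tc = profile.gamma_s, profile.gamma_l, profile.t_c
    short = arr < tc
    gamma = np.where(short, gs, gl)
    den = 1.0 / gamma - np.log(arr / tc)
    if np.any(den <= 0):
        raise ModelDomainError("duration outside the supplemental-factor domain")
    num = np.where(short, 1.0, 1.0 + (gs / gl - 1.0) * tc / arr)
    return _shape_like(1.0 + num / den, T)


def threshold_intensity(profile: AthleteProfile) -> float:
    """Lactate-threshold intensity: the relative power (percent of the
    aerobic power reserve) of the effort sustainable for 60 minutes,
    ``p_LT = 100 [1 - gamma_l log(60 / t_c)]``."""
    return 100.0 * (1.0 - profile.gamma_l * math.log(60.0 / profile.t_c))


def endurance_summary(profile: AthleteProfile) -> EnduranceSummary:
    """Endurance indices ``E_l = exp(0.1/gamma_l)``,
    ``E_s = exp(-0.1/gamma_s)`` (multiples of ``t_c`` over which 90% /
    110% of crossover power can be held), the crossover distance and the
    lactate-threshold intensity."""
    return EnduranceSummary(
        E_s=math.exp(-0.1 / profile.gamma_s),
        E_l=math.exp(0.1 / profile.gamma_l),
        d_c=profile.d_c,
        p_LT=threshold_intensity(profile),
    )


def verify_self_consistency(
    profile: AthleteProfile, T: float, tol: float = 1e-10
) -> float:
    """Residual of the self-consistency relation at duration ``T``.

    The relation states (in relative power) that
    ``p_max(T) + p_sup(T) = (1/T) * integral_0^T p_max(T - t) dt``; the
    logarithmic ``p_max`` solves it exactly, so the residual returned here
    is pure quadrature error.  The integral is evaluated adaptively,
    split at the crossover time.
    """
    if T <= 0:
        raise ModelDomainError("duration must be positive")
    gs, gl, tc = profile.gamma_s, profile.gamma_l, profile.t_c

    def integrand(s: float) -> float:
        g = gs if s < tc else gl
        return 1.0 - g * math.log(s / tc)

    edges = [0.0, min(T, tc)]
    if T > tc:
        edges.append(T)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _err = integrate.quad(
            integrand, a, b, epsabs=min(tol, 1e-10) * 1e-2, epsrel=1e-13, limit=200
        )
        total += val
    lhs = p_max(T, profile) + supplemental_power_rel(T, profile)
    return total / T - lhs


# --------------------------------------------------------------------------
# Race results and parameter estimation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RaceResult:
    """One race: distance in metres, finish time in minutes."""

    distance: float
    time: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.time <= 0:
            raise ValueError("time must be positive")
        v = self.velocity
        if not (VELOCITY_SANITY[0] < v < VELOCITY_SANITY[1]):
            warnings.warn(
                f"implied velocity {v:.1f} m/min outside the sanity window "
                f"{VELOCITY_SANITY} for {self.distance:g} m",
                stacklevel=2,
            )

    @property
    def velocity(self) -> float:
        return self.distance / self.time


@dataclass(frozen=True)
class RaceSet:
    """An ordered set of race results, sorted by distance, no duplicates."""

    results: tuple[RaceResult, ...]
    name: str = ""

    def __init__(self, results: Iterable[RaceResult], name: str = "") -> None:
        ordered = tuple(sorted(results, key=lambda r: r.distance))
        for a, b in zip(ordered[:-1], ordered[1:]):
            if a.distance == b.distance:
                raise ValueError(f"duplicate distance {a.distance:g} m")
        object.__setattr__(self, "results", ordered)
        object.__setattr__(self, "name", name)

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def distances(self) -> np.ndarray:
        return np.array([r.distance for r in self.results])

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.results])


@dataclass(frozen=True)
class FitOptions:
    """Controls for :func:`fit_profile`.

    The optimiser is a derivative-free simplex over log-transformed
    parameters (positivity for free), multi-started on a coarse grid in
    ``(t_c, gamma_l, gamma_s)`` with ``v_m`` anchored at the observed
    velocity of the result raced closest to six minutes; the best start is
    then polished with tight tolerances.  Everything is deterministic; the
    seed is carried for API symmetry with the synthetic generator.
    """

    tc_starts: tuple[float, ...] = TC_STARTS
    gamma_l_starts: tuple[float, ...] = GAMMA_L_STARTS
    gamma_s_starts: tuple[float, ...] = GAMMA_S_STARTS
    coarse_maxfev: int = 800
    coarse_fatol: float = 1e-12
    polish_maxfev: int = 40000
    polish_fatol: float = 1e-17
    polish_xatol: float = 1e-12
    polish_rounds: int = 2
    seed: int = 0


@dataclass(frozen=True)
class FitReport:
    """Fitted profile with per-distance diagnostics.

    ``relative_errors`` are signed percent deviations
    ``100 (T_model - T_obs)/T_obs``; ``objective`` is the minimised sum of
    squared *fractional* deviations (multiply by 1e4 for percent^2 units
    -- the argmin is the same on either scale)."""

    profile: AthleteProfile
    distances: tuple[float, ...]
    observed_times: tuple[float, ...]
    predicted_times: tuple[float, ...]
    relative_errors: tuple[float, ...]
    mean_abs_error: float
    objective: float
    n_starts_converged: int
    warnings: tuple[str, ...] = ()
    name: str = ""

    @property
    def objective_percent(self) -> float:
        return self.objective * 1e4

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "profile": self.profile.as_dict(),
            "distances_m": list(self.distances),
            "observed_times_min": list(self.observed_times),
            "predicted_times_min": list(self.predicted_times),
            "relative_errors_pct": list(self.relative_errors),
            "mean_abs_error_pct": self.mean_abs_error,
            "objective": self.objective,
            "objective_percent": self.objective_percent,
            "n_starts_converged": self.n_starts_converged,
            "warnings": list(self.warnings),
        }


_LOG_LO = np.log(
    [FIT_BOUNDS["t_c"][0], FIT_BOUNDS["v_m"][0], FIT_BOUNDS["gamma_s"][0], FIT_BOUNDS["gamma_l"][0]]
)
_LOG_HI = np.log(
    [FIT_BOUNDS["t_c"][1], FIT_BOUNDS["v_m"][1], FIT_BOUNDS["gamma_s"][1], FIT_BOUNDS["gamma_l"][1]]
)
_PENALTY = 1e6


def _objective_theta(theta: np.ndarray, d: np.ndarray, t: np.ndarray) -> float:
    """Sum of squared fractional time deviations at log-parameters theta;
    bound violations and model-domain failures return a large penalty so
    the simplex keeps moving."""
    lo_viol = np.clip(_LOG_LO - theta, 0.0, None).sum()
    hi_viol = np.clip(theta - _LOG_HI, 0.0, None).sum()
    if lo_viol + hi_viol > 0:
        return _PENALTY * (1.0 + lo_viol + hi_viol)
    tc, vm, gs, gl = np.exp(theta)
    dc = vm * tc
    gamma = np.where(d < dc, gs, gl)
    with np.errstate(over="ignore", under="ignore"):
        z = -(d / dc) / gamma * np.exp(-1.0 / gamma)
    if np.any(z >= 0.0) or np.any(z < -_INV_E):
        return _PENALTY
    w = _wm1_raw(z)
    r = (-d / (gamma * vm * w) - t) / t
    return float(r @ r)


def objective(profile: AthleteProfile, race_set: RaceSet) -> float:
    """Sum over the set of squared fractional deviations
    ``((T_model - T_obs)/T_obs)^2``; +inf when any prediction is
    undefined for the profile."""
    try:
        pred = np.atleast_1d(race_time(race_set.distances, profile))
    except ModelDomainError:
        return math.inf
    r = (pred - race_set.times) / race_set.times
    return float(r @ r)


def fit_profile(race_set: RaceSet, options: FitOptions | None = None) -> FitReport:
    """Estimate ``(t_c, v_m, gamma_s, gamma_l)`` from race results by
    minimising the sum of squared relative time deviations.

    Requires at least four results; for both endurance exponents to be
    identifiable the distances must straddle the fitted crossover
    distance, otherwise the report carries a "branch undetermined"
    warning.  Deterministic: identical inputs give identical reports.
    """
    opts = options or FitOptions()
    if len(race_set) < 4:
        raise InsufficientDataError(
            f"need at least 4 race results for a 4-parameter fit, got {len(race_set)}"
        )
    d = race_set.distances.astype(float)
    t = race_set.times.astype(float)

    j = int(np.argmin(np.abs(t - 6.0)))
    vm0 = float(np.clip(d[j] / t[j], FIT_BOUNDS["v_m"][0] * 1.05, FIT_BOUNDS["v_m"][1] * 0.95))

    best_theta = None
    best_val = math.inf
    n_converged = 0
    for tc0, gl0, gs0 in product(opts.tc_starts, opts.gamma_l_starts, opts.gamma_s_starts):
        theta0 = np.log([tc0, vm0, gs0, gl0])
        res = optimize.minimize(
            _objective_theta,
            theta0,
            args=(d, t),
            method="Nelder-Mead",
            options={
                "maxfev": opts.coarse_maxfev,
                "fatol": opts.coarse_fatol,
                "xatol": 1e-6,
            },
        )
        if res.success:
            n_converged += 1
        if res.fun < best_val:
            best_val = res.fun
            best_theta = res.x
    for _ in range(opts.polish_rounds):
        res = optimize.minimize(
            _objective_theta,
            best_theta,
            args=(d, t),
            method="Nelder-Mead",
            options={
                "maxfev": opts.polish_maxfev,
                "fatol": opts.polish_fatol,
                "xatol": opts.polish_xatol,
            },
        )
        if res.fun <= best_val:
            best_val = res.fun
            best_theta = res.x

    tc, vm, gs, gl = np.exp(best_theta)
    profile = AthleteProfile(t_c=float(tc), v_m=float(vm), gamma_s=float(gs), gamma_l=float(gl))
    pred = np.atleast_1d(race_time(d, profile))
    rel = 100.0 * (pred - t) / t

    warns: list[str] = []
    if np.all(d >= profile.d_c):
        warns.append("branch undetermined: no distance below d_c; gamma_s unidentified")
    if np.all(d < profile.d_c):
        warns.append("branch undetermined: no distance at or above d_c; gamma_l unidentified")
    LOG.info(
        "fit %s: t_c=%.4f v_m=%.3f gamma_s=%.5f gamma_l=%.5f obj=%.3e",
        race_set.name or "<unnamed>", tc, vm, gs, gl, best_val,
    )
    return FitReport(
        profile=profile,
        distances=tuple(float(x) for x in d),
        observed_times=tuple(float(x) for x in t),
        predicted_times=tuple(float(x) for x in pred),
        relative_errors=tuple(float(x) for x in rel),
        mean_abs_error=float(np.mean(np.abs(rel))),
        objective=float(best_val),
        n_starts_converged=n_converged,
        warnings=tuple(warns),
        name=race_set.name,
    )


def generate_race_set(
    profile: AthleteProfile,
    distances: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "synthetic",
) -> RaceSet:
    """Synthetic race results: model times with multiplicative Gaussian
    noise, ``T_j = T(d_j) * (1 + eps_j)``, ``eps ~ N(0, noise_sd/100)``.

    The noise is multiplicative because the fit minimises *relative*
    deviations; ``noise_sd`` is in percent and 0 gives exact model times.
    Reproducible for a fixed seed.
    """
    dist = np.asarray(list(distances), dtype=float)
    times = np.atleast_1d(race_time(dist, profile))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        times = times * (1.0 + rng.normal(0.0, noise_sd / 100.0, size=times.shape))
    return RaceSet(
        (RaceResult(distance=float(dd), time=float(tt)) for dd, tt in zip(dist, times)),
        name=name,
    )


# --------------------------------------------------------------------------
# Characteristic paces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PaceQuery:
    """A pace request: intensity ``p_hat`` (fraction of the
    duration-limited power reserve) for exactly one of a duration
    (minutes), a distance (metres), or the profile's crossover time."""

    intensity: float = 1.0
    duration: float | None = None
    distance: float | None = None
    at_crossover: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        targets = sum(
            (self.duration is not None, self.distance is not None, self.at_crossover)
        )
        if targets != 1:
            raise ValueError("exactly one of duration/distance/at_crossover must be set")
        if not (0.0 < self.intensity <= 1.2):
            raise ValueError(f"intensity must lie in (0, 1.2], got {self.intensity}")
        if self.intensity > 1.0:
            warnings.warn("supra-maximal intensity requested (p_hat > 1)", stacklevel=2)
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.distance is not None and self.distance <= 0:
            raise ValueError("distance must be positive")


def velocity_at_intensity_duration(p_hat: float, T: float, profile: AthleteProfile) -> float:
    """Velocity (m/min) of a run of duration ``T`` at intensity ``p_hat``
    of the power sustainable over ``T``:
    ``v = p_hat * v_m * [1 - gamma * log(T/t_c)]`` (``gamma_l`` for
    ``T >= t_c``).  Independent of ``P_b`` and ``P_m``; ``v(1, t_c) = v_m``.
    """
    if p_hat <= 0:
        raise ModelDomainError("intensity must be positive")
    if T <= 0:
        raise ModelDomainError("duration must be positive")
    gamma = profile.gamma_l if T >= profile.t_c else profile.gamma_s
    bracket = 1.0 - gamma * math.log(T / profile.t_c)
    if bracket <= 0:
        raise ModelDomainError(
            f"duration {T:g} min outside the model's validity (bracket <= 0)"
        )
    return p_hat * profile.v_m * bracket


def velocity_at_intensity_distance(p_hat: float, d: float, profile: AthleteProfile) -> float:
    """Velocity (m/min) to cover distance ``d`` at intensity ``p_hat``:

        v = -p_hat * v_m * gamma * W_-1[-(d/d_c)/(p_hat gamma) exp(-1/gamma)]

    (``gamma_l`` for ``d >= d_c``).  At ``p_hat = 1`` this is the mean
    race velocity; for any ``p_hat`` it is self-consistent with the
    duration form: running ``d`` at the returned ``v`` takes ``T = d/v``
    and ``velocity_at_intensity_duration(p_hat, T)`` returns ``v`` again.
    """
    if p_hat <= 0:
        raise ModelDomainError("intensity must be positive")
    _, gamma, z = _race_lambert_parts(float(d), profile, intensity=p_hat)
    w = _wm1_raw(z)
    return float(p_hat * profile.v_m * (-gamma[0]) * w[0])


@dataclass(frozen=True)
class ProfileVariant:
    """A single-parameter perturbation of a profile used in sensitivity
    pace tables: override ``gamma_l`` or ``gamma_s``, or scale ``t_c``
    (which rescales ``d_c`` with it)."""

    label: str
    gamma_l: float | None = None
    gamma_s: float | None = None
    tc_factor: float | None = None

    def apply(self, profile: AthleteProfile) -> AthleteProfile:
        kw: dict = {}
        if self.gamma_l is not None:
            kw["gamma_l"] = self.gamma_l
        if self.gamma_s is not None:
            kw["gamma_s"] = self.gamma_s
        if self.tc_factor is not None:
            kw["t_c"] = profile.t_c * self.tc_factor
        return replace(profile, **kw) if kw else profile


@dataclass(frozen=True)
class PaceEntry:
    """One cell of a pace table; pace in seconds per kilometre."""

    velocity: float
    pace_s_per_km: float
    query: PaceQuery
    variant: str
    valid: bool = True
    note: str = ""

    @property
    def pace_s_per_mile(self) -> float:
        return self.pace_s_per_km * MILE / 1000.0


@dataclass(frozen=True)
class PaceTable:
    """Query-by-variant grid of paces; first column is the unmodified
    profile, labelled "original"."""

    profile: AthleteProfile
    queries: tuple[PaceQuery, ...]
    variant_labels: tuple[str, ...]
    rows: tuple[tuple[PaceEntry, ...], ...]

    def entry(self, row: int, variant: str) -> PaceEntry:
        return self.rows[row][self.variant_labels.index(variant)]

    def render(self, per_mile: bool = False) -> str:
        unit = "/mile" if per_mile else "/km"
        header = ["pace at max power for"] + [f"{v} [{unit}]" for v in self.variant_labels]
        widths = [max(len(header[0]), *(len(q.label or "?") for q in self.queries))]
        widths += [max(10, len(h)) for h in header[1:]]
        lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
        for q, row in zip(self.queries, self.rows):
            cells = [(q.label or "?").ljust(widths[0])]
            for e, w in zip(row, widths[1:]):
                txt = (
                    format_pace(e.pace_s_per_mile if per_mile else e.pace_s_per_km)
                    if e.valid
                    else "--"
                )
                cells.append(txt.ljust(w))
            lines.append("  ".join(cells))
        return "\n".join(lines)


def pace_table(
    profile: AthleteProfile,
    queries: Sequence[PaceQuery],
    variants: Sequence[ProfileVariant] = (),
) -> PaceTable:
    """Evaluate every query under the original profile and each variant.

    An at-crossover query is a *fixed duration* equal to the base
    profile's ``t_c``: under endurance variants its pace is unchanged
    (the log term vanishes at ``T = t_c``), while under ``t_c`` variants
    it shifts because the variant's crossover moves away from the queried
    duration.  Cells whose domain check fails are marked invalid; the
    table is still returned.
    """
    cols = (ProfileVariant("original"),) + tuple(variants)
    rows: list[tuple[PaceEntry, ...]] = []
    for q in queries:
        T_fixed = profile.t_c if q.at_crossover else q.duration
        entries: list[PaceEntry] = []
        for var in cols:
            prof = var.apply(profile)
            try:
                if q.distance is not None:
                    v = velocity_at_intensity_distance(q.intensity, q.distance, prof)
                else:
                    v = velocity_at_intensity_duration(q.intensity, T_fixed, prof)
                entries.append(
                    PaceEntry(velocity=v, pace_s_per_km=60000.0 / v, query=q, variant=var.label)
                )
            except ModelDomainError as exc:
                entries.append(
                    PaceEntry(
                        velocity=math.nan,
                        pace_s_per_km=math.nan,
                        query=q,
                        variant=var.label,
                        valid=False,
                        note=str(exc),
                    )
                )
        rows.append(tuple(entries))
    return PaceTable(
        profile=profile,
        queries=tuple(queries),
        variant_labels=tuple(c.label for c in cols),
        rows=tuple(rows),
    )


#: The eight standard pace-table rows: race paces (intensity 1) for named
#: distances and durations, plus the interval pace at the crossover time.
STANDARD_PACE_QUERIES = (
    PaceQuery(distance=MILE, label="1 mile (R-pace)"),
    PaceQuery(duration=5.0, label="5min"),
    PaceQuery(at_crossover=True, label="time t_c (I-pace)"),
    PaceQuery(distance=5000.0, label="5000m"),
    PaceQuery(distance=10000.0, label="10000m"),
    PaceQuery(duration=60.0, label="60min (T-pace)"),
    PaceQuery(distance=HALF_MARATHON, label="Half marathon"),
    PaceQuery(distance=MARATHON, label="marathon (M-pace)"),
)

ENDURANCE_VARIANTS = (
    ProfileVariant("gamma_l=0.04", gamma_l=0.04),
    ProfileVariant("gamma_l=0.08", gamma_l=0.08),
    ProfileVariant("gamma_s=0.15", gamma_s=0.15),
    ProfileVariant("gamma_s=0.05", gamma_s=0.05),
)

TC_VARIANTS = (
    ProfileVariant("0.8 t_c", tc_factor=0.8),
    ProfileVariant("0.9 t_c", tc_factor=0.9),
    ProfileVariant("1.1 t_c", tc_factor=1.1),
    ProfileVariant("1.2 t_c", tc_factor=1.2),
)


# --------------------------------------------------------------------------
# Race-result CSV I/O
# --------------------------------------------------------------------------

def read_race_csv(path: str | Path) -> RaceSet:
    """Read race results from a CSV with columns ``distance_m`` and
    ``time`` (clock notation or bare seconds), plus optional ``label``."""
    path = Path(path)
    results: list[RaceResult] = []
    seen: dict[float, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        fields = [f.strip() for f in reader.fieldnames]
        for col in ("distance_m", "time"):
            if col not in fields:
                raise ParseError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):
            try:
                dist = parse_distance(row["distance_m"])
                t = parse_time(row["time"])
            except (ParseError, KeyError, TypeError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from exc
            if dist in seen:
                raise ParseError(
                    f"{path}: duplicate distance {dist:g} m (rows {seen[dist]} and {i})"
                )
            seen[dist] = i
            results.append(
                RaceResult(distance=dist, time=t, label=(row.get("label") or None))
            )
    if not results:
        raise ParseError(f"{path}: no data rows")
    return RaceSet(results, name=path.stem)


def write_race_csv(race_set: RaceSet, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["distance_m", "time", "label"])
        for r in race_set:
            writer.writerow([f"{r.distance:g}", format_time(r.time), r.label or ""])


# --------------------------------------------------------------------------
# Embedded fixtures: printed record/athlete tables and pace tables
# --------------------------------------------------------------------------
# Race times, fitted parameters, per-distance model times and signed percent
# errors as printed, stored digit-for-digit; read-only reference data for the
# reproduction checks and the CLI `tables` command.

_T12_DISTANCES = (1000.0, 1500.0, MILE, 3000.0, 5000.0, 10000.0, HALF_MARATHON, MARATHON)
_T34_DISTANCES = (800.0, 1500.0, 3000.0, 5000.0, 10000.0, HALF_MARATHON, MARATHON)


@dataclass(frozen=True)
class RecordFixture:
    """One printed record or athlete set: times, fitted parameters, model
    times and signed percent errors, exactly as printed."""

    name: str
    t_c: float
    v_m: float
    gamma_s: float
    gamma_l: float
    E_s: float
    E_l: float
    distances: tuple[float, ...]
    times: tuple[str, ...]
    model_times: tuple[str, ...]
    errors_pct: tuple[float, ...]
    mean_abs_pct: float

    def profile(self) -> AthleteProfile:
        return AthleteProfile(
            t_c=self.t_c, v_m=self.v_m, gamma_s=self.gamma_s, gamma_l=self.gamma_l
        )

    def race_set(self) -> RaceSet:
        return RaceSet(
            (
                RaceResult(distance=d, time=parse_time(t))
                for d, t in zip(self.distances, self.times)
            ),
            name=self.name,
        )


def _rec(name, tc, vm, gs100, gl100, Es, El, mean_pct, rows, distances=_T12_DISTANCES):
    times, model, errs = zip(*rows)
    return RecordFixture(
        name=name,
        t_c=tc,
        v_m=vm,
        gamma_s=gs100 / 100.0,
        gamma_l=gl100 / 100.0,
        E_s=Es,
        E_l=El,
        distances=distances,
        times=times,
        model_times=model,
        errors_pct=errs,
        mean_abs_pct=mean_pct,
    )


RECORD_FIXTURES = {
    f.name: f
    for f in (
        _rec("WR_men", 6.26, 411.72, 9.99, 5.36, 0.37, 6.46, 0.12, (
            ("02:11.96", "02:11.94", -0.02),
            ("03:26.00", "03:26.24", +0.12),
            ("03:43.13", "03:42.91", -0.10),
            ("07:20.67", "07:20.99", +0.07),
            ("12:37.35", "12:37.10", -0.03),
            ("26:17.53", "26:18.84", +0.08),
            ("58:23.00", "58:11.94", -0.32),
            ("2:01:39.00", "2:01:52.99", +0.19),
        )),
        _rec("WR_2000_men", 5.50, 417.07, 9.87, 6.19, 0.36, 5.04, 0.21, (
            ("02:11.96", "02:11.94", -0.02),
            ("03:26.00", "03:26.24", +0.12),
            ("03:43.13", "03:42.91", -0.10),
            ("07:20.67", "07:19.38", -0.29),
            ("12:39.36", "12:38.37", -0.13),
            ("26:22.75", "26:33.98", +0.71),
            ("59:22.00", "59:18.82", -0.09),
            ("2:05:42.00", "2:05:26.57", -0.20),
        )),
        _rec("WR_1990_men", 5.90, 405.00, 11.76, 5.93, 0.43, 5.41, 0.22, (
            ("02:12.80", "02:12.82", +0.01),
            ("03:29.46", "03:29.26", -0.10),
            ("03:46.32", "03:46.50", +0.08),
            ("07:29.45", "07:30.88", +0.32),
            ("12:58.39", "12:56.88", -0.19),
            ("27:08.23", "27:08.68", +0.03),
            ("1:00:46.00", "1:00:25.03", -0.58),
            ("2:06:50.00", "2:07:21.71", +0.42),
        )),
        _rec("WR_1980_men", 5.26, 405.27, 12.74, 6.21, 0.46, 5.00, 0.46, (
            ("02:13.40", "02:13.41", +0.01),
            ("03:31.36", "03:31.26", -0.05),
            ("03:48.80", "03:48.89", +0.04),
            ("07:32.10", "07:34.44", +0.52),
            ("13:08.40", "13:04.65", -0.48),
            ("27:22.47", "27:30.09", +0.46),
            ("1:02:16.00", "1:01:26.52", -1.32),
            ("2:09:01.00", "2:10:02.03", +0.79),
        )),
        _rec("US_men", 6.08, 406.06, 10.35, 5.67, 0.38, 5.83, 0.18, (
            ("02:13.90", "02:13.87", -0.02),
            ("03:29.30", "03:29.61", +0.15),
            ("03:46.91", "03:46.62", -0.13),
            ("07:29.00", "07:28.52", -0.11),
            ("12:53.60", "12:51.55", -0.26),
            ("26:44.36", "26:53.60", +0.58),
            ("59:43.00", "59:41.08", -0.05),
            ("2:05:38.00", "2:05:26.28", -0.16),
        )),
        _rec("EU_men", 4.97, 412.81, 12.24, 5.76, 0.44, 5.67, 0.11, (
            ("02:12.18", "02:12.17", -0.01),
            ("03:28.81", "03:28.90", +0.04),
            ("03:46.32", "03:46.24", -0.04),
            ("07:26.62", "07:26.39", -0.05),
            ("12:49.71", "12:48.61", -0.14),
            ("26:46.57", "26:49.72", +0.20),
            ("59:32.00", "59:38.51", +0.18),
            ("2:05:48.00", "2:05:34.12", -0.18),
        )),
        _rec("GER_men", 4.79, 411.05, 11.22, 6.11, 0.41, 5.14, 0.17, (
            ("02:14.53", "02:14.52", -0.01),
            ("03:31.58", "03:31.71", +0.06),
            ("03:49.22", "03:49.10", -0.05),
            ("07:30.50", "07:30.28", -0.05),
            ("12:54.70", "12:57.09", +0.31),
            ("27:21.53", "27:13.07", -0.52),
            ("1:00:34.00", "1:00:45.41", +0.31),
            ("2:08:33.00", "2:08:28.19", -0.06),
        )),
        _rec("WR_women", 8.30, 361.37, 9.60, 4.85, 0.35, 7.88, 0.42, (
            ("02:28.98", "02:28.78", -0.13),
            ("03:50.07", "03:52.05", +0.86),
            ("04:12.56", "04:10.70", -0.74),
            ("08:20.68", "08:18.13", -0.51),
            ("14:11.15", "14:12.40", +0.15),
            ("29:17.45", "29:29.07", +0.66),
            ("1:04:51.00", "1:04:50.60", -0.01),
            ("2:15:25.00", "2:15:00.95", -0.30),
        )),
        # The 2000 women's set is stored exactly as printed (8 rows); four
        # Chinese results were excluded by the source for doping reasons.
        _rec("WR_2000_women", 10.01, 352.14, 10.27, 5.53, 0.38, 6.10, 0.20, (
            ("02:28.98", "02:29.07", +0.06),
            ("03:52.47", "03:52.94", +0.20),
            ("04:12.56", "04:11.75", -0.32),
            ("08:21.64", "08:21.94", +0.06),
            ("14:31.48", "14:29.77", -0.20),
            ("30:13.74", "30:14.88", +0.06),
            ("1:06:40.00", "1:06:56.85", +0.42),
            ("2:20:43.00", "2:20:18.48", -0.29),
        )),
        _rec("WR_1990_women", 5.50, 364.74, 12.13, 5.74, 0.44, 5.70, 1.05, (
            ("02:30.67", "02:30.17", -0.33),
            ("03:52.47", "03:57.27", +2.06),
            ("04:21.68", "04:16.95", -1.81),
            ("08:22.62", "08:25.93", +0.66),
            ("14:37.33", "14:31.08", -0.71),
            ("30:13.74", "30:24.18", +0.58),
            ("1:08:32.00", "1:07:34.87", -1.39),
            ("2:21:06.00", "2:22:16.17", +0.83),
        )),
        _rec("US_women", 10.80, 347.42, 9.39, 5.17, 0.34, 6.92, 0.34, (
            ("02:31.80", "02:32.01", +0.14),
            ("03:56.29", "03:56.68", +0.17),
            ("04:16.71", "04:15.62", -0.42),
            ("08:25.83", "08:26.40", +0.11),
            ("14:38.92", "14:37.27", -0.19),
            ("30:13.17", "30:24.74", +0.64),
            ("1:07:34.00", "1:07:03.57", -0.75),
            ("2:19:36.00", "2:20:00.22", +0.29),
        )),
        _rec("EU_women", 10.19, 351.63, 10.25, 4.63, 0.38, 8.66, 0.37, (
            ("02:28.98", "02:29.08", +0.07),
            ("03:52.47", "03:52.92", +0.20),
            ("04:12.56", "04:11.73", -0.33),
            ("08:21.42", "08:21.75", +0.07),
            ("14:23.75", "14:27.22", +0.40),
            ("29:56.34", "29:56.03", -0.02),
            ("1:06:25.00", "1:05:40.14", -1.13),
            ("2:15:25.00", "2:16:23.60", +0.72),
        )),
        _rec("GER_women", 5.87, 356.56, 13.91, 5.01, 0.49, 7.35, 0.70, (
            ("02:30.67", "02:30.48", -0.13),
            ("03:57.71", "03:59.58", +0.79),
            ("04:21.59", "04:19.83", -0.67),
            ("08:29.89", "08:34.62", +0.93),
            ("14:42.03", "14:41.99", -0.00),
            ("30:57.00", "30:34.60", -1.21),
            ("1:07:58.00", "1:07:25.42", -0.80),
            ("2:19:19.00", "2:20:46.06", +1.04),
        )),
    )
}

# Personal-best sets of leading UK marathon runners (2015 ranking), seven
# distances from 800 m.  Note: the printed v_m of female runner 03 is
# 368.12 m/min here although the accompanying text cites 373.5 m/min for
# the same runner (which matches *male* runner 03); both tables are stored
# as printed.
ATHLETE_FIXTURES = {
    f.name: f
    for f in (
        _rec("UK_marathon_men_01", 23.84, 353.28, 8.16, 4.67, 0.29, 8.52, 0.76, (
            ("01:52.08", "01:52.52", +0.39),
            ("03:41.88", "03:41.06", -0.37),
            ("07:48.90", "07:46.84", -0.44),
            ("13:28.32", "13:31.65", +0.41),
            ("28:49.02", "28:32.80", -0.94),
            ("1:01:25.02", "1:02:32.11", +1.82),
            ("2:10:55.02", "2:09:41.73", -0.93),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_02", 11.28, 360.35, 11.65, 5.07, 0.42, 7.20, 0.24, (
            ("01:49.98", "01:49.94", -0.04),
            ("03:40.80", "03:40.95", +0.07),
            ("08:00.48", "08:00.34", -0.03),
            ("13:57.66", "14:01.83", +0.50),
            ("29:23.04", "29:09.19", -0.79),
            ("1:04:07.02", "1:04:12.25", +0.14),
            ("2:13:40.98", "2:13:52.45", +0.14),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_03", 4.57, 373.49, 10.26, 4.85, 0.38, 7.86, 0.27, (
            ("01:58.32", "01:58.32", +0.00),
            ("03:57.48", "03:57.48", -0.00),
            ("08:16.62", "08:16.24", -0.08),
            ("14:13.32", "14:09.91", -0.40),
            ("29:18.48", "29:26.13", +0.43),
            ("1:04:30.00", "1:04:49.91", +0.51),
            ("2:15:51.00", "2:15:11.79", -0.48),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_04", 19.88, 357.87, 8.27, 5.70, 0.30, 5.78, 0.49, (
            ("01:51.78", "01:52.20", +0.38),
            ("03:41.94", "03:40.71", -0.56),
            ("07:46.74", "07:46.78", +0.01),
            ("13:31.20", "13:32.52", +0.16),
            ("28:42.18", "28:31.86", -0.60),
            ("1:02:22.98", "1:03:06.46", +1.16),
            ("2:12:57.00", "2:12:10.52", -0.58),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_05", 8.57, 349.94, 4.84, 4.19, 0.13, 10.86, 0.99, (
            ("02:09.48", "02:08.54", -0.73),
            ("04:05.22", "04:08.44", +1.31),
            ("08:40.50", "08:34.37", -1.18),
            ("14:38.58", "14:36.90", -0.19),
            ("30:04.02", "30:10.06", +0.33),
            ("1:04:46.98", "1:05:55.65", +1.77),
            ("2:18:21.00", "2:16:24.13", -1.41),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_06", 6.88, 382.82, 6.93, 5.70, 0.24, 5.79, 0.60, (
            ("01:55.20", "01:55.20", +0.00),
            ("03:45.66", "03:45.66", -0.00),
            ("08:00.12", "07:53.93", -1.29),
            ("13:33.00", "13:35.29", +0.28),
            ("27:57.24", "28:25.13", +1.66),
            ("1:03:00.00", "1:03:04.39", +0.12),
            ("2:13:40.02", "2:12:33.95", -0.82),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_07", 8.44, 355.63, 5.72, 5.62, 0.17, 5.93, 0.75, (
            ("02:05.10", "02:04.97", -0.11),
            ("04:02.40", "04:02.87", +0.19),
            ("08:28.62", "08:26.15", -0.49),
            ("14:35.94", "14:30.06", -0.67),
            ("30:04.02", "30:17.72", +0.76),
            ("1:06:04.02", "1:07:09.06", +1.64),
            ("2:22:55.98", "2:20:56.89", -1.39),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_08", 8.17, 367.03, 8.15, 5.81, 0.29, 5.59, 0.65, (
            ("01:57.42", "01:57.12", -0.26),
            ("03:49.98", "03:51.04", +0.46),
            ("08:14.04", "08:10.42", -0.73),
            ("14:01.02", "14:04.01", +0.36),
            ("29:32.70", "29:26.30", -0.36),
            ("1:04:28.02", "1:05:23.05", +1.42),
            ("2:18:49.02", "2:17:31.77", -0.93),
        ), _T34_DISTANCES),
        _rec("UK_marathon_men_09", 5.28, 347.39, 15.25, 4.82, 0.52, 7.95, 0.27, (
            ("02:00.42", "02:00.42", +0.00),
            ("04:10.08", "04:10.08", -0.00),
            ("08:47.70", "08:51.43", +0.71),
            ("15:18.30", "15:09.93", -0.91),
            ("31:30.90", "31:30.08", -0.04),
            ("1:09:12.00", "1:09:20.92", +0.21),
            ("2:24:31.02", "2:24:32.68", +0.02),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_01", 13.01, 319.66, 5.45, 4.70, 0.16, 8.39, 0.37, (
            ("02:17.28", "02:17.17", -0.08),
            ("04:25.56", "04:25.95", +0.15),
            ("09:13.08", "09:12.71", -0.07),
            ("15:44.22", "15:47.11", +0.31),
            ("32:39.36", "32:42.02", +0.14),
            ("1:12:36.00", "1:11:45.67", -1.16),
            ("2:28:04.02", "2:29:05.72", +0.69),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_02", 9.48, 316.60, 6.80, 4.28, 0.23, 10.34, 0.64, (
            ("02:18.60", "02:18.31", -0.21),
            ("04:29.58", "04:30.60", +0.38),
            ("09:32.82", "09:28.54", -0.75),
            ("16:13.02", "16:09.74", -0.34),
            ("33:01.98", "33:23.16", +1.07),
            ("1:12:28.02", "1:13:01.34", +0.77),
            ("2:32:40.02", "2:31:12.50", -0.96),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_03", 3.85, 368.12, 5.82, 4.41, 0.18, 9.64, 0.37, (
            ("02:05.94", "02:05.94", -0.00),
            ("04:05.40", "04:05.12", -0.11),
            ("08:22.20", "08:26.50", +0.86),
            ("14:29.10", "14:25.36", -0.43),
            ("30:01.08", "29:51.82", -0.51),
            ("1:05:40.02", "1:05:30.03", -0.25),
            ("2:15:25.02", "2:16:00.78", +0.44),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_04", 9.45, 317.48, 6.93, 5.06, 0.24, 7.23, 1.03, (
            ("02:18.72", "02:17.68", -0.75),
            ("04:26.04", "04:29.59", +1.33),
            ("09:36.72", "09:26.96", -1.69),
            ("16:08.10", "16:11.38", +0.34),
            ("33:24.72", "33:39.59", +0.74),
            ("1:13:21.00", "1:14:10.86", +1.13),
            ("2:36:39.00", "2:34:47.30", -1.19),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_05", 5.92, 297.47, 9.70, 4.62, 0.36, 8.71, 0.30, (
            ("02:28.80", "02:28.80", -0.00),
            ("04:57.42", "04:57.42", -0.00),
            ("10:22.86", "10:21.12", -0.28),
            ("17:43.02", "17:42.23", -0.07),
            ("36:40.02", "36:42.61", +0.12),
            ("1:19:55.02", "1:20:39.07", +0.92),
            ("2:48:55.98", "2:47:45.34", -0.70),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_06", 12.36, 303.80, 9.00, 6.19, 0.33, 5.02, 0.35, (
            ("02:17.40", "02:17.16", -0.18),
            ("04:30.84", "04:31.69", +0.31),
            ("09:40.44", "09:39.64", -0.14),
            ("16:47.82", "16:46.53", -0.13),
            ("35:18.00", "35:11.88", -0.29),
            ("1:17:43.02", "1:18:25.22", +0.90),
            ("2:46:19.02", "2:45:29.11", -0.50),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_07", 16.50, 281.73, 7.43, 4.28, 0.26, 10.33, 0.77, (
            ("02:29.82", "02:29.38", -0.29),
            ("04:51.42", "04:52.95", +0.52),
            ("10:18.72", "10:17.25", -0.24),
            ("17:58.98", "17:48.35", -0.98),
            ("36:31.98", "36:45.40", +0.61),
            ("1:19:07.02", "1:20:19.99", +1.54),
            ("2:48:16.02", "2:46:13.19", -1.22),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_08", 5.40, 300.16, 16.76, 5.16, 0.55, 6.93, 0.96, (
            ("02:20.22", "02:20.22", -0.00),
            ("04:55.20", "04:55.20", -0.00),
            ("10:08.70", "10:20.47", +1.93),
            ("18:13.98", "17:44.85", -2.66),
            ("37:07.98", "36:59.37", -0.39),
            ("1:20:39.00", "1:21:45.39", +1.37),
            ("2:51:46.02", "2:51:06.21", -0.39),
        ), _T34_DISTANCES),
        _rec("UK_marathon_women_09", 14.64, 272.55, 7.25, 4.45, 0.25, 9.47, 0.48, (
            ("02:37.26", "02:36.54", -0.46),
            ("05:04.32", "05:06.82", +0.82),
            ("10:48.48", "10:46.06", -0.37),
            ("18:26.70", "18:32.44", +0.52),
            ("38:34.98", "38:19.98", -0.65),
            ("1:24:06.00", "1:23:55.81", -0.20),
            ("2:53:25.02", "2:53:58.66", +0.32),
        ), _T34_DISTANCES),
    )
}


@dataclass(frozen=True)
class PaceFixture:
    """Printed pace tables for a hypothetical runner whose race times
    follow the VDOT reference model with the given score.

    ``vdot_ref`` holds the VDOT model's own paces (display-only: external
    reference values, never computed here).  Grids are 8 rows x 5 columns
    (original + four variants); ``None`` marks an "orig." cell, i.e. the
    printed table refers back to the original column.
    """

    name: str
    vdot: int
    t_c: float
    v_m: float
    gamma_l: float
    gamma_s: float
    vdot_ref: tuple[str, ...]
    endurance_grid: tuple[tuple[str | None, ...], ...]
    tc_grid: tuple[tuple[str | None, ...], ...]

    def profile(self) -> AthleteProfile:
        return AthleteProfile(
            t_c=self.t_c, v_m=self.v_m, gamma_s=self.gamma_s, gamma_l=self.gamma_l
        )


PACE_FIXTURES = {
    f.name: f
    for f in (
        PaceFixture(
            name="VDOT40", vdot=40, t_c=12.35, v_m=214.88, gamma_l=0.051, gamma_s=0.096,
            vdot_ref=("04:20", "-", "04:42", "04:49", "05:00", "05:06", "05:15", "05:29"),
            endurance_grid=(
                ("04:25.21", None, None, "04:16.72", "04:32.06"),
                ("04:16.96", None, None, "04:05.87", "04:27.14"),
                ("04:39.22", None, None, None, None),
                ("04:49.06", "04:46.79", "04:55.54", None, None),
                ("05:00.67", "04:55.58", "05:15.85", None, None),
                ("05:03.67", "04:58.07", "05:19.64", None, None),
                ("05:14.30", "05:05.68", "05:41.31", None, None),
                ("05:28.16", "05:15.70", "06:09.16", None, None),
            ),
            tc_grid=(
                ("04:25.21", "04:31.27", "04:28.03", "04:22.70", "04:20.46"),
                ("04:16.96", "04:22.12", "04:19.37", "04:14.82", "04:12.90"),
                ("04:39.22", "04:42.43", "04:40.73", "04:36.70", "04:34.43"),
                ("04:49.06", "04:52.69", "04:50.76", "04:47.53", "04:46.15"),
                ("05:00.67", "05:04.62", "05:02.52", "04:59.02", "04:57.52"),
                ("05:03.67", "05:07.47", "05:05.45", "05:02.07", "05:00.63"),
                ("05:14.30", "05:18.63", "05:16.33", "05:12.49", "05:10.86"),
                ("05:28.16", "05:32.89", "05:30.37", "05:26.18", "05:24.39"),
            ),
        ),
        PaceFixture(
            name="VDOT60", vdot=60, t_c=12.67, v_m=298.51, gamma_l=0.052, gamma_s=0.092,
            vdot_ref=("03:05", "-", "03:23", "03:25", "03:32", "03:40", "03:42", "03:52"),
            endurance_grid=(
                ("03:05.04", None, None, "02:54.93", "03:12.36"),
                ("03:05.15", None, None, "02:56.39", "03:12.07"),
                ("03:21.00", None, None, None, None),
                ("03:24.14", "03:23.36", "03:26.00", None, None),
                ("03:32.41", "03:29.49", "03:39.64", None, None),
                ("03:38.78", "03:34.33", "03:49.55", None, None),
                ("03:42.12", "03:36.53", "03:56.62", None, None),
                ("03:51.99", "03:43.51", "04:15.08", None, None),
            ),
            tc_grid=(
                ("03:05.04", "03:08.94", "03:06.86", "03:03.42", "03:01.97"),
                ("03:05.15", "03:08.72", "03:06.82", "03:03.67", "03:02.34"),
                ("03:21.00", "03:23.37", "03:22.11", "03:19.25", "03:17.68"),
                ("03:24.14", "03:26.73", "03:25.36", "03:23.06", "03:22.08"),
                ("03:32.41", "03:35.22", "03:33.72", "03:31.23", "03:30.17"),
                ("03:38.78", "03:41.60", "03:40.10", "03:37.60", "03:36.54"),
                ("03:42.12", "03:45.20", "03:43.56", "03:40.83", "03:39.66"),
                ("03:51.99", "03:55.36", "03:53.57", "03:50.58", "03:49.31"),
            ),
        ),
        # The VDOT-80 caption prints its gamma_s ambiguously; 0.088 is the
        # evident intent and is used here (flagged, not silently corrected).
        PaceFixture(
            name="VDOT80", vdot=80, t_c=12.92, v_m=376.85, gamma_l=0.053, gamma_s=0.088,
            vdot_ref=("02:25", "-", "02:41", "02:40", "02:46", "02:54", "02:53", "03:01"),
            endurance_grid=(
                ("02:23.98", None, None, "02:13.52", "02:30.46"),
                ("02:26.99", None, None, "02:19.37", "02:32.00"),
                ("02:39.22", None, None, None, None),
                ("02:39.45", "02:39.39", "02:39.59", None, None),
                ("02:45.91", "02:44.14", "02:49.88", None, None),
                ("02:53.33", "02:49.64", "03:01.52", None, None),
                ("02:53.50", "02:49.59", "03:02.65", None, None),
                ("03:01.22", "02:54.99", "03:16.46", None, None),
            ),
            tc_grid=(
                ("02:23.98", "02:26.80", "02:25.30", "02:22.81", "02:21.76"),
                ("02:26.99", "02:29.69", "02:28.25", "02:25.87", "02:24.85"),
                ("02:39.22", "02:41.12", "02:40.11", "02:37.90", "02:36.71"),
                ("02:39.45", "02:41.48", "02:40.40", "02:38.17", "02:36.87"),
                ("02:45.91", "02:48.11", "02:46.94", "02:44.99", "02:44.16"),
                ("02:53.33", "02:55.60", "02:54.39", "02:52.38", "02:51.53"),
                ("02:53.50", "02:55.91", "02:54.63", "02:52.49", "02:51.58"),
                ("03:01.22", "03:03.85", "03:02.45", "03:00.11", "02:59.12"),
            ),
        ),
    )
}


# --------------------------------------------------------------------------
# Reproduction of the printed tables
# --------------------------------------------------------------------------

MODEL_TIME_TOL = 1e-3     # relative; slack for 2-decimal parameter rounding
MEAN_ERROR_TOL = 0.03     # percentage points on the printed "mean" row
PACE_TOL_S = 0.2          # seconds per kilometre (exact caption parameters)
# The VDOT-60/80 captions print gamma_l to only 3 decimals and that rounding
# propagates to ~0.22 s/km in the long-distance cells (visible because the
# exact-override columns agree to <0.01 s); their grids get a wider band.
PACE_TOL_ROUNDED_S = 0.25


@dataclass(frozen=True)
class TableIssue:
    table: str
    item: str
    observed: float
    expected: float
    tol: float


@dataclass(frozen=True)
class TableReport:
    n_checks: int
    issues: tuple[TableIssue, ...]

    @property
    def ok(self) -> bool:
        return not self.issues


def _parse_pace(text: str) -> float:
    """Printed pace cell (mm:ss.xx) to seconds per km."""
    return parse_time(text) * 60.0


def reproduce_tables(refit: bool = True) -> TableReport:
    """Recompute every reproducible cell of the embedded fixtures and
    compare against print: per-distance model times (0.1% relative),
    refitted mean absolute errors for the 13 record sets (0.03
    percentage points), and the six sensitivity pace grids (0.2 s/km).
    """
    issues: list[TableIssue] = []
    n = 0

    for fixtures in (RECORD_FIXTURES, ATHLETE_FIXTURES):
        for fx in fixtures.values():
            prof = fx.profile()
            pred = np.atleast_1d(race_time(np.array(fx.distances), prof))
            for dist, printed, got in zip(fx.distances, fx.model_times, pred):
                n += 1
                expect = parse_time(printed)
                if abs(got - expect) / expect > MODEL_TIME_TOL:
                    issues.append(TableIssue(fx.name, f"model time {dist:g} m",
                                             float(got), expect, MODEL_TIME_TOL))

    if refit:
        for fx in RECORD_FIXTURES.values():
            n += 1
            report = fit_profile(fx.race_set())
            if abs(report.mean_abs_error - fx.mean_abs_pct) > MEAN_ERROR_TOL:
                issues.append(TableIssue(fx.name, "refit mean |error| (pp)",
                                         report.mean_abs_error, fx.mean_abs_pct,
                                         MEAN_ERROR_TOL))

    for fx in PACE_FIXTURES.values():
        prof = fx.profile()
        pace_tol = PACE_TOL_S if fx.name == "VDOT40" else PACE_TOL_ROUNDED_S
        for kind, variants, grid in (
            ("endurance", ENDURANCE_VARIANTS, fx.endurance_grid),
            ("t_c", TC_VARIANTS, fx.tc_grid),
        ):
            table = pace_table(prof, STANDARD_PACE_QUERIES, variants)
            for row, (query, computed) in enumerate(zip(STANDARD_PACE_QUERIES, table.rows)):
                for col, printed in enumerate(grid[row]):
                    if printed is None:
                        continue
                    n += 1
                    got = computed[col].pace_s_per_km
                    expect = _parse_pace(printed)
                    if abs(got - expect) > pace_tol:
                        issues.append(TableIssue(
                            f"{fx.name}/{kind}",
                            f"{query.label} @ {table.variant_labels[col]}",
                            got, expect, pace_tol))

    return TableReport(n_checks=n, issues=tuple(issues))
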