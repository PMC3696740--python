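"""Closed-form and root-finding analysis of the noise-free ring model.

All results use the Heaviside gain. A winner-take-all (WTA) state is a
single superthreshold bump of half-width ``a`` centered on one stimulus
peak; a fusion state has bumps of half-widths ``a`` (right) and ``b``
(left) on both peaks. Rivalrous oscillations arise when the WTA state
loses existence and the slow depression variable periodically carries
the dominant bump's resource down to the escape level at which the
suppressed peak reaches threshold.

Every closed form here is re-derived from the defining threshold and
escape conditions; tests validate each against an independent numerical
solution of those conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq, root

from ._slowflow import (
    NoRivalryError,
    asymmetric_dominance_times,
    oscillation_exists,
    symmetric_dominance_time,
)

__all__ = [
    "BumpSolution",
    "SlowSwitchValues",
    "RegimeLabel",
    "NoRivalryError",
    "wta_half_width",
    "wta_half_width_explicit",
    "wta_solution",
    "wta_exists",
    "fusion_half_widths",
    "solve_escape_system",
    "pre_switch_resources",
    "dominance_time_ring",
    "rivalry_exists",
    "classify_regime",
    "regime_partition",
]


@dataclass
class BumpSolution:
    """Stationary bump(s): half-width(s), interior resource level, profile U(x)."""

    half_width_a: float
    half_width_b: float | None
    q_inside: float
    profile: Callable[[np.ndarray], np.ndarray]


@dataclass
class SlowSwitchValues:
    """Resource levels of the dominant bump immediately before a switch.

    q0 is the symmetric-input escape value; qR (qL) the level to which
    the right (left) bump's resource must fall for the opposite percept
    to escape under asymmetric input. a0/aR is the bump half-width at
    the switch (identical for both sides and independent of the
    asymmetry).
    """

    q0: float
    qR: float
    qL: float
    a0: float
    aR: float


@dataclass
class RegimeLabel:
    label: str  # winner_take_all | rivalry | fusion | no_active_state
    boundary_values: dict = field(default_factory=dict)


def _threshold_residual(a: float, I0: float, Ia: float, kappa: float, beta: float) -> float:
    """U(pi/4 +- a) - kappa for a single right bump of half-width a."""
    return (
        math.sin(4 * a) / (2 * (1 + beta))
        + I0 * math.cos(4 * a)
        + Ia * math.cos(2 * a)
        - kappa
    )


def wta_half_width(I0: float, Ia: float, kappa: float, beta: float) -> float | None:
    """Half-width of the winner-take-all bump, or None if no bump exists.

    Solves the threshold condition
    sin(4a)/[2(1+beta)] + I0 cos(4a) + Ia cos(2a) = kappa on (0, pi/4)
    by bracketed bisection; when several roots exist the largest (the
    stable, wider bump) is returned.
    """
    f = lambda a: _threshold_residual(a, I0, Ia, kappa, beta)
    aa = np.linspace(1e-12, np.pi / 4 - 1e-12, 2001)
    vals = np.array([f(a) for a in aa])
    roots = []
    for i in range(len(aa) - 1):
        if vals[i] == 0.0:
            roots.append(aa[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, aa[i], aa[i + 1], xtol=1e-14))
    if not roots:
        return None
    return float(max(roots))


def wta_half_width_explicit(I0: float, kappa: float, beta: float) -> float | None:
    """Explicit symmetric-input (Ia=0) half-width, stable "+" branch.

    a = (1/2) arctan[(1 + sqrt(1 + 4(1+beta)^2 (I0^2 - kappa^2))) /
                     (2(1+beta)(I0 + kappa))].
    Returns None when the discriminant is negative (no bump).
    """
    disc = 1.0 + 4.0 * (1 + beta) ** 2 * (I0**2 - kappa**2)
    if disc < 0:
        return None
    t = (1.0 + math.sqrt(disc)) / (2.0 * (1 + beta) * (I0 + kappa))
    a = 0.5 * math.atan(t)
    if not (0 < a < math.pi / 4):
        return None
    return a


def wta_solution(I0: float, Ia: float, kappa: float, beta: float) -> BumpSolution | None:
    a = wta_half_width(I0, Ia, kappa, beta)
    if a is None:
        return None
    amp = math.sin(2 * a) / (1 + beta)

    def profile(x):
        x = np.asarray(x, dtype=float)
        return (amp + Ia) * np.sin(2 * x) - I0 * np.cos(4 * x)

    return BumpSolution(a, None, 1.0 / (1 + beta), profile)


def wta_exists(I0: float, Ia: float, kappa: float, beta: float) -> tuple[bool, float]:
    """Existence of the right-dominant WTA state, with its margin.

    The bump exists as a stationary state whenever the threshold
    condition has a root; it is a genuine winner-take-all state only if
    the suppressed peak at x = -pi/4 stays subthreshold,
    U(-pi/4) = I0 - Ia - sin(2a)/(1+beta) < kappa.
    Returns (exists, margin) with margin = kappa - U(-pi/4) (positive
    means the WTA state exists); margin is NaN when no bump solves the
    threshold condition.
    """
    a = wta_half_width(I0, Ia, kappa, beta)
    if a is None:
        return False, float("nan")
    u_suppressed = I0 - Ia - math.sin(2 * a) / (1 + beta)
    margin = kappa - u_suppressed
    return margin > 0, margin


def _fusion_residuals(v, I0, Ia, kappa, beta):
    a, b = v
    drive = (math.sin(2 * a) - math.sin(2 * b)) / (1 + beta)
    r1 = (drive + Ia) * math.cos(2 * a) + I0 * math.cos(4 * a) - kappa
    r2 = -(drive + Ia) * math.cos(2 * b) + I0 * math.cos(4 * b) - kappa
    return [r1, r2]


def fusion_half_widths(
    I0: float, Ia: float, kappa: float, beta: float
) -> tuple[float, float] | None:
    """Half-widths (a, b) of the two-bump fusion state, or None.

    The threshold conditions U(pi/4 +- a) = U(-pi/4 +- b) = kappa give a
    2x2 implicit system. For symmetric input it reduces to
    a = b = (1/4) arccos(kappa / I0).
    """
    if Ia == 0.0:
        if I0 <= 0 or kappa / I0 > 1.0:
            return None
        a = 0.25 * math.acos(kappa / I0)
        return (a, a) if 0 < a < math.pi / 4 else None
    guess = fusion_half_widths(I0, 0.0, kappa, beta)
    if guess is None:
        return None
    sol = root(_fusion_residuals, list(guess), args=(I0, Ia, kappa, beta), tol=1e-13)
    a, b = sol.x
    res = _fusion_residuals(sol.x, I0, Ia, kappa, beta)
    if not sol.success or max(abs(r) for r in res) > 1e-10:
        return None
    if not (0 < a < math.pi / 4 and 0 < b < math.pi / 4):
        return None
    return float(a), float(b)


def solve_escape_system(I0: float, Ia_side: float, kappa: float) -> tuple[float, float]:
    """Numerically solve the defining switch conditions for (a, q).

    At the moment the suppressed percept escapes, the dominant bump of
    half-width a and interior resource q satisfies simultaneously its
    threshold condition and the escape condition that the opposite peak
    reaches threshold:

        q sin(4a)/2 + I0 cos(4a) + Ia_side cos(2a) = kappa,
        I0 - Ia_side - q sin(2a) = kappa.

    ``Ia_side`` is +Ia when the right bump is dominant and -Ia when the
    left one is. This solver is independent of the closed forms in
    :func:`pre_switch_resources` and serves as their oracle.
    """

    # eliminate q through the escape condition and bracket the scalar
    # residual in a (robust independent route, no closed form involved)
    num = I0 - Ia_side - kappa
    if num <= 0:
        raise NoRivalryError("escape requires I0 - Ia_side > kappa")

    def residual(a: float) -> float:
        q = num / math.sin(2 * a)
        return q * math.sin(4 * a) / 2 + I0 * math.cos(4 * a) + Ia_side * math.cos(2 * a) - kappa

    aa = np.linspace(1e-6, math.pi / 4 - 1e-9, 4001)
    vals = np.array([residual(a) for a in aa])
    for i in range(len(aa) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            a = brentq(residual, aa[i], aa[i + 1], xtol=1e-15)
            return float(a), float(num / math.sin(2 * a))
    raise NoRivalryError("escape conditions have no solution at these inputs")


def pre_switch_resources(I0: float, Ia: float, kappa: float) -> SlowSwitchValues:
    """Closed-form pre-switch resource levels and bump half-width.

    Eliminating the half-width from the threshold + escape conditions
    gives cos(2a*) = (I0 + kappa)/(2 I0), independent of the asymmetry,
    hence sin(2a*) = sqrt((I0 - kappa)(3 I0 + kappa))/(2 I0) and

        q0 = 2 I0 sqrt((I0 - kappa)/(3 I0 + kappa)),
        qR = 2 I0 (I_L - kappa)/sqrt((3 I0 + kappa)(I0 - kappa)),
        qL = 2 I0 (I_R - kappa)/sqrt((3 I0 + kappa)(I0 - kappa)),

    with I_R = I0 + Ia and I_L = I0 - Ia. For Ia = 0 all three coincide.
    """
    if I0 <= kappa:
        raise NoRivalryError("escape requires I0 > kappa")
    c = (I0 + kappa) / (2 * I0)
    if c > 1.0:
        raise NoRivalryError("no switch half-width: (I0+kappa)/(2 I0) > 1")
    a_star = 0.5 * math.acos(c)
    s = math.sqrt((I0 - kappa) * (3 * I0 + kappa))
    q0 = 2 * I0 * math.sqrt((I0 - kappa) / (3 * I0 + kappa))
    qR = 2 * I0 * ((I0 - Ia) - kappa) / s
    qL = 2 * I0 * ((I0 + Ia) - kappa) / s
    return SlowSwitchValues(q0=q0, qR=qR, qL=qL, a0=a_star, aR=a_star)


def rivalry_exists(I0: float, Ia: float, kappa: float, beta: float) -> bool:
    """Whether a rivalrous relaxation oscillation exists (fast-slow)."""
    try:
        sv = pre_switch_resources(I0, Ia, kappa)
    except NoRivalryError:
        return False
    qi = 1.0 / (1 + beta)
    if Ia == 0.0:
        return oscillation_exists(sv.q0, beta)
    if not (qi < sv.qR < 1.0 and qi < sv.qL < 1.0):
        return False
    try:
        dominance_time_ring(I0, Ia, kappa, beta, tau=50.0)
    except NoRivalryError:
        return False
    return True


def dominance_time_ring(
    I0: float, Ia: float, kappa: float, beta: float, tau: float
) -> tuple[float, float]:
    """Fast-slow dominance times (T_R, T_L) of the rivalrous oscillation.

    The escape levels come from :func:`pre_switch_resources`; the
    dominance times are the positive fixed point of the slow resource
    return map (exact integration of the piecewise-linear slow flow).
    Raises :class:`NoRivalryError` outside the oscillation regime.
    """
    sv = pre_switch_resources(I0, Ia, kappa)
    if Ia == 0.0:
        T = symmetric_dominance_time(sv.q0, beta, tau)
        return T, T
    return asymmetric_dominance_times(sv.qR, sv.qL, beta, tau)


def classify_regime(I0: float, Ia: float, kappa: float, beta: float) -> RegimeLabel:
    """Label one parameter point as WTA / rivalry / fusion / no_active_state.

    Priority follows the attractor reached from a winner-take-all
    initial condition: a stable WTA state wins; otherwise a rivalrous
    oscillation; otherwise fusion; otherwise no superthreshold state.
    """
    exists, margin = wta_exists(I0, Ia, kappa, beta)
    bounds = {"wta_margin": margin}
    if exists:
        return RegimeLabel("winner_take_all", bounds)
    try:
        sv = pre_switch_resources(I0, Ia, kappa)
        bounds["q0"] = sv.q0
        bounds["q_low"] = 1.0 / (1 + beta)
        bounds["q_high"] = 2.0 / (2 + beta)
    except NoRivalryError:
        sv = None
    if sv is not None and rivalry_exists(I0, Ia, kappa, beta):
        return RegimeLabel("rivalry", bounds)
    ab = fusion_half_widths(I0, Ia, kappa, beta)
    if ab is not None:
        bounds["fusion_a"], bounds["fusion_b"] = ab
        return RegimeLabel("fusion", bounds)
    return RegimeLabel("no_active_state", bounds)


def regime_partition(
    beta_grid: np.ndarray, I0_grid: np.ndarray, kappa: float, Ia: float = 0.0
) -> np.ndarray:
    """Labels over a (beta, I0) grid; shape (len(beta_grid), len(I0_grid))."""
    out = np.empty((len(beta_grid), len(I0_grid)), dtype=object)
    for i, b in enumerate(beta_grid):
        for j, I0 in enumerate(I0_grid):
            out[i, j] = classify_regime(I0, Ia, kappa, b).label
    return out
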