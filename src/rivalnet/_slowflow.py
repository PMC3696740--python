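"""Fast-slow (adiabatic) dominance-time solvers shared by the models.

During a dominance phase the active population's resource variable
relaxes toward 1/(1+beta) with rate (1+beta)/tau; while suppressed it
recovers toward 1 with rate 1/tau. A switch occurs by escape when the
dominant side's resource falls to a model-specific escape value
``q_esc``. Requiring the resource trajectory to be periodic over one
alternation cycle yields a return map whose fixed point gives the
dominance time T.

The return-map equation always admits the trivial root T = 0; a
genuine relaxation oscillation corresponds to its unique positive root,
which exists iff

    1/(1+beta) < q_esc < (1 + n) / (1 + n + beta),

where n is the number of dominance phases spent suppressed per cycle
(n = 1 for two percepts, n = 2 for three). The solvers here evaluate
the exact integration of the piecewise-linear slow flow; no further
closed form is used.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq, root


class NoRivalryError(ValueError):
    """Raised when no rivalrous oscillation exists at the requested point."""


def oscillation_exists(q_esc: float, beta: float, n_suppressed: int = 1) -> bool:
    lo = 1.0 / (1.0 + beta)
    hi = (1.0 + n_suppressed) / (1.0 + n_suppressed + beta)
    return lo < q_esc < hi


def symmetric_dominance_time(
    q_esc: float, beta: float, tau: float, n_suppressed: int = 1
) -> float:
    """Dominance time T of the symmetric relaxation oscillation.

    Solves the periodicity condition

        q_esc = qi + (1 - (1 - q_esc) e^{-n T/tau} - qi) e^{-(1+beta) T/tau},

    qi = 1/(1+beta), for its unique positive root by bracketed
    root-finding.
    """
    if not oscillation_exists(q_esc, beta, n_suppressed):
        raise NoRivalryError(
            f"escape value q_esc={q_esc:.4f} outside the oscillation range "
            f"({1/(1+beta):.4f}, {(1+n_suppressed)/(1+n_suppressed+beta):.4f})"
        )
    qi = 1.0 / (1.0 + beta)

    def g(T: float) -> float:
        rec = 1.0 - (1.0 - q_esc) * math.exp(-n_suppressed * T / tau)
        return qi + (rec - qi) * math.exp(-(1.0 + beta) * T / tau) - q_esc

    # g(0) = 0 with g'(0) > 0 inside the existence range and g(inf) < 0
    t_lo = 1e-9 * tau
    while g(t_lo) <= 0.0:
        t_lo *= 10.0
        if t_lo > tau:
            raise NoRivalryError("return map has no positive root")
    t_hi = tau
    while g(t_hi) > 0.0:
        t_hi *= 2.0
        if t_hi > 1e6 * tau:  # pragma: no cover - defensive
            raise NoRivalryError("return map root escaped to infinity")
    return brentq(g, t_lo, t_hi, xtol=1e-12 * tau, rtol=8.9e-16)


def asymmetric_dominance_times(
    qR_esc: float, qL_esc: float, beta: float, tau: float
) -> tuple[float, float]:
    """(T_R, T_L) for a two-percept oscillation with unequal escape values.

    ``qR_esc`` is the level to which the right side's resource must fall
    for the left percept to escape (and vice versa). The pair solves the
    coupled periodicity conditions

        qR_esc = qi + (1 - (1 - qR_esc) e^{-T_L/tau} - qi) e^{-(1+beta) T_R/tau}
        qL_esc = qi + (1 - (1 - qL_esc) e^{-T_R/tau} - qi) e^{-(1+beta) T_L/tau}.

    Reduces exactly to the symmetric solution when the escape values
    coincide.
    """
    qi = 1.0 / (1.0 + beta)
    for q in (qR_esc, qL_esc):
        if not (qi < q < 1.0):
            raise NoRivalryError(f"escape value {q:.4f} outside ({qi:.4f}, 1)")
    if math.isclose(qR_esc, qL_esc, rel_tol=0.0, abs_tol=1e-14):
        T = symmetric_dominance_time(qR_esc, beta, tau)
        return T, T

    def eqs(v):
        TR, TL = v
        r1 = qi + (1 - (1 - qR_esc) * math.exp(-TL / tau) - qi) * math.exp(
            -(1 + beta) * TR / tau
        ) - qR_esc
        r2 = qi + (1 - (1 - qL_esc) * math.exp(-TR / tau) - qi) * math.exp(
            -(1 + beta) * TL / tau
        ) - qL_esc
        return [r1, r2]

    # start from the symmetric oscillation at the mean escape value
    q_mid = 0.5 * (qR_esc + qL_esc)
    try:
        T0 = symmetric_dominance_time(q_mid, beta, tau)
    except NoRivalryError:
        T0 = 0.2 * tau
    sol = root(eqs, [T0, T0], tol=1e-13)
    TR, TL = sol.x
    if not sol.success or TR <= 0 or TL <= 0 or max(abs(r) for r in eqs(sol.x)) > 1e-9:
        raise NoRivalryError("no positive periodic solution at these inputs")
    return float(TR), float(TL)
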