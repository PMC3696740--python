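"""Space-free two-population mutual-inhibition network with depression.

    duR = [-uR + H(IR - qL uL)] dt + dW1
    duL = [-uL + H(IL - qR uR)] dt + dW2
    tau dqR = [1 - qR - beta uR qR] dt
    tau dqL = [1 - qL - beta uL qL] dt

H is the Heaviside step with H(0) = 1; independent white noise of
variance density eps enters the activity equations only. The membrane
timescale is 1 (10 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._slowflow import (
    NoRivalryError,
    asymmetric_dominance_times,
    symmetric_dominance_time,
)
from .params import ReducedParams
from .records import DominanceRecord, records_from_switches
from .ring_analysis import RegimeLabel

PERCEPT_LABELS = ("L", "R")


def _H(x: float) -> float:
    return 1.0 if x >= 0.0 else 0.0


@dataclass
class ReducedState:
    uR: float
    uL: float
    qR: float
    qL: float
    t: float = 0.0


@dataclass
class ReducedTrajectory:
    params: ReducedParams
    snap_times: np.ndarray
    snaps: np.ndarray  # columns uR, uL, qR, qL
    final_state: ReducedState


@dataclass
class EnergySnapshot:
    """Adiabatic energy and the barriers out of each dominant state.

    dER = 1 - IL*qR is the energy gap between the right-dominant state
    and fusion; dEL = 1 - IR*qL likewise for the left. Depression lowers
    the gap of the currently dominant side over time, which is what
    carries the network over to the other percept.
    """

    E: float
    dER: float
    dEL: float


def initial_state(params: ReducedParams, init: str = "random") -> ReducedState:
    """"random": u ~ U(0,1), q ~ U(1/(1+beta), 1); "dominant_right"/"_left":
    a deterministic point inside the rivalry basin (winner at rate 1 with
    fully depressed resource, loser silent and recovered)."""
    if init == "random":
        rng = np.random.default_rng(params.seed + 0x5EED)
        qlo = 1.0 / (1 + params.beta)
        return ReducedState(
            uR=rng.uniform(0, 1),
            uL=rng.uniform(0, 1),
            qR=rng.uniform(qlo, 1),
            qL=rng.uniform(qlo, 1),
        )
    if init in ("dominant_right", "dominant_left"):
        qlo = 1.0 / (1 + params.beta)
        sR = init == "dominant_right"
        return ReducedState(
            uR=1.0 if sR else 0.0,
            uL=0.0 if sR else 1.0,
            qR=qlo + 1e-3 if sR else 1.0,
            qL=1.0 if sR else qlo + 1e-3,
        )
    raise ValueError(f"unknown init {init!r}")


def simulate_reduced(
    params: ReducedParams,
    init: ReducedState | str = "random",
    snap_stride: int = 0,
    max_switches: int = 2_000_000,
) -> tuple[ReducedTrajectory, list[DominanceRecord]]:
    """Euler-Maruyama integration with online debounced switch detection."""
    state = initial_state(params, init) if isinstance(init, str) else init
    v = np.array([state.uR, state.uL, state.qR, state.qL], dtype=float)
    n_steps = int(round(params.t_total / params.dt))
    n_snap = (n_steps + snap_stride - 1) // snap_stride if snap_stride > 0 else 0
    snaps = np.empty((n_snap, 4))
    snap_times = np.empty(n_snap)
    sw_times = np.empty(max_switches)
    sw_from = np.empty(max_switches, dtype=np.int64)
    n_sw, status = _kernels.reduced_kernel(
        v,
        params.IR,
        params.IL,
        params.beta,
        params.tau,
        params.dt,
        n_steps,
        math.sqrt(params.eps),
        params.seed % 2**32,
        params.min_dwell,
        snap_stride,
        snaps,
        snap_times,
        sw_times,
        sw_from,
    )
    if status != 0:
        raise FloatingPointError(f"non-finite state at step {status}")
    records = records_from_switches(
        sw_times[:n_sw], sw_from[:n_sw], PERCEPT_LABELS, params.burn_in, params.time_unit_ms
    )
    traj = ReducedTrajectory(
        params=params,
        snap_times=snap_times,
        snaps=snaps,
        final_state=ReducedState(*v, t=n_steps * params.dt),
    )
    return traj, records


def dominance_time_reduced(IR: float, IL: float, beta: float, tau: float) -> tuple[float, float]:
    """Fast-slow dominance times (T_R, T_L).

    The suppressed left percept escapes when the dominant right side's
    resource falls to IL (cross-inhibition qR uR drops to the left
    input), and vice versa; the dominance times are the positive fixed
    point of the slow resource return map. Raises NoRivalryError
    outside the oscillation regime.
    """
    if IR == IL:
        T = symmetric_dominance_time(IR, beta, tau)
        return T, T
    return asymmetric_dominance_times(IL, IR, beta, tau)


def fusion_only_threshold(beta: float) -> float:
    """Symmetric input level above which only the fusion state remains
    among {WTA, rivalry, fusion}: I = (2+beta)/[2(1+beta)]."""
    return (2.0 + beta) / (2.0 * (1.0 + beta))


def fixed_point_regimes(IR: float, IL: float, beta: float) -> RegimeLabel:
    """Classify the noise-free reduced network's attractor structure.

    A stable winner-take-all state in population j exists iff I_j > 0
    and I_k < 1/(1+beta); a stable fusion state iff both inputs exceed
    1/(1+beta). A rivalrous oscillation requires both escape levels
    inside the resource range and a positive root of the return map.
    """
    qi = 1.0 / (1 + beta)
    wta_R = IR > 0 and IL < qi
    wta_L = IL > 0 and IR < qi
    fusion = IR > qi and IL > qi
    rivalry = False
    if qi < IL < 1 and qi < IR < 1:
        try:
            dominance_time_reduced(IR, IL, beta, tau=50.0)
            rivalry = True
        except NoRivalryError:
            rivalry = False
    bounds = {
        "wta_R": wta_R,
        "wta_L": wta_L,
        "fusion": fusion,
        "rivalry": rivalry,
        "fusion_only_threshold": fusion_only_threshold(beta),
    }
    if wta_R or wta_L:
        return RegimeLabel("winner_take_all", bounds)
    if rivalry and fusion:
        return RegimeLabel("rivalry", bounds)
    if fusion:
        return RegimeLabel("fusion_only", bounds)
    return RegimeLabel("no_active_state", bounds)


def energy(state: ReducedState, IR: float, IL: float) -> EnergySnapshot:
    """Adiabatic Hopfield-style energy of the depression-scaled network.

    E = H(IL - qR uR) H(IR - qL uL) - IL qR H(IL - qR uR)
        - IR qL H(IR - qL uL),   H(0) = 1.

    With q = 1 (beta = 0) this reduces to the depression-free energy.
    """
    hR = _H(IL - state.qR * state.uR)
    hL = _H(IR - state.qL * state.uL)
    E = hR * hL - IL * state.qR * hR - IR * state.qL * hL
    return EnergySnapshot(E=E, dER=1.0 - IL * state.qR, dEL=1.0 - IR * state.qL)
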