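"""Three-population competitive network: perceptual tristability.

Each population inhibits the other two through depressing synapses:

    du_j = [-u_j + H(I - sum_{k != j} q_k u_k)] dt + dW_j
    tau dq_j = [1 - q_j - beta u_j q_j] dt,    j = 1, 2, 3,

with a common input I. Without noise the network cycles through the
three percepts in a fixed order set by resource recovery: the
population suppressed longest has the most recovered synapses and wins
the escape, so switches always move "forward". Noise makes
"switch-backs" (1 -> 3 -> 1 patterns) possible, eroding the history
dependence that depression provides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._slowflow import NoRivalryError, symmetric_dominance_time
from .params import TristableParams
from .records import DominanceRecord, records_from_switches

PERCEPT_LABELS = ("1", "2", "3")


@dataclass
class TristableTrajectory:
    params: TristableParams
    snap_times: np.ndarray
    snaps: np.ndarray  # columns u1 u2 u3 q1 q2 q3
    final_u: np.ndarray
    final_q: np.ndarray


@dataclass
class SwitchSequence:
    """Forward/backward classification of a percept sequence.

    Each consecutive triple of percepts is a "switch forward" if it
    contains all three percepts, and a "switch back" if the first and
    third coincide. p_f is the forward fraction; triples lists the
    per-triple labels for audit.
    """

    percepts: list[str]
    p_f: float
    n_forward: int
    n_back: int
    triples: list[str] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return self.n_forward + self.n_back


def initial_state(params: TristableParams, init: str = "random") -> tuple[np.ndarray, np.ndarray]:
    if init == "random":
        rng = np.random.default_rng(params.seed + 0x5EED)
        qlo = 1.0 / (1 + params.beta)
        return rng.uniform(0, 1, 3), rng.uniform(qlo, 1, 3)
    if init == "dominant_1":
        qlo = 1.0 / (1 + params.beta)
        return np.array([1.0, 0.0, 0.0]), np.array([qlo + 1e-3, 1.0, 0.9])
    raise ValueError(f"unknown init {init!r}")


def simulate_tristable(
    params: TristableParams,
    init: tuple[np.ndarray, np.ndarray] | str = "random",
    snap_stride: int = 0,
    max_switches: int = 2_000_000,
) -> tuple[TristableTrajectory, list[DominanceRecord]]:
    u, q = initial_state(params, init) if isinstance(init, str) else init
    u = np.asarray(u, dtype=float).copy()
    q = np.asarray(q, dtype=float).copy()
    n_steps = int(round(params.t_total / params.dt))
    n_snap = (n_steps + snap_stride - 1) // snap_stride if snap_stride > 0 else 0
    snaps = np.empty((n_snap, 6))
    snap_times = np.empty(n_snap)
    sw_times = np.empty(max_switches)
    sw_from = np.empty(max_switches, dtype=np.int64)
    n_sw, status = _kernels.tristable_kernel(
        u,
        q,
        params.I,
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
    traj = TristableTrajectory(
        params=params, snap_times=snap_times, snaps=snaps, final_u=u, final_q=q
    )
    return traj, records


def dominance_time_tristable(I: float, beta: float, tau: float) -> float:
    """Fast-slow dominance time of the symmetric three-percept cycle.

    The dominant population's resource must fall to I for the next
    percept to escape its inhibition; each population is then
    suppressed for two dominance phases per cycle, so T is the positive
    fixed point of the return map with a recovery interval of 2T.
    """
    return symmetric_dominance_time(I, beta, tau, n_suppressed=2)


def switch_statistics(records: list[DominanceRecord]) -> SwitchSequence:
    """Classify percept triples as switch-forward or switch-back.

    A triple (p1, p2, p3) of consecutive percepts (p2 != p1, p3 != p2
    by construction) is forward when all three percepts differ and back
    when p3 == p1. With fewer than three records the statistics are
    empty (p_f = NaN).
    """
    percepts = [r.percept for r in records]
    triples: list[str] = []
    nf = nb = 0
    for i in range(len(percepts) - 2):
        trio = percepts[i : i + 3]
        if trio[0] == trio[2]:
            triples.append("back")
            nb += 1
        elif len(set(trio)) == 3:
            triples.append("forward")
            nf += 1
        else:  # repeated adjacent percepts cannot occur in valid records
            triples.append("invalid")
    p_f = nf / (nf + nb) if (nf + nb) > 0 else float("nan")
    return SwitchSequence(percepts=percepts, p_f=p_f, n_forward=nf, n_back=nb, triples=triples)


def pf_sweep(
    eps_grid: list[float],
    I: float = 0.6,
    beta: float = 1.0,
    tau: float = 50.0,
    t_total: float = 4000.0,
    dt: float = 1e-4,
    seeds: tuple[int, ...] = (0, 1, 2),
) -> list[dict]:
    """Forward-switch probability p_f as a function of noise amplitude.

    Pools switch triples across seeds at each eps; returns one row per
    eps with p_f and the number of classified triples.
    """
    rows = []
    for eps in eps_grid:
        nf = nb = 0
        for seed in seeds:
            p = TristableParams(
                I=I, beta=beta, tau=tau, eps=eps, dt=dt, t_total=t_total, seed=seed
            )
            _, recs = simulate_tristable(p, init="dominant_1")
            st = switch_statistics(recs)
            nf += st.n_forward
            nb += st.n_back
        rows.append(
            {
                "eps": eps,
                "p_f": nf / (nf + nb) if nf + nb else float("nan"),
                "n_switches": nf + nb,
                "seeds": len(seeds),
            }
        )
    return rows
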