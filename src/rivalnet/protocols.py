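"""Pooled simulation protocols for the headline statistics.

These drivers reproduce, at desk scale, the pooled-epoch measurements
behind the main reported quantities: mean dominance times of the
depression-free noisy ring under symmetric and asymmetric bimodal
input, the running contrast-inference probability, and the
fast-slow-vs-simulation comparison for all three models. Each pools
several independent seeds derived deterministically from one base seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import reduced_net, ring_analysis, ring_model, tristable_net
from ._slowflow import NoRivalryError
from .params import ReducedParams, RingParams, TristableParams
from .records import DominanceRecord


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic, well-separated seed streams below 2**31."""
    return [(base_seed * 1_000_003 + 7919 * k) % 2**31 for k in range(n)]


def noise_only_ring_records(
    base_seed: int,
    Ia: float = 0.0,
    n_seeds: int = 17,
    t_per_seed: float = 8000.0,
    I0: float = 0.9,
    eps: float = 0.04,
) -> list[DominanceRecord]:
    """Pooled dominance epochs of the depression-free stochastic ring.

    Simulates the noisy field without depression (beta = 0) from the
    winner-take-all initial condition for ``t_per_seed`` model units per
    seed and concatenates the dominance records.
    """
    records: list[DominanceRecord] = []
    for seed in replicate_seeds(base_seed, n_seeds):
        p = RingParams(I0=I0, Ia=Ia, beta=0.0, eps=eps, t_total=t_per_seed, seed=seed)
        _, recs = ring_model.simulate_ring(p, init="wta_right", peak_stride=0)
        records.extend(recs)
    return records


@dataclass
class FastSlowRow:
    model: str
    param: float
    T_sim: float
    T_analytic: float

    @property
    def rel_err(self) -> float:
        if not (math.isfinite(self.T_sim) and math.isfinite(self.T_analytic)):
            return float("nan")
        return abs(self.T_sim - self.T_analytic) / self.T_sim


def _steady_duration(records: list[DominanceRecord], n_last: int = 6) -> float:
    """Mean of the last few epoch durations (nan when too few epochs)."""
    if len(records) < 3:
        return float("nan")
    d = [r.duration for r in records[-n_last:]]
    return float(np.mean(d))


def fast_slow_comparison(
    ring_I0=(0.80, 0.84, 0.88, 0.92),
    reduced_I=(0.55, 0.60, 0.65, 0.70),
    tristable_I=(0.60,),
    tau: float = 50.0,
    kappa: float = 0.5,
    beta: float = 1.0,
) -> list[FastSlowRow]:
    """Analytic fast-slow dominance times vs noise-free simulation.

    For each parameter point the analytic T comes from the slow-flow
    return map and the simulated T from the mean late-cycle epoch
    duration of a noise-free run started at a dominant state. Either
    entry is NaN when the oscillation does not exist on that route
    (analytic: escape level out of range; simulation: the trajectory
    settles into fusion or winner-take-all).
    """
    rows: list[FastSlowRow] = []
    for I0 in ring_I0:
        try:
            T_an = ring_analysis.dominance_time_ring(I0, 0.0, kappa, beta, tau)[0]
        except NoRivalryError:
            T_an = float("nan")
        horizon = 50.0 + 8.0 * (T_an if math.isfinite(T_an) else 50.0)
        p = RingParams(I0=I0, beta=beta, tau=tau, eps=0.0, t_total=max(horizon, 400.0), seed=0)
        _, recs = ring_model.simulate_ring(p, init="wta_right", peak_stride=0)
        rows.append(FastSlowRow("ring", I0, _steady_duration(recs), T_an))
    for I in reduced_I:
        try:
            T_an = reduced_net.dominance_time_reduced(I, I, beta, tau)[0]
        except NoRivalryError:
            T_an = float("nan")
        horizon = 50.0 + 8.0 * (T_an if math.isfinite(T_an) else 50.0)
        p = ReducedParams(IR=I, IL=I, beta=beta, tau=tau, eps=0.0, dt=1e-4,
                          t_total=max(horizon, 400.0), seed=0)
        _, recs = reduced_net.simulate_reduced(p, init="dominant_right")
        rows.append(FastSlowRow("reduced", I, _steady_duration(recs), T_an))
    for I in tristable_I:
        try:
            T_an = tristable_net.dominance_time_tristable(I, beta, tau)
        except NoRivalryError:
            T_an = float("nan")
        horizon = 50.0 + 12.0 * (T_an if math.isfinite(T_an) else 50.0)
        p = TristableParams(I=I, beta=beta, tau=tau, eps=0.0, dt=1e-4,
                            t_total=max(horizon, 400.0), seed=0)
        _, recs = tristable_net.simulate_tristable(p, init="dominant_1")
        rows.append(FastSlowRow("tristable", I, _steady_duration(recs), T_an))
    return rows
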