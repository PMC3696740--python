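"""Stochastic ring neural field with short-term synaptic depression.

The model describes an orientation column driven by a bimodal stimulus
at the two orthogonal angles -pi/4 and +pi/4. Synaptic input u(x,t)
evolves with cosine lateral coupling modulated by the fraction q(x,t)
of available presynaptic resources:

    tau_m du = [-u + w*(q f(u)) + I(x)] dt + dW(x,t),
    tau   dq = [1 - q - beta q f(u)] dt,

with w(x-y) = cos(2(x-y)) on the periodic domain [-pi/2, pi/2),
f either a Heaviside step at kappa or a sigmoid with gain gamma, and
spatially correlated noise <dW(x) dW(y)> = eps * scale * cos(x-y) dt.
With beta = 0, q stays at 1 and the depression-free noisy field is
recovered. Dominance of the right (left) percept is read out as the
larger activity peak over x > 0 (x < 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import RingParams
from .records import DominanceRecord, records_from_switches
from .ring_analysis import wta_half_width, fusion_half_widths

PERCEPT_LABELS = ("L", "R")


def grid(n_grid: int) -> np.ndarray:
    """n uniformly spaced points on the half-open interval [-pi/2, pi/2)."""
    return -np.pi / 2 + np.pi * np.arange(n_grid) / n_grid


@dataclass
class FieldState:
    """Spatial state of the ring field at time t."""

    x: np.ndarray
    u: np.ndarray
    q: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.u) == len(self.q)):
            raise ValueError("x, u, q must have equal length")


@dataclass
class RingTrajectory:
    """Decimated simulation output.

    ``peaks[:, 0]`` / ``peaks[:, 1]`` are the left/right window peak
    activities at ``peak_times``; snapshots (if requested) hold the full
    u and q profiles at ``snap_times``.
    """

    params: RingParams
    peak_times: np.ndarray
    peaks: np.ndarray
    snap_times: np.ndarray | None = None
    u_snaps: np.ndarray | None = None
    q_snaps: np.ndarray | None = None
    final_state: FieldState | None = None


def bimodal_input(x, I0: float, Ia: float):
    """Bimodal stimulus -I0 cos(4x) + Ia sin(2x).

    The peak at +pi/4 has height I0 + Ia (the right input I_R) and the
    peak at -pi/4 has height I0 - Ia (the left input I_L).
    """
    x = np.asarray(x, dtype=float)
    out = -I0 * np.cos(4 * x) + Ia * np.sin(2 * x)
    return out if out.ndim else float(out)


def recurrent_drive(state: FieldState, params: RingParams) -> np.ndarray:
    """Convolution w*(q f(u)) evaluated at every grid point.

    Uses the separable identity cos(2(x-y)) = cos2x cos2y + sin2x sin2y,
    reducing the integral to two inner products (rectangle rule with
    weight pi/n_grid).
    """
    if len(state.u) != params.n_grid or len(state.q) != params.n_grid:
        raise ValueError("state arrays inconsistent with params.n_grid")
    x = state.x
    if params.heaviside:
        f = (state.u >= params.kappa).astype(float)
    else:
        f = 1.0 / (1.0 + np.exp(-params.gamma * (state.u - params.kappa)))
    qf = state.q * f
    dx = np.pi / params.n_grid
    c2, s2 = np.cos(2 * x), np.sin(2 * x)
    A = dx * np.dot(c2, qf)
    B = dx * np.dot(s2, qf)
    return A * c2 + B * s2


def sample_noise(params: RingParams, n_steps: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Euler-Maruyama noise increments xi * sqrt(dt) for n_steps steps.

    The spatially correlated field is realized exactly through its
    rank-2 Karhunen-Loeve expansion on the stored grid,
    xi(x) = sqrt(eps*scale) (eta1 cos x + eta2 sin x), which gives
    <xi(x) xi(y)> = eps*scale*cos(x-y) per unit time. Note cos(x-y) is
    2pi-periodic while the domain has length pi, so noise at the two
    endpoints +-pi/2 is anti-correlated; the expansion matches the
    correlation function as specified, without wrapping.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = grid(params.n_grid)
    amp = math.sqrt(params.eps * params.noise_corr_scale)
    eta = rng.standard_normal((n_steps, 2))
    modes = np.stack([np.cos(x), np.sin(x)])
    return math.sqrt(params.dt) * amp * (eta @ modes)


def initial_state(params: RingParams, preset: str = "wta_right") -> FieldState:
    """Construct a named noise-free initial condition.

    ``wta_right`` / ``wta_left``: the stationary winner-take-all bump at
    +-pi/4 (explicit half-width; resources depressed to 1/(1+beta)
    inside the bump). ``fusion``: the symmetric two-bump state.
    ``flat``: u = I(x), q = 1.
    """
    x = grid(params.n_grid)
    I = bimodal_input(x, params.I0, params.Ia)
    q = np.ones(params.n_grid)
    if preset in ("wta_right", "wta_left"):
        sgn = 1.0 if preset == "wta_right" else -1.0
        a = wta_half_width(params.I0, sgn * params.Ia, params.kappa, params.beta)
        if a is None:
            raise ValueError("winner-take-all bump does not exist at these parameters")
        center = sgn * np.pi / 4
        u = (
            sgn * math.sin(2 * a) / (1 + params.beta) * np.sin(2 * x)
            - params.I0 * np.cos(4 * x)
            + params.Ia * np.sin(2 * x)
        )
        q = np.where(np.abs(x - center) < a, 1.0 / (1 + params.beta), 1.0)
    elif preset == "fusion":
        ab = fusion_half_widths(params.I0, params.Ia, params.kappa, params.beta)
        if ab is None:
            raise ValueError("fusion state does not exist at these parameters")
        a, b = ab
        drive = (math.sin(2 * a) - math.sin(2 * b)) / (1 + params.beta)
        u = (drive + params.Ia) * np.sin(2 * x) - params.I0 * np.cos(4 * x)
        inside = (np.abs(x - np.pi / 4) < a) | (np.abs(x + np.pi / 4) < b)
        q = np.where(inside, 1.0 / (1 + params.beta), 1.0)
    elif preset == "flat":
        u = I.copy()
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return FieldState(x=x, u=u, q=q, t=0.0)


def simulate_ring(
    params: RingParams,
    init: FieldState | str = "wta_right",
    snap_stride: int = 0,
    peak_stride: int = 1,
    max_switches: int = 500_000,
) -> tuple[RingTrajectory, list[DominanceRecord]]:
    """Integrate the ring field and extract dominance epochs.

    ``snap_stride`` > 0 stores full (u, q) profiles every that many
    steps; ``peak_stride`` > 0 stores the two window peaks (set to 0 to
    skip and rely on the online switch detector only). Switch detection
    runs online inside the kernel with the debounce/burn-in conventions
    of the params.
    """
    state = initial_state(params, init) if isinstance(init, str) else init
    x = state.x
    u = state.u.astype(float).copy()
    q = state.q.astype(float).copy()
    I = bimodal_input(x, params.I0, params.Ia)
    n_steps = int(round(params.t_total / params.dt))
    n_snap = (n_steps + snap_stride - 1) // snap_stride if snap_stride > 0 else 0
    n_peak = (n_steps + peak_stride - 1) // peak_stride if peak_stride > 0 else 0
    snaps_u = np.empty((n_snap, params.n_grid))
    snaps_q = np.empty((n_snap, params.n_grid))
    snap_times = np.empty(n_snap)
    peaks = np.empty((n_peak, 2))
    peak_times = np.empty(n_peak)
    sw_times = np.empty(max_switches)
    sw_from = np.empty(max_switches, dtype=np.int64)
    heaviside = params.heaviside
    gamma = 0.0 if heaviside else float(params.gamma)
    n_sw, status = _kernels.ring_kernel(
        u,
        q,
        I,
        np.cos(2 * x),
        np.sin(2 * x),
        np.cos(x),
        np.sin(x),
        np.pi / params.n_grid,
        params.kappa,
        params.beta,
        gamma,
        heaviside,
        params.tau,
        params.tau_m,
        params.dt,
        n_steps,
        math.sqrt(params.eps * params.noise_corr_scale),
        params.seed % 2**32,
        params.min_dwell,
        snap_stride,
        snaps_u,
        snaps_q,
        snap_times,
        peak_stride,
        peaks,
        peak_times,
        sw_times,
        sw_from,
    )
    if status != 0:
        raise FloatingPointError(
            f"non-finite field state detected at step {status} (t={status * params.dt:.3f})"
        )
    records = records_from_switches(
        sw_times[:n_sw], sw_from[:n_sw], PERCEPT_LABELS, params.burn_in, params.time_unit_ms
    )
    traj = RingTrajectory(
        params=params,
        peak_times=peak_times,
        peaks=peaks,
        snap_times=snap_times if snap_stride > 0 else None,
        u_snaps=snaps_u if snap_stride > 0 else None,
        q_snaps=snaps_q if snap_stride > 0 else None,
        final_state=FieldState(x=x, u=u, q=q, t=n_steps * params.dt),
    )
    return traj, records


def detect_dominance(trajectory: RingTrajectory, params: RingParams | None = None) -> list[DominanceRecord]:
    """Extract dominance epochs from stored peak traces.

    The right percept is dominant while the activity peak over
    x in (0, pi/2) strictly exceeds the peak over (-pi/2, 0); ties
    retain the incumbent. A switch is committed at the first crossing
    that persists for at least ``min_dwell`` time units; epochs starting
    before ``burn_in`` are dropped. This offline path reproduces the
    online kernel detector exactly on stride-1 traces.
    """
    if params is None:
        params = trajectory.params
    t = trajectory.peak_times
    if len(t) == 0:
        raise ValueError("trajectory holds no peak traces; rerun with peak_stride > 0")
    pL, pR = trajectory.peaks[:, 0], trajectory.peaks[:, 1]
    sw_t: list[float] = []
    sw_f: list[int] = []
    dom = -1
    cand = -1
    cand_t = 0.0
    for i in range(len(t)):
        lead = dom
        if pR[i] > pL[i]:
            lead = 1
        elif pL[i] > pR[i]:
            lead = 0
        if dom == -1:
            dom = lead
        elif lead == dom:
            cand = -1
        elif lead != -1:
            if cand == lead:
                if t[i] - cand_t >= params.min_dwell:
                    sw_t.append(cand_t)
                    sw_f.append(dom)
                    dom = cand
                    cand = -1
            else:
                cand = lead
                cand_t = t[i]
    return records_from_switches(
        np.array(sw_t), np.array(sw_f, dtype=np.int64), PERCEPT_LABELS, params.burn_in, params.time_unit_ms
    )
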