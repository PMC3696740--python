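"""Parameter containers for the rivalry models.

All models are expressed in dimensionless "model time units"; one unit
corresponds to ``time_unit_ms`` milliseconds of physical time (default
10 ms, the excitatory synaptic time constant that sets ``tau_m = 1``).
The depression recovery timescale ``tau`` is therefore 20-80 units
(200-800 ms), usually 50.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

DEFAULT_TIME_UNIT_MS = 10.0


def _validate_common(p: "ReducedParams | TristableParams") -> None:
    if p.beta < 0:
        raise ValueError(f"beta must be >= 0, got {p.beta}")
    if p.tau <= 1.0:
        raise ValueError(f"tau must exceed the membrane timescale 1, got {p.tau}")
    if p.eps < 0:
        raise ValueError(f"noise variance eps must be >= 0, got {p.eps}")
    if p.dt <= 0 or p.t_total <= 0:
        raise ValueError("dt and t_total must be positive")


@dataclass(frozen=True)
class RingParams:
    """Parameters of the stochastic ring neural field with depression.

    The field lives on the orientation domain x in [-pi/2, pi/2) with
    cosine lateral coupling ``w(x-y) = cos(2(x-y))`` and a bimodal drive
    ``I(x) = -I0 cos(4x) + Ia sin(2x)`` peaked at the two orthogonal
    orientations +-pi/4.

    Parameters
    ----------
    kappa : firing threshold of the Heaviside/sigmoid gain.
    beta : synaptic-resource depletion rate (0 disables depression).
    tau : resource recovery timescale, in model units.
    tau_m : membrane/synaptic timescale (1 by convention).
    I0 : symmetric amplitude of the bimodal input.
    Ia : input asymmetry; right peak receives I0+Ia, left I0-Ia.
    eps : noise variance density of the spatially correlated noise.
    gamma : sigmoid gain; ``None`` or ``inf`` selects the Heaviside limit.
    n_grid : number of spatial grid points on [-pi/2, pi/2).
    dt : Euler-Maruyama timestep (model units).
    t_total : simulated duration (model units).
    seed : RNG seed for the noise path.
    noise_corr_scale : coefficient on the cosine spatial correlation;
        1 realizes <xi xi'> = eps cos(x-y) delta(t-s), pi the variant
        with an extra factor pi.
    burn_in : initial interval (model units) whose dominance epochs are
        discarded.
    min_dwell : a candidate switch must persist this long (model units)
        before being logged.
    time_unit_ms : physical milliseconds per model time unit.
    """

    kappa: float = 0.5
    beta: float = 1.0
    tau: float = 50.0
    tau_m: float = 1.0
    I0: float = 0.9
    Ia: float = 0.0
    eps: float = 0.0
    gamma: float | None = None
    n_grid: int = 512
    dt: float = 1e-3
    t_total: float = 2000.0
    seed: int = 0
    noise_corr_scale: float = 1.0
    burn_in: float = 50.0
    min_dwell: float = 0.5
    time_unit_ms: float = DEFAULT_TIME_UNIT_MS

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not (self.tau > self.tau_m > 0):
            raise ValueError("need tau > tau_m > 0")
        if self.eps < 0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")
        if self.n_grid < 8:
            raise ValueError("n_grid must be >= 8")
        if self.dt <= 0 or self.t_total <= 0:
            raise ValueError("dt and t_total must be positive")
        if self.noise_corr_scale < 0:
            raise ValueError("noise_corr_scale must be >= 0")

    @property
    def heaviside(self) -> bool:
        import math

        return self.gamma is None or math.isinf(self.gamma)

    @property
    def I_R(self) -> float:
        return self.I0 + self.Ia

    @property
    def I_L(self) -> float:
        return self.I0 - self.Ia

    def full_resolution(self) -> "RingParams":
        """Full-resolution variant (dt=1e-4, 2000 grid points)."""
        return dataclasses.replace(self, dt=1e-4, n_grid=2000)


@dataclass(frozen=True)
class ReducedParams:
    """Two-population mutual-inhibition network with depression and noise."""

    IR: float = 0.6
    IL: float = 0.6
    beta: float = 1.0
    tau: float = 50.0
    eps: float = 0.0
    dt: float = 1e-4
    t_total: float = 2000.0
    seed: int = 0
    burn_in: float = 50.0
    min_dwell: float = 0.5
    time_unit_ms: float = DEFAULT_TIME_UNIT_MS

    def __post_init__(self) -> None:
        _validate_common(self)

    def full_resolution(self) -> "ReducedParams":
        return dataclasses.replace(self, dt=1e-6)


@dataclass(frozen=True)
class TristableParams:
    """Three-population competitive network with symmetric input I."""

    I: float = 0.6
    beta: float = 1.0
    tau: float = 50.0
    eps: float = 0.0
    dt: float = 1e-4
    t_total: float = 2000.0
    seed: int = 0
    burn_in: float = 50.0
    min_dwell: float = 0.5
    time_unit_ms: float = DEFAULT_TIME_UNIT_MS

    def __post_init__(self) -> None:
        _validate_common(self)

    def full_resolution(self) -> "TristableParams":
        return dataclasses.replace(self, dt=1e-6)


_PARAM_TYPES = {
    "ring": RingParams,
    "reduced": ReducedParams,
    "tristable": TristableParams,
}


def params_to_dict(p: Any) -> dict:
    d = dataclasses.asdict(p)
    for name, cls in _PARAM_TYPES.items():
        if isinstance(p, cls):
            d["model"] = name
    return d


def params_from_dict(d: dict) -> Any:
    d = dict(d)
    model = d.pop("model")
    cls = _PARAM_TYPES[model]
    return cls(**d)


def params_to_json(p: Any, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(p), fh, indent=2, sort_keys=True)


def params_from_json(path: str) -> Any:
    with open(path) as fh:
        return params_from_dict(json.load(fh))
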