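"""Headline experiment drivers.

Each registered experiment runs one self-contained analysis end to end
at desk scale (pooled tens of seconds of
simulated time per replicate) or, via scale="full_resolution", at the
original resolution and duration. Outputs land in a directory:
params.json, dominance records CSV, fit/summary JSON, and a log with
the seeds used.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dominance_stats, reduced_net, ring_analysis, ring_model, tristable_net
from .params import ReducedParams, RingParams, TristableParams
from .records import records_to_csv


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    seed: int = 1
    scale: str = "desk"  # desk | full_resolution
    n_replicates: int = 4

    def replicate_seeds(self) -> list[int]:
        # deterministic, well-separated streams below 2**31
        return [(self.seed * 1_000_003 + 7919 * k) % 2**31 for k in range(self.n_replicates)]


def _ring_params(spec: ExperimentSpec, **kw) -> RingParams:
    p = RingParams(**kw)
    return p.full_resolution() if spec.scale == "full_resolution" else p


def _pool_ring(spec: ExperimentSpec, t_total: float, **kw):
    records = []
    for seed in spec.replicate_seeds():
        p = _ring_params(spec, seed=seed, t_total=t_total, **kw)
        _, recs = ring_model.simulate_ring(p, init="wta_right", peak_stride=0)
        records.extend(recs)
    return records


def ring_states(spec: ExperimentSpec, out: Path) -> dict:
    """Noise-free ring at I0 = 0.6 / 0.84 / 1.0: WTA, rivalry, fusion."""
    rows = []
    for I0, init in ((0.6, "wta_right"), (0.84, "wta_right"), (1.0, "fusion")):
        p = _ring_params(spec, I0=I0, eps=0.0, t_total=600.0, seed=spec.seed)
        _, recs = ring_model.simulate_ring(p, init=init, peak_stride=0)
        lab = ring_analysis.classify_regime(I0, 0.0, p.kappa, p.beta).label
        rows.append({"I0": I0, "n_epochs": len(recs), "regime": lab})
    return {"states": rows}


def ring_levelt(spec: ExperimentSpec, out: Path) -> dict:
    """Fast-slow ring dominance times vs input strength and asymmetry."""
    sym = []
    for I0 in np.linspace(0.8, 0.88, 9):
        try:
            T, _ = ring_analysis.dominance_time_ring(I0, 0.0, 0.5, 1.0, 50.0)
            sym.append({"I0": float(I0), "T": T})
        except ring_analysis.NoRivalryError:
            sym.append({"I0": float(I0), "T": None})
    asym = []
    for Ia in np.linspace(0.0, 0.02, 5):
        try:
            TR, TL = ring_analysis.dominance_time_ring(0.84, float(Ia), 0.5, 1.0, 50.0)
            asym.append({"Ia": float(Ia), "T_R": TR, "T_L": TL})
        except ring_analysis.NoRivalryError:
            asym.append({"Ia": float(Ia), "T_R": None, "T_L": None})
    pd.DataFrame(sym).to_csv(out / "symmetric_T.csv", index=False)
    pd.DataFrame(asym).to_csv(out / "asymmetric_T.csv", index=False)
    return {"symmetric": sym, "asymmetric": asym}


def ring_partition(spec: ExperimentSpec, out: Path) -> dict:
    """Regime partition over the (beta, I0) plane at kappa = 0.5."""
    betas = np.linspace(0.2, 2.0, 10)
    I0s = np.linspace(0.55, 1.1, 12)
    labels = ring_analysis.regime_partition(betas, I0s, kappa=0.5)
    rows = [
        {"beta": float(b), "I0": float(i0), "label": labels[i, j]}
        for i, b in enumerate(betas)
        for j, i0 in enumerate(I0s)
    ]
    pd.DataFrame(rows).to_csv(out / "partition.csv", index=False)
    counts = pd.Series([r["label"] for r in rows]).value_counts().to_dict()
    return {"label_counts": counts}


def noise_only_exponential(spec: ExperimentSpec, out: Path) -> dict:
    """Depression-free noisy ring (I0=0.9, eps=0.04): exponential dominance."""
    t_total = 20_000.0 if spec.scale == "full_resolution" else 4000.0
    records = _pool_ring(spec, t_total, I0=0.9, Ia=0.0, beta=0.0, eps=0.04)
    records_to_csv(records, out / "records.csv")
    summary = dominance_stats.summarize_records(records)
    if len(records) >= 2:
        fit = dominance_stats.fit_exponential([r.duration for r in records])
        summary["exp_mean_T_s"] = fit.mean_T * 0.01
        summary["ks_distance"] = fit.ks_distance
    return summary


def symmetric_inference(spec: ExperimentSpec, out: Path) -> dict:
    """Symmetric-input inference trace p[I_R > I_L | n cycles] -> 1/2."""
    t_total = 20_000.0 if spec.scale == "full_resolution" else 4000.0
    records = _pool_ring(spec, t_total, I0=0.9, Ia=0.0, beta=0.0, eps=0.04)
    trace = dominance_stats.inference_probability(records)
    pd.DataFrame({"n": np.arange(1, trace.n + 1), "p_n": trace.p_n}).to_csv(
        out / "inference_trace.csv", index=False
    )
    return {"n_cycles": trace.n, "p_final": float(trace.p_n[-1]), "p_inf": trace.p_inf}


def asymmetric_inference(spec: ExperimentSpec, out: Path) -> dict:
    """Asymmetric noisy ring (I_R=0.92, I_L=0.88): exponential fits + p_inf."""
    t_total = 20_000.0 if spec.scale == "full_resolution" else 4000.0
    records = _pool_ring(spec, t_total, I0=0.9, Ia=0.02, beta=0.0, eps=0.04)
    records_to_csv(records, out / "records.csv")
    summary = dominance_stats.summarize_records(records)
    for lab in ("L", "R"):
        d = [r.duration for r in records if r.percept == lab]
        if len(d) >= 2:
            fit = dominance_stats.fit_exponential(d)
            summary[f"ks_{lab}"] = fit.ks_distance
    if summary.get("n_L") and summary.get("n_R"):
        summary["p_inf"] = dominance_stats.exceedance_probability(
            summary["mean_T_R"], summary["mean_T_L"]
        )
    return summary


def ring_depression_noise(spec: ExperimentSpec, out: Path) -> dict:
    """Ring with depression + noise (beta=0.2, eps=0.01): gamma-peaked fits."""
    t_total = 20_000.0 if spec.scale == "full_resolution" else 6000.0
    records = _pool_ring(spec, t_total, I0=0.9, Ia=0.02, beta=0.2, tau=50.0, eps=0.01)
    records_to_csv(records, out / "records.csv")
    summary = dominance_stats.summarize_records(records)
    for lab in ("L", "R"):
        d = [r.duration for r in records if r.percept == lab]
        try:
            fit = dominance_stats.fit_gamma_3point(d)
            summary[f"gamma_k_{lab}"] = fit.k
            summary[f"gamma_sigma_{lab}"] = fit.sigma
        except dominance_stats.FitError as err:
            summary[f"gamma_fit_{lab}"] = f"failed: {err}"
    return summary


def inference_sweep(spec: ExperimentSpec, out: Path) -> dict:
    """Asymptotic inference p_inf vs I_R for depression/noise mixtures."""
    combos = [(0.0, 0.04), (0.2, 0.01)]
    rows = []
    for beta, eps in combos:
        for Ia in (0.0, 0.01, 0.02):
            records = _pool_ring(
                spec, 3000.0, I0=0.9, Ia=Ia, beta=beta, tau=50.0, eps=eps
            )
            s = dominance_stats.summarize_records(records)
            p_inf = (
                dominance_stats.exceedance_probability(s["mean_T_R"], s["mean_T_L"])
                if s.get("n_L") and s.get("n_R")
                else None
            )
            rows.append({"beta": beta, "eps": eps, "Ia": Ia, "p_inf": p_inf, **s})
    pd.DataFrame(rows).to_csv(out / "sweep.csv", index=False)
    return {"rows": len(rows)}


def reduced_levelt(spec: ExperimentSpec, out: Path) -> dict:
    """Reduced-network fast-slow dominance times vs I_R (Levelt)."""
    rows = []
    for IR in np.linspace(0.55, 0.64, 10):
        try:
            TR, TL = reduced_net.dominance_time_reduced(float(IR), 0.55, 1.0, 50.0)
            rows.append({"I_R": float(IR), "T_R": TR, "T_L": TL})
        except reduced_net.NoRivalryError:
            rows.append({"I_R": float(IR), "T_R": None, "T_L": None})
    pd.DataFrame(rows).to_csv(out / "levelt_reduced.csv", index=False)
    return {"rows": rows}


def reduced_depression_noise(spec: ExperimentSpec, out: Path) -> dict:
    """Reduced net with depression + noise (I_R=0.82, I_L=0.78, beta=0.2)."""
    dt = 1e-6 if spec.scale == "full_resolution" else 1e-4
    t_total = 20_000.0 if spec.scale == "full_resolution" else 10_000.0
    records = []
    for seed in spec.replicate_seeds():
        p = ReducedParams(
            IR=0.82, IL=0.78, beta=0.2, tau=50.0, eps=0.036, dt=dt, t_total=t_total, seed=seed
        )
        _, recs = reduced_net.simulate_reduced(p, init="dominant_right")
        records.extend(recs)
    records_to_csv(records, out / "records.csv")
    return dominance_stats.summarize_records(records)


def tristable_cycle(spec: ExperimentSpec, out: Path) -> dict:
    """Noise-free tristable cycle at I=0.6: fixed forward order."""
    dt = 1e-6 if spec.scale == "full_resolution" else 1e-4
    p = TristableParams(I=0.6, beta=1.0, tau=50.0, eps=0.0, dt=dt, t_total=2000.0, seed=spec.seed)
    _, recs = tristable_net.simulate_tristable(p, init="dominant_1")
    records_to_csv(recs, out / "records.csv")
    st = tristable_net.switch_statistics(recs)
    return {"n_epochs": len(recs), "p_f": st.p_f}


def tristable_dominance_curve(spec: ExperimentSpec, out: Path) -> dict:
    """Tristable dominance time vs input strength: fast-slow vs simulation."""
    rows = []
    for I in np.linspace(0.55, 0.70, 7):
        try:
            T = tristable_net.dominance_time_tristable(float(I), 1.0, 50.0)
        except tristable_net.NoRivalryError:
            T = None
        rows.append({"I": float(I), "T_analytic": T})
    pd.DataFrame(rows).to_csv(out / "tristable_T.csv", index=False)
    return {"rows": rows}


def tristable_switchback(spec: ExperimentSpec, out: Path) -> dict:
    """Noise makes switch-backs possible (eps = 0 vs 0.003)."""
    dt = 1e-6 if spec.scale == "full_resolution" else 1e-4
    out_rows = []
    for eps in (0.0, 0.003):
        p = TristableParams(
            I=0.6, beta=1.0, tau=50.0, eps=eps, dt=dt, t_total=4000.0, seed=spec.seed
        )
        _, recs = tristable_net.simulate_tristable(p, init="dominant_1")
        st = tristable_net.switch_statistics(recs)
        out_rows.append({"eps": eps, "p_f": st.p_f, "n_triples": st.n_classified})
    return {"rows": out_rows}


def pf_noise_sweep(spec: ExperimentSpec, out: Path) -> dict:
    """p_f vs noise amplitude for the tristable network."""
    t_total = 20_000.0 if spec.scale == "full_resolution" else 4000.0
    rows = tristable_net.pf_sweep(
        [0.001, 0.003, 0.01, 0.03],
        t_total=t_total,
        seeds=tuple(spec.replicate_seeds()),
    )
    pd.DataFrame(rows).to_csv(out / "pf_sweep.csv", index=False)
    return {"rows": rows}


EXPERIMENTS = {
    fn.__name__: fn
    for fn in (
        ring_states,
        ring_levelt,
        ring_partition,
        noise_only_exponential,
        symmetric_inference,
        asymmetric_inference,
        ring_depression_noise,
        inference_sweep,
        reduced_levelt,
        reduced_depression_noise,
        tristable_cycle,
        tristable_dominance_curve,
        tristable_switchback,
        pf_noise_sweep,
    )
}


def run_experiment(spec: ExperimentSpec, out_dir: str | Path) -> dict:
    """Run a registered experiment; writes params, outputs, and a summary."""
    if spec.name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {spec.name!r}; known: {sorted(EXPERIMENTS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("experiment in progress\n")
    t0 = time.time()
    summary = EXPERIMENTS[spec.name](spec, out)
    summary = {
        "experiment": spec.name,
        "seed": spec.seed,
        "scale": spec.scale,
        "replicate_seeds": spec.replicate_seeds(),
        "runtime_s": round(time.time() - t0, 2),
        **summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    with open(out / "spec.json", "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2)
    marker.unlink()
    return summary
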