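"""Seeded synthetic datasets with the structure of the study's experiments.

Every generator is a pure function of (parameters, seed): a
:class:`DatasetManifest` records everything needed to regenerate a dataset
bit-for-bit. Trace *i* of a dataset draws from the independent substream
``(seed, i)``, so adding traces never reshuffles existing ones.

Noise is additive Gaussian — averaged multi-shot stopped-flow traces are
approximately Gaussian — with a default standard deviation of 2% of the
noiseless trace's dynamic range. Stopped-flow traces are truncated by a
configurable instrument dead time (default 2 ms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .parameters import RateParameters, AssayConditions
from .scheme import simulate_timecourse, default_time_grid
from .observables import (
    AmplitudeModel,
    Trace,
    ProductTimeCourse,
    TrapConfig,
    fret_signal,
    simulate_competition_trace,
)
from .lfer import AnalogueRecord

__all__ = [
    "NoiseModel",
    "DatasetManifest",
    "generate_stopped_flow_dataset",
    "generate_quench_flow_dataset",
    "generate_mechanism_product_dataset",
    "generate_trap_trace",
    "generate_analogue_table",
    "regenerate",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise; sigma either absolute (a.u.) or a fraction
    of the noiseless trace's dynamic range."""

    kind: str = "additive-gaussian"
    sigma: float = 0.02
    fraction_of_range: bool = True
    per_point_independent: bool = True

    def __post_init__(self) -> None:
        if self.kind != "additive-gaussian":
            raise ValueError(f"unsupported noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def sigma_abs(self, clean: np.ndarray) -> float:
        if self.fraction_of_range:
            return self.sigma * float(np.ptp(clean))
        return self.sigma

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = self.sigma_abs(clean)
        if s == 0:
            return clean.copy()
        return clean + rng.normal(0.0, s, size=clean.shape)


@dataclass
class DatasetManifest:
    """Full provenance of one synthetic dataset; regenerates it exactly."""

    generator: str
    seed: int
    noise: dict
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        return cls(**json.loads(text))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _apply_dead_time(time: np.ndarray, dead_time: float) -> np.ndarray:
    keep = time >= dead_time
    return time[keep]


def generate_stopped_flow_dataset(
    params: RateParameters,
    amp: AmplitudeModel,
    dntp_concs: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    conditions: Optional[AssayConditions] = None,
    t_max: float = 50.0,
    n_points: int = 150,
    dead_time: float = 0.002,
) -> tuple[list[Trace], DatasetManifest]:
    """Forward stopped-flow FRET dataset: one trace per [dNTP].

    Defaults emulate the forward assay: 400 nM labeled enzyme mixed with
    200 nM acceptor DNA and varying dNTP, 50 s detection window, 2 ms
    mixing dead time removed from the front of each trace.
    """
    concs = list(map(float, dntp_concs))
    if len(concs) < 1:
        raise ValueError("need >= 1 dNTP concentration")
    base = conditions or AssayConditions(enzyme_total=0.4, dna_total=0.2)
    grid = default_time_grid(t_max=t_max, n=n_points)
    grid_cut = _apply_dead_time(grid, dead_time)
    traces = []
    for i, c in enumerate(concs):
        cond = AssayConditions(
            enzyme_total=base.enzyme_total,
            dna_total=base.dna_total,
            dntp_0=c,
            temperature=base.temperature,
            chemistry_blocked=base.chemistry_blocked,
        )
        traj = simulate_timecourse(params, cond, grid)
        clean = fret_signal(traj, amp).signal
        keep = grid >= dead_time
        noisy = noise.apply(clean[keep], _rng(seed, i))
        traces.append(
            Trace(
                time=grid_cut.copy(),
                signal=noisy,
                meta={
                    "kind": "forward",
                    "dntp_conc": c,
                    "replicate": 0,
                    "trace_index": i,
                    "seed": seed,
                    "enzyme_total": cond.enzyme_total,
                    "dna_total": cond.dna_total,
                },
            )
        )
    manifest = DatasetManifest(
        generator="generate_stopped_flow_dataset",
        seed=int(seed),
        noise=asdict(noise),
        payload={
            "params": params.to_dict(),
            "amp": asdict(amp),
            "dntp_concs": concs,
            "conditions": base.to_dict(),
            "t_max": t_max,
            "n_points": n_points,
            "dead_time": dead_time,
        },
    )
    return traces, manifest


def generate_quench_flow_dataset(
    kpol: float,
    KD: float,
    dntp_concs: Sequence[float],
    times: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[list[ProductTimeCourse], DatasetManifest]:
    """Rapid-quench product time courses under the reduced biochemical model.

    fraction(t) = A·(1 − exp(−kobs·t)) with kobs = kpol·[S]/(K_D + [S]) —
    the two-parameter description the single-turnover analysis assumes.
    Noisy fractions are clipped to [0, 1] (gel quantification cannot leave
    that range).
    """
    concs = list(map(float, dntp_concs))
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("empty time list")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    courses = []
    for i, c in enumerate(concs):
        kobs = kpol * c / (KD + c)
        clean = amplitude * (1.0 - np.exp(-kobs * t))
        noisy = np.clip(noise.apply(clean, _rng(seed, i)), 0.0, 1.0)
        courses.append(
            ProductTimeCourse(
                time=t.copy(),
                fraction_product=noisy,
                meta={
                    "kind": "quench_flow",
                    "dntp_conc": c,
                    "kobs_true": kobs,
                    "trace_index": i,
                    "seed": seed,
                },
            )
        )
    manifest = DatasetManifest(
        generator="generate_quench_flow_dataset",
        seed=int(seed),
        noise=asdict(noise),
        payload={
            "kpol": float(kpol),
            "KD": float(KD),
            "dntp_concs": concs,
            "times": t.tolist(),
            "amplitude": float(amplitude),
        },
    )
    return courses, manifest


def generate_trap_trace(
    params: RateParameters,
    amp: AmplitudeModel,
    trap: TrapConfig = TrapConfig(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_shots: int = 1,
    t_max: float = 50.0,
    n_points: int = 150,
) -> tuple[Trace, DatasetManifest]:
    """Competition-assay trace (average of ``n_shots`` noisy shots)."""
    grid = default_time_grid(t_max=t_max, n=n_points)
    clean_trace = simulate_competition_trace(params, amp, trap, grid)
    shots = np.stack(
        [noise.apply(clean_trace.signal, _rng(seed, i)) for i in range(n_shots)]
    )
    trace = Trace(
        time=clean_trace.time,
        signal=shots.mean(axis=0),
        meta={**clean_trace.meta, "n_shots": n_shots, "seed": seed},
    )
    manifest = DatasetManifest(
        generator="generate_trap_trace",
        seed=int(seed),
        noise=asdict(noise),
        payload={
            "params": params.to_dict(),
            "amp": asdict(amp),
            "trap": asdict(trap),
            "n_shots": n_shots,
            "t_max": t_max,
            "n_points": n_points,
        },
    )
    return trace, manifest


def generate_mechanism_product_dataset(
    params: RateParameters,
    dntp_concs: Sequence[float],
    times: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(fraction_of_range=False),
    seed: int = 0,
    conditions: Optional[AssayConditions] = None,
) -> tuple[list[ProductTimeCourse], DatasetManifest]:
    """Quench-flow product curves simulated from the full mechanism.

    Unlike :func:`generate_quench_flow_dataset` (the reduced hyperbolic
    model the classical single-turnover analysis assumes), this generator
    integrates the six-state mechanism itself, so the curves carry the
    lag of the sequential chain; they are the product-side data for joint
    mechanism fitting. Default conditions follow the quench-flow design:
    50 nM DNA, 200 nM polymerase, 5 ms to 50 s log-spaced quench times,
    absolute Gaussian noise on the product fraction.
    """
    from .observables import product_fraction

    concs = list(map(float, dntp_concs))
    if len(concs) < 1:
        raise ValueError("need >= 1 dNTP concentration")
    base = conditions or AssayConditions(enzyme_total=0.2, dna_total=0.05)
    if times is None:
        times = np.geomspace(0.005, 50.0, 20)
    t = np.asarray(list(times), dtype=float)
    if np.any(np.diff(t) <= 0) or t[0] <= 0:
        raise ValueError("times must be strictly increasing and > 0")
    grid = np.concatenate([[0.0], t])
    courses = []
    for i, c in enumerate(concs):
        cond = AssayConditions(
            enzyme_total=base.enzyme_total, dna_total=base.dna_total, dntp_0=c,
            temperature=base.temperature,
        )
        traj = simulate_timecourse(params, cond, grid)
        clean = product_fraction(traj).fraction_product[1:]
        noisy = np.clip(noise.apply(clean, _rng(seed, i)), 0.0, 1.0)
        courses.append(
            ProductTimeCourse(
                time=t.copy(),
                fraction_product=noisy,
                meta={
                    "kind": "quench_flow_mechanism",
                    "dntp_conc": c,
                    "enzyme_total": cond.enzyme_total,
                    "dna_total": cond.dna_total,
                    "trace_index": i,
                    "seed": seed,
                },
            )
        )
    manifest = DatasetManifest(
        generator="generate_mechanism_product_dataset",
        seed=int(seed),
        noise=asdict(noise),
        payload={
            "params": params.to_dict(),
            "dntp_concs": concs,
            "times": t.tolist(),
            "conditions": base.to_dict(),
        },
    )
    return courses, manifest


#: Synthetic stand-in pKa4 grid spanning the typical bisphosphonate-analogue
#: toolkit range (the real per-analogue values are supplementary data).
DEFAULT_PKA4_GRID = tuple(np.linspace(7.0, 11.0, 8).round(4))


def generate_analogue_table(
    slope: float,
    intercept: float,
    pka4_values: Sequence[float] = DEFAULT_PKA4_GRID,
    noise_sd_log10: float = 0.05,
    seed: int = 0,
) -> tuple[list[AnalogueRecord], DatasetManifest]:
    """Synthetic analogue series on a log-linear LFER truth.

    log10(kpol) = slope·pKa4 + intercept + N(0, noise_sd_log10); kpol is
    returned on the linear scale. pKa4 values default to a synthetic grid
    spanning 7–11.
    """
    pka = list(map(float, pka4_values))
    if len(set(pka)) < 2:
        raise ValueError("need >= 2 distinct pKa4 values (slope undefined otherwise)")
    rng = _rng(seed, 0)
    records = []
    for j, x in enumerate(pka):
        log_kpol = slope * x + intercept + (
            rng.normal(0.0, noise_sd_log10) if noise_sd_log10 > 0 else 0.0
        )
        records.append(
            AnalogueRecord(label=f"analogue_{j}", pKa4=x, kpol=float(10.0**log_kpol))
        )
    manifest = DatasetManifest(
        generator="generate_analogue_table",
        seed=int(seed),
        noise={"kind": "log10-gaussian", "sigma": float(noise_sd_log10)},
        payload={
            "slope": float(slope),
            "intercept": float(intercept),
            "pka4_values": pka,
        },
    )
    return records, manifest


def regenerate(manifest: DatasetManifest):
    """Rebuild a dataset from its manifest (bit-for-bit identical)."""
    p = manifest.payload
    if manifest.generator == "generate_stopped_flow_dataset":
        noise = NoiseModel(**manifest.noise)
        return generate_stopped_flow_dataset(
            RateParameters.from_dict(p["params"]),
            AmplitudeModel(**p["amp"]),
            p["dntp_concs"],
            noise=noise,
            seed=manifest.seed,
            conditions=AssayConditions.from_dict(p["conditions"]),
            t_max=p["t_max"],
            n_points=p["n_points"],
            dead_time=p["dead_time"],
        )
    if manifest.generator == "generate_mechanism_product_dataset":
        return generate_mechanism_product_dataset(
            RateParameters.from_dict(p["params"]),
            p["dntp_concs"],
            p["times"],
            noise=NoiseModel(**manifest.noise),
            seed=manifest.seed,
            conditions=AssayConditions.from_dict(p["conditions"]),
        )
    if manifest.generator == "generate_quench_flow_dataset":
        return generate_quench_flow_dataset(
            p["kpol"], p["KD"], p["dntp_concs"], p["times"],
            noise=NoiseModel(**manifest.noise), seed=manifest.seed,
            amplitude=p["amplitude"],
        )
    if manifest.generator == "generate_trap_trace":
        return generate_trap_trace(
            RateParameters.from_dict(p["params"]),
            AmplitudeModel(**p["amp"]),
            TrapConfig(**p["trap"]),
            noise=NoiseModel(**manifest.noise),
            seed=manifest.seed,
            n_shots=p["n_shots"],
            t_max=p["t_max"],
            n_points=p["n_points"],
        )
    if manifest.generator == "generate_analogue_table":
        return generate_analogue_table(
            p["slope"], p["intercept"], p["pka4_values"],
            noise_sd_log10=manifest.noise["sigma"], seed=manifest.seed,
        )
    raise ValueError(f"unknown generator {manifest.generator!r}")
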