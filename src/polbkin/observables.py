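"""Observable models: FRET fluorescence, gel product fraction, trap assay.

The stopped-flow assay reports fingers closure: an AEDANS donor on the
fingers subdomain is quenched by a Dabcyl acceptor on the DNA when the
fingers close. The assay therefore distinguishes only two amplitude
classes — open {E_DNA, EO, EOP} versus closed {EC, ECS, ECP} — and the
observable is linear in occupancy.

The competition (trap) experiment mixes a pre-equilibrated, chemistry
blocked labeled ternary complex with excess unlabeled binary complex; the
trap removes free nucleotide, the labeled complex relaxes back to E_DNA,
and the fluorescence rise reports the reverse rates of fingers closing and
the non-covalent step. The trap is reduced to a pseudo-first-order sink on
free dNTP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parameters import (
    OPEN_SPECIES,
    CLOSED_SPECIES,
    SPECIES_INDEX,
    RateParameters,
    AssayConditions,
)
from .scheme import StateTrajectory, simulate_timecourse, default_time_grid

__all__ = [
    "AmplitudeModel",
    "Trace",
    "ProductTimeCourse",
    "TrapConfig",
    "fret_signal",
    "product_fraction",
    "ternary_equilibrium_state",
    "simulate_competition_trace",
]


@dataclass(frozen=True)
class AmplitudeModel:
    """Two-level fluorescence amplitude model.

    ``a_open`` and ``a_closed`` are relative emissions per unit complex
    (closing quenches the donor, so a_open > a_closed >= 0); ``scale`` and
    ``offset`` are per-trace instrument nuisances in arbitrary units.
    """

    a_open: float = 1.0
    a_closed: float = 0.35
    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_open > self.a_closed >= 0):
            raise ValueError(
                f"need a_open > a_closed >= 0, got a_open={self.a_open}, a_closed={self.a_closed}"
            )


@dataclass
class Trace:
    """One fluorescence time series with assay metadata."""

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D and equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "signal": self.signal})


@dataclass
class ProductTimeCourse:
    """Fraction of complexes converted to product versus time."""

    time: np.ndarray
    fraction_product: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fraction_product = np.asarray(self.fraction_product, dtype=float)
        if self.time.shape != self.fraction_product.shape:
            raise ValueError("time and fraction_product must be equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        eps = 1e-9
        if np.any(self.fraction_product < -eps) or np.any(self.fraction_product > 1 + eps):
            raise ValueError("fraction_product must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "fraction_product": self.fraction_product}
        )


@dataclass(frozen=True)
class TrapConfig:
    """Pseudo-first-order reduction of the dark-complex nucleotide trap.

    ``trap_excess`` is the fold excess of unlabeled binary complex (>= 1);
    ``capture_rate`` the effective removal rate of free dNTP (default
    effectively instantaneous); ``irreversible`` asserts the trapped
    nucleotide never returns (extendable trap DNA consumes it).
    """

    trap_excess: float = 10.0
    capture_rate: float = 1e3
    irreversible: bool = True

    def __post_init__(self) -> None:
        if self.trap_excess < 1:
            raise ValueError("trap_excess must be >= 1")
        if not self.capture_rate > 0:
            if self.irreversible:
                raise ValueError(
                    "capture_rate must be > 0 for an irreversible trap"
                )
            raise ValueError("capture_rate must be > 0")


def fret_signal(traj: StateTrajectory, amp: AmplitudeModel, meta: Optional[dict] = None) -> Trace:
    """Project a trajectory onto the two-level fluorescence observable.

    signal(t) = scale * (a_open * [open] + a_closed * [closed]) + offset.
    """
    open_occ = traj.open_occupancy()
    closed_occ = traj.closed_occupancy()
    sig = amp.scale * (amp.a_open * open_occ + amp.a_closed * closed_occ) + amp.offset
    m = {"kind": "forward", "dntp_conc": traj.conditions.dntp_0}
    if meta:
        m.update(meta)
    return Trace(time=traj.time.copy(), signal=sig, meta=m)


def product_fraction(traj: StateTrajectory, meta: Optional[dict] = None) -> ProductTimeCourse:
    """Fraction product = ([ECP] + [EOP]) / total complex."""
    tot = traj.total_complex
    if np.any(tot <= 0):
        raise ValueError("zero total complex: product fraction undefined")
    frac = (traj.species("ECP") + traj.species("EOP")) / tot
    frac = np.clip(frac, 0.0, 1.0)
    m = {"dntp_conc": traj.conditions.dntp_0}
    if meta:
        m.update(meta)
    return ProductTimeCourse(time=traj.time.copy(), fraction_product=frac, meta=m)


def ternary_equilibrium_state(params: RateParameters, conditions: AssayConditions) -> np.ndarray:
    """Equilibrium species vector of the chemistry-blocked binding chain.

    Distributes total complex and total nucleotide over
    E_DNA + dNTP ⇌ EO ⇌ EC ⇌ ECS using K_D, K2 = k2f/k2r, K3 = k3f/k3r
    (a step with zero reverse rate and nonzero forward rate drains fully
    forward and is rejected here since no finite equilibrium exists).
    """
    c_tot = conditions.complex_total
    s_tot = conditions.dntp_0
    if params.k2f > 0 and params.k2r == 0:
        raise ValueError("no finite equilibrium: k2f > 0 with k2r = 0")
    if params.k3f > 0 and params.k3r == 0:
        raise ValueError("no finite equilibrium: k3f > 0 with k3r = 0")
    K2 = params.k2f / params.k2r if params.k2r > 0 else 0.0
    K3 = params.k3f / params.k3r if params.k3r > 0 else 0.0
    gamma = (1.0 + K2 + K2 * K3) / params.KD_dNTP  # bound complex per free E per free S

    def resid(s_free: float) -> float:
        e_free = c_tot / (1.0 + gamma * s_free)
        bound = gamma * s_free * e_free
        return s_free + bound - s_tot

    s_free = brentq(resid, 0.0, s_tot) if s_tot > 0 else 0.0
    e_free = c_tot / (1.0 + gamma * s_free)
    eo = e_free * s_free / params.KD_dNTP
    y = np.zeros(len(SPECIES_INDEX))
    y[SPECIES_INDEX["E_DNA"]] = e_free
    y[SPECIES_INDEX["EO"]] = eo
    y[SPECIES_INDEX["EC"]] = K2 * eo
    y[SPECIES_INDEX["ECS"]] = K3 * K2 * eo
    y[SPECIES_INDEX["dNTP"]] = s_free
    return y


def simulate_competition_trace(
    params: RateParameters,
    amp: AmplitudeModel,
    trap: TrapConfig = TrapConfig(),
    time_grid=None,
    conditions: Optional[AssayConditions] = None,
    meta: Optional[dict] = None,
) -> Trace:
    """Simulate the fluorescence rise of the nucleotide-trap experiment.

    The labeled ternary complex (chemistry blocked by the dideoxy primer)
    is equilibrated over steps 1–3, then free dNTP is removed by the trap
    sink; the complex relaxes back toward E_DNA and the donor dequenches.
    """
    if conditions is None:
        conditions = AssayConditions(
            enzyme_total=0.4, dna_total=0.2, dntp_0=1.0, chemistry_blocked=True
        )
    if not conditions.chemistry_blocked:
        raise ValueError("competition assay requires chemistry_blocked conditions")
    if time_grid is None:
        time_grid = default_time_grid()
    params = params.replace(k4f=0.0)
    y0 = ternary_equilibrium_state(params, conditions)
    traj = simulate_timecourse(
        params, conditions, time_grid, y0=y0, dntp_sink_rate=trap.capture_rate
    )
    m = {"kind": "competition", "dntp_conc": conditions.dntp_0}
    if meta:
        m.update(meta)
    return fret_signal(traj, amp, meta=m)
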