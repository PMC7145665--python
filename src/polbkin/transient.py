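"""Classical pre-steady-state analyses.

Single/double exponential fits of transient traces, the hyperbolic
dependence of kobs on [dNTP] yielding kpol and the apparent nucleotide
K_D, misincorporation fidelity from catalytic specificities, and the
summed-band product quantification used for slippage-prone repeats.

Rates are fitted in log space so positivity is structural; standard
errors come from the local curvature at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

from .observables import Trace, ProductTimeCourse

__all__ = [
    "ExponentialFit",
    "HyperbolicFit",
    "FidelityResult",
    "GelTable",
    "fit_single_exponential",
    "fit_double_exponential",
    "fit_hyperbola",
    "compute_fidelity",
    "sum_product_bands",
]

TimeCourse = Union[Trace, ProductTimeCourse]


def _xy(tc: TimeCourse) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tc, ProductTimeCourse):
        return tc.time, tc.fraction_product
    return tc.time, tc.signal


@dataclass
class ExponentialFit:
    """Result of a one- or two-phase exponential fit.

    ``rates`` are ordered fast → slow; ``amplitudes`` are signed (negative
    for rising phases in the y = offset + Σ A_i exp(-k_i t) convention).
    ``flags`` collects degeneracy/convergence warnings; an empty list
    means a clean fit.
    """

    n_phases: int
    rates: np.ndarray
    amplitudes: np.ndarray
    offset: float
    rate_ses: np.ndarray
    amplitude_ses: np.ndarray
    offset_se: float
    sse: float
    ndata: int
    flags: list = field(default_factory=list)
    rising: bool = True

    @property
    def ok(self) -> bool:
        return not self.flags

    def summary(self) -> str:
        lines = [f"Exponential fit ({self.n_phases} phase{'s' if self.n_phases > 1 else ''})"]
        for i, (k, se) in enumerate(zip(self.rates, self.rate_ses), 1):
            lines.append(f"  k{i} = {k:.6g} +/- {se:.2g} s^-1")
        lines.append(f"  SSE = {self.sse:.3g} over {self.ndata} points")
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def _exp_model(t, offset, amps, rates):
    y = np.full_like(t, offset, dtype=float)
    for a, k in zip(amps, rates):
        y = y + a * np.exp(-k * t)
    return y


def _fit_exponential(t, y, n_phases: int, k_init: Sequence[float]) -> ExponentialFit:
    rng = np.ptp(y)
    flags: list = []
    if rng == 0 or rng < 1e-12 * max(1.0, abs(y).max()):
        flags.append("degenerate: constant data, rate unidentifiable")
        nan = np.full(n_phases, np.nan)
        return ExponentialFit(
            n_phases=n_phases, rates=nan, amplitudes=nan, offset=float(y.mean()),
            rate_ses=nan, amplitude_ses=nan, offset_se=0.0,
            sse=0.0, ndata=t.size, flags=flags,
        )

    rising = y[-1] > y[0]
    p = lmfit.Parameters()
    p.add("offset", value=float(y[-1]))
    lo, hi = np.log(1e-6), np.log(1e7)
    for i, k0 in enumerate(k_init, 1):
        p.add(f"logk{i}", value=float(np.log(k0)), min=lo, max=hi)
        p.add(f"a{i}", value=float((y[0] - y[-1]) / len(k_init)))

    def resid(pars):
        rates = [np.exp(pars[f"logk{i}"].value) for i in range(1, n_phases + 1)]
        amps = [pars[f"a{i}"].value for i in range(1, n_phases + 1)]
        return _exp_model(t, pars["offset"].value, amps, rates) - y

    out = lmfit.minimize(resid, p, method="leastsq")
    if not out.success:
        flags.append("non-convergence: " + str(out.message))

    logks = np.array([out.params[f"logk{i}"].value for i in range(1, n_phases + 1)])
    amps = np.array([out.params[f"a{i}"].value for i in range(1, n_phases + 1)])
    logk_ses = np.array(
        [out.params[f"logk{i}"].stderr or np.nan for i in range(1, n_phases + 1)]
    )
    amp_ses = np.array([out.params[f"a{i}"].stderr or np.nan for i in range(1, n_phases + 1)])
    if np.any(np.abs(logks - lo) < 1e-6) or np.any(np.abs(logks - hi) < 1e-6):
        flags.append("rate at bound: fit unreliable")

    rates = np.exp(logks)
    rate_ses = rates * logk_ses  # delta method from log-space curvature
    order = np.argsort(rates)[::-1]
    return ExponentialFit(
        n_phases=n_phases,
        rates=rates[order],
        amplitudes=amps[order],
        offset=float(out.params["offset"].value),
        rate_ses=rate_ses[order],
        amplitude_ses=amp_ses[order],
        offset_se=float(out.params["offset"].stderr or np.nan),
        sse=float(np.sum(out.residual**2)),
        ndata=int(t.size),
        flags=flags,
        rising=bool(rising),
    )


def _rate_guess(t, y) -> float:
    """Crude rate from the time at which the transient is ~63% complete."""
    span = y[-1] - y[0]
    if span == 0:
        return 1.0 / max(t[-1], 1e-9)
    frac = (y - y[0]) / span
    idx = np.argmax(frac >= 0.632)
    t63 = t[idx] if frac[idx] >= 0.632 and t[idx] > 0 else t[-1] / 3
    return 1.0 / max(t63, 1e-9)


def fit_single_exponential(tc: TimeCourse) -> ExponentialFit:
    """Fit y = A·(1 − e^(−kt)) + c (rising) or A·e^(−kt) + c (falling).

    Direction is auto-detected. Requires at least four points spanning at
    least one half-life of the transient; a flagged (never silent)
    degenerate result is returned for constant data.
    """
    t, y = _xy(tc)
    if t.size < 4:
        raise ValueError("need >= 4 points for a single-exponential fit")
    fit = _fit_exponential(t, y, 1, [_rate_guess(t, y)])
    if fit.ok and t[-1] * fit.rates[0] < np.log(2):
        fit.flags.append("window spans < 1 half-life: rate poorly determined")
    return fit


def fit_double_exponential(trace: TimeCourse, alpha: float = 0.05) -> ExponentialFit:
    """Two-phase exponential fit with an F-test fallback to one phase.

    Fits y = offset + A₁e^(−k₁t) + A₂e^(−k₂t) (phases ordered fast→slow)
    and keeps the second phase only if the extra-sum-of-squares F-test
    rejects the single-phase model at ``alpha``; otherwise the
    single-phase fit is returned with a fallback flag.
    """
    t, y = _xy(trace)
    if t.size < 8:
        raise ValueError("need >= 8 points for a double-exponential fit")
    k0 = _rate_guess(t, y)
    single = _fit_exponential(t, y, 1, [k0])
    double = _fit_exponential(t, y, 2, [5 * k0, 0.2 * k0])
    if "degenerate: constant data, rate unidentifiable" in single.flags:
        return single

    n = t.size
    df2 = n - 5  # offset + 2 amplitudes + 2 rates
    if double.sse <= 0 or df2 <= 0:
        p_extra = 0.0
    elif double.sse >= single.sse:
        p_extra = 1.0
    else:
        f = ((single.sse - double.sse) / 2.0) / (double.sse / df2)
        p_extra = float(stats.f.sf(f, 2, df2))
    if p_extra >= alpha or not np.all(np.isfinite(double.rates)):
        warnings.warn(
            "second exponential phase not supported by the data "
            f"(F-test p = {p_extra:.3g}); returning single-phase fit",
            stacklevel=2,
        )
        single.flags.append("fallback: second phase not supported (F-test)")
        return single
    return double


@dataclass
class HyperbolicFit:
    """kpol / apparent-K_D fit of kobs = kpol·[S] / (K_D + [S])."""

    kpol: float
    KD_app: float
    kpol_se: float
    KD_se: float
    sse: float
    ndata: int
    flags: list = field(default_factory=list)

    @property
    def specificity(self) -> float:
        """Catalytic specificity kpol/K_D, μM⁻¹·s⁻¹."""
        return self.kpol / self.KD_app

    @property
    def ok(self) -> bool:
        return not self.flags

    def summary(self) -> str:
        lines = [
            "Hyperbolic kobs([dNTP]) fit",
            f"  kpol   = {self.kpol:.6g} +/- {self.kpol_se:.2g} s^-1",
            f"  K_D    = {self.KD_app:.6g} +/- {self.KD_se:.2g} uM",
            f"  kpol/K_D = {self.specificity:.4g} uM^-1 s^-1",
            f"  SSE = {self.sse:.3g} over {self.ndata} points",
        ]
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def fit_hyperbola(
    kobs_points: Sequence[tuple[float, float]],
    kobs_ses: Optional[Sequence[float]] = None,
) -> HyperbolicFit:
    """Fit the hyperbolic concentration dependence of single-turnover rates.

    ``kobs_points`` are ([dNTP] in μM, kobs in s⁻¹) pairs from ≥3 distinct
    concentrations. The kobs errors grow with the rate, so when per-point
    standard errors from the exponential fits are supplied the residuals
    are weighted 1/SE² and the parameter SEs use those scales directly;
    otherwise the fit is unweighted with SEs from the residual scatter.
    Flags (post hoc) datasets whose concentrations never reach the fitted
    K_D, where kpol is extrapolated rather than measured.
    """
    pts = np.asarray(kobs_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 ([dNTP], kobs) points")
    s, k = pts[:, 0], pts[:, 1]
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    w = None
    if kobs_ses is not None:
        se_arr = np.asarray(list(kobs_ses), dtype=float)
        if se_arr.shape != k.shape or np.any(~(se_arr > 0)):
            raise ValueError("kobs_ses must be positive, one per point")
        w = 1.0 / se_arr

    p = lmfit.Parameters()
    p.add("log_kpol", value=float(np.log(max(k.max(), 1e-9))), min=np.log(1e-9), max=np.log(1e7))
    p.add("log_KD", value=float(np.log(np.median(s))), min=np.log(1e-6), max=np.log(1e9))

    def resid(pars):
        kpol = np.exp(pars["log_kpol"].value)
        kd = np.exp(pars["log_KD"].value)
        r = kpol * s / (kd + s) - k
        return r if w is None else w * r

    out = lmfit.minimize(resid, p, method="leastsq", scale_covar=w is None)
    kpol = float(np.exp(out.params["log_kpol"].value))
    kd = float(np.exp(out.params["log_KD"].value))
    kpol_se = kpol * float(out.params["log_kpol"].stderr or np.nan)
    kd_se = kd * float(out.params["log_KD"].stderr or np.nan)
    flags: list = []
    if not out.success:
        flags.append("non-convergence: " + str(out.message))
    if s.max() < kd:
        flags.append(
            "kpol poorly identified: all concentrations below the fitted K_D"
        )
        warnings.warn(flags[-1], stacklevel=2)
    return HyperbolicFit(
        kpol=kpol, KD_app=kd, kpol_se=kpol_se, KD_se=kd_se,
        sse=float(np.sum(out.residual**2)), ndata=int(s.size), flags=flags,
    )


@dataclass(frozen=True)
class FidelityResult:
    """Fidelity from catalytic specificities of correct vs incorrect dNTP."""

    specificity_correct: float
    specificity_incorrect: float
    fidelity: float
    loss_vs_reference: Optional[float] = None


def compute_fidelity(
    correct: HyperbolicFit,
    incorrect: HyperbolicFit,
    reference_fidelity: Optional[float] = None,
) -> FidelityResult:
    """Fidelity = (kpol/K_D)_correct / (kpol/K_D)_incorrect.

    When a reference fidelity is supplied (conventionally the wild-type
    enzyme on the control substrate), the loss in fidelity is
    reference / fidelity.
    """
    sc = correct.specificity
    si = incorrect.specificity
    if si <= 0:
        raise ValueError("zero incorrect specificity: fidelity undefined")
    fid = sc / si
    loss = reference_fidelity / fid if reference_fidelity is not None else None
    return FidelityResult(
        specificity_correct=sc,
        specificity_incorrect=si,
        fidelity=fid,
        loss_vs_reference=loss,
    )


@dataclass
class GelTable:
    """Quenched-timepoint gel quantification: per-band product intensities.

    ``bands`` has the time column removed: one column per product length,
    values are band intensities (arbitrary, >= 0); ``substrate`` is the
    unextended-primer band.
    """

    time: np.ndarray
    bands: pd.DataFrame
    substrate: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        if self.bands.shape[0] != self.time.size or self.substrate.size != self.time.size:
            raise ValueError("time, bands and substrate must have equal length")
        if self.bands.shape[1] < 1:
            raise ValueError("need >= 1 band column")
        if (self.bands.values < 0).any() or (self.substrate < 0).any():
            raise ValueError("intensities must be >= 0")


def sum_product_bands(gel: GelTable, meta: Optional[dict] = None) -> ProductTimeCourse:
    """Total-product quantification for slippage-prone substrates.

    Repetitive templates yield multiple product lengths; individual
    single-nucleotide rates are not extractable (the substrate/product
    slippage equilibria are unknown), so the rate estimate comes from
    fraction(t) = Σ bands / (Σ bands + substrate), to be fed to
    :func:`fit_single_exponential`.
    """
    total_product = gel.bands.sum(axis=1).to_numpy()
    denom = total_product + gel.substrate
    if np.any(denom <= 0):
        rows = np.flatnonzero(denom <= 0)
        raise ValueError(f"all-zero gel rows at indices {rows.tolist()}: fraction undefined")
    frac = total_product / denom
    m = {"kind": "gel_summed_bands", "n_bands": gel.bands.shape[1]}
    if meta:
        m.update(meta)
    return ProductTimeCourse(time=gel.time.copy(), fraction_product=frac, meta=m)
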