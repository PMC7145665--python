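"""Linear free energy relationship (Brønsted-type) analysis.

Across a series of β,γ-bridging dGTP analogues, log10(kpol) regressed on
the fourth acid-dissociation constant (pKa4) of the pyrophosphate-analogue
leaving group probes whether phosphodiester bond formation is
rate-limiting: a steep negative slope means the transition state feels
leaving-group basicity (chemistry rate-limiting); a slope near zero means
some earlier step limits the rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = ["AnalogueRecord", "LFERFit", "fit_lfer", "compare_slopes"]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class AnalogueRecord:
    """One nucleotide analogue: leaving-group pKa4 and measured kpol (s⁻¹)."""

    label: str
    pKa4: float
    kpol: float
    kpol_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.kpol > 0:
            raise ValueError(f"kpol must be > 0, got {self.kpol} for {self.label}")
        if not np.isfinite(self.pKa4):
            raise ValueError(f"pKa4 must be finite for {self.label}")


@dataclass(frozen=True)
class LFERFit:
    """Fitted LFER line log10(kpol) = slope·pKa4 + intercept."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int

    def summary(self) -> str:
        return (
            "LFER fit: log10(kpol) = slope * pKa4 + intercept\n"
            f"  slope     = {self.slope:.4g} +/- {self.slope_se:.2g} per pKa4 unit\n"
            f"  intercept = {self.intercept:.4g} +/- {self.intercept_se:.2g}\n"
            f"  R^2 = {self.r_squared:.4f}, n = {self.n}"
        )


def fit_lfer(records: Sequence[AnalogueRecord], weighted: bool = False) -> LFERFit:
    """Least-squares LFER slope across an analogue series.

    Unweighted OLS by default; with ``weighted=True`` and per-analogue kpol
    SEs available, 1/SE² weights on the log10 scale are used (SEs
    propagated as se/(kpol·ln10)).
    """
    if len(records) < 2:
        raise ValueError("need >= 2 analogues")
    x = np.array([r.pKa4 for r in records])
    if np.unique(x).size < 2:
        raise ValueError("slope undefined: all pKa4 values identical")
    y = np.log10([r.kpol for r in records])
    X = sm.add_constant(x)
    if weighted:
        ses = [r.kpol_se for r in records]
        if any(se is None or se <= 0 for se in ses):
            raise ValueError("weighted fit requires positive kpol_se on every record")
        w = np.array([1.0 / (se / (r.kpol * LN10)) ** 2 for r, se in zip(records, ses)])
        model = sm.WLS(y, X, weights=w)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    if len(records) == 2:
        se_int, se_slope = np.nan, np.nan
    else:
        se_int, se_slope = res.bse
    return LFERFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(se_slope),
        intercept_se=float(se_int),
        r_squared=float(res.rsquared) if np.isfinite(res.rsquared) else 0.0,
        n=len(records),
    )


def compare_slopes(fit_a: LFERFit, fit_b: LFERFit) -> tuple[float, float, float]:
    """Difference between two LFER slopes from independent series.

    Returns (difference a−b, SE of the difference, large-sample z-score).
    This is a convenience statistic beyond the usual qualitative slope
    comparison; with the small n typical of analogue series it is
    approximate.
    """
    diff = fit_a.slope - fit_b.slope
    se = float(np.hypot(fit_a.slope_se, fit_b.slope_se))
    z = diff / se if se > 0 else np.inf if diff != 0 else 0.0
    return float(diff), se, float(z)
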