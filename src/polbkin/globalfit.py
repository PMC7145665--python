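"""Constrained global fitting of the mechanism to multi-trace FRET data.

:class:`SchemeGlobalFit` is the modelling entry point: it holds a dataset
(forward stopped-flow traces at several nucleotide concentrations, plus
optional quench-flow product curves), a constraint policy, and an initial
parameter set; :meth:`SchemeGlobalFit.fit` returns a
:class:`SchemeGlobalFitResults` carrying estimates, standard errors,
diagnostics, a ``summary()`` table, and confidence-contour profiling
(:meth:`SchemeGlobalFitResults.profile_pair`).

The standard constraint policy mirrors the experimental design: the
nucleotide K_D is fixed at its biochemically measured value, the reverse
rates of fingers closing and the non-covalent step at the competition
assay values, pyrophosphorolysis at zero; the forward conformational
rates, chemistry, and the post-chemistry step are estimated. Free rate
constants are optimized in log10 space (they span orders of magnitude);
per-trace scale and offset are linear nuisances profiled out analytically
at every objective evaluation, and the closed/open amplitude ratio is a
single shared free parameter. Weights are 1/sigma^2 with sigma estimated
per trace from high-frequency late-time residual scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import lmfit
from scipy import stats

from .parameters import RateParameters, AssayConditions
from .scheme import simulate_timecourse
from .observables import Trace, ProductTimeCourse, product_fraction

__all__ = [
    "Constraint",
    "ParameterConstraints",
    "standard_policy",
    "SchemeGlobalFit",
    "SchemeGlobalFitResults",
    "ContourMap",
    "fit_global",
    "profile_objective",
    "fitspace_threshold",
]

RATE_NAMES = ("KD_dNTP", "kon_dNTP", "k2f", "k2r", "k3f", "k3r", "k4f", "k4r", "k5f", "k5r")


@dataclass(frozen=True)
class Constraint:
    """One parameter's status: fixed at a value, bounded, or free."""

    kind: str  # "fixed" | "bounded" | "free"
    value: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "bounded", "free"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "fixed" and self.value is None:
            raise ValueError("fixed constraint needs a value")
        if self.kind == "bounded":
            if self.lo is None or self.hi is None or not (self.lo < self.hi):
                raise ValueError("bounded constraint needs lo < hi")
            if self.value is not None and not (self.lo <= self.value <= self.hi):
                raise ValueError("fixed/init value outside bounds")


class ParameterConstraints:
    """Constraint policy over the mechanism rate constants."""

    def __init__(self, constraints: dict[str, Constraint]):
        unknown = set(constraints) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        self._c = dict(constraints)
        if not self.free_names():
            raise ValueError("at least one parameter must be free")

    def __getitem__(self, name: str) -> Constraint:
        return self._c.get(name, Constraint("fixed", value=None, note="implicitly fixed at init"))

    def get(self, name: str) -> Optional[Constraint]:
        return self._c.get(name)

    def free_names(self) -> list[str]:
        return [n for n in RATE_NAMES if n in self._c and self._c[n].kind != "fixed"]

    def fixed_items(self) -> dict[str, float]:
        return {
            n: c.value for n, c in self._c.items() if c.kind == "fixed" and c.value is not None
        }

    def record(self) -> dict[str, dict]:
        return {
            n: {"kind": c.kind, "value": c.value, "lo": c.lo, "hi": c.hi, "note": c.note}
            for n, c in self._c.items()
        }


def standard_policy(
    KD_dNTP: float,
    k2r: float,
    k3r: float,
    kon_dNTP: float = 100.0,
    free: Sequence[str] = ("k2f", "k3f", "k4f", "k5f"),
    lo: float = 1e-3,
    hi: float = 1e4,
) -> ParameterConstraints:
    """The study's constraint policy.

    K_D fixed at the biochemically measured value, reverse rates of steps
    2 and 3 fixed at the competition-assay values, pyrophosphorolysis
    fixed to zero, the nucleotide on-rate a fixed convention; the forward
    conformational rates, chemistry, and post-chemistry reopening are
    free within wide bounds.
    """
    c = {
        "KD_dNTP": Constraint("fixed", value=KD_dNTP, note="K_D from biochemical fit"),
        "kon_dNTP": Constraint("fixed", value=kon_dNTP, note="association-rate convention"),
        "k2r": Constraint("fixed", value=k2r, note="fingers reopening from competition assay"),
        "k3r": Constraint("fixed", value=k3r, note="NCS reverse from competition assay"),
        "k4r": Constraint("fixed", value=0.0, note="pyrophosphorolysis negligible, fixed 0"),
        "k5r": Constraint("fixed", value=0.0, note="no rebinding pool in forward assay"),
    }
    for name in free:
        c[name] = Constraint("bounded", lo=lo, hi=hi, note="estimated from the fit")
    return ParameterConstraints(c)


def estimate_trace_sigma(y: np.ndarray, tail_fraction: float = 0.25) -> float:
    """Noise SD from first differences of the flat late part of a trace.

    Uses a median-based scale and discards exactly-zero differences:
    product fractions clipped at the [0, 1] boundary produce runs of
    identical values whose differences would otherwise drive the
    estimate (and hence the trace weight) to nonsense.
    """

    def robust_scale(d: np.ndarray):
        d = d[d != 0.0]
        if d.size < 3:
            return None
        s = 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)
        return s if s > 0 and np.isfinite(s) else None

    n = y.size
    tail = y[max(0, int(n * (1 - tail_fraction))):]
    s = robust_scale(np.diff(tail)) if tail.size >= 3 else None
    if s is None:
        s = robust_scale(np.diff(y))
    if s is None:
        s = max(1e-6 * max(abs(float(np.ptp(y))), 1.0), 1e-12)
    return s


@dataclass
class ContourMap:
    """Profiled-objective grid over one parameter pair (FitSpace style)."""

    param_x: str
    param_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    objective: np.ndarray  # shape (len(grid_y), len(grid_x))
    chisqr_min: float
    threshold: float
    bounded_x: bool
    bounded_y: bool
    boundary: list = field(default_factory=list)  # polygons [(x, y) arrays]

    @property
    def constrained(self) -> bool:
        return self.bounded_x and self.bounded_y


def fitspace_threshold(chisqr_min: float, n_points: int, n_free: int, alpha: float = 0.05) -> float:
    """Objective threshold for the confidence region.

    chi2 threshold = chi2_min * (1 + p/(n-p) * F(1-alpha; p, n-p)): the
    standard F-distribution rule for a p-parameter joint confidence region
    in nonlinear least squares.
    """
    dof = n_points - n_free
    if dof <= 0:
        raise ValueError("more free parameters than data points")
    f = stats.f.ppf(1.0 - alpha, n_free, dof)
    return chisqr_min * (1.0 + n_free * f / dof)


def profile_interval(
    residual_fn: Callable[[lmfit.Parameters], np.ndarray],
    best: lmfit.Parameters,
    name: str,
    chisqr_min: float,
    delta_chisqr: float = 1.0,
    step: float = 0.3,
    max_steps: int = 9,
    n_bisect: int = 3,
) -> tuple[float, float]:
    """Profile-likelihood interval for one parameter (in its own scale).

    Walks the named parameter outward from its estimate in ``step``
    increments (log10 units for ``log10_*`` parameters), re-optimizing all
    other free parameters, until the profiled chi-square exceeds
    ``chisqr_min + delta_chisqr``; the crossing is then bisected. With
    weighted residuals, ``delta_chisqr=1`` gives the 1-sigma profile
    interval. Returns (lo, hi); an endpoint is ±inf when the target is
    not crossed within the searched range (parameter weakly constrained
    on that side).
    """
    target = chisqr_min + delta_chisqr
    is_log = name.startswith("log10_")
    warm = {"params": best}

    def chis_at(val: float) -> float:
        # warm-start each re-optimization from the previous profile point
        p = warm["params"].copy()
        p[name].value = float(val)
        p[name].vary = False
        if any(par.vary for par in p.values()):
            # the walk needs chi-square to ~1% of delta_chisqr, not machine
            # precision: loose tolerances keep each re-optimization cheap
            out = lmfit.minimize(residual_fn, p, method="leastsq", ftol=1e-6, xtol=1e-6)
            warm["params"] = out.params
            return float(out.chisqr)
        return float(np.sum(residual_fn(p) ** 2))

    center = best[name].value
    bounds = []
    for direction in (-1.0, +1.0):
        warm["params"] = best
        lo_val, hi_val = center, None
        crossed = False
        for i in range(1, max_steps + 1):
            val = center + direction * step * i
            val = min(max(val, best[name].min), best[name].max)
            c = chis_at(val)
            if c >= target:
                hi_val = val
                crossed = True
                break
            lo_val = val
            if val in (best[name].min, best[name].max):
                break
        if not crossed:
            bounds.append(direction * np.inf)
            continue
        a, b = lo_val, hi_val
        for _ in range(n_bisect):
            mid = 0.5 * (a + b)
            if chis_at(mid) >= target:
                b = mid
            else:
                a = mid
        bounds.append(0.5 * (a + b))
    lo, hi = bounds
    if is_log:
        lo = 10.0**lo if np.isfinite(lo) else 0.0
        hi = 10.0**hi if np.isfinite(hi) else np.inf
    return (lo, hi) if lo <= hi else (hi, lo)


def profile_objective(
    residual_fn: Callable[[lmfit.Parameters], np.ndarray],
    params: lmfit.Parameters,
    pair: tuple[str, str],
    grid_x: np.ndarray,
    grid_y: np.ndarray,
) -> np.ndarray:
    """Profiled chi-square over a grid of one parameter pair.

    At each grid node the two named parameters are clamped and all
    remaining free parameters re-optimized; returns the matrix of
    minimized objectives (shape ``(len(grid_y), len(grid_x))``).
    """
    name_x, name_y = pair
    obj = np.empty((len(grid_y), len(grid_x)))
    base = params.copy()
    for iy, gy in enumerate(grid_y):
        for ix, gx in enumerate(grid_x):
            p = base.copy()
            for name, val in ((name_x, gx), (name_y, gy)):
                p[name].value = float(val)
                p[name].vary = False
                p[name].min, p[name].max = -np.inf, np.inf
            if any(par.vary for par in p.values()):
                out = lmfit.minimize(residual_fn, p, method="leastsq")
                obj[iy, ix] = float(np.sum(out.residual**2))
            else:
                obj[iy, ix] = float(np.sum(residual_fn(p) ** 2))
    return obj


def _contour_polygons(grid_x, grid_y, obj, level) -> list:
    try:
        from contourpy import contour_generator

        gen = contour_generator(x=grid_x, y=grid_y, z=obj)
        return [np.asarray(seg) for seg in gen.lines(level)]
    except Exception:  # pragma: no cover - contour extraction is cosmetic
        return []


class SchemeGlobalFit:
    """Global mechanism fit to a multi-trace FRET dataset.

    Parameters
    ----------
    traces : sequence of Trace
        Forward stopped-flow traces; each must carry ``dntp_conc`` in its
        metadata (μM). Two or more distinct concentrations are
        recommended for identifiability (a warning is issued otherwise).
    constraints : ParameterConstraints
        Fixed/bounded/free status per rate constant.
    init : RateParameters
        Starting values; must satisfy the fixed constraints.
    product_courses : sequence of ProductTimeCourse, optional
        Quench-flow data fitted jointly (off by default; supply to enable).
    amp_ratio_init : float
        Closed/open amplitude ratio (shared across traces). Fixed by
        default: with per-trace scale and offset free and the total
        complex constant within a trace, open and closed occupancies are
        complementary and the ratio is exactly degenerate with the
        per-trace nuisances — floating it only destabilizes the
        covariance. Set ``fit_amp_ratio=True`` to float it anyway (e.g.
        for datasets whose enzyme totals vary within a trace).
    rtol, atol : float
        Integrator tolerances during the search.
    """

    def __init__(
        self,
        traces: Sequence[Trace],
        constraints: ParameterConstraints,
        init: RateParameters,
        product_courses: Sequence[ProductTimeCourse] = (),
        amp_ratio_init: float = 0.35,
        fit_amp_ratio: bool = False,
        rtol: float = 1e-7,
        atol: float = 1e-10,
    ):
        if len(traces) == 0:
            raise ValueError("need at least one trace")
        concs = {t.meta.get("dntp_conc") for t in traces}
        if None in concs:
            raise ValueError("every trace needs dntp_conc metadata (μM)")
        if len(concs) < 2:
            warnings.warn(
                "fewer than 2 distinct dNTP concentrations: mechanism parameters "
                "may be poorly identified",
                stacklevel=2,
            )
        for name, val in constraints.fixed_items().items():
            init_val = getattr(init, name)
            if abs(init_val - val) > 1e-12 * max(1.0, abs(val)):
                init = init.replace(**{name: val})
        self.traces = list(traces)
        self.product_courses = list(product_courses)
        self.constraints = constraints
        self.init = init
        self.amp_ratio_init = amp_ratio_init
        self.fit_amp_ratio = fit_amp_ratio
        self.rtol = rtol
        self.atol = atol
        self._weights = [1.0 / estimate_trace_sigma(t.signal) for t in self.traces]
        self._pc_weights = [
            1.0 / estimate_trace_sigma(np.asarray(pc.fraction_product))
            for pc in self.product_courses
        ]
        self.n_points = sum(t.time.size for t in self.traces) + sum(
            pc.time.size for pc in self.product_courses
        )

    # ---- parameter mapping -------------------------------------------------

    def _make_params(self, init: RateParameters) -> lmfit.Parameters:
        p = lmfit.Parameters()
        for name in RATE_NAMES:
            c = self.constraints.get(name)
            val = getattr(init, name)
            if c is None or c.kind == "fixed":
                fixed_val = val if (c is None or c.value is None) else c.value
                p.add(f"c_{name}", value=float(fixed_val), vary=False)
            else:
                lo = c.lo if c.lo is not None else 1e-6
                hi = c.hi if c.hi is not None else 1e6
                v = np.clip(val if val > 0 else np.sqrt(lo * hi), lo, hi)
                p.add(
                    f"log10_{name}",
                    value=float(np.log10(v)),
                    min=float(np.log10(lo)),
                    max=float(np.log10(hi)),
                )
        p.add(
            "amp_ratio",
            value=float(self.amp_ratio_init),
            min=0.0,
            max=0.99,
            vary=self.fit_amp_ratio,
        )
        return p

    def _params_to_rates(self, p: lmfit.Parameters) -> RateParameters:
        kw = {}
        for name in RATE_NAMES:
            if f"log10_{name}" in p:
                kw[name] = 10.0 ** p[f"log10_{name}"].value
            else:
                kw[name] = p[f"c_{name}"].value
        return RateParameters(**kw)

    # ---- objective ---------------------------------------------------------

    def _conditions_for(self, trace: Trace) -> AssayConditions:
        m = trace.meta
        return AssayConditions(
            enzyme_total=float(m.get("enzyme_total", 0.4)),
            dna_total=float(m.get("dna_total", 0.2)),
            dntp_0=float(m["dntp_conc"]),
        )

    def _raw_residuals(self, p: lmfit.Parameters) -> list[np.ndarray]:
        """Unweighted model-minus-data residuals, one chunk per curve.

        A pathological parameter set during the search is penalized with a
        large constant chunk rather than aborting the optimizer.
        """
        rates = self._params_to_rates(p)
        r = p["amp_ratio"].value
        chunks = []
        for trace in self.traces:
            grid = np.concatenate([[0.0], trace.time]) if trace.time[0] > 0 else trace.time
            try:
                traj = simulate_timecourse(
                    rates, self._conditions_for(trace), grid, rtol=self.rtol, atol=self.atol
                )
            except Exception:
                chunks.append(np.full(trace.time.size, 1e3))
                continue
            sl = slice(1, None) if trace.time[0] > 0 else slice(None)
            basis = traj.open_occupancy()[sl] + r * traj.closed_occupancy()[sl]
            # per-trace scale/offset: linear least squares, closed form
            A = np.column_stack([basis, np.ones_like(basis)])
            coef, *_ = np.linalg.lstsq(A, trace.signal, rcond=None)
            chunks.append(A @ coef - trace.signal)
        for pc in self.product_courses:
            grid = np.concatenate([[0.0], pc.time]) if pc.time[0] > 0 else pc.time
            cond = AssayConditions(
                enzyme_total=float(pc.meta.get("enzyme_total", 0.2)),
                dna_total=float(pc.meta.get("dna_total", 0.05)),
                dntp_0=float(pc.meta["dntp_conc"]),
            )
            try:
                traj = simulate_timecourse(rates, cond, grid, rtol=self.rtol, atol=self.atol)
            except Exception:
                chunks.append(np.full(pc.time.size, 1e3))
                continue
            sl = slice(1, None) if pc.time[0] > 0 else slice(None)
            frac = product_fraction(traj).fraction_product[sl]
            chunks.append(frac - np.asarray(pc.fraction_product))
        return chunks

    def _residual(self, p: lmfit.Parameters) -> np.ndarray:
        chunks = self._raw_residuals(p)
        weights = self._weights + self._pc_weights
        return np.concatenate([w * c for w, c in zip(weights, chunks)])

    def _reestimate_weights(self, p: lmfit.Parameters) -> None:
        """Refine per-curve noise scales from the current fit residuals.

        The initial difference-based scales are biased when a product
        curve saturates against the [0, 1] boundary (clipping truncates
        the noise); residual-based scales, excluding boundary-clipped
        points, are not. Truth-free: uses only data and current model.
        """
        chunks = self._raw_residuals(p)
        n_tr = len(self.traces)
        new_w = []
        for i, chunk in enumerate(chunks):
            resid = chunk
            if i >= n_tr:
                f = np.asarray(self.product_courses[i - n_tr].fraction_product)
                free = (f > 0.0) & (f < 1.0)
                if free.sum() >= 5:
                    resid = chunk[free]
            s = float(np.std(resid))
            if not (s > 0 and np.isfinite(s)):
                s = 1e-12
            new_w.append(1.0 / s)
        self._weights = new_w[:n_tr]
        self._pc_weights = new_w[n_tr:]

    def _trace_nuisances(self, p: lmfit.Parameters) -> list[tuple[float, float]]:
        rates = self._params_to_rates(p)
        r = p["amp_ratio"].value
        out = []
        for trace in self.traces:
            grid = np.concatenate([[0.0], trace.time]) if trace.time[0] > 0 else trace.time
            traj = simulate_timecourse(
                rates, self._conditions_for(trace), grid, rtol=self.rtol, atol=self.atol
            )
            sl = slice(1, None) if trace.time[0] > 0 else slice(None)
            basis = traj.open_occupancy()[sl] + r * traj.closed_occupancy()[sl]
            A = np.column_stack([basis, np.ones_like(basis)])
            coef, *_ = np.linalg.lstsq(A, trace.signal, rcond=None)
            out.append((float(coef[0]), float(coef[1])))
        return out

    # ---- fitting -----------------------------------------------------------

    def fit(
        self,
        multistart: int = 5,
        seed: int = 0,
        spread: float = 0.6,
        profile_se: bool = False,
        profile_se_names: Optional[Sequence[str]] = None,
    ) -> "SchemeGlobalFitResults":
        """Minimize the weighted SSE; returns the best of ``multistart``
        seeded starts (log10 values of free rates perturbed by N(0, spread)).

        With ``profile_se=True`` each free rate additionally gets a
        profile-likelihood (delta-chi-square = 1) standard error; on
        curved ridges these are valid where the local-curvature SEs are
        not, at the cost of extra re-optimizations.
        """
        p0 = self._make_params(self.init)
        obj_init = float(np.sum(self._residual(p0) ** 2))
        rng = np.random.default_rng(seed)
        free_names = [n for n, par in p0.items() if par.vary]

        def run_starts(n_starts: int, spread_: float, perturb_first: bool, best=None):
            for start in range(max(1, n_starts)):
                p = p0.copy()
                if start > 0 or perturb_first:
                    for n in free_names:
                        if n == "amp_ratio":
                            continue
                        par = p[n]
                        par.value = float(
                            np.clip(par.value + rng.normal(0.0, spread_), par.min, par.max)
                        )
                out = lmfit.minimize(self._residual, p, method="leastsq")
                if best is None or out.chisqr < best.chisqr:
                    best = out
            return best

        best = run_starts(multistart, spread, perturb_first=False)
        if self.product_courses:
            # refine the noise scales from the fit residuals and polish:
            # difference-based sigma estimates are biased (far too small)
            # for product curves whose tails are clipped at the [0, 1]
            # boundary; FRET traces are unaffected and keep their scales
            self._reestimate_weights(best.params)
            p_best = best.params.copy()
            obj_init = float(np.sum(self._residual(p0) ** 2))
            best = lmfit.minimize(self._residual, p_best, method="leastsq")
        # a reduced chi-square far above 1 flags a stalled search (the
        # weights are on the noise scale); widen the search before accepting
        if best.redchi > 3.0:
            best = run_starts(2 * multistart, 2.0 * spread, perturb_first=True, best=best)

        flags: list[str] = []
        if not best.success:
            flags.append("non-convergence: " + str(best.message))
        estimates = self._params_to_rates(best.params)
        bse: dict[str, float] = {}
        for name in self.constraints.free_names():
            key = f"log10_{name}"
            se_log = best.params[key].stderr
            value = getattr(estimates, name)
            bse[name] = float(np.log(10.0) * value * se_log) if se_log else np.nan
            lo, hi = best.params[key].min, best.params[key].max
            if min(best.params[key].value - lo, hi - best.params[key].value) < 1e-6:
                flags.append(f"{name} at bound")
        amp_ratio = float(best.params["amp_ratio"].value)
        amp_ratio_se = float(best.params["amp_ratio"].stderr or np.nan)

        bse_profile: dict[str, float] = {}
        if profile_se:
            names = (
                list(profile_se_names)
                if profile_se_names is not None
                else self.constraints.free_names()
            )
            for name in names:
                # scale the walk to the local curvature so the bisection
                # resolves the crossing to a fraction of the SE
                se_log = best.params[f"log10_{name}"].stderr or 0.1
                step = float(np.clip(1.5 * se_log, 0.03, 0.3))
                lo, hi = profile_interval(
                    self._residual,
                    best.params,
                    f"log10_{name}",
                    float(best.chisqr),
                    step=step,
                    max_steps=max(9, int(np.ceil(2.7 / step))),
                )
                est = getattr(estimates, name)
                half = max(est - lo, hi - est)
                bse_profile[name] = float(half)
                if not np.isfinite(half):
                    flags.append(f"{name}: profile interval open-ended")

        return SchemeGlobalFitResults(
            model=self,
            estimates=estimates,
            bse=bse,
            bse_profile=bse_profile,
            amp_ratio=amp_ratio,
            amp_ratio_se=amp_ratio_se,
            trace_nuisances=self._trace_nuisances(best.params),
            chisqr=float(best.chisqr),
            redchi=float(best.redchi),
            objective_at_init=obj_init,
            nfev=int(best.nfev),
            success=bool(best.success),
            flags=flags,
            constraint_record=self.constraints.record(),
            _minimizer_result=best,
        )


@dataclass
class SchemeGlobalFitResults:
    """Estimates and diagnostics of a global mechanism fit."""

    model: SchemeGlobalFit
    estimates: RateParameters
    bse: dict[str, float]
    bse_profile: dict[str, float]
    amp_ratio: float
    amp_ratio_se: float
    trace_nuisances: list[tuple[float, float]]
    chisqr: float
    redchi: float
    objective_at_init: float
    nfev: int
    success: bool
    flags: list[str]
    constraint_record: dict
    _minimizer_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    @property
    def n_free(self) -> int:
        return len(self.model.constraints.free_names()) + int(self.model.fit_amp_ratio)

    def se(self, name: str) -> float:
        """Fitted SE of a free rate: profile-likelihood if computed and
        finite, local curvature otherwise."""
        prof = self.bse_profile.get(name)
        if prof is not None and np.isfinite(prof):
            return prof
        return self.bse.get(name, np.nan)

    def summary(self) -> str:
        lines = [
            "Global mechanism fit (six-state sequential scheme)",
            f"  traces: {len(self.model.traces)}  points: {self.model.n_points}"
            f"  chi^2: {self.chisqr:.6g}  reduced: {self.redchi:.4g}",
            f"  converged: {self.success}  function evals: {self.nfev}",
            "",
            f"  {'parameter':<10} {'estimate':>12} {'SE':>10}  status",
        ]
        for name in RATE_NAMES:
            c = self.model.constraints.get(name)
            val = getattr(self.estimates, name)
            if c is not None and c.kind != "fixed":
                se = self.bse.get(name, np.nan)
                lines.append(f"  {name:<10} {val:>12.5g} {se:>10.3g}  free ({c.note})")
            else:
                note = c.note if c is not None else "fixed at init"
                lines.append(f"  {name:<10} {val:>12.5g} {'--':>10}  fixed ({note})")
        amp_status = "free" if self.model.fit_amp_ratio else "fixed"
        lines.append(
            f"  {'amp_ratio':<10} {self.amp_ratio:>12.5g} {self.amp_ratio_se:>10.3g}  "
            f"{amp_status} (shared closed/open amplitude)"
        )
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)

    # ---- identifiability ---------------------------------------------------

    def profile_pair(
        self,
        param_x: str,
        param_y: str,
        grid_size: int = 9,
        span_factor: float = 4.0,
        threshold_rule="ftest",
        alpha: float = 0.05,
    ) -> ContourMap:
        """FitSpace-style confidence contour for one parameter pair.

        Grids both parameters geometrically around their estimates
        (``span_factor``-fold each way), re-optimizes every other free
        parameter at each node, and thresholds the profiled objective at
        the F-distribution level (``threshold_rule='ftest'``) or at a fixed
        chi-square ratio (pass a float, e.g. 1.1). A parameter whose
        sub-threshold region reaches the edge of the searched range is
        reported as not constrained by the data (never clipped silently).
        """
        for name in (param_x, param_y):
            if name not in self.model.constraints.free_names():
                raise ValueError(f"{name} is not a free parameter of this fit")
        if isinstance(threshold_rule, str) and threshold_rule == "ftest":
            threshold = fitspace_threshold(self.chisqr, self.model.n_points, self.n_free, alpha)
        else:
            threshold = self.chisqr * float(threshold_rule)

        gx = np.geomspace(
            getattr(self.estimates, param_x) / span_factor,
            getattr(self.estimates, param_x) * span_factor,
            grid_size,
        )
        gy = np.geomspace(
            getattr(self.estimates, param_y) / span_factor,
            getattr(self.estimates, param_y) * span_factor,
            grid_size,
        )
        params = self._minimizer_result.params.copy()
        obj = profile_objective(
            self.model._residual,
            params,
            (f"log10_{param_x}", f"log10_{param_y}"),
            np.log10(gx),
            np.log10(gy),
        )
        inside = obj <= threshold
        bounded_x = not (inside[:, 0].any() or inside[:, -1].any())
        bounded_y = not (inside[0, :].any() or inside[-1, :].any())
        for name, ok in ((param_x, bounded_x), (param_y, bounded_y)):
            if not ok:
                warnings.warn(
                    f"{name} is not constrained by the data within the searched range",
                    stacklevel=2,
                )
        boundary = _contour_polygons(gx, gy, obj, threshold)
        return ContourMap(
            param_x=param_x,
            param_y=param_y,
            grid_x=gx,
            grid_y=gy,
            objective=obj,
            chisqr_min=self.chisqr,
            threshold=threshold,
            bounded_x=bounded_x,
            bounded_y=bounded_y,
            boundary=boundary,
        )

    def to_report(self) -> dict:
        """JSON-serializable report of the fit."""
        return {
            "estimates": self.estimates.to_dict(),
            "standard_errors": self.bse,
            "profile_standard_errors": self.bse_profile,
            "amp_ratio": self.amp_ratio,
            "amp_ratio_se": self.amp_ratio_se,
            "trace_nuisances": self.trace_nuisances,
            "chisqr": self.chisqr,
            "redchi": self.redchi,
            "objective_at_init": self.objective_at_init,
            "nfev": self.nfev,
            "success": self.success,
            "flags": self.flags,
            "constraints": self.constraint_record,
        }


def fit_global(
    dataset: Sequence[Trace],
    constraints: ParameterConstraints,
    init: RateParameters,
    product_courses: Sequence[ProductTimeCourse] = (),
    **fit_kwargs,
) -> SchemeGlobalFitResults:
    """Functional wrapper: build a :class:`SchemeGlobalFit` and fit it."""
    return SchemeGlobalFit(dataset, constraints, init, product_courses=product_courses).fit(
        **fit_kwargs
    )


def profile_contours(
    result: SchemeGlobalFitResults,
    pairs: Sequence[tuple[str, str]],
    grid_size: int = 9,
    threshold_rule="ftest",
    **kwargs,
) -> list[ContourMap]:
    """Confidence contours for several parameter pairs of a converged fit."""
    if not result.success:
        warnings.warn("profiling a non-converged fit", stacklevel=2)
    return [
        result.profile_pair(a, b, grid_size=grid_size, threshold_rule=threshold_rule, **kwargs)
        for a, b in pairs
    ]
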