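# Methods

## Mechanism model

Single-nucleotide incorporation is modelled as a sequential six-state
mass-action scheme: nucleotide binding to the pre-formed binary complex,
fingers closing, a non-covalent step (NCS), phosphodiester bond formation,
and post-chemistry reopening. Internal units are μM and s throughout;
readers of nM-labelled files convert on input.

Assumptions and conventions:

* **Binding is explicit and bimolecular.** Equilibrium data constrain only
  K_D, so the association rate `kon_dNTP` is a convention parameter
  (default 100 μM⁻¹·s⁻¹, near the diffusion limit) and
  `koff = kon · K_D`. This keeps the model well-posed at sub-saturating
  nucleotide, where binding partially limits the observed rates.
* **Pyrophosphorolysis is zero** (`k4r = 0`) unless explicitly overridden:
  single-turnover conditions make the reverse of chemistry negligible.
* **Step 5's reverse flux is zero by default.** Its bimolecular partner
  pool is not modelled; `k5r` exists in the parameter block for
  completeness but multiplies an empty pool.
* **The NCS is an abstract first-order step.** Its structural identity is
  unknown; nothing in the model depends on what it physically is.
* The limiting complex concentration is `min(enzyme, DNA)`; surplus of
  either partner is kinetically silent.
* Integration uses LSODA with an analytic Jacobian, relative tolerance
  1e-8 and absolute tolerance 1e-10 μM by default (1e-7/1e-10 inside the
  global-fit search loop, where speed matters and the weighted residuals
  are insensitive to the difference). Enzyme and nucleotide conservation
  hold to better than 1e-6 relative on the default tolerances and are
  property-tested over random rate sets spanning several orders of
  magnitude.

A matrix-exponential solution of the pseudo-first-order (constant
nucleotide) linearization and a Monte-Carlo first-passage simulation serve
as independent oracles in the test suite only; the production path is
always the nonlinear ODE.

## Observables

The stopped-flow FRET observable uses a **two-level amplitude model**:
open states emit `a_open`, closed states `a_closed < a_open`, with
per-trace scale and offset nuisances. The assay physically distinguishes
only quenched from unquenched donor, so per-state amplitudes would be
unidentifiable. A consequence worth stating plainly: because open and
closed occupancies sum to the constant complex total within a trace, the
shared amplitude ratio `a_closed/a_open` is itself exactly degenerate with
the per-trace scale/offset pair. The global fit therefore holds the ratio
fixed by default (`fit_amp_ratio=True` restores a floating shared ratio
for designs where the total varies within a trace).

The competition (trap) experiment — excess unlabeled binary complex
capturing the nucleotide released from a chemistry-blocked labeled ternary
complex — is reduced to a pseudo-first-order sink on free dNTP (default
rate 1e3 s⁻¹, effectively instantaneous; the ten-fold trap excess and the
extendable trap DNA justify irreversibility). The initial state is the
exact equilibrium of the binding/closing/NCS chain. The fluorescence rise
is fitted with one or two exponentials; a two-phase fit falls back to one
phase when an extra-sum-of-squares F-test at α = 0.05 does not support the
second phase.

Instrument dead time (default 2 ms) is applied by the synthetic-data
generator as a front truncation, not by the simulator.

## Synthetic data

Generators are pure functions of (parameters, seed); dataset manifests
regenerate outputs bit-for-bit, and trace *i* uses the independent
substream `(seed, i)` so datasets extend without reshuffling. Noise is
additive Gaussian — the instruments average ≥10 shots per trace, making
residuals approximately Gaussian — with default SD 2% of the trace's
dynamic range (absolute 2% of full scale for product fractions, which are
clipped to [0, 1] as gel quantification demands).

Frozen default study conditions: forward FRET datasets use 400 nM labeled
enzyme, 200 nM acceptor-labelled DNA, a 50 s window sampled at 150
log-spaced points, and six nucleotide concentrations (1, 2.5, 5, 10, 25,
100 μM) spanning sub-saturating to saturating around the 10 μM nucleotide
K_D stand-in; quench-flow datasets use 50 nM DNA, 200 nM enzyme and 20
log-spaced quench times from 5 ms to 50 s. The analogue-series generator
places eight pKa4 values on a synthetic 7–11 grid (the real analogue
toolkit values live in supplementary sources not carried here) and draws
log10(kpol) about the specified LFER line with SD 0.05 log units.

What the generators deliberately do *not* emulate: photophysics
(bleaching, inner-filter), gel imaging artifacts, heteroscedastic or
correlated noise, and primer-template slippage equilibria. Passing
recovery tests therefore demonstrate estimator correctness under the
stated noise model, not robustness to instrument pathologies.

## Classical fits

Exponential and hyperbolic fits parameterize rates in log space (bounded,
strictly positive) with standard errors from the local curvature;
direction (rising/falling) is auto-detected; degenerate inputs (constant
data, unsupported second phase, concentrations never reaching K_D) are
flagged, never silently returned. The kobs errors from exponential fits
grow with the rate, so the kpol/K_D hyperbola accepts per-point SEs and
weights residuals 1/SE² (the single-turnover pipeline always passes them);
empirical coverage of the nominal 95% intervals is 90–98% across the
exponential, hyperbolic and LFER fitters in the test suite.

Fidelity is the ratio of catalytic specificities kpol/K_D for correct vs
incorrect nucleotide, with an optional loss factor relative to a reference
(conventionally the wild-type enzyme on the control substrate). For
repeat-template (slippage) gels only the summed-band product fraction is
quantified — single-nucleotide rates are not extractable because the
substrate/product slippage equilibria are unknown — and the summed curve
feeds the ordinary exponential fit.

The LFER uses base-10 logarithms (Brønsted convention) and unweighted OLS
by default, since per-analogue errors are rarely reported; a 1/SE²
weighted variant exists. Slope comparison between two series uses a
large-sample z on the difference with SEs added in quadrature — an
approximation at the n≈8 typical of analogue series, provided as a
convenience beyond the usual qualitative comparison.

## Global fitting

`SchemeGlobalFit` minimizes the weighted SSE over all traces (and,
optionally, jointly over quench-flow product curves) with:

* free rate constants in log10 space, bounded [1e-3, 1e4] s⁻¹;
* per-trace scale/offset solved in closed form (variable projection) at
  every objective evaluation;
* per-trace weights 1/σ̂² with σ̂ from a median-based scale of first
  differences over the final quarter of each trace (exactly-zero
  differences, the signature of boundary clipping, are discarded); for
  joint fits the scales are re-estimated once from the fit residuals —
  excluding product points clipped at 0 or 1 — and the fit polished,
  because clipped saturating product curves otherwise bias the
  difference-based estimate far low;
* multistart (default 5 starts, log10 perturbations of SD 0.6) because
  the (k3f, k4f) objective ridge harbours shallow local minima;
* a failed integration during the search penalized, logged and skipped
  rather than aborting the optimizer.

The standard constraint policy fixes K_D (biochemically measured), the
reverse rates of fingers closing and the NCS (competition assay),
pyrophosphorolysis (zero) and the on-rate convention, and estimates the
forward conformational rates, chemistry and the post-chemistry step.

**Identifiability.** With the two-level FRET observable and free per-trace
nuisances, the data constrain k3f and k4f mostly through the flux
combination `k3f·k4f/(k3r + k4f)`: the profiled objective along the
compensating direction is nearly flat at 2% noise (verified by noiseless
Fisher-information profiling). Three consequences are built in:

1. joint fitting with quench-flow product data (whose lag shape carries
   independent information and which does not depend on k5f) is supported
   and used by the recovery protocol;
2. local-curvature SEs are unreliable on the curved ridge, so the results
   object can compute **profile-likelihood SEs** (Δχ² = 1, warm-started
   walk + bisection) and the recovery checks use those;
3. pairwise **confidence contours** re-optimize all other free parameters
   on a log-spaced grid and threshold the profiled objective at the
   F-distribution level χ²_min·(1 + p/(n−p)·F₀.₉₅(p, n−p)) (a fixed-ratio
   threshold is available); a region reaching the grid edge is reported
   as "not constrained by the data", never clipped.

For the NCS-limited variant/hotspot condition the k3f uncertainty remains
of order 40–50% even jointly — an honest property of the assay design, not
of the optimizer — so recovered values for that condition scatter
accordingly across seeds.

## Recovery protocols and problem sizes

The packaged recovery experiments (also what `scripts/acceptance.py`
runs) use: six-concentration FRET datasets (≈ 900 points) plus
six-concentration quench-flow datasets (120 points) at 2% noise, fits
started two-fold away from the generating truth with 5 multistarts, and
profile SEs on the forward rates; the single-turnover pipeline uses 15
quench times per concentration over seven half-lives; LFER recovery
averages 1000 seeded eight-point series. The multi-seed recovery claim is
spot-checked at one fixed seed per condition in the test suite, keeping
the default run at a few minutes on one core.

## Known limitations

* The two-level amplitude model caps what FRET data can say about steps
  that interconvert closed states; per-state amplitudes would require a
  different labelling scheme, not a different fitter.
* K_D values, the post-chemistry rate and a few reverse rates of the
  published parameter sets are synthetic stand-ins (flagged per condition
  in `presets.STAND_IN_FIELDS`); recovery experiments are internally
  consistent but those fields are not literature values.
* No multi-turnover/burst kinetics, no Bayesian posterior sampling, no
  alternative-mechanism model selection; the mechanism is fixed.
* The slope-comparison z-test and the F-based contour threshold are
  large-sample approximations.
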