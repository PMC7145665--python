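# polbkin

Pre-steady-state kinetic analysis of single-nucleotide incorporation by DNA
polymerase β (pol β), built around the question of *which step limits the
rate*: for the wild-type enzyme phosphodiester bond formation is
rate-limiting, but for the colon-cancer variant K289M on the AACAA mutational
hotspot of the APC gene a pre-catalytic **non-covalent step (NCS)** becomes
slower than chemistry, with consequences for fidelity.

The package is for enzymologists doing transient kinetics: it simulates the
six-state incorporation mechanism, models the stopped-flow FRET and
rapid-quench observables, generates realistic seeded synthetic datasets, and
fits them — classically (exponentials, kpol/K_D hyperbola, fidelity, LFER
slopes) and globally (constrained multi-trace mechanism fits with
FitSpace-style confidence contours).

## The model

The mechanism is the sequential scheme

```
E·DNA + dNTP  ⇌(kon, koff=kon·K_D)  E(o)·DNA·dNTP  ⇌(k+2/k−2)  E(c)·DNA·dNTP
              ⇌(k+3/k−3)  E(c*)·DNA·dNTP  →(k+4)  E(c*)·DNA+1  →(k+5)  E(o)·DNA+1
```

with fingers closing (k±2), the NCS (k±3), chemistry (k+4, reverse
pyrophosphorolysis fixed at 0) and post-chemistry reopening (k+5), integrated
as a stiff mass-action ODE system (μM, s). The FRET observable distinguishes
only open {E·DNA, E(o)·dNTP, E(o)·DNA+1} from closed
{E(c), E(c*), E(c*)·DNA+1} states (the fingers-borne AEDANS donor is quenched
by the DNA-borne Dabcyl acceptor when the fingers close); the quench-flow
observable is the product fraction ([E(c*)·DNA+1] + [E(o)·DNA+1]) / total.

Classical analyses: single-turnover rates follow
`kobs = kpol·[dNTP]/(K_D + [dNTP])`; fidelity is
`(kpol/K_D)_correct / (kpol/K_D)_incorrect`; the Brønsted-type LFER is the
OLS slope of log10(kpol) on the leaving-group pKa4 across a dGTP-analogue
series — a near-zero slope means chemistry is *not* rate-limiting.

## Worked example

Recover the wild-type/control rate constants from a seeded synthetic
stopped-flow + quench-flow dataset, with the nucleotide K_D, the reverse
rates and pyrophosphorolysis constrained as in the experimental design:

```python
from polbkin.recovery import recover_scheme_condition

rec = recover_scheme_condition("wt_control", seed=1)
print(rec.results.summary())
```

prints (abridged):

```
Global mechanism fit (six-state sequential scheme)
  traces: 6  points: 810  chi^2: 798.675  reduced: 0.9909
  converged: True  function evals: 60

  parameter      estimate         SE  status
  KD_dNTP              10         --  fixed (K_D from biochemical fit)
  k2f               171.5       1.48  free (estimated from the fit)
  k2r                 2.1         --  fixed (fingers reopening from competition assay)
  k3f              21.489       8.67  free (estimated from the fit)
  k3r                19.8         --  fixed (NCS reverse from competition assay)
  k4f              18.037       6.87  free (estimated from the fit)
  k4r                   0         --  fixed (pyrophosphorolysis negligible, fixed 0)
  k5f              10.222      0.202  free (estimated from the fit)
```

The dataset was generated at the published wild-type/control rates
(k+2 = 173, k+3 = 24, k+4 = 16.6 s⁻¹) with 2% Gaussian noise; the fit
recovers fingers closing to better than 1% and the NCS/chemistry rates
within their (strongly anticorrelated) uncertainties. Identifiability of any
parameter pair can be inspected with
`rec.results.profile_pair("k3f", "k4f")`, which re-optimizes the remaining
parameters on a grid and reports whether the confidence region closes within
the searched range.

The classical single-turnover pipeline:

```python
from polbkin.recovery import recover_kpol
fit = recover_kpol(12.6, seed=1)   # truth: WT/control kpol
print(f"kpol = {fit.kpol:.2f} ± {fit.kpol_se:.2f} 1/s, K_D = {fit.KD_app:.1f} µM")
# kpol = 12.41 ± 0.38 1/s, K_D = 9.7 µM
```

A thin CLI mirrors the library (`polbkin simulate|fit-exp|fit-hyperbola|
fit-global|fitspace|lfer|pipeline`), reading/writing the CSV/TSV trace and
table formats described in `polbkin.io`.

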