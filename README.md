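# fractumor

Fractional and fractal-fractional simulation of a three-species
tumor–immune interaction model, for researchers studying how memory
(non-Markovian) effects reshape the dynamics of tumor–host–immune
competition.

## The model

A single tumor-site compartment holds tumor cells `T(t)`, healthy host
cells `H(t)`, and effector immune cells `E(t)` (dimensionless densities):

```
dT/dt = T(1 − T) − β₁₂ T H − β₁₃ T E
dH/dt = k₂ H(1 − H) − β₂₁ T H
dE/dt = k₃ T E/(T + s₃) − β₃₁ T E − c₃ E
```

Tumor and host cells grow logistically and compete; effector cells are
recruited at a saturating rate driven by tumor load, kill tumor cells,
and are themselves inactivated by them.  At the headline parameter set
(β₁₂ = 1, β₁₃ = 2.5, k₂ = 0.6, β₂₁ = 1.5, k₃ = 4.5, s₃ = 1, β₃₁ = 0.2,
c₃ = 0.5) the classical system is chaotic.

The ordinary time derivative `d/dt` can be replaced by fractional
derivatives of order α ∈ (0, 1] with three memory kernels — power law
(Liouville–Caputo), exponential (Caputo–Fabrizio), Mittag-Leffler
(Atangana–Baleanu) — and by their fractal-fractional extensions with
fractal dimension τ ∈ (0, 1].  Each operator gets a dedicated
time-stepper:

| scheme | operator | method |
|---|---|---|
| `caputo_abm` | power law | fractional Adams–Bashforth–Moulton predictor–corrector |
| `cfc_two_step` | exponential kernel | two-step Adams recursion |
| `abc_pi` | Mittag-Leffler kernel | implicit product-integration rule |
| `ff_power`, `ff_exp`, `ff_ml` | fractal-fractional variants | product-integration / two-step Adams |
| `classical_rk` | ordinary derivative | adaptive DOP853 reference |

The package also enumerates the system's six equilibrium families with
existence conditions and Jacobian-based stability, classifies simulated
attractors (fixed point / period-k / chaotic via peak structure and the
Gottwald–Melbourne 0–1 test), and runs one-parameter sensitivity sweeps.
See `docs/methods.md` for the numerical policies and their rationale.

## Worked example

Enumerate equilibria and classify stability at the headline parameters:

```python
from fractumor import HEADLINE_PARAMS, equilibria, classify_stability

for eq in equilibria(HEADLINE_PARAMS):
    if eq.exists:
        eq = classify_stability(eq, HEADLINE_PARAMS)
        print(eq.family, eq.coords.round(6), eq.stability)
```

prints

```
P1 [0. 0. 0.] unstable
P2 [0. 1. 0.] nonhyperbolic
P3 [1. 0. 0.] unstable
P4 [0.132503 0.       0.346999] unstable
```

Four of the six families exist here: total extinction `P1` and the
tumor-only state `P3` are unstable; the tumor-free state `P2` is
nonhyperbolic precisely because β₁₂ = 1 puts a zero eigenvalue on the
tumor direction (for β₁₂ > 1 it becomes stable — host cells outcompete
an incipient tumor); the tumor–effector state `P4` sits at the smaller
positive root T* ≈ 0.1325 of the characteristic quadratic
β₃₁T² + (c₃ + s₃β₃₁ − k₃)T + s₃c₃ = 0 and is an unstable focus — the
source of the system's oscillations.  With no stable equilibrium, the
attractor is a cycle or a chaotic set.

Simulate and classify a regime (the limit-cycle parameter set):

```python
from fractumor import SolverGrid, SolverSpec, simulate, classify_attractor
from dataclasses import replace

params = replace(HEADLINE_PARAMS, b12=0.745)
traj = simulate(params, [0.3, 0.3, 0.3], SolverGrid(t_final=300, h=0.005),
                SolverSpec("caputo_abm", alpha=0.98))
report = classify_attractor(traj)
print(report.label, round(report.K_statistic, 3), round(report.period_estimate, 2))
```

prints

```
period_1 0.0 18.58
```

— a limit cycle with one amplitude level, near-zero 0–1 chaos statistic,
and a return time of ≈ 18.6 time units.

The same operations are available from the shell:

```
fractumor equilibria --config run.yaml
fractumor simulate   --config run.yaml --scheme abc_pi --alpha 0.9
fractumor classify   --config run.yaml
fractumor sweep      --config run.yaml --param b12 --values 0.7,0.8,0.9,1.0
fractumor validate
fractumor plot       --config run.yaml
```

where `run.yaml` holds the eight parameters (aliases `a31`, `d3`,
`beta12`… accepted), the initial state, and optional scheme/grid choices
(defaults: `h = 0.001`, `t_final = 500`, `caputo_abm`, α = 1).

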