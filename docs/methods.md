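# Methods

## The model

`fractumor` simulates a single-compartment competition model of tumor
growth with three dimensionless state variables: tumor cells `T`, healthy
host cells `H`, and effector immune cells `E`:

    dT/dt = T(1 - T) - b12·T·H - b13·T·E
    dH/dt = k2·H(1 - H) - b21·T·H
    dE/dt = k3·T·E/(T + s3) - b31·T·E - c3·E

Tumor and host cells grow logistically and suppress each other through
mass-action competition (`b12`, `b21`); effector cells kill tumor cells
(`b13`), are recruited at a saturating (Michaelis–Menten) rate driven by
tumor load (`k3`, half-saturation `s3`), are inactivated by tumor cells
(`b31`), and die at rate `c3`.  The dimensionless form arises from scaling
each population by its carrying capacity (or the effector half-saturation
scale) and time by the tumor growth rate; `nondimensionalize` performs
this reduction, with the `b21` reduction taken as `b21' · s1 / k1'` by
symmetry with the `T·H` coupling seen from the tumor equation (the
dimensional source for this one constant is ambiguous in the literature
this model descends from; the chosen form is the only dimensionally
consistent one).

The headline parameter set, used throughout the bundled experiments, is

    b12 = 1, b13 = 2.5, k2 = 0.6, b21 = 1.5, k3 = 4.5, s3 = 1,
    b31 = 0.2, c3 = 0.5,

under which the classical (integer-order) system is chaotic.  Config
files accept the aliases `beta12…beta31`, `a31` (for `b31`) and `d3`
(for `c3`) that appear in the simulation literature for this model.

## Equilibria

Six structural families are enumerated: total extinction `P1 = (0,0,0)`,
the tumor-free state `P2 = (0,1,0)`, the tumor-only state `P3 = (1,0,0)`,
a tumor–effector state `P4 = (T*, 0, (1−T*)/b13)`, a tumor–host state
`P5` with `E = 0`, and an interior state `P6`.  The tumor coordinate `T*`
of `P4`/`P6` solves the characteristic quadratic obtained by clearing the
denominator of the effector nullcline `k3·T/(T+s3) = b31·T + c3`:

    b31·T² + (c3 + s3·b31 − k3)·T + s3·c3 = 0.

Note the leading coefficient is `b31`, not `b13`: only with `b31` do the
resulting points actually zero the vector field, which the test suite
verifies to 1e−10 against the right-hand side for 100 random parameter
draws and against an independent bisection of the nullcline itself.  The
admissible root is the smaller positive one (the larger exceeds the
tumor carrying capacity at typical parameters: 18.87 vs 0.1325 at the
headline set).  Families are flagged existing only when their printed
inequality conditions hold, coordinates are nonnegative, and the residual
check passes; degenerate algebra (complex roots, `b12·b21 = k2`
denominators) is reported in a diagnostic field rather than skipped.
Stability is classified from the Jacobian eigenvalues with a 1e−9
tolerance on real parts; borderline points are reported `nonhyperbolic`,
never guessed.

## Fractional operators and schemes

Three fractional derivatives of order `alpha ∈ (0, 1]` are supported,
differing in their memory kernel, plus fractal-fractional variants with
dimension `tau ∈ (0, 1]`:

| scheme        | kernel               | method                                     |
|---------------|----------------------|--------------------------------------------|
| `caputo_abm`  | power law            | Adams–Bashforth–Moulton predictor–corrector |
| `cfc_two_step`| exponential          | two-step Adams recursion                    |
| `abc_pi`      | Mittag-Leffler       | implicit product-integration rule           |
| `ff_power`    | power law + fractal  | two-point-Lagrange product integration      |
| `ff_exp`      | exponential + fractal| two-step Adams recursion                    |
| `ff_ml`       | ML kernel + fractal  | Lagrange product integration + local term   |
| `classical_rk`| —                    | adaptive DOP853 reference (rtol 1e−12)      |

All schemes advance the three components synchronously from the previous
time level (no Gauss–Seidel staggering), evaluate the full convolution
history at every step (vectorized dot products, O(N²) total cost), and
raise an error naming the step index if the state leaves the finite
domain.

Numerical policies, fixed once and recorded in each run's metadata JSON:

- **ABM corrector**: applied once per step (standard predictor–corrector
  usage, not iterated to convergence).
- **Two-step bootstrap** (`cfc_two_step`, `ff_exp`): the unavailable
  first history level is generated by one explicit Euler step; its O(h²)
  local error sits below scheme order.
- **Implicit solve** (`abc_pi`): the `q0` weight multiplies the unknown
  level, so each step is solved by fixed-point iteration seeded with the
  explicit part (tolerance 1e−12, max 50 iterations, error with step
  index and residual on failure).  A single-correction
  `mode="predictor"` variant is available.
- **Exponential-kernel normalization**: the integral inverse of the
  exponential-kernel derivative is taken in the Losada–Nieto form
  `(1−alpha)·phi + alpha·∫phi`, whose `alpha → 1` limit is the ordinary
  integral; the two-step recursion then reduces exactly to classical
  Adams–Bashforth 2 at `alpha = 1`.  The alternative normalization that
  keeps explicit `(2−alpha)/2` factors — which rescales the classical
  limit by 1/2 and breaks agreement with the classical reference — is
  available as `normalization="printed"` for comparison with the
  originally published recursion.
- **Fractal factor**: the fractal-fractional operators contribute a
  `t^(tau−1)` factor on the vector field inside the integral
  reformulation (for `ff_exp` the full factor is `tau·t^(tau−1)`, for the
  Lagrange schemes the `tau` sits in the prefactor).  At `t = 0` with
  `tau < 1` this factor is singular; the first node is regularized to
  `1e−12·h`.  For `tau` near 1 (the regime exercised here) the
  regularized factor is O(1); very small `tau` values would magnify the
  first-node weight and are not recommended with this policy.
- **`ff_ml` reading**: the published recursion for the
  Mittag-Leffler-kernel fractal-fractional scheme carries three internal
  inconsistencies with the operator it discretizes (node exponent
  `alpha−1` instead of `tau−1`, local term normalized by `Γ(alpha)`
  instead of `B(alpha)`, missing `alpha` in the convolution prefactor).
  The default implementation follows the operator definition (the
  Atangana–Baleanu integral applied to `tau·t^(tau−1)·f`); pass
  `printed=True` to reproduce the published variant verbatim.
- **Leading-interval convention**: the two-point-Lagrange schemes need a
  node left of `t_0`; the convention `K_{−1} = K_0` degrades the first
  interval to a rectangle (an Euler-like first step), again below scheme
  order.

### Validation oracles

- Power-law relaxation `D^α y = −y` has exact solution `E_α(−t^α)`; ABM
  errors at `t = 1` decrease monotonically over `h ∈ {0.04, …, 0.005}`.
- The Mittag-Leffler-kernel operator's relaxation solution is **not**
  `E_α(−t^α)`: by Laplace transform it is
  `y(t) = y0·B/(B+1−α)·E_α(−α t^α/(B+1−α))` (implemented as
  `abc_relaxation_exact`), including a finite jump at `t = 0+`.  The
  implicit product-integration solver converges monotonically to this
  solution; measured against `E_α(−t^α)` instead it plateaus at the
  operator difference (~9e−3 at `α = 0.8`), which is a property of the
  operator, not a solver defect.
- At `(alpha, tau) = (1, 1)` every scheme tracks the adaptive classical
  reference within ~1e−7 max-norm on `t ∈ [0, 20]` at `h = 0.001`, and
  the two-step schemes show empirical order 2 under step halving.

## The Mittag-Leffler function

`mittag_leffler(alpha, z)` targets 1e−10 relative accuracy for
`z ∈ [−50, 5]`, `alpha ∈ (0, 1]`.  Taylor summation is used for `z ≥ 0`
(positive terms, no cancellation) and `exp` at `alpha = 1`.  For negative
arguments the Taylor series cancels catastrophically in double precision
(partial sums reach `exp(c·|z|^(1/alpha))` while the result is
`O(1/|z|)`), so the evaluator integrates the complete-monotonicity
representation

    E_α(−x) = sin(απ)/(απ) · ∫₀^∞ e^{−(xu)^{1/α}} / (u² + 2u·cos(απ) + 1) du

with adaptive quadrature, placing break points across the `u ≈ 1` peak
whose width shrinks like `cos(απ/2)` as `alpha → 1`.  Validated against a
50-digit arbitrary-precision series (worst relative error 4.5e−12 over
`alpha ∈ [0.05, 0.999]`, `x ∈ [0.01, 50]`), against the closed form
`E_{1/2}(z) = e^{z²}erfc(−z)`, and against direct 200-term summation for
moderate arguments.  The function is an oracle only: no integrator
evaluates it inside a time loop.

## Attractor classification

The dynamical regimes reported for this model — chaotic attractor, limit
cycle, periodic orbit — are traditionally asserted from visual inspection
of phase portraits.  `classify_attractor` operationalizes them:

1. discard a transient (default 50% of the run);
2. `fixed_point` if the analyzed component (host cells `H` by default,
   whose oscillations separate the regimes most cleanly) spans less than
   `tol_fixed_point = 1e−4`;
3. `period_k` if the strict-local-maximum amplitudes fall into
   `k ≤ max_period` single-linkage clusters (merge tolerance 1e−3 of the
   signal range) with every level visited at least twice, **or** if the
   stride-k amplitude differences have constant sign and contract
   geometrically — the signature of a trajectory still converging toward
   a period-k orbit, which a fixed clustering tolerance misses (fractional
   trajectories approach their attractors slowly, and chaotic amplitude
   sequences fail the constant-sign test);
4. else `chaotic` if the 0–1 test statistic `K ≥ 0.7`, `unresolved`
   otherwise (`K ≤ 0.2` is consistent with regular dynamics; the gap is
   deliberately inconclusive).

The 0–1 statistic (correlation method) drives translation variables
`(p_c, q_c)` with the series at ~100 seeded random frequencies
`c ∈ (π/5, 4π/5)` and takes the median correlation between time and the
oscillation-corrected mean-square displacement, clipped to `[0, 1]`.  It
is validated on the standard benchmarks (fully chaotic logistic map
`K ≈ 1`, sampled sine `K ≈ 0`, constant `K ≈ 0`) and is invariant to
amplitude scaling.

**Honest limits, stated plainly.**  The 0–1 test assumes a long,
coarsely sampled series: on this model (mean cycle time ≈ 43 time units
at headline parameters) it saturates only with ≳ 50 cycles sampled at
~10 points per cycle — e.g. `K = 0.98` on a 3000-unit classical chaotic
window — whereas oversampled or few-cycle windows push `K` toward 0.
A 300-unit run therefore cannot be certified chaotic by `K`; aperiodic
short windows come out `unresolved`.  Separately, the fractional order
itself damps the chaos: at `alpha = 0.98` the power-law and
Mittag-Leffler-kernel trajectories of the headline parameter set collapse
onto a period-1 limit cycle (post-transient peak-amplitude spread below
1e−3 out to `t = 1000`), while the classical limit `alpha = 1` and the
exponential-kernel scheme at 0.98 retain irregular amplitude structure.
Passing classifications on short synthetic benchmarks demonstrate the
machinery, not asymptotic statements about the flow.

## Experiment scales

The bundled experiments run the headline protocol at reduced scale
chosen for desk reproducibility: `h = 0.005`, `t_final = 300` for regime
classification (the original protocol is `h = 0.001`, `t_final = 500`),
`t ∈ [0, 20]` at `h = 0.001` for the classical-limit comparison, and the
regime-stability check refines `h = 0.005 → 0.0025` with the
exponential-kernel scheme, whose O(N) cost suits routine re-runs.  The
sensitivity sweeps over `b12` and `c3` use ICs `(0.3, 0.7, 0.7)` at
`alpha = 0.98`.

## Known limitations

- O(N²) history sums: a 500,000-step run (the original protocol) takes
  minutes per scheme; no FFT fast path is currently wired in.
- The fractal-factor regularization is tuned for `tau` near 1.
- The 0–1 statistic limitations above; Lyapunov spectra for the
  memory-carrying (non-Markovian) schemes are out of scope.
- Variable-order `alpha(t)`, nonuniform grids, and delay terms are not
  supported.
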