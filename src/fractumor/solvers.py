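"""Fractional and fractal-fractional time-stepping schemes.

Six schemes, each exposed generically for any autonomous vector field
``f(t, y) -> ndarray`` and bound to the tumor-immune model through
:func:`simulate`:

``caputo_abm``
    Adams-Bashforth-Moulton predictor-corrector for the power-law
    (Liouville-Caputo) derivative, with product-integration weights.
``cfc_two_step``
    Two-step Adams-type recursion for the exponential-kernel
    (Caputo-Fabrizio-Caputo) derivative.
``abc_pi``
    Implicit product-integration rule for the Mittag-Leffler-kernel
    (Atangana-Baleanu-Caputo) derivative, solved by fixed-point iteration.
``ff_power`` / ``ff_exp`` / ``ff_ml``
    Fractal-fractional counterparts: the fractal dimension ``tau`` enters
    integral reformulations through an extra ``t**(tau-1)`` factor on the
    vector field.
``classical_rk``
    High-accuracy adaptive classical integration, the alpha = tau = 1
    validation reference.

All memory (convolution) sums run over the full past at every step; the
history dot products are vectorized, so a run of N steps costs O(N^2)
flops but only O(N) Python-level iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .special import normalization_B, normalization_M

__all__ = [
    "SolverGrid",
    "SolverSpec",
    "Trajectory",
    "ConvolutionWeights",
    "BlowUpError",
    "FixedPointError",
    "SCHEMES",
    "abm_weights",
    "abc_pi_weights",
    "solve_caputo_abm",
    "solve_cfc_two_step",
    "solve_abc_pi",
    "solve_ff_power",
    "solve_ff_exponential",
    "solve_ff_mittag_leffler",
    "solve_classical_reference",
    "solve",
    "simulate",
]

VectorField = Callable[[float, np.ndarray], np.ndarray]

#: Regularization of the fractal factor t**(tau-1) at t = 0 (tau < 1): the
#: first node is shifted to eps_reg * h so the factor stays finite.
_EPS_REG = 1e-12

SCHEMES = (
    "caputo_abm",
    "cfc_two_step",
    "abc_pi",
    "ff_power",
    "ff_exp",
    "ff_ml",
    "classical_rk",
)


class BlowUpError(RuntimeError):
    """Trajectory left the finite domain; carries the offending step index."""

    def __init__(self, step: int, scheme: str):
        self.step = step
        super().__init__(f"{scheme}: nonfinite state at step {step}")


class FixedPointError(RuntimeError):
    """Implicit solve failed to converge; carries step index and residual."""

    def __init__(self, step: int, residual: float):
        self.step = step
        self.residual = residual
        super().__init__(
            f"abc_pi: fixed-point iteration did not converge at step {step} "
            f"(residual {residual:.3e})"
        )


@dataclass(frozen=True)
class SolverGrid:
    """Uniform time grid from ``t0`` to ``t_final`` with step ``h``."""

    t_final: float
    h: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"step size h must be positive, got {self.h}")
        if self.t_final <= self.t0:
            raise ValueError("t_final must exceed t0")
        n = self.n_steps
        if abs(self.t0 + n * self.h - self.t_final) > 1e-12 * max(1.0, abs(self.t_final)):
            raise ValueError(
                f"grid does not close: t0 + n*h = {self.t0 + n * self.h} != {self.t_final}"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.t_final - self.t0) / self.h))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class SolverSpec:
    """Scheme choice plus fractional order ``alpha`` and fractal dimension
    ``tau`` (``tau`` is meaningful only for the ``ff_*`` schemes)."""

    scheme: str = "caputo_abm"
    alpha: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"fractional order alpha must lie in (0, 1], got {self.alpha}")
        if not 0 < self.tau <= 1:
            raise ValueError(f"fractal dimension tau must lie in (0, 1], got {self.tau}")
        if self.scheme == "classical_rk" and (self.alpha != 1 or self.tau != 1):
            raise ValueError("classical_rk is defined only for alpha = tau = 1")
        if not self.scheme.startswith("ff_") and self.tau != 1:
            raise ValueError(f"scheme {self.scheme!r} does not use tau; set tau = 1")


@dataclass
class Trajectory:
    """Time-indexed solution with provenance metadata."""

    times: np.ndarray
    states: np.ndarray
    scheme: str
    alpha: float = 1.0
    tau: float = 1.0
    params: dict | None = None
    initial: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def H(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 2]

    def component(self, name: str) -> np.ndarray:
        idx = {"T": 0, "H": 1, "E": 2}[name]
        return self.states[:, idx]

    def to_frame(self) -> pd.DataFrame:
        cols = ["T", "H", "E"] if self.states.shape[1] == 3 else [
            f"y{i}" for i in range(self.states.shape[1])
        ]
        frame = pd.DataFrame(self.states, columns=cols)
        frame.insert(0, "t", self.times)
        return frame

    def write_csv(self, path) -> None:
        # str(float) is shortest-roundtrip in Python 3, so the CSV re-reads
        # bit-for-bit.
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, **meta) -> "Trajectory":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=frame["t"].to_numpy(),
            states=frame.drop(columns="t").to_numpy(),
            scheme=meta.pop("scheme", "unknown"),
            **meta,
        )


@dataclass(frozen=True)
class ConvolutionWeights:
    """Product-integration weight sequence with its generating scalars."""

    kind: str
    values: np.ndarray
    alpha: float
    h: float


def _validate_y0(y0) -> np.ndarray:
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError(f"initial state must be finite, got {y}")
    return y


def _check_finite(y: np.ndarray, step: int, scheme: str) -> None:
    if not np.all(np.isfinite(y)):
        raise BlowUpError(step, scheme)


def _fractal_nodes(times: np.ndarray, h: float) -> np.ndarray:
    """Node times used for the t**(tau-1) factor, with the t=0 node
    regularized to eps_reg * h."""
    nodes = times.copy()
    if nodes[0] == 0.0:
        nodes[0] = _EPS_REG * h
    return nodes


# --------------------------------------------------------------------------
# Adams-Bashforth-Moulton predictor-corrector (power-law kernel)
# --------------------------------------------------------------------------

def abm_weights(alpha: float, h: float, k: int) -> tuple[ConvolutionWeights, ConvolutionWeights]:
    """Predictor (theta) and corrector (gamma) weights for the step to
    ``t_{k+1}``.

    theta_{zeta} = (h^alpha/alpha) * ((k+1-zeta)^alpha - (k-zeta)^alpha),
    zeta = 0..k; gamma_{zeta} follows the three-case rule (end weight
    h^alpha/(alpha(alpha+1)) at zeta = k+1).  Both reduce to classical
    rectangle/trapezoid quadrature at alpha = 1.
    """
    zeta = np.arange(k + 1, dtype=float)
    theta = (h**alpha / alpha) * ((k + 1 - zeta) ** alpha - (k - zeta) ** alpha)

    gamma = np.empty(k + 2)
    pref = h**alpha / (alpha * (alpha + 1))
    gamma[0] = pref * (k ** (alpha + 1) - (k - alpha) * (k + 1) ** alpha)
    if k >= 1:
        z = np.arange(1, k + 1, dtype=float)
        gamma[1 : k + 1] = pref * (
            (k - z + 2) ** (alpha + 1) + (k - z) ** (alpha + 1) - 2 * (k - z + 1) ** (alpha + 1)
        )
    gamma[k + 1] = pref
    return (
        ConvolutionWeights("abm_theta", theta, alpha, h),
        ConvolutionWeights("abm_gamma", gamma, alpha, h),
    )


def solve_caputo_abm(f: VectorField, y0, grid: SolverGrid, alpha: float) -> Trajectory:
    """Fractional Adams-Bashforth-Moulton predictor-corrector.

    Explicit rectangle-rule predictor followed by one trapezoid-type
    corrector application per step; the full convolution history enters
    every step.  All components advance synchronously from the previous
    time level.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    y0 = _validate_y0(y0)
    times = grid.times
    n, h, dim = grid.n_steps, grid.h, y0.size

    m = np.arange(n + 1, dtype=float)
    b_core = (m + 1) ** alpha - m**alpha                  # predictor cores
    a_core = (m + 2) ** (alpha + 1) + m ** (alpha + 1) - 2 * (m + 1) ** (alpha + 1)
    k_arr = np.arange(n, dtype=float)
    c0 = k_arr ** (alpha + 1) - (k_arr - alpha) * (k_arr + 1) ** alpha

    pred_pref = h**alpha / math.gamma(alpha + 1)
    corr_pref = h**alpha / math.gamma(alpha + 2)

    y = np.empty((n + 1, dim))
    F = np.empty((n + 1, dim))
    y[0] = y0
    F[0] = f(times[0], y0)

    for k in range(n):
        pred = y0 + pred_pref * (b_core[: k + 1][::-1] @ F[: k + 1])
        _check_finite(pred, k + 1, "caputo_abm")
        f_pred = f(times[k + 1], pred)
        hist = a_core[:k][::-1] @ F[1 : k + 1] if k >= 1 else 0.0
        y[k + 1] = y0 + corr_pref * (hist + c0[k] * F[0] + f_pred)
        _check_finite(y[k + 1], k + 1, "caputo_abm")
        F[k + 1] = f(times[k + 1], y[k + 1])

    return Trajectory(times, y, "caputo_abm", alpha=alpha)


# --------------------------------------------------------------------------
# Caputo-Fabrizio-Caputo two-step Adams scheme (exponential kernel)
# --------------------------------------------------------------------------

def _cf_coefficients(alpha: float, normalization: str) -> tuple[float, float]:
    """Local and integral coefficients of the exponential-kernel integral.

    ``consistent``: the Losada-Nieto form (1-alpha)*phi + alpha*Int(phi),
    whose alpha -> 1 limit is the ordinary integral.  ``printed`` keeps the
    (2-alpha)/2 normalization factors of the derivation, which rescale the
    classical limit by 1/2.
    """
    if normalization == "consistent":
        return 1.0 - alpha, alpha
    if normalization == "printed":
        M = normalization_M(alpha)
        return (1.0 - alpha) / M, alpha / M
    raise ValueError(f"unknown normalization {normalization!r}")


def solve_cfc_two_step(
    f: VectorField, y0, grid: SolverGrid, alpha: float, normalization: str = "consistent"
) -> Trajectory:
    """Two-step Adams-type scheme for the exponential-kernel derivative:

        y_{n+1} = y_n + cL*(f_n - f_{n-1}) + cI*(3h/2 f_n - h/2 f_{n-1})

    with local/integral coefficients (cL, cI) from the exponential-kernel
    integral.  At alpha = 1 the local term vanishes and the recursion is
    classical Adams-Bashforth 2.  The first step is bootstrapped with one
    explicit Euler step (O(h^2) local error, below scheme order).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    y0 = _validate_y0(y0)
    if grid.n_steps < 2:
        raise ValueError("cfc_two_step needs at least two steps")
    cL, cI = _cf_coefficients(alpha, normalization)
    times = grid.times
    n, h = grid.n_steps, grid.h

    y = np.empty((n + 1, y0.size))
    y[0] = y0
    f_prev = f(times[0], y0)
    y[1] = y0 + h * f_prev
    _check_finite(y[1], 1, "cfc_two_step")
    for k in range(1, n):
        f_cur = f(times[k], y[k])
        y[k + 1] = y[k] + cL * (f_cur - f_prev) + cI * h * (1.5 * f_cur - 0.5 * f_prev)
        _check_finite(y[k + 1], k + 1, "cfc_two_step")
        f_prev = f_cur

    return Trajectory(times, y, "cfc_two_step", alpha=alpha)


# --------------------------------------------------------------------------
# Atangana-Baleanu-Caputo product-integration rule (Mittag-Leffler kernel)
# --------------------------------------------------------------------------

def abc_pi_weights(alpha: float, h: float, n: int) -> ConvolutionWeights:
    """Weights (p_n, q_0..q_{n-1}) of the implicit product-integration rule.

    Returned values are ``[p_n, q_0, ..., q_{n-1}]``; ``q_0`` includes the
    local-term contribution ``(1-alpha)/(alpha*h^alpha)``.  At alpha = 1
    they reduce to the trapezoid rule (p_n = q_0 = 1/2, q_j = 1).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    g2 = math.gamma(alpha + 2)
    p_n = ((n - 1) ** (alpha + 1) - n**alpha * (n - alpha - 1)) / g2
    q = np.empty(n)
    q[0] = 1.0 / g2 + (1.0 - alpha) / (alpha * h**alpha)
    if n > 1:
        j = np.arange(1, n, dtype=float)
        q[1:] = ((j - 1) ** (alpha + 1) - 2 * j ** (alpha + 1) + (j + 1) ** (alpha + 1)) / g2
    return ConvolutionWeights("abc_pq", np.concatenate(([p_n], q)), alpha, h)


def solve_abc_pi(
    f: VectorField,
    y0,
    grid: SolverGrid,
    alpha: float,
    mode: str = "fixed_point",
    tol: float = 1e-12,
    max_iter: int = 50,
) -> Trajectory:
    """Implicit product-integration scheme for the Mittag-Leffler-kernel
    derivative:

        y_n = y_0 + (alpha h^alpha / B(alpha)) * (p_n f_0 + sum_j q_{n-j} f_j)

    The j = n term carries q_0 and makes each step implicit; it is solved by
    functional iteration seeded with the explicit part (``mode='fixed_point'``)
    or by a single predictor-corrector sweep (``mode='predictor'``).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if mode not in ("fixed_point", "predictor"):
        raise ValueError(f"unknown mode {mode!r}")
    y0 = _validate_y0(y0)
    times = grid.times
    n, h = grid.n_steps, grid.h
    g2 = math.gamma(alpha + 2)
    pref = alpha * h**alpha / normalization_B(alpha)

    idx = np.arange(1, n + 1, dtype=float)
    p = ((idx - 1) ** (alpha + 1) - idx**alpha * (idx - alpha - 1)) / g2  # p_1..p_n
    q = np.empty(n)  # q_0..q_{n-1}
    q[0] = 1.0 / g2 + (1.0 - alpha) / (alpha * h**alpha)
    if n > 1:
        j = np.arange(1, n, dtype=float)
        q[1:] = ((j - 1) ** (alpha + 1) - 2 * j ** (alpha + 1) + (j + 1) ** (alpha + 1)) / g2

    y = np.empty((n + 1, y0.size))
    F = np.empty((n + 1, y0.size))
    y[0] = y0
    F[0] = f(times[0], y0)

    for step in range(1, n + 1):
        hist = q[1:step][::-1] @ F[1:step] if step > 1 else 0.0
        base = y0 + pref * (p[step - 1] * F[0] + hist)
        _check_finite(base, step, "abc_pi")
        w0 = pref * q[0]
        if mode == "predictor":
            pred = base + w0 * F[step - 1]
            y[step] = base + w0 * f(times[step], pred)
        else:
            cur = base
            for _ in range(max_iter):
                nxt = base + w0 * f(times[step], cur)
                _check_finite(nxt, step, "abc_pi")
                res = float(np.max(np.abs(nxt - cur)))
                cur = nxt
                if res <= tol * max(1.0, float(np.max(np.abs(cur)))):
                    break
            else:
                raise FixedPointError(step, res)
            y[step] = cur
        _check_finite(y[step], step, "abc_pi")
        F[step] = f(times[step], y[step])

    return Trajectory(times, y, "abc_pi", alpha=alpha)


# --------------------------------------------------------------------------
# Fractal-fractional schemes
# --------------------------------------------------------------------------

def _lagrange_cores(alpha: float, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-point-Lagrange product-integration cores A_m, B_m (m = n - zeta).

    At alpha = 1 they collapse to A = 3, B = 1: the classical two-step
    Adams increment 3/2 K_zeta - 1/2 K_{zeta-1} after the Gamma(alpha+2)
    prefactor.
    """
    m = np.arange(n_steps + 1, dtype=float)
    A = (m + 1) ** alpha * (m + alpha + 2) - m**alpha * (m + 2 * alpha + 2)
    B = (m + 1) ** (alpha + 1) - m**alpha * (m + alpha + 1)
    return A, B


def solve_ff_power(
    f: VectorField, y0, grid: SolverGrid, alpha: float, tau: float
) -> Trajectory:
    """Fractal-fractional power-law scheme (two-point Lagrange product
    integration applied to ``K(t, y) = t**(tau-1) * f(t, y)``):

        y_{n+1} = y_0 + tau h^alpha/Gamma(alpha+2)
                  * sum_zeta [K_zeta A_{n-zeta} - K_{zeta-1} B_{n-zeta}]

    with the convention K_{-1} = K_0 (the leading interval degrades to a
    rectangle, keeping the first step explicit Euler-like).  The fractal
    factor at t = 0 is regularized per module policy.
    """
    if not 0 < alpha <= 1 or not 0 < tau <= 1:
        raise ValueError(f"alpha and tau must lie in (0, 1], got {alpha}, {tau}")
    y0 = _validate_y0(y0)
    times = grid.times
    n, h = grid.n_steps, grid.h
    A, B = _lagrange_cores(alpha, n)
    pref = tau * h**alpha / math.gamma(alpha + 2)
    t_frac = _fractal_nodes(times, h) ** (tau - 1.0)

    y = np.empty((n + 1, y0.size))
    K = np.empty((n + 1, y0.size))
    y[0] = y0
    K[0] = t_frac[0] * f(times[0], y0)

    for k in range(n):
        s_cur = A[: k + 1][::-1] @ K[: k + 1]
        s_prev = B[k] * K[0] + (B[:k][::-1] @ K[:k] if k >= 1 else 0.0)
        y[k + 1] = y0 + pref * (s_cur - s_prev)
        _check_finite(y[k + 1], k + 1, "ff_power")
        K[k + 1] = t_frac[k + 1] * f(times[k + 1], y[k + 1])

    return Trajectory(times, y, "ff_power", alpha=alpha, tau=tau)


def solve_ff_exponential(
    f: VectorField,
    y0,
    grid: SolverGrid,
    alpha: float,
    tau: float,
    normalization: str = "consistent",
) -> Trajectory:
    """Fractal-fractional exponential-decay scheme: the two-step
    exponential-kernel recursion applied to ``F(t, y) = tau * t**(tau-1)
    * f(t, y)``.  At tau = 1 it coincides with :func:`solve_cfc_two_step`;
    at alpha = tau = 1 it is classical Adams-Bashforth 2.  Bootstrap is one
    explicit Euler step on F.
    """
    if not 0 < alpha <= 1 or not 0 < tau <= 1:
        raise ValueError(f"alpha and tau must lie in (0, 1], got {alpha}, {tau}")
    y0 = _validate_y0(y0)
    if grid.n_steps < 2:
        raise ValueError("ff_exp needs at least two steps")
    if normalization == "consistent":
        cL, cI = 1.0 - alpha, alpha
    elif normalization == "printed":
        # Eq.-level coefficients tau/M and tau*alpha/M with the bare
        # t**(tau-1) factor; tau is then applied below through F, so divide
        # it back out of the local coefficient pair.
        M = normalization_M(alpha)
        cL, cI = 1.0 / M, alpha / M
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    times = grid.times
    n, h = grid.n_steps, grid.h
    t_frac = tau * _fractal_nodes(times, h) ** (tau - 1.0)

    y = np.empty((n + 1, y0.size))
    y[0] = y0
    F_prev = t_frac[0] * f(times[0], y0)
    y[1] = y0 + h * F_prev
    _check_finite(y[1], 1, "ff_exp")
    for k in range(1, n):
        F_cur = t_frac[k] * f(times[k], y[k])
        y[k + 1] = y[k] + cL * (F_cur - F_prev) + cI * h * (1.5 * F_cur - 0.5 * F_prev)
        _check_finite(y[k + 1], k + 1, "ff_exp")
        F_prev = F_cur

    return Trajectory(times, y, "ff_exp", alpha=alpha, tau=tau)


def solve_ff_mittag_leffler(
    f: VectorField,
    y0,
    grid: SolverGrid,
    alpha: float,
    tau: float,
    printed: bool = False,
) -> Trajectory:
    """Fractal-fractional Mittag-Leffler-kernel scheme: product-integration
    convolution plus the nonlocal operator's local term,

        y_{n+1} = y_0 + tau t_n^{tau-1} (1-alpha)/B(alpha) * f(t_n, y_n)
                  + tau alpha h^alpha/(Gamma(alpha+2) B(alpha))
                    * sum_zeta [K_zeta A_{n-zeta} - K_{zeta-1} B_{n-zeta}]

    with ``K(t, y) = t**(tau-1) f(t, y)`` and K_{-1} = K_0 as in
    :func:`solve_ff_power`.  ``printed=True`` reproduces the originally
    published variant (exponent alpha-1 on the node factors, local term
    normalized by Gamma(alpha), no alpha in the convolution prefactor)
    instead of the operator-consistent reading.
    """
    if not 0 < alpha <= 1 or not 0 < tau <= 1:
        raise ValueError(f"alpha and tau must lie in (0, 1], got {alpha}, {tau}")
    y0 = _validate_y0(y0)
    times = grid.times
    n, h = grid.n_steps, grid.h
    A, B = _lagrange_cores(alpha, n)
    Bnorm = normalization_B(alpha)
    nodes = _fractal_nodes(times, h)
    if printed:
        t_frac = nodes ** (alpha - 1.0)
        local_pref = tau * (1.0 - alpha) / math.gamma(alpha)
        conv_pref = tau * h**alpha / (math.gamma(alpha + 2) * Bnorm)
    else:
        t_frac = nodes ** (tau - 1.0)
        local_pref = tau * (1.0 - alpha) / Bnorm
        conv_pref = tau * alpha * h**alpha / (math.gamma(alpha + 2) * Bnorm)

    y = np.empty((n + 1, y0.size))
    K = np.empty((n + 1, y0.size))
    y[0] = y0
    F0 = f(times[0], y0)
    K[0] = t_frac[0] * F0
    F_cur = F0

    for k in range(n):
        s_cur = A[: k + 1][::-1] @ K[: k + 1]
        s_prev = B[k] * K[0] + (B[:k][::-1] @ K[:k] if k >= 1 else 0.0)
        y[k + 1] = y0 + local_pref * t_frac[k] * F_cur + conv_pref * (s_cur - s_prev)
        _check_finite(y[k + 1], k + 1, "ff_ml")
        F_cur = f(times[k + 1], y[k + 1])
        K[k + 1] = t_frac[k + 1] * F_cur

    return Trajectory(times, y, "ff_ml", alpha=alpha, tau=tau)


# --------------------------------------------------------------------------
# Classical reference and dispatch
# --------------------------------------------------------------------------

def solve_classical_reference(f: VectorField, y0, grid: SolverGrid) -> Trajectory:
    """High-accuracy adaptive classical integration of dy/dt = f(t, y),
    sampled on the grid (relative tolerance 1e-12)."""
    y0 = _validate_y0(y0)
    sol = solve_ivp(
        f,
        (grid.t0, grid.t_final),
        y0,
        method="DOP853",
        t_eval=grid.times,
        rtol=1e-12,
        atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"classical reference integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T, "classical_rk")


_DISPATCH = {
    "caputo_abm": lambda f, y0, g, s: solve_caputo_abm(f, y0, g, s.alpha),
    "cfc_two_step": lambda f, y0, g, s: solve_cfc_two_step(f, y0, g, s.alpha),
    "abc_pi": lambda f, y0, g, s: solve_abc_pi(f, y0, g, s.alpha),
    "ff_power": lambda f, y0, g, s: solve_ff_power(f, y0, g, s.alpha, s.tau),
    "ff_exp": lambda f, y0, g, s: solve_ff_exponential(f, y0, g, s.alpha, s.tau),
    "ff_ml": lambda f, y0, g, s: solve_ff_mittag_leffler(f, y0, g, s.alpha, s.tau),
    "classical_rk": lambda f, y0, g, s: solve_classical_reference(f, y0, g),
}


def solve(f: VectorField, y0, grid: SolverGrid, spec: SolverSpec) -> Trajectory:
    """Dispatch to the scheme named in ``spec``."""
    traj = _DISPATCH[spec.scheme](f, y0, grid, spec)
    traj.alpha, traj.tau = spec.alpha, spec.tau
    return traj


def simulate(params, initial: Sequence[float], grid: SolverGrid, spec: SolverSpec) -> Trajectory:
    """Integrate the tumor-immune model with the requested scheme, attaching
    parameter and initial-condition provenance to the trajectory."""
    from .model import rhs

    def f(t, y):
        return rhs(t, y, params)

    traj = solve(f, np.asarray(initial, dtype=float), grid, spec)
    traj.params = params.as_dict()
    traj.initial = np.asarray(initial, dtype=float)
    traj.meta.update({"h": grid.h, "t_final": grid.t_final, "t0": grid.t0})
    return traj
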