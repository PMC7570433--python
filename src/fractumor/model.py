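"""Three-species tumor-immune interaction model.

State ``(T, H, E)``: dimensionless densities of tumor cells, healthy host
cells, and effector immune cells in a single tumor-site compartment.  Tumor
and host cells grow logistically and compete; effector cells are recruited
at a Michaelis-Menten rate driven by tumor load, are inactivated by tumor
cells, and die naturally.  The dimensionless system is

    dT/dt = T(1 - T) - b12*T*H - b13*T*E
    dH/dt = k2*H(1 - H) - b21*T*H
    dE/dt = k3*T*E/(T + s3) - b31*T*E - c3*E

with eight positive rate constants.  This module provides the vector field,
its Jacobian, the reduction from dimensional rates, and the enumeration and
linear stability classification of the six equilibrium families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DimensionalParameters",
    "ModelParameters",
    "EquilibriumPoint",
    "HEADLINE_PARAMS",
    "rhs",
    "nondimensionalize",
    "jacobian",
    "tumor_quadratic_roots",
    "equilibria",
    "classify_stability",
]

_STABILITY_TOL = 1e-9
_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional rates: growth/stimulation (1/time), carrying capacities /
    half-saturation (cells), pairwise interaction rates (1/(cells*time)),
    and the effector natural death rate (1/time)."""

    k1p: float
    k2p: float
    k3p: float
    s1: float
    s2: float
    s3p: float
    b12p: float
    b13p: float
    b21p: float
    b31p: float
    c3p: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"DimensionalParameters.{name} must be positive, got {value}")
        if self.k1p <= self.k2p:
            raise ValueError(
                "tumor cells are assumed to proliferate faster than host cells (k1p > k2p); "
                f"got k1p={self.k1p}, k2p={self.k2p}"
            )


@dataclass(frozen=True)
class ModelParameters:
    """The eight dimensionless rate constants of the tumor-immune system."""

    b12: float
    b13: float
    k2: float
    b21: float
    k3: float
    s3: float
    b31: float
    c3: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"ModelParameters.{name} must be positive, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}


#: Parameter set used throughout the headline simulations (chaotic regime at
#: b12 = 1; the limit-cycle and periodic regimes override b12).
HEADLINE_PARAMS = ModelParameters(
    b12=1.0, b13=2.5, k2=0.6, b21=1.5, k3=4.5, s3=1.0, b31=0.2, c3=0.5
)


@dataclass
class EquilibriumPoint:
    """One of the six structural equilibrium families P1..P6."""

    family: str
    coords: np.ndarray
    exists: bool
    conditions: dict[str, bool] = field(default_factory=dict)
    diagnostic: str = ""
    stability: str | None = None
    eigenvalues: np.ndarray | None = None

    def to_jsonable(self) -> dict:
        eig = None
        if self.eigenvalues is not None:
            eig = [[float(e.real), float(e.imag)] for e in self.eigenvalues]
        return {
            "family": self.family,
            "coords": [None if not np.isfinite(c) else float(c) for c in self.coords],
            "exists": bool(self.exists),
            "conditions": {k: bool(v) for k, v in self.conditions.items()},
            "diagnostic": self.diagnostic,
            "stability": self.stability,
            "eigenvalues_re_im": eig,
        }


def _check_state(state: np.ndarray, s3: float) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"state must have three components (T, H, E), got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state must be finite, got {y}")
    if y[0] + s3 == 0:
        raise ValueError("T + s3 = 0: Michaelis-Menten recruitment term undefined")
    return y


def rhs(t: float, state, params: ModelParameters) -> np.ndarray:
    """Autonomous vector field of the dimensionless system (``t`` is ignored)."""
    T, H, E = _check_state(state, params.s3)
    p = params
    return np.array(
        [
            T * (1.0 - T) - p.b12 * T * H - p.b13 * T * E,
            p.k2 * H * (1.0 - H) - p.b21 * T * H,
            p.k3 * T * E / (T + p.s3) - p.b31 * T * E - p.c3 * E,
        ]
    )


def nondimensionalize(dp: DimensionalParameters) -> ModelParameters:
    """Reduce dimensional rates to the eight dimensionless constants.

    States are rescaled by their carrying capacities / half-saturation and
    time by the tumor growth rate ``k1p``; interaction rates pick up the
    partner population's scale.  The ``b21`` reduction mirrors the ``b12``
    one with the tumor scale ``s1`` (the T*H coupling seen by host cells).
    """
    return ModelParameters(
        b12=dp.b12p * dp.s2 / dp.k1p,
        b13=dp.b13p * dp.s3p / dp.k1p,
        k2=dp.k2p / dp.k1p,
        b21=dp.b21p * dp.s1 / dp.k1p,
        k3=dp.k3p / dp.k1p,
        s3=dp.s3p / dp.s1,
        b31=dp.b31p * dp.s1 / dp.k1p,
        c3=dp.c3p / dp.k1p,
    )


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Jacobian matrix of the vector field at ``state``.

    The (2,3) and (3,2) entries vanish identically: host cells do not couple
    to effector cells except through the tumor population.
    """
    T, H, E = _check_state(state, params.s3)
    p = params
    d = T + p.s3
    return np.array(
        [
            [-p.b12 * H - p.b13 * E - 2.0 * T + 1.0, -p.b12 * T, -p.b13 * T],
            [-p.b21 * H, p.k2 * (1.0 - H) - p.k2 * H - p.b21 * T, 0.0],
            [p.k3 * E / d - p.k3 * T * E / d**2 - p.b31 * E, 0.0, p.k3 * T / d - p.b31 * T - p.c3],
        ]
    )


def tumor_quadratic_roots(params: ModelParameters) -> tuple[complex, complex]:
    """Roots of the tumor-coordinate characteristic quadratic

        b31*x**2 + (c3 + s3*b31 - k3)*x + s3*c3 = 0

    obtained by clearing the denominator of the effector nullcline
    ``k3*T/(T + s3) - b31*T - c3 = 0``; its positive solutions are the tumor
    coordinates of the tumor-effector (P4) and interior (P6) equilibria.
    Returned in ascending real part; complex conjugate pairs are returned as
    such.  (The smaller positive root is the biologically admissible one;
    the larger typically exceeds the tumor carrying capacity.)
    """
    p = params
    roots = np.roots([p.b31, p.c3 + p.s3 * p.b31 - p.k3, p.s3 * p.c3])
    r1, r2 = sorted(roots, key=lambda r: (r.real, r.imag))
    return complex(r1), complex(r2)


def _acceptable_tumor_root(params: ModelParameters, upper: float) -> float | None:
    """Smallest strictly positive real quadratic root below ``upper``."""
    candidates = []
    for r in tumor_quadratic_roots(params):
        if abs(r.imag) < 1e-12 and r.real > 0 and r.real < upper:
            candidates.append(r.real)
    return min(candidates) if candidates else None


def _residual_ok(coords: np.ndarray, params: ModelParameters) -> bool:
    if not np.all(np.isfinite(coords)):
        return False
    return float(np.max(np.abs(rhs(0.0, coords, params)))) <= _RESIDUAL_TOL


def equilibria(params: ModelParameters) -> list[EquilibriumPoint]:
    """Enumerate the six equilibrium families and check their existence
    conditions.

    A family is flagged ``exists`` only when its printed existence
    conditions hold, its coordinates are nonnegative, and the vector field
    residual at the point is below 1e-10 in max-norm.  Degenerate algebra
    (complex tumor roots, vanishing denominators) is reported in the
    ``diagnostic`` field rather than silently skipped.
    """
    p = params
    nan3 = np.full(3, np.nan)
    points: list[EquilibriumPoint] = []

    # P1: extinction of all three populations.
    points.append(EquilibriumPoint("P1", np.zeros(3), True, {"always": True}))
    # P2: tumor-free state, host cells at carrying capacity.
    points.append(EquilibriumPoint("P2", np.array([0.0, 1.0, 0.0]), True, {"always": True}))
    # P3: tumor-only state at carrying capacity.
    points.append(EquilibriumPoint("P3", np.array([1.0, 0.0, 0.0]), True, {"always": True}))

    # P4: tumor-effector state, host cells extinct.
    t4 = _acceptable_tumor_root(p, upper=np.inf)
    cond4 = {"k3 > c3 + s3*b31": p.k3 > p.c3 + p.s3 * p.b31}
    if t4 is None:
        points.append(
            EquilibriumPoint("P4", nan3, False, {**cond4, "T* < 1": False},
                             diagnostic="no positive real tumor root")
        )
    else:
        coords4 = np.array([t4, 0.0, (1.0 - t4) / p.b13])
        cond4["T* < 1"] = t4 < 1.0
        exists4 = all(cond4.values()) and np.all(coords4 >= 0) and _residual_ok(coords4, p)
        points.append(EquilibriumPoint("P4", coords4, bool(exists4), cond4))

    # P5: tumor-host coexistence, effector cells extinct.
    denom = p.b12 * p.b21 - p.k2
    cond5 = {
        "b21 > k2": p.b21 > p.k2,
        "b12 > 1": p.b12 > 1.0,
        "b12*b21 > k2": denom > 0,
    }
    if denom == 0:
        points.append(
            EquilibriumPoint("P5", nan3, False, cond5,
                             diagnostic="degenerate denominator b12*b21 = k2")
        )
    else:
        coords5 = np.array(
            [p.k2 * (p.b12 - 1.0) / denom, (p.b21 - p.k2) / denom, 0.0]
        )
        exists5 = all(cond5.values()) and np.all(coords5 >= 0) and _residual_ok(coords5, p)
        points.append(EquilibriumPoint("P5", coords5, bool(exists5), cond5))

    # P6: interior state with all three populations present.
    cond6 = {
        "k3 > c3 + s3*b31": p.k3 > p.c3 + p.s3 * p.b31,
        "b12 < 1": p.b12 < 1.0,
        "b12*b21 > k2": p.b12 * p.b21 > p.k2,
        "b21 > k2": p.b21 > p.k2,
    }
    diag6 = "degenerate denominator b12*b21 = k2" if denom == 0 else ""
    t6 = _acceptable_tumor_root(p, upper=p.k2 / p.b21)
    if t6 is None:
        points.append(
            EquilibriumPoint("P6", nan3, False, {**cond6, "T* < k2/b21": False},
                             diagnostic=diag6 or "no positive real tumor root below k2/b21")
        )
    else:
        cond6["T* < k2/b21"] = True
        coords6 = np.array(
            [
                t6,
                (p.k2 - p.b21 * t6) / p.k2,
                (p.k2 * (1.0 - p.b12) + t6 * (p.b21 * p.b12 - p.k2)) / (p.k2 * p.b13),
            ]
        )
        exists6 = all(cond6.values()) and np.all(coords6 >= 0) and _residual_ok(coords6, p)
        points.append(EquilibriumPoint("P6", coords6, bool(exists6), cond6, diagnostic=diag6))

    return points


def classify_stability(eq: EquilibriumPoint, params: ModelParameters) -> EquilibriumPoint:
    """Fill in eigenvalues of the Jacobian at the point and a three-way
    stability verdict.

    ``stable`` iff all eigenvalue real parts are below -1e-9, ``unstable``
    iff any exceeds +1e-9, ``nonhyperbolic`` otherwise (ties are reported,
    never guessed).
    """
    if not eq.exists:
        raise ValueError(f"cannot classify stability of nonexistent equilibrium {eq.family}")
    eigvals = np.linalg.eigvals(jacobian(eq.coords, params))
    real_parts = eigvals.real
    if np.all(real_parts < -_STABILITY_TOL):
        label = "stable"
    elif np.any(real_parts > _STABILITY_TOL):
        label = "unstable"
    else:
        label = "nonhyperbolic"
    return replace(eq, stability=label, eigenvalues=eigvals)
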