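"""Attractor classification and parameter sweeps.

Operationalizes the qualitative regime labels used for this system --
fixed point, periodic orbit (period-k), limit cycle, chaotic attractor --
as a reproducible procedure: discard a transient, extract the peak
structure of one component (host cells by default, whose oscillations
separate the regimes most cleanly), cluster peak amplitudes by single
linkage, and fall back on the 0-1 test for chaos (Gottwald-Melbourne
correlation method) when the peak structure is aperiodic.

Caveat spelled out in the methods note: chaos is an asymptotic property.
The 0-1 statistic needs on the order of fifty oscillation cycles sampled
near the cycle timescale to saturate; on short windows it stays near zero
and aperiodic trajectories come out ``unresolved`` rather than
``chaotic``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .model import ModelParameters
from .solvers import SolverGrid, SolverSpec, Trajectory, simulate

__all__ = [
    "DiagnosticsConfig",
    "AttractorReport",
    "SweepResult",
    "drop_transient",
    "find_peaks",
    "zero_one_chaos_K",
    "classify_attractor",
    "parameter_sweep",
]


@dataclass(frozen=True)
class DiagnosticsConfig:
    """Thresholds and knobs of the attractor classifier.

    transient_fraction
        Fraction of the trajectory discarded before analysis.
    component
        Which state component's peak structure is analyzed.
    tol_fixed_point
        Post-transient amplitude range below which the trajectory is a
        fixed point (absolute, states are O(1)).
    cluster_rel_tol
        Single-linkage merge tolerance for peak amplitudes, relative to
        the signal range.
    max_period
        Largest peak-amplitude cluster count reported as period-k; more
        clusters (or clusters without repeat visits) count as aperiodic.
    chaos_threshold / regular_threshold
        0-1 statistic cutoffs: K >= chaos_threshold labels chaotic,
        K <= regular_threshold is consistent with regular dynamics, the
        gap is unresolved.
    stride
        Sampling stride for the 0-1 test; 0 means automatic (aim for
        ~10 samples per mean peak interval, subject to keeping >= 100
        strided samples).
    n_c / seed
        Number of random test frequencies for the 0-1 statistic and the
        seed that draws them.
    """

    transient_fraction: float = 0.5
    component: str = "H"
    tol_fixed_point: float = 1e-4
    cluster_rel_tol: float = 1e-3
    max_period: int = 8
    chaos_threshold: float = 0.7
    regular_threshold: float = 0.2
    stride: int = 0
    n_c: int = 100
    seed: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class AttractorReport:
    label: str  # fixed_point | period_k | chaotic | unresolved
    peaks: np.ndarray
    peak_times: np.ndarray
    n_clusters: int | None
    period_estimate: float | None
    K_statistic: float | None
    transient_fraction: float
    config: dict = field(default_factory=dict)
    error: str | None = None

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "n_peaks": int(len(self.peaks)),
            "peak_amplitudes": [float(a) for a in self.peaks],
            "n_clusters": self.n_clusters,
            "period_estimate": self.period_estimate,
            "K_statistic": self.K_statistic,
            "transient_fraction": self.transient_fraction,
            "config": self.config,
            "error": self.error,
        }


@dataclass
class SweepResult:
    varied_name: str
    values: list[float]
    reports: list[AttractorReport]
    trajectories: list[Trajectory] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, r in zip(self.values, self.reports):
            rows.append(
                {
                    "varied_value": v,
                    "label": r.label,
                    "K": r.K_statistic,
                    "period_estimate": r.period_estimate,
                    "n_peaks": len(r.peaks),
                }
            )
        return pd.DataFrame(rows)


def drop_transient(traj: Trajectory, fraction: float) -> Trajectory:
    """Return the trailing part of the trajectory after discarding the
    first ``fraction`` of its nodes (inclusive endpoint: fraction 0.5 of
    1000 steps keeps nodes 500..1000)."""
    if not 0 <= fraction < 1:
        raise ValueError(f"transient fraction must lie in [0, 1), got {fraction}")
    start = int(round(fraction * (len(traj.times) - 1)))
    if start >= len(traj.times):
        raise ValueError("transient cut leaves an empty trajectory")
    out = Trajectory(
        traj.times[start:],
        traj.states[start:],
        traj.scheme,
        alpha=traj.alpha,
        tau=traj.tau,
        params=traj.params,
        initial=traj.initial,
        meta=dict(traj.meta),
    )
    out.meta["transient_cut"] = {"fraction": fraction, "dropped_nodes": start}
    return out


def find_peaks(series, times) -> list[tuple[float, float]]:
    """Strict interior local maxima of ``series`` as (time, amplitude)
    pairs; flat peaks are collapsed to their midpoint sample."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 3:
        raise ValueError("series must have at least three samples")
    idx, _ = _scipy_find_peaks(y)
    return [(float(t[i]), float(y[i])) for i in idx]


def zero_one_chaos_K(series, sampling_stride: int = 1, n_c: int = 100, seed: int = 0) -> float:
    """0-1 test for chaos, correlation method.

    Maps a regularly sampled scalar series to K in [0, 1]: for each of
    ``n_c`` random frequencies c in (pi/5, 4pi/5), the series drives a
    translation variable pair (p_c, q_c); K_c is the correlation between
    time and the (oscillation-corrected) mean-square displacement of that
    walk, and K is the median over c, clipped to [0, 1].  Bounded (p, q)
    walks (regular dynamics) give K near 0, diffusive walks (chaos) give
    K near 1.  Deterministic given ``seed``.
    """
    phi = np.asarray(series, dtype=float)
    if phi.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(phi) < 1000:
        raise ValueError(f"series too short for the 0-1 test: {len(phi)} < 1000 samples")
    if n_c < 50:
        raise ValueError(f"need at least 50 test frequencies, got {n_c}")
    if sampling_stride < 1:
        raise ValueError("sampling_stride must be >= 1")
    phi = phi[::sampling_stride]
    if len(phi) < 100:
        raise ValueError("strided series shorter than 100 samples")

    rng = np.random.default_rng(seed)
    cs = rng.uniform(np.pi / 5, 4 * np.pi / 5, n_c)
    N = len(phi)
    n_cut = max(10, N // 10)
    ns = np.arange(1, n_cut + 1)
    j = np.arange(1, N + 1)
    mean_phi = phi.mean()

    Ks = np.empty(n_c)
    for i, c in enumerate(cs):
        p = np.cumsum(phi * np.cos(j * c))
        q = np.cumsum(phi * np.sin(j * c))
        M = np.empty(n_cut)
        for k, n in enumerate(ns):
            dp = p[n:] - p[:-n]
            dq = q[n:] - q[:-n]
            M[k] = np.mean(dp * dp + dq * dq)
        # subtract the bounded oscillatory part so regular dynamics give a
        # flat (uncorrelated) displacement curve
        D = M - mean_phi**2 * (1 - np.cos(ns * c)) / (1 - np.cos(c))
        sd = D.std()
        Ks[i] = 0.0 if sd == 0 else float(np.corrcoef(ns, D)[0, 1])
    return float(np.clip(np.median(Ks), 0.0, 1.0))


def _cluster_amplitudes(amps: np.ndarray, tol: float) -> int:
    """Number of single-linkage clusters of sorted amplitudes at merge
    distance ``tol``."""
    if len(amps) == 0:
        return 0
    a = np.sort(amps)
    return int(1 + np.sum(np.diff(a) > tol))


def _converging_period(amps: np.ndarray, max_period: int) -> int | None:
    """Detect convergence toward a period-k orbit from a drifting peak
    sequence: for some k, the stride-k amplitude differences all share a
    sign, shrink (5% slack per step) and at least halve overall --
    geometric contraction toward k fixed amplitude levels.  Irregular
    (chaotic) amplitude sequences fail the constant-sign test."""
    for k in range(1, max_period + 1):
        if len(amps) < k + 3:
            break
        d = amps[k:] - amps[:-k]
        if np.all(d > 0) or np.all(d < 0):
            mag = np.abs(d)
            if np.all(mag[1:] <= mag[:-1] * 1.05) and mag[-1] <= 0.5 * mag[0]:
                return k
    return None


def _auto_stride(n_samples: int, peak_idx_spacing: float | None) -> int:
    if peak_idx_spacing is None or not np.isfinite(peak_idx_spacing):
        return max(1, n_samples // 1000)
    stride = max(1, int(round(peak_idx_spacing / 10.0)))
    # keep at least ~1000 strided samples when the series allows it
    return min(stride, max(1, n_samples // 1000))


def classify_attractor(traj: Trajectory, config: DiagnosticsConfig | None = None) -> AttractorReport:
    """Label the long-time behavior of a trajectory.

    Procedure: drop the transient; ``fixed_point`` if the analyzed
    component's amplitude range is below tolerance; else ``period_k`` if
    the peak amplitudes fall into k <= max_period clusters each visited at
    least twice; else ``chaotic`` if the 0-1 statistic exceeds its
    threshold, ``unresolved`` otherwise.  All thresholds come from the
    config and are echoed in the report.
    """
    cfg = config or DiagnosticsConfig()
    tail = drop_transient(traj, cfg.transient_fraction)
    y = tail.component(cfg.component)
    if len(y) < 1000:
        raise ValueError(
            f"post-transient trajectory too short to classify: {len(y)} < 1000 samples"
        )
    peaks = find_peaks(y, tail.times)
    peak_times = np.array([p[0] for p in peaks])
    amps = np.array([p[1] for p in peaks])

    amp_range = float(y.max() - y.min())
    report = AttractorReport(
        label="unresolved",
        peaks=amps,
        peak_times=peak_times,
        n_clusters=None,
        period_estimate=None,
        K_statistic=None,
        transient_fraction=cfg.transient_fraction,
        config=cfg.as_dict(),
    )

    if amp_range < cfg.tol_fixed_point:
        report.label = "fixed_point"
        return report

    # 0-1 statistic is always reported alongside the peak-structure verdict
    dt_idx = float(np.median(np.diff(peak_times))) if len(peak_times) > 2 else None
    h = float(tail.times[1] - tail.times[0])
    stride = cfg.stride if cfg.stride >= 1 else _auto_stride(
        len(y), None if dt_idx is None else dt_idx / h
    )
    report.K_statistic = zero_one_chaos_K(y, stride, cfg.n_c, cfg.seed)

    n_clusters = _cluster_amplitudes(amps, cfg.cluster_rel_tol * amp_range)
    report.n_clusters = n_clusters
    settled = (
        0 < n_clusters <= cfg.max_period
        and len(amps) >= 2 * n_clusters  # every amplitude level revisited
    )
    k_periodic = n_clusters if settled else _converging_period(amps, cfg.max_period)
    if k_periodic:
        report.label = f"period_{k_periodic}"
        report.n_clusters = k_periodic
        if len(peak_times) > k_periodic:
            base = float(np.median(np.diff(peak_times)))
            report.period_estimate = base * k_periodic
        return report

    if report.K_statistic >= cfg.chaos_threshold:
        report.label = "chaotic"
    return report


def parameter_sweep(
    base: ModelParameters,
    varied_name: str,
    values,
    spec: SolverSpec,
    ic,
    grid: SolverGrid,
    config: DiagnosticsConfig | None = None,
    keep_trajectories: bool = False,
) -> SweepResult:
    """Re-simulate and classify for each value of one model parameter.

    Per-value failures (e.g. nonpositive parameter values) are recorded in
    the corresponding report's ``error`` field; the sweep continues.
    """
    if varied_name not in ModelParameters.__dataclass_fields__:
        raise ValueError(f"unknown model parameter {varied_name!r}")
    cfg = config or DiagnosticsConfig()
    reports: list[AttractorReport] = []
    trajs: list[Trajectory] = []
    for v in values:
        try:
            params = dc_replace(base, **{varied_name: float(v)})
            traj = simulate(params, ic, grid, spec)
            reports.append(classify_attractor(traj, cfg))
            if keep_trajectories:
                trajs.append(traj)
        except Exception as exc:  # recorded, never fatal to the sweep
            reports.append(
                AttractorReport(
                    label="unresolved",
                    peaks=np.array([]),
                    peak_times=np.array([]),
                    n_clusters=None,
                    period_estimate=None,
                    K_statistic=None,
                    transient_fraction=cfg.transient_fraction,
                    config=cfg.as_dict(),
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
            if keep_trajectories:
                trajs.append(None)  # type: ignore[arg-type]
    return SweepResult(varied_name, [float(v) for v in values],
                       reports, trajs if keep_trajectories else None)
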