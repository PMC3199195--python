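"""Numerical integration, limit-cycle extraction and frequency calibration.

All simulations in the package go through :func:`integrate`, a thin,
deterministic wrapper around :func:`scipy.integrate.solve_ivp` with a
stiff-capable adaptive method and tight default tolerances.  The limit
cycle of one uncoupled cell is extracted by discarding a transient,
estimating the period from successive TetR peaks, and sampling one closed
orbit densely; phases are measured from the TetR maximum (phase 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    REFERENCE_CYCLE_POINT,
    SPECIES,
    CouplingParams,
    RepressilatorParams,
    make_coupled_rhs,
    make_single_rhs,
)

__all__ = [
    "IntegratorSettings",
    "Trajectory",
    "LimitCycle",
    "integrate",
    "integrate_single",
    "integrate_coupled",
    "find_limit_cycle",
    "state_at_phase",
    "free_running_frequency",
    "calibrate_frequency",
    "CalibrationError",
]


@dataclass(frozen=True)
class IntegratorSettings:
    """Adaptive-integrator controls shared by every simulation."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    #: output samples per (estimated) oscillation period
    samples_per_period: int = 200

    def halved(self) -> "IntegratorSettings":
        """Settings with both tolerances tightened by 10x (convergence checks)."""
        return IntegratorSettings(
            self.method, self.rtol / 10, self.atol / 10, self.samples_per_period
        )


@dataclass
class Trajectory:
    """Uniformly sampled solution of the single- or two-cell ODEs.

    ``states`` has one row per time point; 6 columns for a single cell,
    12 for the coupled pair (cell A block then cell B block).
    """

    times: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("a trajectory needs at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != len(self.times):
            raise ValueError("times and states are misaligned")

    @property
    def n_cells(self) -> int:
        return self.states.shape[1] // 6

    def species(self, name: str, cell: str = "a") -> np.ndarray:
        """Concentration time course of one species ('lp'...'cr') of one cell."""
        col = SPECIES.index(name)
        if self.n_cells == 2 and cell == "b":
            col += 6
        elif cell not in ("a", "b"):
            raise ValueError("cell must be 'a' or 'b'")
        return self.states[:, col]

    def to_frame(self):
        """Tidy table (time, cell, species, value) for CSV export."""
        import pandas as pd

        rows = []
        for ci in range(self.n_cells):
            cell = "ab"[ci]
            for si, sp in enumerate(SPECIES):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.times,
                            "cell": cell,
                            "species": sp,
                            "value": self.states[:, 6 * ci + si],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class IntegrationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    t_end: float,
    settings: IntegratorSettings = IntegratorSettings(),
    t_start: float = 0.0,
    n_samples: int | None = None,
    meta: dict | None = None,
) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` and sample the dense solution uniformly.

    Deterministic for fixed inputs.  Raises :class:`IntegrationError` with
    the failure time if the step size collapses.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    y0 = np.asarray(y0, dtype=float)
    sol = solve_ivp(
        rhs,
        (t_start, t_end),
        y0,
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t = {sol.t[-1]:.6g}: {sol.message}"
        )
    if n_samples is None:
        n_samples = max(len(sol.t), 2)
    t = np.linspace(t_start, t_end, n_samples)
    return Trajectory(t, sol.sol(t).T, meta=dict(meta or {}))


def integrate_single(
    p: RepressilatorParams,
    y0: Sequence[float] = REFERENCE_CYCLE_POINT,
    t_end: float = 5000.0,
    settings: IntegratorSettings = IntegratorSettings(),
    n_samples: int | None = None,
) -> Trajectory:
    """Simulate one uncoupled cell."""
    return integrate(
        make_single_rhs(p),
        y0,
        t_end,
        settings,
        n_samples=n_samples,
        meta={"params": p, "coupling": None},
    )


def integrate_coupled(
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    c: CouplingParams,
    y0: Sequence[float],
    t_end: float,
    settings: IntegratorSettings = IntegratorSettings(),
    n_samples: int | None = None,
) -> Trajectory:
    """Simulate the two-cell system from a 12-component initial state."""
    return integrate(
        make_coupled_rhs(p_a, p_b, c),
        y0,
        t_end,
        settings,
        n_samples=n_samples,
        meta={"params": (p_a, p_b), "coupling": c},
    )


@dataclass
class LimitCycle:
    """One closed orbit of an uncoupled cell, parameterised by phase.

    ``orbit`` holds dense samples over exactly one period; phase 0 is the
    maximum of the TetR protein (``tp``), the coupling species.
    """

    period: float
    times: np.ndarray  # in [0, period], relative to the tp maximum
    orbit: np.ndarray  # (len(times), 6)
    params: RepressilatorParams
    closure_gap: float = 0.0

    @property
    def frequency(self) -> float:
        return 1.0 / self.period

    def state_at_phase(self, phase_deg: float) -> np.ndarray:
        return state_at_phase(self, phase_deg)

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "times": self.times.tolist(),
            "orbit": self.orbit.tolist(),
            "closure_gap": self.closure_gap,
        }


class NoLimitCycleError(RuntimeError):
    pass


def _refined_peak_times(
    t: np.ndarray, x: np.ndarray, prominence: float | None = None
) -> np.ndarray:
    """Local-maximum times refined by a quadratic fit through 3 samples."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(x, prominence=prominence)
    out = []
    for i in idx:
        if i == 0 or i == len(x) - 1:
            continue
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        dt = t[i + 1] - t[i]
        out.append(t[i] + shift * dt)
    return np.array(out)


def find_limit_cycle(
    p: RepressilatorParams,
    transient_periods: float = 30.0,
    detect_peaks: int = 20,
    closure_tol: float = 1e-3,
    settings: IntegratorSettings = IntegratorSettings(),
    y0: Sequence[float] = REFERENCE_CYCLE_POINT,
    orbit_samples: int = 2000,
    period_hint: float | None = None,
) -> LimitCycle:
    """Converge onto the stable orbit of one cell and return one closed period.

    The transient is discarded (``transient_periods`` estimated periods),
    the period is the mean spacing of the last ``detect_peaks`` refined
    ``tp`` maxima, and the orbit is one period of the same dense solution
    starting at a ``tp`` maximum.  ``period_hint`` (rough period guess)
    skips the bootstrap pass.  Raises :class:`NoLimitCycleError` if the
    signal is damped or the orbit fails to close within ``closure_tol``
    (relative).
    """
    rhs = make_single_rhs(p)
    y0 = np.asarray(y0, dtype=float)

    period_rough = period_hint
    if period_rough is None:
        # bootstrap a period estimate, growing the window until enough peaks
        t_end = 2000.0
        for _ in range(8):
            traj = integrate(rhs, y0, t_end, settings, n_samples=int(t_end))
            tp = traj.species("tp")
            if tp.max() - tp.min() < 1e-6 * max(tp.max(), 1.0):
                raise NoLimitCycleError("signal is damped: no sustained oscillation")
            peaks = _refined_peak_times(traj.times, tp)
            if len(peaks) >= 8:
                break
            t_end *= 2
        else:
            raise NoLimitCycleError("could not collect enough oscillation peaks")
        period_rough = float(np.mean(np.diff(peaks[-8:])))

    # one dense run covering transient + detection window + one spare period
    t_end = (transient_periods + detect_peaks + 3) * period_rough
    sol = solve_ivp(
        rhs, (0.0, t_end), y0,
        method=settings.method, rtol=settings.rtol, atol=settings.atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    t = np.linspace(
        0.0, t_end, int((t_end / period_rough) * settings.samples_per_period)
    )
    tp = sol.sol(t)[1]
    if tp.max() - tp.min() < 1e-6 * max(tp.max(), 1.0):
        raise NoLimitCycleError("signal is damped: no sustained oscillation")
    peaks = _refined_peak_times(t, tp)
    tail = peaks[peaks > transient_periods * period_rough]
    if len(tail) < 3:
        raise NoLimitCycleError("too few post-transient peaks for a period estimate")
    spacings = np.diff(tail[-min(detect_peaks, len(tail)):])
    period = float(np.mean(spacings))
    if np.std(spacings) > 0.01 * period:
        raise NoLimitCycleError(
            f"peak spacings vary by {np.std(spacings)/period:.2%}: signal not periodic"
        )

    # one closed orbit of the same dense solution, from a refined tp maximum
    t_peak = tail[-2] if tail[-2] + period <= t_end else tail[-3]
    ts = np.linspace(t_peak, t_peak + period, orbit_samples)
    orbit = sol.sol(ts).T
    scale = np.maximum(np.abs(orbit).max(axis=0), 1e-12)
    gap = float(np.linalg.norm((orbit[-1] - orbit[0]) / scale) / np.sqrt(6))
    if gap > closure_tol:
        raise NoLimitCycleError(f"orbit closure gap {gap:.3g} exceeds {closure_tol:.3g}")
    return LimitCycle(period, ts - t_peak, orbit, p, closure_gap=gap)


def state_at_phase(lc: LimitCycle, phase_deg: float) -> np.ndarray:
    """Orbit point at a given phase (degrees past the TetR maximum).

    Phases outside [0, 360) are wrapped modulo 360.
    """
    phase = float(phase_deg) % 360.0
    t = phase / 360.0 * lc.period
    out = np.empty(6)
    for j in range(6):
        out[j] = np.interp(t, lc.times, lc.orbit[:, j])
    return out


def free_running_frequency(
    p: RepressilatorParams,
    settings: IntegratorSettings = IntegratorSettings(),
    **kwargs,
) -> float:
    """Free-running oscillation frequency (cycles per model time unit)."""
    return find_limit_cycle(p, settings=settings, **kwargs).frequency


def calibrate_frequency(
    p: RepressilatorParams,
    f_target: float,
    rel_tol: float = 1e-3,
    s_bracket: tuple[float, float] = (0.02, 12.0),
    max_iter: int = 40,
    settings: IntegratorSettings = IntegratorSettings(),
    measure_transient_periods: float = 15.0,
    measure_detect_peaks: int = 12,
) -> RepressilatorParams:
    """Scale the protein degradation rates to hit a target free frequency.

    A single common factor ``s`` multiplies ``k_lp, k_tp, k_cp``; the
    measured free-running frequency is a smooth, increasing function of
    ``s`` over the working range, so a secant iteration (falling back to
    bisection on the bracket) converges in a handful of simulations.
    Returns the scaled parameter set; all other constants untouched.
    """
    if f_target <= 0:
        raise CalibrationError("target frequency must be positive")

    cache: dict[float, float] = {}

    def f_of(s: float) -> float:
        if s not in cache:
            # period scales roughly as s^-1.25 around the base set; a rough
            # hint only sizes the integration window, it never biases f
            hint = None
            if 1.0 in cache:
                hint = 1.0 / (cache[1.0] * s**1.25)
            try:
                cache[s] = free_running_frequency(
                    p.with_degradation_scale(s), settings=settings,
                    period_hint=hint,
                    transient_periods=measure_transient_periods,
                    detect_peaks=measure_detect_peaks,
                )
            except NoLimitCycleError as err:
                raise CalibrationError(
                    f"oscillation lost at degradation scale {s:.4g}"
                ) from err
        return cache[s]

    f1 = f_of(1.0)
    # local power law f ~ f1 * s^gamma gives an excellent first guess
    s = (f_target / f1) ** (1 / 1.25)
    s = float(np.clip(s, *s_bracket))
    s_prev, f_prev = 1.0, f1
    lo, hi = s_bracket
    for _ in range(max_iter):
        f = f_of(s)
        if abs(f - f_target) / f_target < rel_tol:
            return p.with_degradation_scale(s)
        # maintain a shrinking bracket using monotonicity
        if f < f_target:
            lo = max(lo, s)
        else:
            hi = min(hi, s)
        if f != f_prev:
            s_new = s - (f - f_target) * (s - s_prev) / (f - f_prev)
        else:
            s_new = 0.5 * (lo + hi)
        s_prev, f_prev = s, f
        s = s_new if lo < s_new < hi else 0.5 * (lo + hi)
        if hi - lo < 1e-12:
            break
    raise CalibrationError(
        f"calibration to f = {f_target:.6g} did not converge within "
        f"{max_iter} iterations (bracket [{lo:.4g}, {hi:.4g}])"
    )
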