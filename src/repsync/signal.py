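"""Observables of oscillatory trajectories and the synchronisation criteria.

A pair of coupled oscillators counts as *synchronized* when three
conditions hold: the oscillation is undamped, the two signals harmonise
within an epsilon-neighbourhood after a finite time ``t_sync``, and the
resulting signal is monofrequential.  The epsilon is "one minute per
day": 1/1440 of the oscillation period, applied to the mutual offset of
matched TetR peaks.

Two flavours of the harmonisation test are provided.  For cells with
identical kinetics (the phase-shift study) the peak offset itself must
shrink below eps*T, since the symmetric locked state has zero lag.  For
detuned cells (the frequency-ratio study) the locked state keeps a
constant nonzero lag, so the criterion is applied to the *drift* of the
offset instead: two clocks count as synchronized once their mutual
offset settles into a band narrower than one minute per day-analogue
period and stays there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import root

from .model import CouplingParams, RepressilatorParams, coupled_jacobian, coupled_rhs
from .simulate import Trajectory, _refined_peak_times

__all__ = [
    "FrequencyEstimate",
    "SyncOutcome",
    "detect_peaks",
    "estimate_frequency",
    "phase_difference_series",
    "time_to_sync",
    "find_fixed_point",
    "is_damped",
    "classify",
    "InsufficientCyclesError",
    "NoOscillationError",
    "MarginalStabilityError",
    "InconsistentEvidenceError",
]

#: "one minute per day" as a fraction of the oscillation period
EPSILON_FRACTION = 1.0 / 1440.0


class InsufficientCyclesError(RuntimeError):
    pass


class NoOscillationError(RuntimeError):
    pass


class MarginalStabilityError(RuntimeError):
    pass


class InconsistentEvidenceError(RuntimeError):
    """Linear stability and trajectory amplitude disagree (e.g. bistability:
    a stable steady state coexisting with a persisting oscillation)."""


@dataclass(frozen=True)
class FrequencyEstimate:
    value: float
    method: Literal["fft", "peak-count"]
    n_cycles_used: int
    uncertainty: float

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class SyncOutcome:
    """Classification of a coupled run: synchronized / polyfrequential / damped."""

    classification: Literal["synchronized", "polyfrequential", "damped"]
    t_sync: float | None = None
    sync_frequency: FrequencyEstimate | None = None

    def __post_init__(self) -> None:
        if self.classification == "synchronized":
            if self.t_sync is None or self.t_sync < 0:
                raise ValueError("synchronized outcome requires t_sync >= 0")
        elif self.t_sync is not None or self.sync_frequency is not None:
            raise ValueError("t_sync/sync_frequency only apply when synchronized")

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "t_sync": self.t_sync,
            "sync_frequency": None
            if self.sync_frequency is None
            else self.sync_frequency.value,
        }


def detect_peaks(
    traj: Trajectory,
    species: str = "tp",
    cell: str = "a",
    min_prominence_frac: float = 0.0,
) -> np.ndarray:
    """Times of local maxima of one species, refined by quadratic interpolation.

    ``min_prominence_frac`` ignores maxima whose prominence is below that
    fraction of the signal's range (suppresses ripple on beat waveforms).
    """
    x = traj.species(species, cell)
    prom = min_prominence_frac * (x.max() - x.min()) if min_prominence_frac else None
    times = _refined_peak_times(traj.times, x, prominence=prom)
    if len(times) < 2:
        raise InsufficientCyclesError(
            f"fewer than 2 maxima of {species!r} in the trajectory"
        )
    return times


def estimate_frequency(
    traj: Trajectory,
    species: str = "tp",
    cell: str = "a",
    method: Literal["fft", "peak-count"] = "fft",
) -> FrequencyEstimate:
    """Dominant oscillation frequency of one species' time course.

    ``fft`` locates the dominant nonzero bin of the periodogram and
    refines it by parabolic interpolation on the log-amplitude of the
    three surrounding bins; ``peak-count`` averages the spacing of
    refined local maxima.  On a common >= 50-cycle window the two agree
    to well under 1%.
    """
    x = traj.species(species, cell)
    if x.max() - x.min() < 1e-9 * max(abs(x).max(), 1.0):
        raise NoOscillationError("flat signal: no oscillation to measure")
    if method == "peak-count":
        pk = detect_peaks(traj, species, cell)
        n = len(pk)
        value = (n - 1) / (pk[-1] - pk[0])
        unc = np.std(np.diff(pk)) * value**2 / np.sqrt(max(n - 1, 1))
        return FrequencyEstimate(float(value), "peak-count", n - 1, float(unc))
    if method != "fft":
        raise ValueError("method must be 'fft' or 'peak-count'")
    dt = traj.times[1] - traj.times[0]
    amp = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), dt)
    k = int(np.argmax(amp[1:]) + 1)
    df = freqs[1]
    if 1 <= k < len(amp) - 1 and amp[k - 1] > 0 and amp[k + 1] > 0:
        la, lb, lc = np.log(amp[k - 1]), np.log(amp[k]), np.log(amp[k + 1])
        denom = la - 2 * lb + lc
        shift = 0.0 if denom == 0 else 0.5 * (la - lc) / denom
    else:
        shift = 0.0
    value = freqs[k] + shift * df
    n_cycles = int(value * (traj.times[-1] - traj.times[0]))
    return FrequencyEstimate(float(value), "fft", n_cycles, float(df / 2))


def _matched_peak_offsets(
    traj: Trajectory, species: str = "tp"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cycle offsets of cell B's peaks from cell A's, wrapped to (-T/2, T/2].

    Returns (peak times of A used, offsets, period estimate).  Raises
    :class:`InsufficientCyclesError` if either cell has fewer than 2 peaks.
    """
    pa = detect_peaks(traj, species, "a", min_prominence_frac=0.05)
    pb = detect_peaks(traj, species, "b", min_prominence_frac=0.05)
    T = float(np.median(np.diff(pa)))
    offs = np.empty(len(pa))
    for i, t in enumerate(pa):
        d = t - pb[np.argmin(np.abs(pb - t))]
        d = (d + T / 2) % T - T / 2
        offs[i] = -d if d != T / 2 else T / 2  # offset of B relative to A
    return pa, offs, T


def phase_difference_series(
    traj: Trajectory, species: str = "tp"
) -> tuple[np.ndarray, np.ndarray]:
    """(cycle times, peak-time offset of cell B from cell A) per cycle."""
    pa, offs, _ = _matched_peak_offsets(traj, species)
    return pa, offs


def time_to_sync(
    traj: Trajectory,
    period: float,
    epsilon_fraction: float = EPSILON_FRACTION,
    hold_cycles: int = 10,
    criterion: Literal["offset", "drift"] = "offset",
    species: str = "tp",
) -> float | None:
    """First time after which the pair stays harmonised until trajectory end.

    ``offset``: the wrapped peak offset |dt| must stay below
    ``epsilon_fraction * period`` (identical cells lock at zero lag).
    ``drift``: the *unwrapped* offset must settle into a band of total
    width ``epsilon_fraction * period`` and stay there (detuned cells lock
    at a constant nonzero lag; slow beats and phase slips both show up as
    a wandering offset, however slow, and are rejected).  In both modes
    the condition must hold for at least ``hold_cycles`` consecutive
    cycles and through the end of the trajectory; returns ``None`` if it
    never does.
    """
    pa, offs, T_est = _matched_peak_offsets(traj, species)
    eps = epsilon_fraction * period
    if criterion == "offset":
        ok = np.abs(offs) < eps
        if len(ok) < hold_cycles or not ok[-1]:
            return None
        bad = np.nonzero(~ok)[0]
        start = 0 if len(bad) == 0 else bad[-1] + 1
        if len(ok) - start < hold_cycles:
            return None
        return 0.0 if start == 0 else float(pa[start])
    if criterion != "drift":
        raise ValueError("criterion must be 'offset' or 'drift'")
    if len(offs) < hold_cycles + 1:
        return None
    unwrapped = np.unwrap(offs, period=T_est)
    # earliest index from which the offset stays inside an eps-wide band:
    # running max/min from the right make this a single backward sweep
    run_max = np.maximum.accumulate(unwrapped[::-1])[::-1]
    run_min = np.minimum.accumulate(unwrapped[::-1])[::-1]
    settled = (run_max - run_min) < eps
    if not settled[-1]:
        return None
    first = int(np.argmax(settled))
    if len(offs) - first < hold_cycles:
        return None
    return 0.0 if first == 0 else float(pa[first])


def _single_cell_fixed_point(p: RepressilatorParams) -> np.ndarray:
    """Symmetric fixed point of one cell (lp = tp = cp, lr = tr = cr)."""
    from scipy.optimize import brentq

    # protein balance: k_r * r = k_p * x  ->  r = k_p x / k_r (per gene);
    # with symmetric defaults all three genes share the same value x.
    def g(x):
        r = p.k_lp * x / p.k_lr
        return p.hill(x) - (p.k_lr + p.k_lr2) * r

    hi = 1.0
    while g(hi) > 0:
        hi *= 2
        if hi > 1e9:
            raise RuntimeError("no sign change while bracketing the fixed point")
    x = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-15)
    r = p.k_lp * x / p.k_lr
    return np.array([x, x, x, r, r, r])


def find_fixed_point(
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    c: CouplingParams,
    residual_tol: float = 1e-10,
) -> np.ndarray:
    """Steady state of the coupled system (12 components).

    Newton iterations (scipy ``root`` with the analytic Jacobian) from the
    decoupled single-cell fixed points, plus perturbed fallback seeds.
    """
    base = np.concatenate(
        [_single_cell_fixed_point(p_a), _single_cell_fixed_point(p_b)]
    )
    seeds = [base, base * 1.2, base * 0.8]
    fun = lambda y: coupled_rhs(np.maximum(y, 0.0), p_a, p_b, c)
    jac = lambda y: coupled_jacobian(np.maximum(y, 0.0), p_a, p_b, c)
    for seed in seeds:
        sol = root(fun, seed, jac=jac, method="hybr", tol=1e-13)
        y = np.maximum(sol.x, 0.0)
        if np.linalg.norm(fun(y)) < residual_tol:
            return y
    raise RuntimeError("no fixed point found from any seed")


def is_damped(
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    c: CouplingParams,
    margin: float = 1e-8,
) -> bool:
    """Linear stability of the coupled steady state.

    True iff every Jacobian eigenvalue at the fixed point has negative
    real part (the steady state attracts, oscillations decay).  An
    eigenvalue within ``margin`` of the imaginary axis raises
    :class:`MarginalStabilityError` rather than guessing.
    """
    y = find_fixed_point(p_a, p_b, c)
    eig = np.linalg.eigvals(coupled_jacobian(y, p_a, p_b, c))
    reals = eig.real
    if np.any(np.abs(reals) < margin):
        raise MarginalStabilityError(
            f"eigenvalue real part within {margin:g} of zero: marginal case"
        )
    return bool(np.all(reals < 0))


def _terminal_monofrequential(
    traj: Trajectory,
    window_cycles: int,
    period: float,
    rel_peak_threshold: float = 0.10,
    freq_match_tol: float = 0.01,
    amp_settle_tol: float = 0.01,
) -> tuple[bool, FrequencyEstimate | None]:
    """Check the terminal window for a single common dominant frequency.

    A cell is monofrequential when no Hann-windowed spectral amplitude
    away from the integer harmonics of the dominant peak exceeds
    ``rel_peak_threshold`` of it (quasiperiodic beats show up as sideband
    families near the fundamental).  Both cells must additionally agree
    on the fundamental within ``freq_match_tol``.
    """
    t_end = traj.times[-1]
    sel = traj.times >= t_end - window_cycles * period
    sub = Trajectory(traj.times[sel], traj.states[sel])
    fundamentals = []
    for cell in ("a", "b"):
        x = sub.species("tp", cell)
        amp = np.abs(np.fft.rfft((x - x.mean()) * np.hanning(len(x))))
        freqs = np.fft.rfftfreq(len(x), sub.times[1] - sub.times[0])
        k = int(np.argmax(amp[1:]) + 1)
        f0 = freqs[k]
        # mask the Hann main lobes of every harmonic (4 bins each side)
        # and the sub-fundamental drift region; the rest is sideband space
        mask = np.ones(len(freqs), bool)
        for h in range(0, len(freqs) // max(k, 1) + 1):
            c = h * k
            mask[max(0, c - 4): c + 5] = False
        mask[freqs < 0.1 * f0] = False
        if mask.any() and amp[mask].max() > rel_peak_threshold * amp[k]:
            return False, None
        # a truly periodic locked state has constant peak heights; slow
        # common amplitude modulation (torus) evades finite-resolution
        # FFTs but shows up directly in the peak-height spread (locked
        # states sit at ~0.1%, modulated ones at several %)
        pk = _refined_peak_times(sub.times, x, prominence=0.05 * (x.max() - x.min()))
        heights = np.interp(pk, sub.times, x)
        if len(heights) >= 3:
            spread = (heights.max() - heights.min()) / heights.mean()
            if spread > amp_settle_tol:
                return False, None
        fundamentals.append(estimate_frequency(sub, "tp", cell, "fft"))
    fa, fb = fundamentals
    if abs(fa.value - fb.value) / fb.value > freq_match_tol:
        return False, None
    return True, FrequencyEstimate(
        0.5 * (fa.value + fb.value), "fft", fa.n_cycles_used, fa.uncertainty
    )


def classify(
    traj: Trajectory,
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    c: CouplingParams,
    period: float,
    epsilon_fraction: float = EPSILON_FRACTION,
    hold_cycles: int = 10,
    terminal_window_cycles: int = 80,
) -> SyncOutcome:
    """Full three-condition classification of a coupled run.

    Damped if the linearisation predicts decay and the trajectory's
    terminal amplitude has collapsed; otherwise synchronized when the
    harmonisation criterion fires (offset flavour for identical cells,
    drift flavour for detuned ones) and the terminal windows of both
    cells are monofrequential at a common frequency; else polyfrequential.
    Inconsistent evidence (stable steady state but sustained oscillation)
    raises rather than guesses.
    """
    tp_a = traj.species("tp", "a")
    tail = tp_a[traj.times >= traj.times[-1] - 2 * period]
    amplitude_dead = (tail.max() - tail.min()) < 1e-3 * (tp_a.max() - tp_a.min())
    try:
        linearly_damped = is_damped(p_a, p_b, c)
    except MarginalStabilityError:
        linearly_damped = amplitude_dead
    if linearly_damped and amplitude_dead:
        return SyncOutcome("damped")
    if linearly_damped != amplitude_dead:
        raise InconsistentEvidenceError(
            "eigenvalues and trajectory amplitude disagree (bistable regime?)"
        )

    identical = p_a == p_b
    criterion = "offset" if identical else "drift"
    try:
        t_sync = time_to_sync(
            traj, period, epsilon_fraction, hold_cycles, criterion=criterion
        )
    except InsufficientCyclesError:
        return SyncOutcome("polyfrequential")
    if t_sync is None:
        return SyncOutcome("polyfrequential")
    mono, f_common = _terminal_monofrequential(traj, terminal_window_cycles, period)
    if not mono:
        return SyncOutcome("polyfrequential")
    return SyncOutcome("synchronized", t_sync=t_sync, sync_frequency=f_common)
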