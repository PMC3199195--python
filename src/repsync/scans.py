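"""Study-level experiments on the coupled pair.

Two scans delimit the synchronisation behaviour: the phase-shift x
coupling scan (time-to-sync surface for identical cells started at
different points of the common limit cycle) and the frequency-ratio x
coupling scan (Arnold-tongue style synchronisation window for detuned
cells, each started on its own limit cycle).  ``sync_window`` bisects the
window boundary in initial-frequency ratio at fixed coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import CouplingParams, RepressilatorParams
from .signal import InconsistentEvidenceError, SyncOutcome, classify
from .simulate import (
    IntegratorSettings,
    LimitCycle,
    calibrate_frequency,
    find_limit_cycle,
    integrate_coupled,
    state_at_phase,
)

__all__ = [
    "ScanResult",
    "DEFAULT_DIFF_GRID",
    "phase_scan",
    "frequency_scan",
    "sync_window",
    "simulate_pair",
]

#: the study's coupling-strength grid, weak to strong
DEFAULT_DIFF_GRID = (0.01, 0.03, 0.05, 0.07, 0.09, 0.11, 0.13)


@dataclass
class ScanResult:
    """Grid of :class:`~repsync.signal.SyncOutcome` over (axis1 x diff)."""

    axis1_name: str  # "phase_deg" or "ratio"
    axis1: np.ndarray
    diffs: np.ndarray
    cells: list[list[SyncOutcome | None]]  # [i_axis1][j_diff]
    provenance: dict = field(default_factory=dict)

    def t_sync_surface(self) -> np.ndarray:
        out = np.full((len(self.axis1), len(self.diffs)), np.nan)
        for i, row in enumerate(self.cells):
            for j, oc in enumerate(row):
                if oc is not None and oc.classification == "synchronized":
                    out[i, j] = oc.t_sync
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.axis1):
            for j, d in enumerate(self.diffs):
                oc = self.cells[i][j]
                rows.append(
                    {
                        self.axis1_name: a,
                        "diff": d,
                        "classification": None if oc is None else oc.classification,
                        "t_sync": None if oc is None else oc.t_sync,
                        "sync_frequency": None
                        if oc is None or oc.sync_frequency is None
                        else oc.sync_frequency.value,
                    }
                )
        return pd.DataFrame(rows)


def simulate_pair(
    p_a: RepressilatorParams,
    p_b: RepressilatorParams,
    diff: float,
    y0: np.ndarray,
    period: float,
    horizon_periods: float = 200.0,
    settings: IntegratorSettings = IntegratorSettings(),
    samples_per_period: int = 60,
    **classify_kwargs,
) -> SyncOutcome:
    """Simulate one coupled run over the horizon and classify it."""
    c = CouplingParams(diff)
    t_end = horizon_periods * period
    traj = integrate_coupled(
        p_a, p_b, c, y0, t_end, settings,
        n_samples=int(horizon_periods * samples_per_period),
    )
    return classify(traj, p_a, p_b, c, period, **classify_kwargs)


def phase_scan(
    p: RepressilatorParams,
    phases: Sequence[float] = tuple(np.linspace(0.0, 360.0, 37)[:-1]),
    diffs: Sequence[float] = DEFAULT_DIFF_GRID,
    horizon_periods: float = 200.0,
    settings: IntegratorSettings = IntegratorSettings(),
    lc: LimitCycle | None = None,
) -> ScanResult:
    """Time-to-sync over (initial phase shift x coupling strength).

    Both cells share the parameter set ``p``; cell A starts at phase 0 of
    the limit cycle and cell B at the scanned phase.  Per-cell failures
    are recorded as ``None`` and the scan continues.
    """
    if lc is None:
        lc = find_limit_cycle(p, settings=settings)
    a0 = state_at_phase(lc, 0.0)
    cells: list[list[SyncOutcome | None]] = []
    for phase in phases:
        row: list[SyncOutcome | None] = []
        b0 = state_at_phase(lc, phase)
        for diff in diffs:
            try:
                row.append(
                    simulate_pair(
                        p, p, diff, np.concatenate([a0, b0]), lc.period,
                        horizon_periods, settings,
                    )
                )
            except Exception:
                row.append(None)
        cells.append(row)
    return ScanResult(
        "phase_deg",
        np.asarray(phases, float),
        np.asarray(diffs, float),
        cells,
        provenance={
            "params": p,
            "period": lc.period,
            "horizon_periods": horizon_periods,
            "settings": settings,
        },
    )


def frequency_scan(
    p_base: RepressilatorParams,
    ratios: Sequence[float] = tuple(np.linspace(0.65, 1.35, 25)),
    diffs: Sequence[float] = DEFAULT_DIFF_GRID,
    horizon_periods: float = 200.0,
    settings: IntegratorSettings = IntegratorSettings(),
    calibration_rel_tol: float = 1e-3,
) -> ScanResult:
    """Synchronisation window over (initial-frequency ratio x coupling).

    Cell B keeps ``p_base``; cell A is re-calibrated so that its
    free-running frequency is ``ratio`` times the base frequency.  Both
    cells start at phase 0 of their own limit cycles.  Unreachable
    calibrations are recorded as ``None``.
    """
    lc_base = find_limit_cycle(p_base, settings=settings)
    f_base = lc_base.frequency
    b0 = state_at_phase(lc_base, 0.0)
    cells: list[list[SyncOutcome | None]] = []
    for ratio in ratios:
        row: list[SyncOutcome | None] = []
        try:
            p_a = calibrate_frequency(
                p_base, ratio * f_base, rel_tol=calibration_rel_tol,
                settings=settings,
            )
            lc_a = find_limit_cycle(p_a, settings=settings)
            a0 = state_at_phase(lc_a, 0.0)
        except Exception:
            cells.append([None] * len(diffs))
            continue
        for diff in diffs:
            try:
                row.append(
                    simulate_pair(
                        p_a, p_base, diff, np.concatenate([a0, b0]),
                        lc_base.period, horizon_periods, settings,
                    )
                )
            except Exception:
                row.append(None)
        cells.append(row)
    return ScanResult(
        "ratio",
        np.asarray(ratios, float),
        np.asarray(diffs, float),
        cells,
        provenance={
            "params_base": p_base,
            "f_base": f_base,
            "horizon_periods": horizon_periods,
            "settings": settings,
        },
    )


class WindowBracketError(RuntimeError):
    pass


def sync_window(
    p_base: RepressilatorParams,
    diff: float,
    ratio_bracket: tuple[float, float] = (0.55, 1.55),
    tol: float = 0.01,
    horizon_periods: float = 200.0,
    settings: IntegratorSettings = IntegratorSettings(),
    calibration_rel_tol: float = 1e-3,
) -> tuple[float, float]:
    """Boundaries (ratio_lo, ratio_hi) of the synchronisation window.

    Bisects the synchronized/not-synchronized transition on each side of
    ratio 1 to a tolerance ``tol`` in ratio.  Requires that ratio 1.0
    synchronizes at this coupling strength and that both bracket ends do
    not (otherwise :class:`WindowBracketError`).
    """
    lc_base = find_limit_cycle(p_base, settings=settings)
    f_base = lc_base.frequency
    b0 = state_at_phase(lc_base, 0.0)

    def synchronized(ratio: float) -> bool:
        if abs(ratio - 1.0) < 1e-9:
            p_a, a0 = p_base, b0
        else:
            p_a = calibrate_frequency(
                p_base, ratio * f_base, rel_tol=calibration_rel_tol,
                settings=settings,
            )
            lc_a = find_limit_cycle(p_a, settings=settings)
            a0 = state_at_phase(lc_a, 0.0)
        try:
            oc = simulate_pair(
                p_a, p_base, diff, np.concatenate([a0, b0]), lc_base.period,
                horizon_periods, settings,
            )
        except InconsistentEvidenceError:
            # bistable regime: the steady state is linearly stable even if
            # the trajectory still oscillates — the undamped condition is
            # violated, so the cell lies outside the window
            return False
        return oc.classification == "synchronized"

    if not synchronized(1.0):
        raise WindowBracketError(f"ratio 1.0 does not synchronize at diff={diff}")

    bounds = []
    for sign, edge in ((-1, ratio_bracket[0]), (+1, ratio_bracket[1])):
        lo_sync, hi_nosync = 1.0, edge
        if synchronized(edge):
            raise WindowBracketError(
                f"bracket end {edge} still synchronizes at diff={diff}; widen it"
            )
        while abs(hi_nosync - lo_sync) > tol:
            mid = 0.5 * (lo_sync + hi_nosync)
            if synchronized(mid):
                lo_sync = mid
            else:
                hi_nosync = mid
        bounds.append(0.5 * (lo_sync + hi_nosync))
    return bounds[0], bounds[1]
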