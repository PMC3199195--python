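"""Frequency estimation, peak matching and the synchronisation criteria."""

import numpy as np
import pytest

from repsync import (
    CouplingParams,
    RepressilatorParams,
    classify,
    detect_peaks,
    estimate_frequency,
    find_fixed_point,
    integrate_coupled,
    integrate_single,
    is_damped,
    phase_difference_series,
    state_at_phase,
    time_to_sync,
)
from repsync.model import coupled_rhs
from repsync.signal import InsufficientCyclesError, NoOscillationError
from repsync.simulate import Trajectory


def sinusoid_trajectory(freq=0.0016, n_cycles=60, samples_per_cycle=200, two_cells=False,
                        phase_b=0.0):
    t = np.linspace(0, n_cycles / freq, n_cycles * samples_per_cycle)
    a = 5.0 + np.sin(2 * np.pi * freq * t)
    cols = [a] * 6
    if two_cells:
        b = 5.0 + np.sin(2 * np.pi * freq * t - phase_b)
        cols = [a] * 6 + [b] * 6
    return Trajectory(t, np.column_stack(cols))


@pytest.fixture(scope="session")
def free_run(default_params, limit_cycle):
    """60 post-transient cycles of the default cell, started on the orbit."""
    T = limit_cycle.period
    traj = integrate_single(
        default_params, y0=limit_cycle.orbit[0], t_end=60 * T,
        n_samples=60 * 200,
    )
    return traj


class TestPeaksAndFrequency:
    def test_sinusoid_peak_spacing(self):
        traj = sinusoid_trajectory()
        pk = detect_peaks(traj)
        np.testing.assert_allclose(np.diff(pk), 625.0, atol=0.1)

    def test_monotone_signal_raises(self):
        t = np.linspace(0, 100, 500)
        traj = Trajectory(t, np.column_stack([t] * 6))
        with pytest.raises(InsufficientCyclesError):
            detect_peaks(traj)

    def test_flat_signal_raises(self):
        t = np.linspace(0, 100, 500)
        traj = Trajectory(t, np.ones((500, 6)))
        with pytest.raises(NoOscillationError):
            estimate_frequency(traj)

    @pytest.mark.parametrize("method", ["fft", "peak-count"])
    def test_sinusoid_frequency(self, method):
        traj = sinusoid_trajectory()
        est = estimate_frequency(traj, method=method)
        assert est.value == pytest.approx(0.0016, rel=1e-3)

    def test_methods_agree_on_repressilator_trace(self, free_run):
        f_fft = estimate_frequency(free_run, method="fft").value
        f_pk = estimate_frequency(free_run, method="peak-count").value
        assert abs(f_fft - f_pk) / f_pk < 0.01

    def test_peak_count_matches_known_period(self, free_run, limit_cycle):
        f_pk = estimate_frequency(free_run, method="peak-count").value
        assert f_pk == pytest.approx(limit_cycle.frequency, rel=1e-3)


class TestPhaseDifference:
    def test_identical_cells_zero_offsets(self, default_params, limit_cycle):
        T = limit_cycle.period
        y0 = np.concatenate([limit_cycle.orbit[0]] * 2)
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.0), y0,
            20 * T, n_samples=20 * 200,
        )
        _, offs = phase_difference_series(traj)
        assert np.max(np.abs(offs)) < 1e-3 * T

    def test_decoupled_antiphase_offset_is_half_period(self, default_params, limit_cycle):
        T = limit_cycle.period
        y0 = np.concatenate(
            [state_at_phase(limit_cycle, 0.0), state_at_phase(limit_cycle, 180.0)]
        )
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.0), y0,
            20 * T, n_samples=20 * 200,
        )
        _, offs = phase_difference_series(traj)
        np.testing.assert_allclose(np.abs(offs), T / 2, rtol=0.02)

    def test_coupled_offsets_decay(self, default_params, limit_cycle):
        """The published demonstration run: 182 degrees shift, diff = 0.04."""
        T = limit_cycle.period
        y0 = np.concatenate(
            [state_at_phase(limit_cycle, 0.0), state_at_phase(limit_cycle, 182.0)]
        )
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.04), y0,
            120 * T, n_samples=120 * 200,
        )
        _, offs = phase_difference_series(traj)
        assert np.abs(offs[-5:]).max() < 1e-3 * T
        assert np.abs(offs[0]) > 0.05 * T  # starts visibly apart, decays to zero


class TestTimeToSync:
    def test_identical_start_syncs_at_zero(self, default_params, limit_cycle):
        T = limit_cycle.period
        y0 = np.concatenate([limit_cycle.orbit[0]] * 2)
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.0), y0,
            20 * T, n_samples=20 * 200,
        )
        assert time_to_sync(traj, T) == 0.0

    def test_decoupled_antiphase_never_syncs(self, default_params, limit_cycle):
        T = limit_cycle.period
        y0 = np.concatenate(
            [state_at_phase(limit_cycle, 0.0), state_at_phase(limit_cycle, 180.0)]
        )
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.0), y0,
            40 * T, n_samples=40 * 200,
        )
        assert time_to_sync(traj, T) is None

    def test_antiphase_harder_than_small_shift(self, default_params, limit_cycle):
        """Antiphase initial conditions take the longest to harmonise."""
        T = limit_cycle.period
        t_syncs = {}
        for shift in (30.0, 180.0):
            y0 = np.concatenate(
                [state_at_phase(limit_cycle, 0.0), state_at_phase(limit_cycle, shift)]
            )
            traj = integrate_coupled(
                default_params, default_params, CouplingParams(0.04), y0,
                150 * T, n_samples=150 * 200,
            )
            t_syncs[shift] = time_to_sync(traj, T)
        assert t_syncs[30.0] is not None and t_syncs[180.0] is not None
        assert t_syncs[180.0] > t_syncs[30.0]

    def test_time_rescaling_rescales_t_sync(self, default_params, limit_cycle):
        """The epsilon criterion is scale-free: stretching time stretches t_sync."""
        T = limit_cycle.period
        y0 = np.concatenate(
            [state_at_phase(limit_cycle, 0.0), state_at_phase(limit_cycle, 90.0)]
        )
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.04), y0,
            120 * T, n_samples=120 * 200,
        )
        t1 = time_to_sync(traj, T)
        stretched = Trajectory(3.0 * traj.times, traj.states)
        t3 = time_to_sync(stretched, 3.0 * T)
        assert t1 is not None and t3 == pytest.approx(3.0 * t1, rel=1e-9)


class TestFixedPointAndDamping:
    def test_symmetric_fixed_point(self, default_params, coupling):
        y = find_fixed_point(default_params, default_params, coupling)
        np.testing.assert_allclose(y[:6], y[6:], rtol=1e-8)
        res = coupled_rhs(y, default_params, default_params, coupling)
        assert np.linalg.norm(res) < 1e-10

    def test_decoupled_equals_single_cell_duplicated(self, default_params):
        y0 = find_fixed_point(default_params, default_params, CouplingParams(0.0))
        y7 = find_fixed_point(default_params, default_params, CouplingParams(0.07))
        # the symmetric steady state is unaffected by symmetric diffusion
        np.testing.assert_allclose(y0, y7, rtol=1e-6)

    @pytest.mark.parametrize("diff", [0.0, 0.07])
    def test_default_system_is_undamped(self, default_params, diff):
        assert is_damped(default_params, default_params, CouplingParams(diff)) is False


class TestClassify:
    def test_identical_decoupled_cells_sync_immediately(self, default_params, limit_cycle):
        T = limit_cycle.period
        y0 = np.concatenate([limit_cycle.orbit[0]] * 2)
        traj = integrate_coupled(
            default_params, default_params, CouplingParams(0.0), y0,
            60 * T, n_samples=60 * 200,
        )
        oc = classify(traj, default_params, default_params, CouplingParams(0.0), T)
        assert oc.classification == "synchronized"
        assert oc.t_sync == 0.0
        assert oc.sync_frequency.value == pytest.approx(limit_cycle.frequency, rel=0.01)

    def test_decoupled_detuned_cells_polyfrequential(self, default_params, limit_cycle):
        from repsync import calibrate_frequency, find_limit_cycle

        T = limit_cycle.period
        p_b = calibrate_frequency(default_params, 1.2 * limit_cycle.frequency,
                                  rel_tol=2e-3)
        lc_b = find_limit_cycle(p_b, period_hint=T / 1.2)
        y0 = np.concatenate([limit_cycle.orbit[0], lc_b.orbit[0]])
        traj = integrate_coupled(
            default_params, p_b, CouplingParams(0.0), y0, 80 * T,
            n_samples=80 * 200,
        )
        oc = classify(traj, default_params, p_b, CouplingParams(0.0), T)
        assert oc.classification == "polyfrequential"
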