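"""Entrainment: effective phases, return maps, fixed points, circular statistics."""

import numpy as np
import pytest

import dendrophase as dp


def _train(times, window=None):
    times = np.asarray(times, dtype=float)
    if window is None:
        window = (times[0] - 1.0, times[-1] + 1.0)
    return dp.SpikeTrain(times=times, window=window)


class TestEffectivePhases:
    def test_reference_points(self):
        spikes = _train([0.0, 1500.0 / 7.0], window=(-1.0, 10000.0))
        psi = dp.effective_phases(spikes, 7.0, 0.0)
        assert psi[0] == 0.0
        assert psi[1] == pytest.approx(0.5, abs=1e-12)

    def test_offset_origin(self):
        spikes = _train([1000.0], window=(0.0, 2000.0))
        psi = dp.effective_phases(spikes, 10.0, 950.0)
        assert psi[0] == pytest.approx(0.5, abs=1e-12)


class TestPerturbedPeriods:
    def test_regular_train(self):
        spikes = _train(np.arange(0.0, 2000.0, 143.0))
        psi, tp = dp.perturbed_periods(spikes, 7.0, 0.0)
        assert np.allclose(tp, 143.0)
        assert len(psi) == len(spikes.times) - 1

    def test_two_spikes_one_pair(self):
        psi, tp = dp.perturbed_periods(_train([0.0, 120.0]), 7.0, 0.0)
        assert len(psi) == 1 and tp[0] == 120.0

    def test_needs_two_spikes(self):
        with pytest.raises(ValueError):
            dp.perturbed_periods(_train([5.0]), 7.0, 0.0)


class TestFitTpCurve:
    def test_exact_three_mode_recovery(self, rng):
        psi = rng.random(200)
        coef = np.array([140.0, 3.0, -2.0, 1.0, 0.5, -0.7, 0.2])
        def truth(x):
            out = np.full_like(x, coef[0])
            for m in (1, 2, 3):
                out = out + coef[2 * m - 1] * np.cos(2 * np.pi * m * x)
                out = out + coef[2 * m] * np.sin(2 * np.pi * m * x)
            return out
        fn = dp.fit_tp_curve(psi, truth(psi))
        assert np.allclose(fn.coef, coef, atol=1e-9)

    def test_constant_curve(self, rng):
        psi = rng.random(100)
        fn = dp.fit_tp_curve(psi, np.full(100, 150.0))
        assert fn.coef[0] == pytest.approx(150.0)
        assert np.max(np.abs(fn.coef[1:])) < 1e-9

    def test_locked_session_is_refused(self, rng):
        psi = 0.5 + 0.05 * rng.standard_normal(100)  # narrow phase coverage
        with pytest.raises(ValueError, match="locked"):
            dp.fit_tp_curve(np.mod(psi, 1.0), np.full(100, 143.0))

    def test_noisy_curve_rmse(self, rng):
        psi = rng.random(400)
        truth = 143.0 + 5.0 * np.cos(2 * np.pi * psi) - 3.0 * np.sin(4 * np.pi * psi)
        fn = dp.fit_tp_curve(psi, truth + rng.normal(0, 2.0, 400))
        grid = np.linspace(0, 1, 200, endpoint=False)
        truth_grid = 143.0 + 5.0 * np.cos(2 * np.pi * grid) - 3.0 * np.sin(4 * np.pi * grid)
        rmse = np.sqrt(np.mean((fn(grid) - truth_grid) ** 2))
        assert rmse < 1.0


class TestSimulateTp:
    def test_no_drive_gives_natural_period(self):
        tri = dp.TriangularPRC(theta=0.8)
        tp = dp.simulate_tp(tri, 7.0, 7.0, 0.0, 0.3)
        assert tp == pytest.approx(1000.0 / 7.0, rel=1e-9)

    def test_zero_prc_gives_natural_period(self):
        flat = dp.TriangularPRC(theta=0.8, amp=0.0)
        tp = dp.simulate_tp(flat, 7.0, 7.0, 5.0, 0.3)
        assert tp == pytest.approx(1000.0 / 7.0, rel=1e-9)

    def test_fixed_point_self_consistency(self):
        """At the map's stable fixed point the perturbed period equals the
        stimulus period."""
        tri = dp.TriangularPRC(theta=0.9)
        tp_fn = dp.simulate_tp_curve(tri, 7.0, 7.0, 5.0)
        rmap = dp.build_map(tp_fn, 1000.0 / 7.0, provenance="simulated")
        psi_star = [fp.psi for fp in dp.find_fixed_points(rmap) if fp.stable][0]
        tp = dp.simulate_tp(tri, 7.0, 7.0, 5.0, psi_star)
        assert tp == pytest.approx(1000.0 / 7.0, rel=1e-4)

    def test_rejects_offset_prc(self):
        with pytest.raises(ValueError, match="zero-offset"):
            dp.simulate_tp(dp.TriangularPRC(theta=0.8, offset=0.01), 7.0, 7.0, 5.0, 0.1)


class TestReturnMap:
    def test_identity_map_is_degenerate(self):
        rmap = dp.build_map(lambda x: np.full_like(np.asarray(x, float), 100.0), 100.0)
        assert rmap(0.3) == pytest.approx(0.3)
        with pytest.raises(ValueError, match="degenerate"):
            dp.find_fixed_points(rmap)

    def test_constant_offset_is_rotation(self):
        rmap = dp.build_map(lambda x: np.full_like(np.asarray(x, float), 150.0), 100.0)
        assert rmap(0.2) == pytest.approx(0.7)
        assert dp.find_fixed_points(rmap) == []

    def test_rotation_number_without_drive(self):
        """With no drive, the per-spike phase increment is exactly f/f0."""
        f, f0 = 9.0, 7.0
        rmap = dp.build_map(
            lambda x: np.full_like(np.asarray(x, float), 1000.0 / f0), 1000.0 / f
        )
        orbit_lifted = [0.0]
        for _ in range(200):
            orbit_lifted.append(float(rmap.lifted(np.array(orbit_lifted[-1]))))
        incr = np.diff(orbit_lifted)
        assert np.allclose(incr, f / f0, atol=1e-10)

    def test_printed_locking_phases(self):
        """Stable fixed points at 0.537 (theta=0.9) and 0.6 (theta=0.75)."""
        for theta, expect in ((0.9, 0.537), (0.75, 0.6)):
            tp_fn = dp.simulate_tp_curve(dp.TriangularPRC(theta=theta), 7.0, 7.0, 5.0)
            rmap = dp.build_map(tp_fn, 1000.0 / 7.0, provenance="simulated")
            stable = [fp for fp in dp.find_fixed_points(rmap) if fp.stable]
            assert len(stable) == 1
            assert stable[0].psi == pytest.approx(expect, abs=0.005)
            assert abs(stable[0].slope) < 1.0

    def test_earlier_prc_peak_locks_later(self):
        phases = {}
        for theta in (0.9, 0.75):
            tp_fn = dp.simulate_tp_curve(dp.TriangularPRC(theta=theta), 7.0, 7.0, 5.0)
            rmap = dp.build_map(tp_fn, 1000.0 / 7.0)
            phases[theta] = [fp.psi for fp in dp.find_fixed_points(rmap) if fp.stable][0]
        assert phases[0.75] > phases[0.9]

    def test_unlocked_orbit_concentrates_near_closest_approach(self):
        """Where the map nears the diagonal the orbit slows down, so the phase
        histogram peaks there even without a fixed point."""
        tp_fn = dp.simulate_tp_curve(dp.TriangularPRC(theta=0.75), 8.0, 7.0, 5.0)
        rmap = dp.build_map(tp_fn, 1000.0 / 8.0, provenance="simulated")
        assert dp.find_fixed_points(rmap) == []
        orbit = rmap.orbit(0.1, 3000)[500:]
        hist, edges = np.histogram(orbit, bins=20, range=(0, 1))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        grid = np.linspace(0, 1, 2000, endpoint=False)
        gap = np.abs(np.asarray(rmap(grid)) - grid)
        gap = np.minimum(gap, 1 - gap)
        closest = grid[np.argmin(gap)]
        d = abs(mode - closest)
        assert min(d, 1 - d) < 0.1

    def test_map_simulation_equivalence(self):
        """The map's stable fixed point agrees with the long-run mean phase of a
        direct event-by-event phase-oscillator simulation (no map involved)."""
        theta = 0.9
        tp_fn = dp.simulate_tp_curve(dp.TriangularPRC(theta=theta), 7.0, 7.0, 5.0)
        rmap = dp.build_map(tp_fn, 1000.0 / 7.0)
        psi_star = [fp.psi for fp in dp.find_fixed_points(rmap) if fp.stable][0]
        cfg = dp.GeneratorConfig(seed=3, prc=dp.TriangularPRC(theta=theta), jitter_frac=0.0)
        spikes = dp.gen_pacemaker_periodic(cfg, f_hz=7.0, amp=5.0, duration_ms=12000.0)
        psis = dp.effective_phases(spikes.restricted(4000.0, 12000.0), 7.0, 0.0)
        stat = dp.circular_stat(psis)
        d = abs(stat.phase - psi_star)
        assert min(d, 1 - d) < 0.01


class TestCircularStat:
    def test_single_phase(self):
        s = dp.circular_stat([0.3] * 7)
        assert s.amplitude == pytest.approx(1.0)
        assert s.phase == pytest.approx(0.3)

    def test_symmetric_phases_cancel(self):
        s = dp.circular_stat([0.0, 0.25, 0.5, 0.75])
        assert s.amplitude == pytest.approx(0.0, abs=1e-15)

    def test_amplitude_bounded_and_shift_invariant(self, rng):
        psi = rng.random(200) * 0.3
        s0 = dp.circular_stat(psi)
        s1 = dp.circular_stat(np.mod(psi + 0.37, 1.0))
        assert 0 <= s0.amplitude <= 1
        assert s1.amplitude == pytest.approx(s0.amplitude, abs=1e-12)
        d = abs(s1.phase - (s0.phase + 0.37) % 1.0)
        assert min(d, 1 - d) < 1e-12

    def test_uniform_phases_follow_rayleigh_limit(self, rng):
        """Median resultant amplitude of 100 uniform phases is sqrt(ln 2 / 100)."""
        amps = np.abs(np.exp(2j * np.pi * rng.random((10000, 100))).mean(axis=1))
        assert np.median(amps) == pytest.approx(np.sqrt(np.log(2) / 100), rel=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dp.circular_stat([])


class TestBootstrapThreshold:
    def test_reference_value_n100(self):
        thr = dp.bootstrap_threshold(n=100, reps=10000, seed=0)
        assert 0.168 <= thr <= 0.180  # Rayleigh sqrt(-ln .05 / 100) = 0.173

    def test_single_phasor(self):
        assert dp.bootstrap_threshold(n=1, seed=0) == 1.0

    def test_large_n(self):
        thr = dp.bootstrap_threshold(n=10000, reps=4000, seed=1)
        assert thr == pytest.approx(0.0173, abs=0.0015)

    def test_scales_as_inverse_sqrt_n(self):
        ns = np.array([25, 100, 400, 1600])
        thrs = [dp.bootstrap_threshold(n=int(n), reps=10000, seed=2) for n in ns]
        slope = np.polyfit(np.log(ns), np.log(thrs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.02)


class TestBootstrapPhasePvalue:
    def _reference(self, rng, center=0.5, spread=0.02, n=40):
        stats = []
        for _ in range(n):
            psi = np.mod(center + spread * rng.standard_normal(100), 1.0)
            stats.append(dp.circular_stat(psi))
        return stats

    def test_identical_mean_gives_high_p(self, rng):
        ref = self._reference(rng)
        amps = np.array([s.amplitude for s in ref])
        phases = np.array([s.phase for s in ref])
        ref_mean = float(
            np.angle(np.sum(amps * np.exp(2j * np.pi * phases))) / (2 * np.pi) % 1
        )
        p = dp.bootstrap_phase_pvalue(ref, test_mean_phase=ref_mean, reps=4000, seed=0)
        assert p > 0.95
        # the generating mean itself is also unremarkable under the null
        p_true = dp.bootstrap_phase_pvalue(ref, test_mean_phase=0.5, reps=4000, seed=0)
        assert p_true > 0.05

    def test_large_displacement_gives_tiny_p(self, rng):
        ref = self._reference(rng)
        p = dp.bootstrap_phase_pvalue(ref, test_mean_phase=0.8, reps=4000, seed=0)
        assert p < 0.001

    def test_calibration_under_the_null(self):
        """p-values for means drawn from the reference's own distribution are
        roughly uniform."""
        rng = np.random.default_rng(11)
        ref = self._reference(rng, spread=0.05)
        pvals = []
        for _ in range(200):
            draw = np.random.default_rng(rng.integers(2**31)).choice(
                [s.phase for s in ref], size=len(ref)
            )
            mean = float(np.angle(np.exp(2j * np.pi * draw).mean()) / (2 * np.pi) % 1)
            pvals.append(
                dp.bootstrap_phase_pvalue(ref, mean, reps=1000, seed=rng.integers(2**31))
            )
        pvals = np.asarray(pvals)
        for q in (0.25, 0.5, 0.75):
            assert abs(np.mean(pvals <= q) - q) < 0.15

    def test_zero_amplitude_reference_rejected(self):
        flat = [dp.circular_stat([0.0, 0.25, 0.5, 0.75])] * 3
        with pytest.raises(ValueError, match="zero amplitude"):
            dp.bootstrap_phase_pvalue(flat, 0.5)
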