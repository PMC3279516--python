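"""Forward mechanics: WLC elasticity, two-state helices, stochastic pulling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igh_elastica.mechanics import (
    HelixElement,
    IgElement,
    PullingProtocol,
    RigidSegment,
    WLCParams,
    bell_evans_rate,
    helix_unfolded_fraction,
    myomesin_arm,
    serial_chain_extension,
    simulate_pull,
    thermal_energy,
    wlc_extension,
    wlc_force,
)

KT = thermal_energy(298.0)


class TestWLC:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0, WLCParams(0.5, 100.0)) == 0.0

    def test_half_extension_value(self):
        # phi(0.5) = 0.5 + 1 - 0.25 = 1.25 -> F = 1.25 kT/p
        F = wlc_force(50.0, WLCParams(0.5, 100.0))
        assert F == pytest.approx(1.25 * KT / 0.5, rel=1e-12)
        assert F == pytest.approx(10.28, abs=0.02)

    def test_divergence_near_full_extension(self):
        p = WLCParams(0.5, 100.0)
        assert wlc_force(99.0, p) > 100.0 * wlc_force(50.0, p)

    def test_extension_at_or_beyond_contour_rejected(self):
        with pytest.raises(ValueError):
            wlc_force(100.0, WLCParams(0.5, 100.0))

    def test_zero_force_zero_extension(self):
        assert wlc_extension(0.0, WLCParams(0.5, 100.0)) == 0.0

    def test_monotone_in_force(self):
        p = WLCParams(0.5, 80.0)
        x = wlc_extension(np.linspace(0.5, 200.0, 64), p)
        assert np.all(np.diff(x) > 0)

    @given(
        frac=st.floats(min_value=0.05, max_value=0.95),
        L=st.floats(min_value=5.0, max_value=500.0),
        pl=st.floats(min_value=0.2, max_value=2.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_force_extension_round_trip(self, frac, L, pl):
        p = WLCParams(pl, L)
        x = frac * L
        assert wlc_extension(wlc_force(x, p), p) == pytest.approx(x, abs=1e-6)


class TestSerialChain:
    def test_single_unfolded_element_equals_wlc(self):
        ig = IgElement(state="unfolded")
        L = ig.folded_extent + ig.contour_gain_unfolded
        for F in (5.0, 30.0, 120.0):
            assert serial_chain_extension(F, [ig]) == pytest.approx(
                wlc_extension(F, WLCParams(0.5, L))
            )

    def test_additivity(self):
        a = IgElement(state="unfolded")
        b = HelixElement(state="unfolded")
        for F in (2.0, 20.0, 80.0):
            assert serial_chain_extension(F, [a, b]) == pytest.approx(
                serial_chain_extension(F, [a]) + serial_chain_extension(F, [b])
            )

    def test_doubling_contour_doubles_extension(self):
        one = [IgElement(state="unfolded")]
        two = one + [IgElement(state="unfolded")]
        for F in (5.0, 50.0):
            assert serial_chain_extension(F, two) == pytest.approx(
                2.0 * serial_chain_extension(F, one)
            )

    def test_rigid_mode_folded_extent_is_force_independent(self):
        seg = [IgElement(folded_mode="rigid")]
        assert serial_chain_extension(10.0, seg) == serial_chain_extension(100.0, seg)


class TestHelixOccupancy:
    def test_half_occupancy_at_midpoint(self):
        h = HelixElement()
        assert helix_unfolded_fraction(h.midpoint_force, h) == pytest.approx(0.5)

    def test_folded_at_rest(self):
        assert helix_unfolded_fraction(0.0, HelixElement()) < 0.01

    def test_gillespie_two_state_matches_boltzmann(self):
        """Time-averaged occupancy of a rate simulation reproduces the
        closed-form Boltzmann occupancy within 3 standard errors."""
        h = HelixElement()
        rng = np.random.default_rng(12345)
        for F in (28.0, 30.0, 32.0):
            p = helix_unfolded_fraction(F, h)
            ku = h.attempt_frequency * p
            kf = h.attempt_frequency * (1.0 - p)
            n_batches, per_batch = 20, 5000
            estimates = []
            state = 0
            for _ in range(n_batches):
                t_unf = t_tot = 0.0
                for _ in range(per_batch):
                    dwell = rng.exponential(1.0 / (ku if state == 0 else kf))
                    if state == 1:
                        t_unf += dwell
                    t_tot += dwell
                    state ^= 1
                estimates.append(t_unf / t_tot)
            est = float(np.mean(estimates))
            se = float(np.std(estimates, ddof=1) / math.sqrt(n_batches))
            assert abs(est - p) < 3.0 * se + 1e-12


class TestBellEvans:
    def test_zero_force_gives_k0(self):
        assert bell_evans_rate(0.0, 1e-4, 0.3) == pytest.approx(1e-4)

    def test_doubling_force_scale(self):
        F_double = KT * math.log(2.0) / 0.3
        assert bell_evans_rate(F_double, 1e-4, 0.3) == pytest.approx(2e-4)

    def test_log_linear_slope(self):
        F = np.array([10.0, 40.0, 90.0])
        lnk = np.log([bell_evans_rate(f, 1e-4, 0.3) for f in F])
        slope = np.polyfit(F, lnk, 1)[0]
        assert slope == pytest.approx(0.3 / KT, rel=1e-9)


class TestSimulatePull:
    def test_all_rates_zero_gives_smooth_monotone_trace(self):
        elems = [IgElement(k0=0.0) for _ in range(4)]
        prot = PullingProtocol.constant_velocity(
            30.0, 1000.0, force_noise_sd=0.0, seed=0
        )
        tr = simulate_pull(elems, prot)
        assert len(tr.events) == 0
        assert np.all(np.diff(tr.force) >= -1e-9)

    def test_identical_seeds_bit_identical(self):
        arm = myomesin_arm()
        prot = PullingProtocol.constant_velocity(200.0, 1000.0, seed=42)
        t1 = simulate_pull(arm, prot)
        t2 = simulate_pull(arm, prot)
        assert np.array_equal(t1.force, t2.force)
        assert t1.events == t2.events

    def test_event_count_bounded_and_igs_unfold_once(self, fast_pulls):
        for tr in fast_pulls:
            assert len(tr.events) <= 8
            labels = [lbl for _, lbl, _ in tr.events]
            assert len(labels) == len(set(labels))

    def test_force_balance_residual_below_tolerance(self, fast_pulls, slow_pulls):
        for tr in fast_pulls + slow_pulls:
            assert tr.metadata["max_balance_residual_pN"] < 1e-6

    def test_noise_free_stretch_relax_identical(self):
        """With transitions disabled and noise off, the stretch and relax
        curves coincide at matching stage positions (zero hysteresis)."""
        elems = [IgElement(k0=0.0) for _ in range(3)]
        prot = PullingProtocol.stretch_relax(
            30.0, 500.0, force_noise_sd=0.0, seed=0
        )
        tr = simulate_pull(elems, prot)
        n = len(tr) // 2
        # relax stages are offset by one step from the stretch stages
        f_st = tr.force[: n - 1]
        f_rx = tr.force[n:][::-1][1:]
        assert np.allclose(f_st, f_rx, atol=1e-7)

    def test_mean_unfolding_force_increases_with_speed(self):
        """Bell-Evans kinetics: faster pulling shifts unfolding to higher
        force, checked over three speeds with 50 pulls each."""
        arm = myomesin_arm(n_helix=0)
        means = []
        for speed in (100.0, 1000.0, 10_000.0):
            forces = []
            for seed in range(50):
                prot = PullingProtocol.constant_velocity(
                    260.0, speed, sampling_rate=2000.0,
                    force_noise_sd=0.0, seed=seed,
                )
                tr = simulate_pull(arm, prot)
                tidx = np.searchsorted(tr.time, [t for t, _, _ in tr.events])
                forces.extend(tr.force[np.clip(tidx, 0, len(tr) - 1)])
            means.append(np.mean(forces))
        assert means[0] < means[1] < means[2]

    def test_slow_pull_plateau_precedes_first_ig_event(self, slow_pulls):
        from igh_elastica.analysis import detect_plateau

        found = 0
        for tr in slow_pulls:
            pl = detect_plateau(tr)
            if pl is not None:
                found += 1
                assert abs(pl.force - 30.0) < 5.0
        assert found >= 5

    def test_contour_exhaustion_is_not_reachable_quietly(self):
        # a rigid-only chain pulled far produces a linear cantilever ramp
        prot = PullingProtocol.constant_velocity(
            20.0, 1000.0, force_noise_sd=0.0, seed=0
        )
        tr = simulate_pull([RigidSegment(5.0, folded_mode="rigid")], prot)
        expected = 6.0 * (tr.stage_position - 5.0)
        assert np.allclose(tr.force, np.maximum(expected, 0.0), atol=1e-9)


class TestValidation:
    def test_protocol_rejects_nonpositive_speed(self):
        with pytest.raises(ValueError):
            PullingProtocol([(0.0, 10.0, 0.0)])

    def test_trace_requires_increasing_time(self):
        from igh_elastica.mechanics import ForceExtensionTrace

        t = np.array([0.0, 1.0, 1.0])
        z = np.zeros(3)
        with pytest.raises(ValueError):
            ForceExtensionTrace(t, z, z, z)

    def test_helix_element_invariants(self):
        with pytest.raises(ValueError):
            HelixElement(contour_gain_unfolded=-1.0)
        with pytest.raises(ValueError):
            HelixElement(midpoint_force=0.0)
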