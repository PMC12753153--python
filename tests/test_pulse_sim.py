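"""Two-level pulse-sequence propagation, phase cycling, ENDOR, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdrelax.pulse_sim import (
    HyperfineCoupling,
    OffsetEnsemble,
    Pulse,
    PulseSequence,
    RelaxationParams,
    analytic_hahn_amplitude,
    analytic_stimulated_amplitude,
    cpn_phase_cycle,
    dipole_coupling,
    dipole_distance,
    endor_spectrum,
    load_phase_cycle,
    mims_efficiency,
    phase_cycle,
    propagate,
    stimulated_echo_bias,
    train_phase_cycle,
    _rotate,
)

P90_IDEAL = Pulse(0, math.pi / 2)
P180_IDEAL = Pulse(0, math.pi)


def phase_commensurate_offsets(tau_ns: float, n: int = 64) -> OffsetEnsemble:
    """Offsets whose free-precession phases over tau span 0..2pi uniformly,
    so every phase-carrying (non-refocused) pathway term cancels exactly in
    the ensemble average."""
    delta_MHz = (np.arange(n) / n) * 1e3 / tau_ns
    return OffsetEnsemble.explicit(delta_MHz)


class TestPropagatorBasics:
    def test_ideal_hahn_echo_unity_any_offsets(self):
        off = OffsetEnsemble.gaussian(150.0, 64, seed=2)
        tr = propagate(PulseSequence.hahn(250.0, P90_IDEAL, P180_IDEAL), off)
        assert tr.amplitude[0] == pytest.approx(1.0, abs=1e-12)
        assert tr.time_us[0] == pytest.approx(0.5)  # echo at 2 tau

    def test_rotations_preserve_magnetization_norm(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((200, 3))
        axis = rng.standard_normal((200, 3))
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        m2 = _rotate(m, axis, rng.uniform(0, 2 * math.pi, 200))
        assert np.allclose(np.linalg.norm(m2, axis=1), np.linalg.norm(m, axis=1),
                           atol=1e-12)

    def test_transverse_magnitude_nonincreasing_under_relaxation(self):
        relax = RelaxationParams(T1_us=50.0, T2_us=10.0)
        off = OffsetEnsemble.gaussian(50.0, 16, seed=1)
        seq = PulseSequence.full_train(20, 400.0, P90_IDEAL, P180_IDEAL)
        tr = propagate(seq, off, relax)
        assert np.all(np.diff(np.abs(tr.amplitude)) <= 1e-12)

    def test_ideal_full_train_exponential_exact(self):
        relax = RelaxationParams(T1_us=1e6, T2_us=18.0)
        off = OffsetEnsemble.gaussian(100.0, 32, seed=2)
        seq = PulseSequence.full_train(30, 290.0, P90_IDEAL, P180_IDEAL)
        tr = propagate(seq, off, relax)
        assert np.allclose(tr.amplitude, np.exp(-tr.time_us / 18.0), atol=1e-12)

    def test_ideal_full_train_stretched_kernel_exact(self):
        relax = RelaxationParams(T1_us=1e6, T2_us=18.0, stretch=0.75)
        off = OffsetEnsemble.gaussian(100.0, 32, seed=2)
        seq = PulseSequence.full_train(30, 290.0, P90_IDEAL, P180_IDEAL)
        tr = propagate(seq, off, relax)
        assert np.allclose(tr.amplitude, np.exp(-((tr.time_us / 18.0) ** 0.75)),
                           atol=1e-12)

    def test_detection_overlapping_pulse_rejected(self):
        with pytest.raises(ValueError):
            PulseSequence([("pulse", P90_IDEAL), ("detect", +1)])

    def test_t2_bounded_by_twice_t1(self):
        with pytest.raises(ValueError):
            RelaxationParams(T1_us=5.0, T2_us=11.0)


class TestPathwayOracles:
    @pytest.mark.parametrize("t1,t2", [(math.pi / 2, math.pi), (1.0, 2.0), (0.6, 2.8)])
    def test_hard_pulse_hahn_matches_pathway_formula(self, t1, t2):
        """Propagated echo equals sin(theta1) sin^2(theta2/2) once the
        phase-carrying pathways cancel over the offset ensemble."""
        tau = 200.0
        off = phase_commensurate_offsets(tau)
        tr = propagate(PulseSequence.hahn(tau, Pulse(0, t1), Pulse(0, t2)), off)
        assert tr.amplitude[0] == pytest.approx(analytic_hahn_amplitude(t1, t2),
                                                abs=1e-3)

    @pytest.mark.parametrize("angles", [(math.pi / 2,) * 3, (1.0, 1.3, 0.7)])
    def test_hard_pulse_stimulated_echo_matches_pathway_formula(self, angles):
        t1, t2, t3 = angles
        tau = 200.0
        seq = PulseSequence([
            ("pulse", Pulse(0, t1)), ("delay", tau),
            ("pulse", Pulse(0, t2)), ("delay", 10 * tau),
            ("pulse", Pulse(0, t3)), ("delay", tau), ("detect", +1),
        ])
        tr = propagate(seq, phase_commensurate_offsets(tau))
        assert tr.amplitude[0] == pytest.approx(
            analytic_stimulated_amplitude(t1, t2, t3), abs=1e-3)

    def test_selective_hahn_matches_tilted_frame_formula(self):
        """30 ns pulses on a broad Gaussian ensemble: the offset-averaged echo
        equals the analytic refocused-pathway amplitude
        (w1/W) sin(W t90) [(w1/W) sin(W t180/2)]^2."""
        t90, t180 = 15.0, 30.0
        w1 = math.pi / t180
        offs = np.linspace(-400, 400, 8001)
        weights = np.exp(-(offs**2) / (2 * 100.0**2))
        off = OffsetEnsemble.explicit(offs, weights)
        tr = propagate(PulseSequence.hahn(290.0, Pulse(t90, math.pi / 2),
                                          Pulse(t180, math.pi)), off)
        dw = 2 * math.pi * 1e-3 * offs
        omega = np.sqrt(w1**2 + dw**2)
        analytic = (w1 / omega) * np.sin(omega * t90) * ((w1 / omega) * np.sin(omega * t180 / 2)) ** 2
        expected = float(np.sum(weights * analytic) / weights.sum())
        assert tr.amplitude[0] == pytest.approx(expected, abs=1e-3)


class TestPhaseCycling:
    def test_pulse_fid_cancels_exactly(self):
        """After an inversion pulse cycled +-x, the FID of the detection
        pulse cancels exactly in the two-step sum."""
        seq = PulseSequence([
            ("pulse", Pulse(0, math.pi)), ("delay", 500.0),
            ("pulse", P90_IDEAL), ("delay", 120.0), ("detect", +1),
        ])
        scheme = {"name": "two", "steps": [
            {"pulse_phases": {0: 0.0}, "receiver": 1.0},
            {"pulse_phases": {0: math.pi}, "receiver": -1.0},
        ]}
        off = OffsetEnsemble.gaussian(60.0, 48, seed=3)
        assert abs(propagate(seq, off).amplitude[0]) > 1e-3
        assert abs(phase_cycle(seq, scheme, off).amplitude[0]) < 1e-14

    def test_cp2_cycle_suppresses_stimulated_contamination(self):
        """With T2 << 2 tau << T1 the refocused pathway is dead at the final
        window and the uncycled signal is pure stimulated-echo contamination;
        the 4-step cycle must reduce it by at least 10x."""
        relax = RelaxationParams(T1_us=1000.0, T2_us=0.4)
        seq = PulseSequence.cpn(2, 4000.0, Pulse(15.0, math.pi / 2),
                                Pulse(30.0, math.pi))
        off = OffsetEnsemble.gaussian(80.0, 64, seed=5)
        unc = propagate(seq, off, relax).amplitude[-1]
        cyc = phase_cycle(seq, cpn_phase_cycle(2), off, relax).amplitude[-1]
        assert abs(unc) > 10.0 * abs(cyc)

    def test_cycle_preserves_ideal_refocused_echo(self):
        seq = PulseSequence.cpn(3, 2400.0, P90_IDEAL, P180_IDEAL)
        off = OffsetEnsemble.gaussian(80.0, 32, seed=1)
        assert phase_cycle(seq, cpn_phase_cycle(3), off).amplitude[-1] == pytest.approx(
            propagate(seq, off).amplitude[-1], abs=1e-12)

    def test_packaged_cycle_tables_match_builders(self):
        for n in (1, 2, 5):
            packaged = load_phase_cycle(f"cp{n}")
            built = cpn_phase_cycle(n)
            assert len(packaged["steps"]) == len(built["steps"]) == 2**n
            for a, b in zip(packaged["steps"], built["steps"]):
                assert a["receiver"] == b["receiver"]
                assert a["pulse_phases"] == pytest.approx(b["pulse_phases"])
        assert len(load_phase_cycle("full_train")["steps"]) == 2

    def test_malformed_cycle_rejected(self):
        seq = PulseSequence.hahn(200.0, P90_IDEAL, P180_IDEAL)
        off = OffsetEnsemble.gaussian(10.0, 4, seed=0)
        with pytest.raises(ValueError):
            phase_cycle(seq, {"steps": []}, off)
        with pytest.raises(ValueError):
            phase_cycle(seq, {"steps": [{"receiver": 1.0}]}, off)


class TestStimulatedEchoBias:
    def test_ideal_pulses_zero_bias(self):
        relax = RelaxationParams(T1_us=45.5, T2_us=18.0)
        off = OffsetEnsemble.gaussian(100.0, 64, seed=1)
        res = stimulated_echo_bias(290.0, 70, Pulse(0, math.pi), off, relax)
        assert res.bias == pytest.approx(0.0, abs=1e-6)
        assert res.se_adequate

    def test_selective_pulses_positive_bias_when_t1_dominates(self):
        """Selective pulses store magnetization along z where it decays with
        the slower T1, so the fitted Tm overshoots the input T2."""
        relax = RelaxationParams(T1_us=45.0, T2_us=18.0)
        off = OffsetEnsemble.gaussian(100.0, 256, seed=2)
        res = stimulated_echo_bias(290.0, 70, Pulse(30.0, math.pi), off, relax)
        assert res.bias > 0.0


class TestMimsEndor:
    def test_blind_spots_at_integer_a_tau(self):
        for k in range(4):
            tau = 500.0
            a = k / (tau * 1e-3) if k else 0.0
            assert mims_efficiency(a, tau) == pytest.approx(0.0, abs=1e-12)

    def test_maximum_at_half_integer(self):
        assert mims_efficiency(1.0, 500.0) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 5.0), st.floats(100.0, 1000.0))
    def test_bounded_and_periodic(self, a, tau):
        e = mims_efficiency(a, tau)
        assert 0.0 <= e <= 0.5
        # period 1 in the product a*tau (microseconds x MHz)
        assert mims_efficiency(a + 1e3 / tau, tau) == pytest.approx(e, abs=1e-9)

    def test_tau_choices_cover_large_and_small_couplings(self):
        """The short tau (280 ns) favours the MHz-range couplings (which a
        long tau blind-spots), while tau = 600 ns more than triples the
        response of the sub-MHz couplings."""
        # ~1.6 MHz coupling: near maximal at 280 ns, blind-spotted at 600 ns
        assert mims_efficiency(1.6, 280.0) > 0.9 * mims_efficiency(1.6, 1000.0 / (2 * 1.6))
        assert mims_efficiency(1.6, 600.0) < 0.05 * mims_efficiency(1.6, 280.0)
        # 0.14-0.17 MHz couplings: far stronger at 600 ns
        for a in (0.14, 0.17):
            assert mims_efficiency(a, 600.0) > 3.0 * mims_efficiency(a, 280.0)

    def test_endor_doublet_splittings_read_back(self):
        from scipy.signal import argrelextrema

        cpls = [HyperfineCoupling(440.0), HyperfineCoupling(170.0, weight=2.0)]
        freq, amp = endor_spectrum(cpls, 280.0, 144.7)
        peaks = freq[argrelextrema(amp, np.greater, order=8)[0]] - 144.7
        # perpendicular singularities at +- a_perp/2 (the Mims weighting
        # pulls the broad 0.44 MHz doublet slightly inwards)
        for target, tol in ((0.085, 0.01), (0.22, 0.02)):
            for sign in (+1, -1):
                assert np.min(np.abs(peaks - sign * target)) < tol

    def test_blind_spot_tau_suppresses_doublet(self):
        tau_blind = 1e3 / 0.44  # a_perp * tau = 1
        f1, a1 = endor_spectrum([HyperfineCoupling(440.0)], 600.0, 144.7)
        f2, a2 = endor_spectrum([HyperfineCoupling(440.0)], tau_blind, 144.7)
        w1 = (f1 > 144.7 + 0.19) & (f1 < 144.7 + 0.25)
        w2 = (f2 > 144.7 + 0.19) & (f2 < 144.7 + 0.25)
        assert a2[w2].max() < 0.4 * a1[w1].max()

    def test_zero_couplings_gives_matrix_line(self):
        freq, amp = endor_spectrum([], 280.0, 144.7)
        assert freq[np.argmax(amp)] == pytest.approx(144.7, abs=0.01)

    def test_strong_coupling_regime_rejected(self):
        with pytest.raises(ValueError):
            endor_spectrum([HyperfineCoupling(500.0)], 280.0, 0.2)


class TestDipoleDistance:
    def test_pyridine_proton_distance_consistent(self):
        """5.5 Å protons correspond to a_perp ~ 0.47 MHz, the order of the
        measured 440 kHz pyridine-ring coupling."""
        a = dipole_coupling(5.5, g=1.992)
        assert a == pytest.approx(470.0, rel=0.02)  # kHz

    def test_cube_root_scaling(self):
        r1 = dipole_distance(440.0)
        r2 = dipole_distance(220.0)
        assert r2 / r1 == pytest.approx(2.0 ** (1 / 3), rel=1e-12)

    def test_round_trip_exact(self):
        for r in (3.0, 5.5, 8.2):
            assert dipole_distance(dipole_coupling(r)) == pytest.approx(r, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dipole_distance(0.0)
        with pytest.raises(ValueError):
            dipole_coupling(-1.0)
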