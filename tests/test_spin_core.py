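"""Spin operators, Hamiltonian structure, and resonance-field solving."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdrelax.constants import BOHR_MHZ_PER_MT
from gdrelax.spin_core import (
    Orientation,
    SpinSystem,
    boltzmann_weights,
    hamiltonian,
    resonance_fields,
    spin_operators,
    transition_alpha,
    zfs_hamiltonian,
)


class TestSpinOperators:
    def test_spin_half_defining_case(self):
        _, _, sz = spin_operators(0.5)
        assert np.allclose(np.diag(sz), [0.5, -0.5])

    @pytest.mark.parametrize("spin", [0.5, 1.0, 1.5, 3.5])
    def test_commutation_and_tracelessness(self, spin):
        sx, sy, sz = spin_operators(spin)
        assert np.allclose(sx @ sy - sy @ sx, 1j * sz, atol=1e-12)
        assert np.allclose(sy @ sz - sz @ sy, 1j * sx, atol=1e-12)
        for m in (sx, sy, sz):
            assert abs(np.trace(m)) < 1e-12
            assert np.allclose(m, m.conj().T)

    def test_sz_squared_eigenvalues_s72(self):
        _, _, sz = spin_operators(3.5)
        assert sz.shape == (8, 8)
        ev = np.sort(np.linalg.eigvalsh((sz @ sz).real))
        expected = np.sort([49 / 4, 49 / 4, 25 / 4, 25 / 4, 9 / 4, 9 / 4, 1 / 4, 1 / 4])
        assert np.allclose(ev, expected)

    def test_rejects_invalid_spin(self):
        with pytest.raises(ValueError):
            spin_operators(0.7)
        with pytest.raises(ValueError):
            spin_operators(-0.5)


class TestHamiltonian:
    def test_zeeman_ladder_at_zero_zfs(self):
        sys0 = SpinSystem(D=0, E=0, g=1.992)
        h = hamiltonian(sys0, 3400.0, Orientation(0.8, 1.1))
        ev = np.sort(np.linalg.eigvalsh(h))
        gaps = np.diff(ev)
        assert np.allclose(gaps, 1.992 * BOHR_MHZ_PER_MT * 3400.0, rtol=1e-10)

    def test_kramers_doublets_at_zero_field(self):
        sys = SpinSystem(D=4200, E=440)
        ev = np.linalg.eigvalsh(hamiltonian(sys, 0.0, Orientation()))
        # Kramers theorem: 4 doubly degenerate levels for half-integer spin
        assert np.allclose(ev[::2], ev[1::2], atol=1e-8)
        assert len(np.unique(np.round(ev[::2], 6))) == 4

    def test_hermitian_and_real_eigenvalues_random_draws(self):
        rng = np.random.default_rng(0)
        n = 10_000
        d = rng.uniform(-5000, 5000, n)
        e = rng.uniform(-2000, 2000, n)
        th = rng.uniform(0, np.pi, n)
        ph = rng.uniform(0, 2 * np.pi, n)
        b = rng.uniform(0, 5000, n)
        # vectorized: H = b * (n.S) * g mu_B + D-term + E-term
        from gdrelax.spin_core import spin_operators as ops

        sx, sy, sz = ops(3.5)
        stheta, ctheta = np.sin(th), np.cos(th)
        nvec = np.stack([stheta * np.cos(ph), stheta * np.sin(ph), ctheta], axis=1)
        hz = np.einsum("ni,ijk->njk", nvec, np.stack([sx, sy, sz]))
        eye = np.eye(8)
        hzfs = (
            d[:, None, None] * (sz @ sz - 3.5 * 4.5 / 3 * eye)
            + e[:, None, None] * (sx @ sx - sy @ sy)
        )
        h = 1.992 * BOHR_MHZ_PER_MT * b[:, None, None] * hz + hzfs
        assert np.allclose(h, np.conj(np.swapaxes(h, 1, 2)), atol=1e-8)
        ev = np.linalg.eigvals(h[:100])
        assert np.max(np.abs(ev.imag)) < 1e-8

    def test_zfs_traceless_any_parameters(self):
        for d, e in [(1200, 0), (4200, 440), (-900, 333.3)]:
            assert abs(np.trace(zfs_hamiltonian(3.5, d, e))) < 1e-9

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            hamiltonian(SpinSystem(), -1.0, Orientation())

    def test_ct_first_order_zfs_free(self):
        """The central-transition energy deviates from the Zeeman quantum only
        at second order in D (scale D^2/nu)."""
        sys = SpinSystem(D=1200, E=0, g=1.992)
        b = 3400.0
        ev = np.sort(np.linalg.eigvalsh(hamiltonian(sys, b, Orientation(0.0, 0.0))))
        ct_gap = ev[4] - ev[3]
        zeeman = 1.992 * BOHR_MHZ_PER_MT * b
        # at theta=0 the CT is exactly first-order ZFS free
        assert abs(ct_gap - zeeman) < 1200**2 / (zeeman)


class TestTransitionAlpha:
    @pytest.mark.parametrize(
        "mS,expected_alpha",
        [(-0.5, 1.0), (-1.5, math.sqrt(15 / 16)), (-3.5, math.sqrt(7 / 16))],
    )
    def test_values_s72(self, mS, expected_alpha):
        alpha, factor = transition_alpha(3.5, mS)
        assert alpha == pytest.approx(expected_alpha, rel=1e-12)
        assert factor == pytest.approx(
            math.sin(math.pi * expected_alpha / 2) ** 3 / expected_alpha, rel=1e-12
        )

    def test_central_transition_is_reference(self):
        alpha, factor = transition_alpha(3.5, -0.5)
        assert alpha == 1.0 and factor == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 9), st.data())
    def test_alpha_symmetry(self, twos, data):
        """alpha(mS) = alpha(-mS - 1): transitions mirror about the center."""
        s = twos / 2.0
        levels = [-s + k for k in range(int(2 * s))]
        mS = data.draw(st.sampled_from(levels))
        if -mS - 1 in levels:
            a1, _ = transition_alpha(s, mS)
            a2, _ = transition_alpha(s, -mS - 1)
            assert a1 == pytest.approx(a2, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transition_alpha(3.5, 3.5)  # no level above +7/2
        with pytest.raises(ValueError):
            transition_alpha(3.5, 0.2)


class TestBoltzmann:
    def test_high_temperature_limit(self):
        w = boltzmann_weights([0, 1000, 2000], 1e9)
        assert np.allclose(w, 1 / 3, atol=1e-6)

    def test_closed_form_two_levels(self):
        # levels split by the W-band quantum; T chosen so that ratio = 1/e
        nu = 95_000.0  # MHz
        t_equiv = nu / 20836.61912  # ~4.56 K
        w = boltzmann_weights([0.0, nu], t_equiv)
        assert w[1] / w[0] == pytest.approx(math.exp(-1), rel=1e-9)

    def test_population_ordering_opposite_to_energy(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(-1e4, 1e4, 8)
        w = boltzmann_weights(e, 5.0)
        assert np.all(np.argsort(w) == np.argsort(e)[::-1])
        assert w.sum() == pytest.approx(1.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_weights([0, 1], 0.0)


class TestResonanceFields:
    def test_zeeman_collapse_all_transitions_one_field(self):
        sys0 = SpinSystem(D=0, E=0, g=1.992)
        tt = resonance_fields(sys0, Orientation(0.5, 0.3), 95.0, (3000, 3800))
        assert len(tt) == 7
        expected = 95_000.0 / (1.992 * BOHR_MHZ_PER_MT)
        assert np.allclose(tt.table.resonance_field_mT, expected, atol=1e-3)

    def test_ct_shift_bounded_by_second_order(self):
        sys = SpinSystem(D=1200, E=0, g=1.992)
        tt = resonance_fields(sys, Orientation(0.0, 0.0), 95.0, (3000, 3800))
        ct = tt.table[tt.table.mS == -0.5].iloc[0]
        zeeman_field = 95_000.0 / (1.992 * BOHR_MHZ_PER_MT)
        second_order_mT = (1200.0**2 / 95_000.0) / (1.992 * BOHR_MHZ_PER_MT)
        assert abs(ct.resonance_field_mT - zeeman_field) < second_order_mT

    @pytest.mark.parametrize("theta,phi", [(0.0, 0.0), (0.7, 0.4), (1.4, 2.2)])
    def test_ct_present_for_all_orientations(self, theta, phi):
        sys = SpinSystem(D=4200, E=440)
        tt = resonance_fields(sys, Orientation(theta, phi), 94.9, (3200, 3620))
        assert (-0.5) in set(tt.table.mS)

    def test_against_dense_sweep_oracle(self):
        """Bisection roots agree with a brute-force 0.01 mT field sweep."""
        sys = SpinSystem(D=2500, E=300)
        orient = Orientation(0.9, 0.5)
        nu = 94.9e3
        window = (3250, 3550)
        tt = resonance_fields(sys, orient, 94.9, window)

        fields = np.arange(window[0], window[1], 0.01)
        from gdrelax.spin_core import spin_operators, zfs_hamiltonian

        sx, sy, sz = spin_operators(3.5)
        n = orient.direction()
        hdir = sys.g * BOHR_MHZ_PER_MT * (n[0] * sx + n[1] * sy + n[2] * sz)
        hzfs = zfs_hamiltonian(3.5, sys.D, sys.E)
        ev = np.linalg.eigvalsh(fields[:, None, None] * hdir + hzfs)
        gaps = np.diff(ev, axis=1)
        for _, row in tt.table.iterrows():
            t = int(row.mS + 3.5)
            sign_change = np.nonzero(np.diff(np.sign(gaps[:, t] - nu)))[0]
            assert len(sign_change) >= 1
            brute = fields[sign_change[0]]
            assert abs(brute - row.resonance_field_mT) <= 0.02

    def test_out_of_window_transitions_omitted(self):
        sys = SpinSystem(D=4200, E=440)
        tt = resonance_fields(sys, Orientation(0.1, 0.0), 94.9, (3400, 3420))
        assert 0 < len(tt) < 7
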