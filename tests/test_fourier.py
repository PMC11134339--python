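"""Fourier decomposition of iPRCs and the locking-phase prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pacelock.errors import InputError, NoLockingError
from pacelock.fourier import (decompose, orthogonality_check, partial_sum,
                              predicted_locking_phase, triangular_closed_form)
from pacelock.phase import IPRC, TriangularIPRC


class CosineIPRC(IPRC):
    """Z(phi) = cos(2 pi phi): a single-mode input with known transform."""

    def _eval_unit(self, phi):
        return np.cos(2 * np.pi * phi)


class ConstantIPRC(IPRC):
    def __init__(self, c):
        self.c = c

    def _eval_unit(self, phi):
        return np.full_like(phi, self.c)


class TestDecompose:
    def test_pure_cosine_is_a_single_mode(self):
        m = decompose(CosineIPRC(), 5)
        assert m.z0 == pytest.approx(0.0, abs=1e-12)
        assert m.amp[0] == pytest.approx(1.0, abs=1e-9)
        assert m.angle[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(m.amp[1:] < 1e-9)

    def test_constant_has_only_the_mean_term(self):
        m = decompose(ConstantIPRC(0.37), 5)
        assert m.z0 == pytest.approx(0.37, abs=1e-12)
        assert np.all(m.amp < 1e-12)

    def test_skewed_triangle_fundamental(self):
        # theta = 0.9: closed form gives Z1C ~ -0.1075, Z1S ~ -0.3309, D1 = 0.3
        m = decompose(TriangularIPRC(0.9), 3)
        assert m.zc[0] == pytest.approx(-0.1075, abs=5e-4)
        assert m.zs[0] == pytest.approx(-0.3309, abs=5e-4)
        assert m.angle[0] == pytest.approx(0.3, abs=1e-6)

    @pytest.mark.parametrize("theta", [0.3, 0.5, 0.7, 0.9])
    def test_matches_closed_form_to_1e6(self, theta):
        m = decompose(TriangularIPRC(theta), 10)
        for n in range(1, 11):
            znc, zns = triangular_closed_form(theta, n)
            assert m.zc[n - 1] == pytest.approx(znc, abs=1e-6)
            assert m.zs[n - 1] == pytest.approx(zns, abs=1e-6)

    @pytest.mark.parametrize("theta", np.linspace(0.05, 0.95, 10))
    def test_fundamental_angle_identity(self, theta):
        m = decompose(TriangularIPRC(theta), 1)
        assert m.angle[0] == pytest.approx((0.75 - theta / 2) % 1.0, abs=1e-6)

    def test_quadrature_halving_converges(self):
        a = decompose(TriangularIPRC(0.7), 5, grid=32768)
        b = decompose(TriangularIPRC(0.7), 5, grid=65536)
        assert np.max(np.abs(a.zc - b.zc)) < 1e-8
        assert np.max(np.abs(a.zs - b.zs)) < 1e-8

    def test_parseval(self):
        tri = TriangularIPRC(0.6)
        phi = (np.arange(1 << 16) + 0.5) / (1 << 16)
        power = float(np.mean(tri(phi) ** 2))
        m = decompose(tri, 40)
        series = m.z0 ** 2 + 0.5 * np.sum(m.amp ** 2)
        # truncation error shrinks with the number of modes retained
        short = m.z0 ** 2 + 0.5 * np.sum(m.amp[:5] ** 2)
        assert abs(power - series) < abs(power - short)
        assert series == pytest.approx(power, rel=1e-4)


class TestTriangularClosedForm:
    def test_symmetric_fundamental(self):
        znc, zns = triangular_closed_form(0.5, 1)
        assert znc == pytest.approx(-4 / np.pi ** 2)
        assert zns == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_even_modes_vanish(self):
        znc, zns = triangular_closed_form(0.5, 2)
        assert znc == pytest.approx(0.0, abs=1e-15)
        assert zns == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_theta_rejected(self):
        with pytest.raises(InputError):
            triangular_closed_form(0.0, 1)
        with pytest.raises(InputError):
            triangular_closed_form(1.0, 1)

    def test_amplitudes_decay_as_inverse_square(self):
        # log-log slope of the odd-mode amplitudes of the symmetric triangle
        ns = np.arange(1, 11, 2)
        amps = [np.hypot(*triangular_closed_form(0.5, n)) for n in ns]
        slope = np.polyfit(np.log(ns), np.log(amps), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.05)


class TestPartialSum:
    def test_zero_terms_is_the_mean(self):
        m = decompose(TriangularIPRC(0.9), 4)
        phi = np.linspace(0, 1, 7, endpoint=False)
        assert np.allclose(partial_sum(m, 0, phi), m.z0)

    def test_l2_error_strictly_decreases(self):
        tri = TriangularIPRC(0.9)
        m = decompose(tri, 4)
        phi = (np.arange(4096) + 0.5) / 4096
        truth = tri(phi)
        errs = [np.mean((partial_sum(m, n, phi) - truth) ** 2)
                for n in range(5)]
        assert np.all(np.diff(errs) < 0)


class TestLockingPrediction:
    def test_symmetric_triangle_locks_at_half(self):
        m = decompose(TriangularIPRC(0.5), 2)
        stable, unstable = predicted_locking_phase(m, 1)
        assert stable == pytest.approx(0.5, abs=1e-6)
        assert unstable == pytest.approx(0.0, abs=1e-6)

    def test_cosine_locks_at_zero(self):
        stable, _ = predicted_locking_phase(decompose(CosineIPRC(), 1), 1)
        assert stable == pytest.approx(0.0, abs=1e-9)

    def test_vanishing_mode_raises(self):
        # the symmetric triangle has no second mode: driving at the second
        # harmonic is orthogonal to the iPRC
        m = decompose(TriangularIPRC(0.5), 2)
        with pytest.raises(NoLockingError):
            predicted_locking_phase(m, 2)


class TestOrthogonality:
    def test_equal_modes_equal_angles(self):
        assert orthogonality_check(3, 3, 0.2, 0.2) == pytest.approx(0.5,
                                                                    abs=1e-10)

    def test_distinct_modes_vanish(self):
        assert orthogonality_check(2, 5, 0.11, 0.87) == pytest.approx(
            0.0, abs=1e-10)

    def test_quarter_cycle_shift_makes_sine_against_cosine(self):
        assert orthogonality_check(1, 1, 0.25, 0.0) == pytest.approx(
            0.0, abs=1e-10)


@given(st.floats(0.05, 0.95), st.integers(1, 6),
       st.floats(0, 1), st.floats(0.1, 2.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_reconstruction_identity(theta, n, delta, amp):
    """ZnC cos + ZnS sin == Zn cos(2 pi [n phi + Dn]) pointwise, for both
    closed-form triangle coefficients and arbitrary (amp, angle) pairs."""
    phi = np.linspace(0, 1, 41)
    znc, zns = triangular_closed_form(theta, n)
    zn = np.hypot(znc, zns)
    dn = np.mod(np.arctan2(-zns, znc) / (2 * np.pi), 1.0)
    lhs = znc * np.cos(2 * np.pi * n * phi) + zns * np.sin(2 * np.pi * n * phi)
    rhs = zn * np.cos(2 * np.pi * (n * phi + dn))
    assert np.allclose(lhs, rhs, atol=1e-9)
    # and the reverse direction from an (amp, angle) parameterization
    znc2 = amp * np.cos(2 * np.pi * delta)
    zns2 = -amp * np.sin(2 * np.pi * delta)
    lhs2 = znc2 * np.cos(2 * np.pi * n * phi) + zns2 * np.sin(2 * np.pi * n * phi)
    rhs2 = amp * np.cos(2 * np.pi * (n * phi + delta))
    assert np.allclose(lhs2, rhs2, atol=1e-9)
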