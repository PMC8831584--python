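"""Coupled-oscillator matrix: dipole tensors, assembly, diagonalization.

The central oracle is the exact closed-form spectrum of two identical
coupled oscillators (bare tensor): omega*sqrt(1 +/- alpha/R^3) twice
transverse, omega*sqrt(1 -/+ 2 alpha/R^3) longitudinal.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from conftest import random_rotation
from optvdw.geometry import Geometry, make_dimer
from optvdw.hamiltonian import (
    ImaginaryFrequencyError,
    assemble_matrix,
    diagonalize,
    dimer_closed_form,
    dipole_tensor,
    gaussian_width,
)
from optvdw.parameters import QDOParams, load_parameters
from optvdw.units import bohr_to_angstrom


def _fd_hessian_of_potential(r, sigma=None, step=1e-3):
    """Numerical Hessian of v(r) = erf(|r|/sigma)/|r| (or 1/|r| bare)."""

    def v(x):
        d = np.linalg.norm(x)
        if sigma is None:
            return 1.0 / d
        return erf(d / sigma) / d

    h = np.empty((3, 3))
    for a in range(3):
        for b in range(3):
            ea, eb = np.zeros(3), np.zeros(3)
            ea[a] = step
            eb[b] = step
            h[a, b] = (
                v(r + ea + eb) - v(r + ea - eb) - v(r - ea + eb) + v(r - ea - eb)
            ) / (4 * step**2)
    return h


class TestDipoleTensor:
    def test_bare_axial_values(self):
        t = dipole_tensor([0.0, 0.0, 2.0])
        assert t[2, 2] == pytest.approx(-2.0 / 8.0, rel=1e-14)
        assert t[0, 0] == pytest.approx(1.0 / 8.0, rel=1e-14)
        assert t[1, 1] == pytest.approx(1.0 / 8.0, rel=1e-14)
        assert np.allclose(t - np.diag(np.diag(t)), 0.0)
        assert np.trace(t) == pytest.approx(0.0, abs=1e-15)

    def test_bare_matches_interaction_hessian(self):
        rng = np.random.default_rng(7)
        r = rng.normal(size=3) * 3.0 + np.array([4.0, 0, 0])
        t = dipole_tensor(r)
        # T = d^2 v / dR_i dR_j = -Hess_r v for v depending on r = R_i - R_j
        assert np.allclose(t, -_fd_hessian_of_potential(r), atol=1e-8)

    def test_damped_matches_interaction_hessian(self):
        rng = np.random.default_rng(8)
        sigma = 1.7
        for _ in range(5):
            r = rng.normal(size=3, scale=1.5)
            if np.linalg.norm(r) < 0.3:
                continue
            t = dipole_tensor(r, sigma)
            assert np.allclose(t, -_fd_hessian_of_potential(r, sigma), atol=1e-6)

    def test_damped_approaches_bare_at_long_range(self):
        sigma = 1.5
        r = np.array([0.0, 0.0, 20.0 * sigma])
        assert np.allclose(dipole_tensor(r, sigma), dipole_tensor(r), rtol=1e-12)

    def test_damped_finite_isotropic_at_contact(self):
        sigma = 1.2
        t0 = dipole_tensor(np.zeros(3), sigma)
        c = 4.0 / (3.0 * math.sqrt(math.pi) * sigma**3)
        assert np.allclose(t0, c * np.eye(3), rtol=1e-12)
        # approach is continuous: tiny separation stays close to the limit
        t_eps = dipole_tensor([1e-7, 0, 0], sigma)
        assert np.allclose(t_eps, t0, rtol=1e-10)

    def test_series_branch_matches_analytic_at_threshold(self):
        # just above the series switchover the analytic branch must agree
        # with the truncated series to far better than the series error
        sigma = 1.0
        zeta = 1.01e-2
        pref = 2.0 / (math.sqrt(math.pi) * sigma**3)
        c_t = pref * (2.0 / 3.0 - 0.4 * zeta**2 + zeta**4 / 7.0)
        c_r = 2.0 * pref * (1.0 / 3.0 - 0.6 * zeta**2 + (5.0 / 14.0) * zeta**4)
        t = dipole_tensor([0.0, 0.0, zeta * sigma], sigma)
        assert t[0, 0] == pytest.approx(c_t, rel=1e-8)
        assert t[2, 2] == pytest.approx(c_r, rel=1e-8)

    def test_bare_singular_at_contact(self):
        with pytest.raises(ValueError, match="singular"):
            dipole_tensor(np.zeros(3))

    def test_rotation_covariance(self):
        rng = np.random.default_rng(11)
        r = np.array([1.3, -0.4, 2.2])
        q = random_rotation(rng)
        for sigma in (None, 1.4):
            t_rot = dipole_tensor(q @ r, sigma)
            assert np.allclose(t_rot, q @ dipole_tensor(r, sigma) @ q.T, atol=1e-13)

    def test_gaussian_width_value(self):
        # sigma = (sqrt(2/pi) alpha / 3)^(1/3)
        assert gaussian_width(4.5) == pytest.approx(
            (math.sqrt(2.0 / math.pi) * 1.5) ** (1.0 / 3.0), rel=1e-14
        )


class TestAssembly:
    def test_h_dimer_blocks(self, h_params):
        geo = make_dimer("H", 10.0, units="bohr")
        cm = assemble_matrix(geo, h_params, damping="bare")
        m = cm.matrix
        a, w = 4.5, float(h_params.omega[0])
        theta = w * w * a
        assert np.allclose(np.diag(m)[:3], w**2)
        assert m[2, 5] == pytest.approx(theta * (-2.0 / 1000.0), rel=1e-14)
        assert m[0, 3] == pytest.approx(theta * (1.0 / 1000.0), rel=1e-14)
        assert np.allclose(m, m.T)

    def test_atom_count_mismatch(self, h_params):
        with pytest.raises(ValueError, match="atoms"):
            assemble_matrix(Geometry(["H"], np.zeros((1, 3)) + [[0, 0, 1]]), h_params)

    def test_bare_trace_conservation(self, h_params):
        # the bare tensor is traceless, so sum(omega_bar^2) = sum(3 omega_i^2)
        geo = make_dimer("H", 6.0, units="bohr")
        modes = diagonalize(assemble_matrix(geo, h_params, "bare"))
        assert modes.frequencies**2 @ np.ones(6) == pytest.approx(
            6.0 * h_params.omega[0] ** 2, rel=1e-13
        )

    def test_unknown_damping(self, h_params):
        with pytest.raises(ValueError, match="damping"):
            assemble_matrix(make_dimer("H", 5.0), h_params, damping="fermi")


class TestClosedFormOracle:
    def test_frequencies_and_labels(self, h_alpha_omega):
        a, w = h_alpha_omega
        cf = dimer_closed_form(a, w, 10.0)
        rt3 = a / 1000.0
        assert cf.frequencies[0] == pytest.approx(w * math.sqrt(1 - 2 * rt3), rel=1e-14)
        assert cf.frequencies[-1] == pytest.approx(w * math.sqrt(1 + 2 * rt3), rel=1e-14)
        assert "z+" in cf.labels[0] and "z-" in cf.labels[-1]

    def test_matches_numerical_diagonalization(self, h_params):
        geo = make_dimer("H", 10.0, units="bohr")
        modes = diagonalize(assemble_matrix(geo, h_params, "bare"))
        cf = dimer_closed_form(4.5, float(h_params.omega[0]), 10.0)
        assert np.allclose(modes.frequencies, cf.frequencies, rtol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.5, 40.0),
        omega=st.floats(0.05, 1.5),
        margin=st.floats(1.3, 8.0),
        seed=st.integers(0, 2**16),
    )
    def test_random_dimers_match_closed_form(self, alpha, omega, margin, seed):
        # keep 2 alpha / R^3 < 1 by construction via the margin factor
        r = margin * (2.0 * alpha) ** (1.0 / 3.0)
        rng = np.random.default_rng(seed)
        q = random_rotation(rng)
        coords = np.vstack([np.zeros(3), q @ np.array([0.0, 0.0, r])])
        geo = Geometry(["X1", "X2"], bohr_to_angstrom(coords))
        params = QDOParams(alpha0=[alpha, alpha], omega=[omega, omega])
        modes = diagonalize(assemble_matrix(geo, params, "bare"))
        cf = dimer_closed_form(alpha, omega, r)
        assert np.allclose(modes.frequencies, cf.frequencies, rtol=1e-10, atol=0.0)
        assert modes.ground_state_energy == pytest.approx(
            0.5 * cf.frequencies.sum(), rel=1e-12
        )

    def test_dispersion_limit(self, h_alpha_omega):
        # E0(R) - E0(inf) -> -(3/4) alpha^2 omega / R^6 at large R
        a, w = h_alpha_omega
        for r in (40.0, 80.0):
            cf = dimer_closed_form(a, w, r)
            e_int = 0.5 * cf.frequencies.sum() - 3.0 * w
            assert e_int == pytest.approx(-0.75 * a**2 * w / r**6, rel=5e-3)

    def test_collapse_raises(self, h_alpha_omega):
        a, w = h_alpha_omega
        with pytest.raises(ImaginaryFrequencyError):
            dimer_closed_form(a, w, 2.0)  # 2 alpha / R^3 = 9/8 > 1

    def test_numerical_collapse_raises(self, h_params):
        geo = make_dimer("H", 2.0, units="bohr")
        with pytest.raises(ImaginaryFrequencyError):
            diagonalize(assemble_matrix(geo, h_params, "bare"))

    def test_damping_prevents_collapse(self, h_params):
        geo = make_dimer("H", 2.0, units="bohr")
        modes = diagonalize(assemble_matrix(geo, h_params, "gaussian"))
        assert np.all(modes.frequencies > 0)


class TestDiagonalization:
    def test_rotation_invariance(self, benzene_params):
        from optvdw.geometry import make_benzene

        geo = make_benzene()
        rng = np.random.default_rng(5)
        rotated = geo.rotated(random_rotation(rng))
        f0 = diagonalize(assemble_matrix(geo, benzene_params)).frequencies
        f1 = diagonalize(assemble_matrix(rotated, benzene_params)).frequencies
        assert np.allclose(f0, f1, rtol=1e-11)

    def test_translation_invariance(self, benzene_params):
        from optvdw.geometry import make_benzene

        geo = make_benzene()
        f0 = diagonalize(assemble_matrix(geo, benzene_params)).frequencies
        f1 = diagonalize(assemble_matrix(geo.translated([3.0, -2.0, 7.0]), benzene_params)).frequencies
        assert np.allclose(f0, f1, rtol=1e-12)

    def test_eigenvectors_orthonormal(self, h_params):
        modes = diagonalize(assemble_matrix(make_dimer("H", 4.0), h_params))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        assert np.allclose(gram, np.eye(6), atol=1e-12)

    def test_single_atom_modes(self):
        p = load_parameters(["C"])
        geo = Geometry(["C"], np.zeros((1, 3)) + [[1.0, 2.0, 3.0]])
        modes = diagonalize(assemble_matrix(geo, p))
        assert np.allclose(modes.frequencies, p.omega[0], rtol=1e-14)
        assert modes.ground_state_energy == pytest.approx(1.5 * p.omega[0])
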