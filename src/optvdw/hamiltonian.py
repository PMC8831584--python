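"""Coupled quantum-Drude-oscillator (MBD) Hamiltonian.

The model Hamiltonian for N atoms couples mass-weighted dipole
displacements xi_i through the dipole-dipole tensor,

    H = sum_i ( p_i^2/2 + omega_i^2 xi_i^2 / 2 )
        + sum_{i != j} theta_ij xi_i . T_ij . xi_j ,
    theta_ij = omega_i omega_j sqrt(alpha_i^0 alpha_j^0),

so the potential-energy quadratic form is the 3N x 3N matrix with diagonal
blocks omega_i^2 I and off-diagonal blocks theta_ij T_ij. Its eigenvalues
are the squared collective frequencies; half their square-root sum is the
ground-state (dispersion-containing) energy, and single-mode excitations
are the model's excitons.

T is the two-position second derivative of the Coulomb interaction,
optionally damped at short range by Gaussian charge overlap
(v = erf(R/sigma)/R), which keeps the model finite for overlapping atoms.
All quantities here are in Hartree atomic units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import erf

from .geometry import Geometry
from .parameters import QDOParams

__all__ = [
    "CouplingMatrix",
    "ModeSet",
    "DimerClosedForm",
    "ImaginaryFrequencyError",
    "dipole_tensor",
    "gaussian_width",
    "assemble_matrix",
    "diagonalize",
    "dimer_closed_form",
]

#: eigenvalues of the squared-frequency matrix below this (Ha^2) are an error
EIGENVALUE_TOLERANCE = 1e-12


class ImaginaryFrequencyError(ValueError):
    """A squared collective frequency came out negative (oscillator collapse)."""


@dataclass
class CouplingMatrix:
    """The 3N x 3N squared-frequency quadratic form of the coupled oscillators."""

    matrix: np.ndarray
    damping: str  # "bare" or "gaussian"
    sigma: np.ndarray | None = None  # per-atom Gaussian widths (bohr), damped mode

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ModeSet:
    """Collective modes: ascending frequencies (Ha), orthonormal eigenvectors.

    Column k of ``eigenvectors`` holds the collective coordinate of mode k
    over the stacked per-atom displacement components (i, beta) -> 3*i+beta.
    """

    frequencies: np.ndarray
    eigenvectors: np.ndarray
    ground_state_energy: float

    @property
    def n_modes(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.n_modes // 3


def gaussian_width(alpha0):
    """Gaussian charge-cloud width sigma = (sqrt(2/pi) * alpha0 / 3)^(1/3) (bohr)."""
    return (np.sqrt(2.0 / np.pi) * np.asarray(alpha0, float) / 3.0) ** (1.0 / 3.0)


def _tensor_coefficients(d, sigma):
    """Radial coefficients (C_T, C_R) of T = C_T (I - rr^) + C_R rr^.

    ``sigma=None`` gives the bare tensor C_T = 1/d^3, C_R = -2/d^3. The
    damped form derives from v = erf(d/sigma)/d; a series branch keeps it
    numerically stable (and finite, isotropic) as d -> 0.
    """
    d = np.asarray(d, float)
    if sigma is None:
        d3 = d**3
        return 1.0 / d3, -2.0 / d3
    sigma = np.broadcast_to(np.asarray(sigma, float), d.shape).copy()
    zeta = np.divide(d, sigma, out=np.zeros_like(d), where=sigma > 0)
    small = zeta < 1e-2
    pref = 2.0 / (np.sqrt(np.pi) * sigma**3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = erf(zeta)
        gp = (2.0 / np.sqrt(np.pi)) * np.exp(-(zeta**2)) / sigma  # d erf(d/sigma)/dd
        c_t = g / d**3 - gp / d**2
        c_r = 2.0 * gp / sigma**2 + 2.0 * gp / d**2 - 2.0 * g / d**3
    z2 = zeta**2
    c_t_series = pref * (2.0 / 3.0 - 0.4 * z2 + z2**2 / 7.0)
    c_r_series = 2.0 * pref * (1.0 / 3.0 - 0.6 * z2 + (5.0 / 14.0) * z2**2)
    c_t = np.where(small, c_t_series, c_t)
    c_r = np.where(small, c_r_series, c_r)
    return c_t, c_r


def dipole_tensor(r, sigma_pair=None):
    """Dipole-dipole interaction tensor d^2 v / dR_i dR_j for one atom pair.

    ``r`` is the separation vector R_i - R_j in bohr. With ``sigma_pair``
    None the bare Coulomb tensor (I - 3 rr^)/r^3 is returned; otherwise the
    erf-damped tensor for combined Gaussian width ``sigma_pair``.
    """
    r = np.asarray(r, float)
    d = float(np.linalg.norm(r))
    if sigma_pair is None:
        if d == 0.0:
            raise ValueError("bare dipole tensor is singular at zero separation")
        sigma = None
    else:
        sigma_pair = float(sigma_pair)
        if sigma_pair < 0:
            raise ValueError("sigma must be non-negative")
        if sigma_pair == 0.0:
            return dipole_tensor(r, None)
        sigma = sigma_pair
    if d == 0.0:
        # isotropic overlap limit of the damped tensor
        c_iso = 4.0 / (3.0 * math.sqrt(math.pi) * sigma**3)
        return c_iso * np.eye(3)
    c_t, c_r = _tensor_coefficients(np.array(d), None if sigma is None else np.array(sigma))
    rhat = r / d
    proj = np.outer(rhat, rhat)
    return float(c_t) * (np.eye(3) - proj) + float(c_r) * proj


def _pair_tensors(rvec, d, sigma_pair):
    """Vectorized dipole tensors for pair arrays: rvec (..., 3), d (...)."""
    c_t, c_r = _tensor_coefficients(d, sigma_pair)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = rvec / d[..., None]
    rhat = np.nan_to_num(rhat)
    proj = rhat[..., :, None] * rhat[..., None, :]
    eye = np.eye(3)
    return c_t[..., None, None] * (eye - proj) + c_r[..., None, None] * proj


def assemble_matrix(geometry: Geometry, params: QDOParams, damping: str = "gaussian") -> CouplingMatrix:
    """Build the 3N x 3N coupled-oscillator matrix for a geometry.

    Diagonal blocks are omega_i^2 I; off-diagonal blocks are
    theta_ij T_ij with theta_ij = omega_i omega_j sqrt(alpha_i alpha_j).
    In damped mode the pair width is sigma_ij = sqrt(sigma_i^2 + sigma_j^2).
    """
    if damping not in ("bare", "gaussian"):
        raise ValueError(f"unknown damping mode {damping!r}")
    if geometry.n_atoms != params.n_atoms:
        raise ValueError(
            f"geometry has {geometry.n_atoms} atoms but params has {params.n_atoms}"
        )
    n = geometry.n_atoms
    x = geometry.coords_bohr()
    rvec = x[:, None, :] - x[None, :, :]
    d = np.linalg.norm(rvec, axis=-1)
    off = ~np.eye(n, dtype=bool)
    sigma = None
    sigma_pair = None
    if damping == "gaussian":
        sigma = gaussian_width(params.alpha0)
        sigma_pair = np.sqrt(sigma[:, None] ** 2 + sigma[None, :] ** 2)
    elif n > 1 and d[off].min() == 0.0:
        raise ValueError("overlapping atoms are singular with the bare tensor")
    tensors = _pair_tensors(rvec, np.where(off, d, 1.0), sigma_pair)
    theta = (
        params.omega[:, None]
        * params.omega[None, :]
        * np.sqrt(params.alpha0[:, None] * params.alpha0[None, :])
    )
    blocks = np.where(off[:, :, None, None], theta[:, :, None, None] * tensors, 0.0)
    idx = np.arange(n)
    blocks[idx, idx] = params.omega[:, None, None] ** 2 * np.eye(3)
    matrix = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    matrix = 0.5 * (matrix + matrix.T)
    return CouplingMatrix(matrix=matrix, damping=damping, sigma=sigma)


def diagonalize(cm: CouplingMatrix) -> ModeSet:
    """Diagonalize the coupled-oscillator matrix into collective modes.

    Frequencies are the square roots of the eigenvalues (ascending); a
    deterministic sign convention makes each eigenvector's largest-magnitude
    component positive. Negative eigenvalues below -1e-12 Ha^2 raise
    :class:`ImaginaryFrequencyError` (oscillator collapse); tiny negative
    values are clamped to zero.
    """
    m = np.asarray(cm.matrix, float)
    if not np.all(np.isfinite(m)):
        raise ValueError("coupling matrix has non-finite entries")
    evals, evecs = scipy.linalg.eigh(m)
    if evals[0] < -EIGENVALUE_TOLERANCE:
        raise ImaginaryFrequencyError(
            f"negative squared frequency {evals[0]:.3e} Ha^2: the coupled "
            "oscillators collapse (bare tensor at short range?)"
        )
    evals = np.clip(evals, 0.0, None)
    # fix eigenvector signs: largest-magnitude component positive
    lead = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[lead, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    freqs = np.sqrt(evals)
    return ModeSet(
        frequencies=freqs,
        eigenvectors=evecs,
        ground_state_energy=0.5 * float(freqs.sum()),
    )


@dataclass
class DimerClosedForm:
    """Exact modes of two identical coupled QDOs at separation R (bare tensor).

    With the reduced coupling Rt3 = alpha0 / R^3, the six collective
    frequencies are omega*sqrt(1 +/- Rt3) for x and y (transverse) and
    omega*sqrt(1 -/+ 2 Rt3) for z (longitudinal); the symmetric head-to-tail
    z combination (xi1 + xi2) is the lowest branch.
    """

    reduced_coupling: float  # alpha0 / R^3
    frequencies: np.ndarray  # ascending, 6 entries
    labels: list[str]  # matching mode-geometry labels

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.frequencies))


def dimer_closed_form(alpha0: float, omega: float, r_bohr: float) -> DimerClosedForm:
    """Closed-form two-oscillator spectrum used as an exact oracle."""
    if r_bohr <= 0:
        raise ValueError(f"separation must be positive, got {r_bohr}")
    if alpha0 <= 0 or omega <= 0:
        raise ValueError("alpha0 and omega must be positive")
    rt3 = alpha0 / r_bohr**3
    if 2.0 * rt3 >= 1.0:
        raise ImaginaryFrequencyError(
            f"2*alpha0/R^3 = {2 * rt3:.4g} >= 1: imaginary z-mode frequency"
        )
    entries = [
        (omega * math.sqrt(1.0 - 2.0 * rt3), "z+ (xi1+xi2, aligned)"),
        (omega * math.sqrt(1.0 - rt3), "x- (xi1-xi2)"),
        (omega * math.sqrt(1.0 - rt3), "y- (xi1-xi2)"),
        (omega * math.sqrt(1.0 + rt3), "x+ (xi1+xi2)"),
        (omega * math.sqrt(1.0 + rt3), "y+ (xi1+xi2)"),
        (omega * math.sqrt(1.0 + 2.0 * rt3), "z- (xi1-xi2, antialigned)"),
    ]
    entries.sort(key=lambda e: e[0])
    return DimerClosedForm(
        reduced_coupling=rt3,
        frequencies=np.array([e[0] for e in entries]),
        labels=[e[1] for e in entries],
    )
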