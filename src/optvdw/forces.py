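"""Optical van der Waals forces: gradients of exciton energies.

The force on atom i when mode k is excited is F_i = -grad_i omega_bar_k
(plus, optionally, the ground-state dispersion gradient -grad_i E0).
Gradients come from first-order (Hellmann-Feynman) perturbation theory on
the squared-frequency matrix M:

    d omega_bar_k / d lambda = (1 / 2 omega_bar_k) * c_k^T (dM/d lambda) c_k.

Bare-tensor spatial derivatives are analytic; damped-tensor derivatives use
central finite differences of the analytic tensor (step 1e-5 bohr), whose
error is bounded by the finite-difference oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .hamiltonian import (
    ModeSet,
    _pair_tensors,
    assemble_matrix,
    diagonalize,
    gaussian_width,
)
from .parameters import QDOParams
from .units import ANGSTROM_PER_BOHR, EV_PER_HARTREE

__all__ = [
    "ForceField",
    "mode_gradient",
    "ground_state_gradient",
    "optical_force_field",
    "collectivity",
    "DegenerateModeError",
]

#: modes closer than this (Ha) count as degenerate for gradient purposes
GRADIENT_DEGENERACY_GAP = 1e-8
#: finite-difference step for damped-tensor spatial derivatives (bohr)
TENSOR_FD_STEP = 1e-5


class DegenerateModeError(ValueError):
    """Requested a single-mode gradient inside a degenerate subspace."""


@dataclass
class ForceField:
    """Per-atom force vectors for one excited mode (hartree/bohr)."""

    mode: int  # 1-based
    forces: np.ndarray  # (N, 3) Ha/bohr
    includes_ground_state: bool = False

    @property
    def forces_ev_per_angstrom(self) -> np.ndarray:
        return self.forces * (EV_PER_HARTREE / ANGSTROM_PER_BOHR)

    def net_force(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    def net_torque(self, coords_bohr: np.ndarray) -> np.ndarray:
        rel = coords_bohr - coords_bohr.mean(axis=0)
        return np.cross(rel, self.forces).sum(axis=0)


def _bare_tensor_derivative(rvec: np.ndarray) -> np.ndarray:
    """d T^{ab} / d r^c for the bare tensor, vectorized over leading axes."""
    rvec = np.asarray(rvec, float)
    d = np.linalg.norm(rvec, axis=-1)
    d = np.where(d == 0.0, 1.0, d)  # self pairs are zeroed by the caller
    d5 = d**5
    d7 = d**7
    eye = np.eye(3)
    r = rvec
    out = (
        -3.0 * eye[None, :, :, None] * r[..., None, None, :] / d5[..., None, None, None]
        - 3.0
        * (
            eye[None, :, None, :] * r[..., None, :, None]
            + eye[None, None, :, :] * r[..., :, None, None]
        )
        / d5[..., None, None, None]
        + 15.0
        * r[..., :, None, None]
        * r[..., None, :, None]
        * r[..., None, None, :]
        / d7[..., None, None, None]
    )
    return out


def _damped_tensor_derivative(rvec: np.ndarray, sigma_pair: np.ndarray, step: float = TENSOR_FD_STEP) -> np.ndarray:
    """Central finite differences of the damped tensor over the pair vector."""
    rvec = np.asarray(rvec, float)
    shape = rvec.shape[:-1]
    out = np.empty(shape + (3, 3, 3))
    for c in range(3):
        shift = np.zeros(3)
        shift[c] = step
        plus = rvec + shift
        minus = rvec - shift
        t_plus = _pair_tensors(plus, np.linalg.norm(plus, axis=-1), sigma_pair)
        t_minus = _pair_tensors(minus, np.linalg.norm(minus, axis=-1), sigma_pair)
        out[..., c] = (t_plus - t_minus) / (2.0 * step)
    return out


def _weighted_matrix_gradient(
    x: np.ndarray,
    theta: np.ndarray,
    sigma_pair: np.ndarray | None,
    weights: np.ndarray,
    chunk: int = 64,
) -> np.ndarray:
    """grad[i, c] = sum_pq W_pq dM_pq/dR_i^c for symmetric weight matrix W."""
    n = x.shape[0]
    wb = weights.reshape(n, 3, n, 3).transpose(0, 2, 1, 3)  # (i, j, a, b)
    grad = np.zeros((n, 3))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rvec = x[start:stop, None, :] - x[None, :, :]  # (m, n, 3)
        if sigma_pair is None:
            dT = _bare_tensor_derivative(rvec)
        else:
            dT = _damped_tensor_derivative(rvec, sigma_pair[start:stop, :])
        idx = np.arange(start, stop)
        dT[idx - start, idx] = 0.0  # no self term
        # blocks (i,j) and (j,i) both depend on R_i -> factor 2
        grad[start:stop] = 2.0 * np.einsum(
            "ij,ijab,ijabc->ic", theta[start:stop, :], wb[start:stop, :], dT
        )
    return grad


def _prepare(geometry: Geometry, params: QDOParams, damping: str):
    x = geometry.coords_bohr()
    theta = (
        params.omega[:, None]
        * params.omega[None, :]
        * np.sqrt(params.alpha0[:, None] * params.alpha0[None, :])
    )
    sigma_pair = None
    if damping == "gaussian":
        s = gaussian_width(params.alpha0)
        sigma_pair = np.sqrt(s[:, None] ** 2 + s[None, :] ** 2)
    return x, theta, sigma_pair


def _degenerate_subspace(freqs: np.ndarray, k0: int) -> np.ndarray:
    """0-based indices of the degeneracy subspace containing mode k0."""
    members = [k0]
    lo, hi = k0, k0
    while lo > 0 and freqs[lo] - freqs[lo - 1] <= GRADIENT_DEGENERACY_GAP:
        lo -= 1
        members.append(lo)
    while hi < freqs.size - 1 and freqs[hi + 1] - freqs[hi] <= GRADIENT_DEGENERACY_GAP:
        hi += 1
        members.append(hi)
    return np.array(sorted(members))


def mode_gradient(
    geometry: Geometry,
    params: QDOParams,
    damping: str,
    k: int,
    subspace: bool = False,
    modes: ModeSet | None = None,
) -> np.ndarray:
    """Gradient of the mode-k excitation energy w.r.t. atomic positions.

    ``k`` is 1-based ascending in energy. For a mode inside a degenerate
    subspace the single-mode gradient is basis-dependent; it is refused
    unless ``subspace=True``, which returns the subspace-mean gradient
    (the basis-invariant trace). Returns (N, 3) in hartree/bohr.
    """
    if modes is None:
        modes = diagonalize(assemble_matrix(geometry, params, damping))
    if not 1 <= k <= modes.n_modes:
        raise ValueError(f"mode index {k} out of range 1..{modes.n_modes}")
    freqs = modes.frequencies
    k0 = k - 1
    if freqs[k0] <= 0:
        raise ValueError(f"mode {k} has zero frequency; gradient undefined")
    members = _degenerate_subspace(freqs, k0)
    if members.size > 1 and not subspace:
        raise DegenerateModeError(
            f"mode {k} is degenerate with modes {sorted(int(m) + 1 for m in members if m != k0)}; "
            "pass subspace=True for the basis-invariant subspace-mean gradient"
        )
    c = modes.eigenvectors[:, members]
    # W = sum_m c_m c_m^T / (2 omega_m n_sub): gradient of the subspace-mean frequency
    w = (c / (2.0 * freqs[members] * members.size)) @ c.T
    x, theta, sigma_pair = _prepare(geometry, params, damping)
    return _weighted_matrix_gradient(x, theta, sigma_pair, w)


def ground_state_gradient(
    geometry: Geometry,
    params: QDOParams,
    damping: str,
    modes: ModeSet | None = None,
) -> np.ndarray:
    """Gradient of E0 = sum_k omega_bar_k / 2 (the dispersion force is -this)."""
    if modes is None:
        modes = diagonalize(assemble_matrix(geometry, params, damping))
    freqs = modes.frequencies
    keep = freqs > 1e-12
    c = modes.eigenvectors[:, keep]
    w = (c / (4.0 * freqs[keep])) @ c.T
    x, theta, sigma_pair = _prepare(geometry, params, damping)
    return _weighted_matrix_gradient(x, theta, sigma_pair, w)


def optical_force_field(
    geometry: Geometry,
    params: QDOParams,
    damping: str,
    k: int,
    include_ground_state: bool = False,
    subspace: bool = False,
    modes: ModeSet | None = None,
) -> ForceField:
    """Optical vdW force field F_i = -grad_i omega_bar_k for excited mode k."""
    grad = mode_gradient(geometry, params, damping, k, subspace=subspace, modes=modes)
    if include_ground_state:
        grad = grad + ground_state_gradient(geometry, params, damping, modes=modes)
    return ForceField(mode=k, forces=-grad, includes_ground_state=include_ground_state)


def collectivity(field) -> dict[str, float]:
    """Participation measures of a force field (or raw per-atom weight array).

    Returns the effective number of participating atoms
    N_eff = 1 / sum_i w_i^2 with w_i = |F_i|^2 / sum_j |F_j|^2, plus the
    maximum single-atom weight. An all-zero field yields NaN entries.
    """
    if isinstance(field, ForceField):
        vectors = field.forces
    else:
        vectors = np.asarray(field, float)
    if vectors.ndim == 1:
        vectors = vectors.reshape(-1, 3)
    mags2 = np.einsum("ij,ij->i", vectors, vectors)
    total = mags2.sum()
    if total == 0.0:
        return {"n_eff": float("nan"), "max_weight": float("nan")}
    w = mags2 / total
    return {"n_eff": float(1.0 / np.sum(w**2)), "max_weight": float(w.max())}
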