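"""Distance scans, power-law exponents, and optical-vs-dispersion ratios.

The optical vdW interaction energy of mode k is the splitting
Delta_k(R) = omega_bar_k(R) - omega_bar_k(R -> infinity); the dispersion
interaction is E_disp(R) = E0(R) - E0(infinity). Their log-log slopes give
the characteristic power laws (R^-3 for dipole-active modes, R^-6 for
dispersion between two atoms), and the distance where |Delta|/|E_disp|
reaches one is the crossover beyond which optical vdW dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .excitons import splitting_table, track_modes
from .geometry import Geometry
from .hamiltonian import ImaginaryFrequencyError, ModeSet, assemble_matrix, diagonalize
from .parameters import QDOParams

__all__ = [
    "ScanResult",
    "PowerLawFit",
    "scan",
    "fragment_reference",
    "powerlaw_exponent",
    "powerlaw_prefactor",
    "interaction_ratio",
    "crossover_distance",
    "chain_mode_character",
]


@dataclass
class ScanResult:
    """Mode data across a separation scan (distances in angstrom).

    ``frequencies[r, k]`` follows a consistent mode identity k across the
    grid (labels fixed at the largest separation, ascending energy there).
    ``excluded`` flags grid points dropped because the oscillators
    collapsed; ``ambiguous_tracking`` lists (grid index, mode) pairs where
    eigenvector tracking was uncertain (degenerate crossing).
    """

    r_angstrom: np.ndarray
    frequencies: np.ndarray  # (n_R, 3N) hartree
    e0: np.ndarray  # (n_R,) hartree
    reference_frequencies: np.ndarray  # (3N,) hartree
    reference_e0: float
    splittings: np.ndarray  # (n_R, 3N) hartree
    e_disp: np.ndarray  # (n_R,) hartree
    excluded: np.ndarray  # (n_R,) bool
    ambiguous_tracking: list = field(default_factory=list)
    mode_sets: list = field(default_factory=list)  # ModeSet per kept point, ascending R

    @property
    def n_modes(self) -> int:
        return self.frequencies.shape[1]


@dataclass
class PowerLawFit:
    exponent: float
    window: tuple[float, float]
    r: np.ndarray
    local_exponents: np.ndarray
    max_residual: float  # max |ln y - fit| over the window


def fragment_reference(fragment_modes: ModeSet, n_copies: int = 2) -> tuple[np.ndarray, float]:
    """Non-interacting asymptote from isolated-fragment modes.

    Returns (sorted frequencies repeated ``n_copies`` times, total E0), the
    exact R -> infinity limit of ``n_copies`` identical fragments.
    """
    freqs = np.sort(np.tile(fragment_modes.frequencies, n_copies))
    return freqs, n_copies * fragment_modes.ground_state_energy


def scan(
    builder: Callable[[float], Geometry],
    params: QDOParams,
    damping: str,
    r_grid: Sequence[float],
    reference: tuple[np.ndarray, float] | None = None,
) -> ScanResult:
    """Diagonalize ``builder(R)`` over a separation grid with mode tracking.

    ``builder`` maps a separation in angstrom to a Geometry with a fixed
    atom ordering. ``reference`` is an optional (frequencies, E0) asymptote
    (see :func:`fragment_reference`); by default the largest grid R serves
    as the R -> infinity stand-in. Grid points where the coupled system
    collapses (imaginary frequency) are flagged and excluded, not fatal.
    """
    r_grid = np.asarray(sorted(float(r) for r in r_grid))
    if r_grid.size < 4:
        raise ValueError("scan needs a grid of at least 4 points")
    mode_sets: list[ModeSet | None] = []
    excluded = np.zeros(r_grid.size, dtype=bool)
    for r in r_grid:
        try:
            mode_sets.append(diagonalize(assemble_matrix(builder(r), params, damping)))
        except ImaginaryFrequencyError:
            mode_sets.append(None)
    excluded[:] = [ms is None for ms in mode_sets]
    kept = [ms for ms in mode_sets if ms is not None]
    if len(kept) < 4:
        raise ValueError("fewer than 4 usable scan points (oscillator collapse)")
    r_kept = r_grid[~excluded]
    # track from the largest R inward: labels = ascending-energy order at R_max
    perms, ambiguous = track_modes(kept[::-1])
    n_pts = len(kept)
    freqs = np.empty((n_pts, kept[0].n_modes))
    e0 = np.empty(n_pts)
    for s, (ms, perm) in enumerate(zip(kept[::-1], perms)):
        freqs[n_pts - 1 - s] = ms.frequencies[perm]
        e0[n_pts - 1 - s] = ms.ground_state_energy
    ambiguous = [(n_pts - 1 - s, k) for s, k in ambiguous]
    if reference is None:
        ref_freqs = freqs[-1].copy()
        ref_e0 = float(e0[-1])
    else:
        ref_freqs = np.asarray(reference[0], float)
        ref_e0 = float(reference[1])
        if ref_freqs.shape[0] != freqs.shape[1]:
            raise ValueError("reference mode count does not match the scan")
    return ScanResult(
        r_angstrom=r_kept,
        frequencies=freqs,
        e0=e0,
        reference_frequencies=ref_freqs,
        reference_e0=ref_e0,
        splittings=splitting_table(freqs, ref_freqs),
        e_disp=e0 - ref_e0,
        excluded=excluded,
        ambiguous_tracking=ambiguous,
        mode_sets=kept,
    )


def chain_mode_character(modes: ModeSet, params: QDOParams | None = None, axis: str = "z"):
    """Classify the modes of a single linear chain (atoms ordered along ``axis``).

    Returns (axial_weight, mirror_parity, dipole_magnitude) arrays. The
    mirror operation reflects the displacement field through the plane
    perpendicular to the chain at its midpoint (atom i -> N-1-i, axial
    component sign-flipped): a uniform head-to-tail dipole pattern has
    parity -1, a one-node (antisymmetric, zero-net-dipole) pattern +1.
    """
    axis_idx = {"x": 0, "y": 1, "z": 2}[axis.lower()]
    n = modes.n_atoms
    c = modes.eigenvectors.reshape(n, 3, modes.n_modes)
    axial_weight = (c[:, axis_idx, :] ** 2).sum(axis=0)
    flip = np.ones(3)
    flip[axis_idx] = -1.0
    reflected = (c[::-1] * flip[None, :, None]).reshape(3 * n, modes.n_modes)
    parity = np.einsum("ik,ik->k", modes.eigenvectors, reflected)
    if params is None:
        amp = np.ones(n)
    else:
        amp = np.sqrt(params.alpha0) * params.omega
    dipole = np.linalg.norm(np.einsum("i,ibk->kb", amp, c), axis=1)
    return axial_weight, parity, dipole


def powerlaw_exponent(r, y, window: tuple[float, float] | None = None) -> PowerLawFit:
    """Least-squares slope of ln|y| vs ln r, plus pointwise local exponents.

    ``window`` restricts the fit to r in [window[0], window[1]]. The sign
    of y must not change inside the window (the log is otherwise undefined).
    """
    r = np.asarray(r, float)
    y = np.asarray(y, float)
    if window is None:
        window = (float(r.min()), float(r.max()))
    mask = (r >= window[0]) & (r <= window[1])
    if mask.sum() < 3:
        raise ValueError(f"need at least 3 points in window {window}, have {int(mask.sum())}")
    rw, yw = r[mask], y[mask]
    if np.any(yw == 0.0):
        raise ValueError("y vanishes inside the fit window")
    if not (np.all(yw > 0) or np.all(yw < 0)):
        raise ValueError("y changes sign inside the fit window; log-log fit undefined")
    lr = np.log(rw)
    ly = np.log(np.abs(yw))
    slope, intercept = np.polyfit(lr, ly, 1)
    resid = ly - (slope * lr + intercept)
    local = np.gradient(ly, lr)
    return PowerLawFit(
        exponent=float(slope),
        window=window,
        r=rw,
        local_exponents=local,
        max_residual=float(np.abs(resid).max()),
    )


def powerlaw_prefactor(r, y, window: tuple[float, float] | None = None) -> tuple[float, float]:
    """(exponent, |prefactor|) of y ~ prefactor * r^exponent on the window."""
    fit = powerlaw_exponent(r, y, window)
    mask = (np.asarray(r, float) >= fit.window[0]) & (np.asarray(r, float) <= fit.window[1])
    lr = np.log(np.asarray(r, float)[mask])
    ly = np.log(np.abs(np.asarray(y, float)[mask]))
    slope, intercept = np.polyfit(lr, ly, 1)
    return float(slope), float(np.exp(intercept))


def interaction_ratio(result: ScanResult, k: int) -> np.ndarray:
    """|Delta_k| / |E_disp| per grid point (1-based mode index).

    Points with exactly zero dispersion interaction come back as NaN (a
    flagged point, not an error).
    """
    if not 1 <= k <= result.n_modes:
        raise ValueError(f"mode index {k} out of range 1..{result.n_modes}")
    delta = np.abs(result.splittings[:, k - 1])
    disp = np.abs(result.e_disp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(disp > 0, delta / np.where(disp > 0, disp, 1.0), np.nan)
    return ratio


def crossover_distance(r, ratio) -> float:
    """Smallest R where the ratio reaches 1 and stays >= 1 at all larger R.

    Linear interpolation in (ln R, ln ratio) between the bracketing points.
    Raises if the ratio never crosses 1 inside the grid (extend the grid).
    """
    r = np.asarray(r, float)
    ratio = np.asarray(ratio, float)
    ok = np.isfinite(ratio)
    r, ratio = r[ok], ratio[ok]
    if r.size < 2:
        raise ValueError("not enough finite ratio points")
    above = ratio >= 1.0
    # last index that is below 1; crossing must persist afterwards
    below_idx = np.nonzero(~above)[0]
    if below_idx.size == 0:
        return float(r[0])
    i = below_idx[-1] + 1
    if i >= r.size:
        raise ValueError(
            "ratio never settles above 1 inside the grid; extend the scan to larger R"
        )
    lr0, lr1 = np.log(r[i - 1]), np.log(r[i])
    if ratio[i - 1] <= 0.0:
        # degenerate bracket: fall back to linear interpolation in the ratio
        t = (1.0 - ratio[i - 1]) / (ratio[i] - ratio[i - 1])
    else:
        lq0, lq1 = np.log(ratio[i - 1]), np.log(ratio[i])
        t = (0.0 - lq0) / (lq1 - lq0)
    return float(np.exp(lr0 + t * (lr1 - lr0)))
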