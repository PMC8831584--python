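"""Per-element quantum-Drude-oscillator parameters.

Each atom is represented by a charged harmonic oscillator with static
dipole polarizability ``alpha0`` (bohr^3) and characteristic frequency
``omega`` (hartree). The frequency follows from the free-atom dispersion
coefficient through the single-oscillator relation

    C6 = (3/4) * alpha0^2 * omega   <=>   omega = 4 C6 / (3 alpha0^2).

The table below holds the standard free-atom (alpha0, C6) reference values
used by Tkatchenko-Scheffler-type van der Waals methods. No environmental
(Hirshfeld) rescaling is done here; callers may pass multiplicative scale
factors instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["QDOParams", "FREE_ATOM_REFERENCE", "load_parameters", "omega_from_c6"]

#: element -> (alpha0 [bohr^3], C6 [hartree bohr^6]), free-atom reference values
FREE_ATOM_REFERENCE: dict[str, tuple[float, float]] = {
    "H": (4.500, 6.50),
    "He": (1.38, 1.46),
    "Li": (164.2, 1387.0),
    "Be": (38.0, 214.0),
    "B": (21.0, 99.5),
    "C": (12.0, 46.6),
    "N": (7.4, 24.2),
    "O": (5.4, 15.6),
    "F": (3.8, 9.52),
    "Ne": (2.67, 6.38),
    "Na": (162.7, 1556.0),
    "Mg": (71.0, 627.0),
    "Al": (60.0, 528.0),
    "Si": (37.0, 305.0),
    "P": (25.0, 185.0),
    "S": (19.6, 134.0),
    "Cl": (15.0, 94.6),
    "Ar": (11.1, 64.3),
    "K": (292.9, 3897.0),
    "Ca": (160.0, 2221.0),
    "Mn": (63.0, 552.0),
    "Fe": (56.0, 482.0),
    "Cu": (42.0, 253.0),
    "Zn": (38.67, 284.0),
    "Se": (28.9, 210.0),
    "Br": (20.0, 162.0),
    "I": (35.0, 385.0),
}


def omega_from_c6(alpha0, c6):
    """Characteristic QDO frequency from (alpha0, C6): omega = 4 C6 / (3 alpha0^2)."""
    return 4.0 * np.asarray(c6, float) / (3.0 * np.asarray(alpha0, float) ** 2)


@dataclass
class QDOParams:
    """Per-atom oscillator parameters: alpha0 (bohr^3), omega (hartree), C6 (Ha bohr^6)."""

    alpha0: np.ndarray
    omega: np.ndarray
    c6: np.ndarray | None = None

    def __post_init__(self):
        self.alpha0 = np.atleast_1d(np.asarray(self.alpha0, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.alpha0.shape != self.omega.shape:
            raise ValueError("alpha0 and omega must have the same length")
        if np.any(self.alpha0 <= 0):
            raise ValueError("alpha0 must be positive")
        if np.any(self.omega <= 0):
            raise ValueError("omega must be positive")
        if self.c6 is not None:
            self.c6 = np.atleast_1d(np.asarray(self.c6, dtype=float))
            expected = omega_from_c6(self.alpha0, self.c6)
            if not np.allclose(self.omega, expected, rtol=1e-12, atol=0.0):
                raise ValueError("inconsistent c6: omega != 4*C6/(3*alpha0^2)")

    @property
    def n_atoms(self) -> int:
        return self.alpha0.shape[0]


def _per_element_factor(scale, elements) -> np.ndarray:
    if isinstance(scale, Mapping):
        out = np.array([float(scale.get(el, 1.0)) for el in elements])
    else:
        out = np.full(len(elements), float(scale))
    if np.any(out <= 0):
        raise ValueError("scale factors must be positive")
    return out


def load_parameters(elements, scale_alpha=1.0, scale_omega=1.0) -> QDOParams:
    """Look up (alpha0, omega) for a list of element symbols.

    ``scale_alpha`` / ``scale_omega`` may be scalars or per-element mappings;
    they multiply the free-atom values (a crude stand-in for environmental
    screening). C6 is kept self-consistent with the scaled values.
    """
    elements = list(elements)
    unknown = sorted({el for el in elements if el not in FREE_ATOM_REFERENCE})
    if unknown:
        raise KeyError(
            f"no QDO parameters for element(s) {', '.join(unknown)}; "
            f"known elements: {', '.join(sorted(FREE_ATOM_REFERENCE))}"
        )
    alpha0 = np.array([FREE_ATOM_REFERENCE[el][0] for el in elements])
    c6 = np.array([FREE_ATOM_REFERENCE[el][1] for el in elements])
    omega = omega_from_c6(alpha0, c6)
    alpha0 = alpha0 * _per_element_factor(scale_alpha, elements)
    omega = omega * _per_element_factor(scale_omega, elements)
    c6 = 0.75 * alpha0**2 * omega
    return QDOParams(alpha0=alpha0, omega=omega, c6=c6)
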