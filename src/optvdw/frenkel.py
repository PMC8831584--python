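"""Dipole-limit two-fragment exciton (Frenkel) block model.

For two well-separated fragments, the electron-hole excitation operator is
block-decomposed: diagonal blocks carry the isolated-fragment excitation
energies (Tamm-Dancoff, no de-excitations), and the off-diagonal block
couples transitions a on fragment 1 and b on fragment 2 through the dipole
limit of the exchange interaction,

    K_ab = coupling_factor * mu_a^T T(R) mu_b,

with T the bare dipole-dipole tensor of the separation vector. The direct
(overlap-mediated) interaction decays exponentially with distance and is
structurally absent: this model is meant for well-separated fragments.

The hydrogen-atom fixture provides an exact analytic fragment spectrum
(1s->2s dark at 3/8 Ha; threefold 1s->2p bright with |mu| = 128*sqrt(2)/243)
so the coupled levels can be validated against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .hamiltonian import dipole_tensor

__all__ = [
    "Transition",
    "FragmentSpectrum",
    "CoupledExcitons",
    "build_coupled_hamiltonian",
    "hydrogen_fixture",
    "h_dimer_levels",
    "H_2P_DIPOLE",
    "H_1S2S_ENERGY",
]

#: hydrogen 1s -> 2p transition dipole magnitude, <1s|r|2p> = 2^(15/2)/3^5 = 128*sqrt(2)/243 a.u.
H_2P_DIPOLE = 128.0 * math.sqrt(2.0) / 243.0
#: hydrogen n=1 -> n=2 excitation energy (hartree)
H_1S2S_ENERGY = 3.0 / 8.0


@dataclass
class Transition:
    label: str
    energy: float  # hartree
    dipole: np.ndarray  # 3-vector, a.u.

    def __post_init__(self):
        self.dipole = np.asarray(self.dipole, float)
        if self.energy <= 0:
            raise ValueError(f"transition energy must be positive ({self.label})")
        if self.dipole.shape != (3,) or not np.all(np.isfinite(self.dipole)):
            raise ValueError(f"dipole must be a finite 3-vector ({self.label})")


@dataclass
class FragmentSpectrum:
    """Excitations of one isolated fragment: (label, energy, transition dipole)."""

    transitions: list[Transition]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)

    @property
    def energies(self) -> np.ndarray:
        return np.array([t.energy for t in self.transitions])

    @property
    def dipoles(self) -> np.ndarray:
        if not self.transitions:
            return np.zeros((0, 3))
        return np.stack([t.dipole for t in self.transitions])

    def shifted(self, scissor: float) -> "FragmentSpectrum":
        """Rigid (scissor) shift of every excitation energy."""
        return FragmentSpectrum(
            [Transition(t.label, t.energy + scissor, t.dipole) for t in self.transitions],
            self.origin,
        )


@dataclass
class CoupledExcitons:
    """Eigenlevels of the coupled two-fragment Hamiltonian."""

    hamiltonian: np.ndarray
    eigenvalues: np.ndarray  # ascending, hartree
    eigenvectors: np.ndarray
    labels: list[str]  # uncoupled basis labels "frag1:..." / "frag2:..."

    @property
    def n_states(self) -> int:
        return self.eigenvalues.shape[0]


def build_coupled_hamiltonian(
    frag1: FragmentSpectrum,
    frag2: FragmentSpectrum,
    separation,
    coupling_factor: float = 1.0,
) -> CoupledExcitons:
    """Couple two fragment spectra through dipole-dipole exchange.

    ``separation`` is the vector from fragment 2 to fragment 1 (bohr); the
    coupling element between transitions a (frag 1) and b (frag 2) is
    ``coupling_factor * mu_a^T T(separation) mu_b``. The trace of the
    coupled Hamiltonian equals the sum of uncoupled energies exactly.
    """
    separation = np.asarray(separation, float)
    if np.linalg.norm(separation) == 0.0:
        raise ValueError("fragment separation must be nonzero")
    n1, n2 = len(frag1.transitions), len(frag2.transitions)
    t = dipole_tensor(separation)
    k = coupling_factor * frag1.dipoles @ t @ frag2.dipoles.T if n1 and n2 else np.zeros((n1, n2))
    h = np.zeros((n1 + n2, n1 + n2))
    h[:n1, :n1] = np.diag(frag1.energies)
    h[n1:, n1:] = np.diag(frag2.energies)
    h[:n1, n1:] = k
    h[n1:, :n1] = k.T
    evals, evecs = scipy.linalg.eigh(h)
    labels = [f"frag1:{t.label}" for t in frag1.transitions] + [
        f"frag2:{t.label}" for t in frag2.transitions
    ]
    return CoupledExcitons(hamiltonian=h, eigenvalues=evals, eigenvectors=evecs, labels=labels)


def hydrogen_fixture(scissor: float | None = None) -> FragmentSpectrum:
    """Analytic hydrogen-atom n=1 -> n=2 fragment spectrum.

    1s->2s carries zero transition dipole (s-s spherical symmetry);
    1s->2p_x,y,z each carry |mu| = 128*sqrt(2)/243 a.u. along the
    respective axis. All four transitions sit at 3/8 Ha; an optional
    scissor rigidly shifts them.
    """
    mu = H_2P_DIPOLE
    transitions = [
        Transition("1s->2s", H_1S2S_ENERGY, np.zeros(3)),
        Transition("1s->2px", H_1S2S_ENERGY, np.array([mu, 0.0, 0.0])),
        Transition("1s->2py", H_1S2S_ENERGY, np.array([0.0, mu, 0.0])),
        Transition("1s->2pz", H_1S2S_ENERGY, np.array([0.0, 0.0, mu])),
    ]
    spec = FragmentSpectrum(transitions)
    return spec.shifted(scissor) if scissor else spec


def h_dimer_levels(r_bohr: float, scissor: float | None = None) -> CoupledExcitons:
    """Coupled n=2 exciton levels of two hydrogen atoms separated along z.

    Eight states: two R-independent 1s->2s levels, and six 1s->2p states
    forming four levels: a z pair split by -/+ 2 mu^2/R^3 (the aligned
    symmetric combination lowest) and doubly degenerate x, y pairs split
    by -/+ mu^2/R^3.
    """
    if r_bohr <= 0:
        raise ValueError(f"separation must be positive, got {r_bohr}")
    frag = hydrogen_fixture(scissor)
    return build_coupled_hamiltonian(frag, frag, np.array([0.0, 0.0, r_bohr]))
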