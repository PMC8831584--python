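"""Molecular geometries and synthetic structure generators.

Coordinates are stored in angstrom (the interface convention); the
Hamiltonian layer converts to bohr internally. Generators cover the model
systems studied with the coupled-oscillator model: two-atom dimers, benzene
monomer/dimer stacks, linear carbyne-like chains and parallel chain pairs,
and a random-coil cluster for protein-scale stress tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .units import bohr_to_angstrom

__all__ = [
    "Geometry",
    "make_dimer",
    "make_chain",
    "make_parallel_chains",
    "make_benzene",
    "make_benzene_dimer",
    "make_random_coil",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: minimum allowed pairwise distance (angstrom)
MIN_PAIR_DISTANCE = 1e-6


def _axis_vector(axis: str) -> np.ndarray:
    try:
        idx = _AXES[axis.lower()]
    except KeyError:
        raise ValueError(f"unknown axis {axis!r}; expected one of x, y, z") from None
    v = np.zeros(3)
    v[idx] = 1.0
    return v


@dataclass
class Geometry:
    """A set of atoms: element symbols plus Cartesian coordinates in angstrom."""

    elements: list[str]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("elements and coords disagree on atom count")
        if self.n_atoms < 1:
            raise ValueError("geometry needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.n_atoms > 1 and pdist(self.coords).min() <= MIN_PAIR_DISTANCE:
            raise ValueError(
                f"two atoms closer than {MIN_PAIR_DISTANCE} angstrom (overlapping positions)"
            )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def coords_bohr(self) -> np.ndarray:
        from .units import angstrom_to_bohr

        return angstrom_to_bohr(self.coords)

    def translated(self, shift) -> "Geometry":
        return Geometry(list(self.elements), self.coords + np.asarray(shift, float), self.label)

    def rotated(self, rotation_matrix) -> "Geometry":
        R = np.asarray(rotation_matrix, float)
        return Geometry(list(self.elements), self.coords @ R.T, self.label)

    def __add__(self, other: "Geometry") -> "Geometry":
        return Geometry(
            list(self.elements) + list(other.elements),
            np.vstack([self.coords, other.coords]),
            self.label,
        )


def _to_angstrom(value: float, units: str) -> float:
    if units == "angstrom":
        return float(value)
    if units == "bohr":
        return float(bohr_to_angstrom(value))
    raise ValueError(f"unknown length unit {units!r}")


def make_dimer(element: str, separation: float, axis: str = "z", units: str = "angstrom") -> Geometry:
    """Two identical atoms separated by ``separation`` along ``axis``."""
    r = _to_angstrom(separation, units)
    if r <= 0:
        raise ValueError(f"separation must be positive, got {separation}")
    v = _axis_vector(axis)
    coords = np.array([np.zeros(3), r * v])
    return Geometry([element, element], coords, label=f"{element}2 dimer R={r:g} A")


def make_chain(n_atoms: int, spacing: float, element: str = "C", axis: str = "z") -> Geometry:
    """Collinear equally spaced atoms (carbyne-like chain by default)."""
    if n_atoms < 1:
        raise ValueError(f"n_atoms must be >= 1, got {n_atoms}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    v = _axis_vector(axis)
    coords = np.outer(np.arange(n_atoms) * spacing, v)
    return Geometry([element] * n_atoms, coords, label=f"{element}{n_atoms} chain")


def make_parallel_chains(
    n_atoms: int,
    spacing: float,
    separation: float,
    element: str = "C",
    axis: str = "z",
    offset_axis: str = "x",
) -> Geometry:
    """Two identical parallel chains offset perpendicular to the chain axis.

    Zero longitudinal shift: atom i of one chain faces atom i of the other,
    so single-chain modes combine into mirror-symmetric pairs.
    """
    if separation <= 0:
        raise ValueError(f"separation must be positive, got {separation}")
    if _AXES[axis.lower()] == _AXES[offset_axis.lower()]:
        raise ValueError("offset axis must differ from the chain axis")
    chain = make_chain(n_atoms, spacing, element=element, axis=axis)
    other = chain.translated(separation * _axis_vector(offset_axis))
    geo = chain + other
    geo.label = f"parallel {element}{n_atoms} chains R={separation:g} A"
    return geo


# benzene bond lengths (angstrom)
_CC = 1.39
_CH = 1.09


def make_benzene(center=(0.0, 0.0, 0.0)) -> Geometry:
    """Planar D6h benzene monomer in the xy plane (C-C 1.39 A, C-H 1.09 A)."""
    center = np.asarray(center, float)
    angles = np.deg2rad(60.0 * np.arange(6))
    ring = np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1)
    coords = np.vstack([_CC * ring, (_CC + _CH) * ring]) + center
    return Geometry(["C"] * 6 + ["H"] * 6, coords, label="benzene")


def make_benzene_dimer(separation: float) -> Geometry:
    """Cofacial (sandwich-stacked) benzene dimer with ring-plane distance R.

    ``separation = math.inf`` is accepted as a sentinel for the isolated
    monomer (12 atoms).
    """
    if math.isinf(separation):
        return make_benzene()
    if separation <= 0:
        raise ValueError(f"separation must be positive, got {separation}")
    a = make_benzene()
    b = make_benzene(center=(0.0, 0.0, separation))
    geo = a + b
    geo.label = f"benzene dimer R={separation:g} A"
    return geo


_COIL_ELEMENTS = ["H", "C", "N", "O", "S"]
_COIL_WEIGHTS = [0.50, 0.32, 0.08, 0.09, 0.01]


def make_random_coil(
    n_atoms: int,
    seed: int = 0,
    step: float = 1.5,
    min_dist: float = 1.1,
    max_tries: int = 200,
) -> Geometry:
    """Self-avoiding random walk with a protein-like element composition.

    A synthetic stand-in for a protein interior: roughly bonded-neighbour
    step lengths and excluded volume, no chemistry. Used for feasibility
    tests at the thousand-atom scale.
    """
    if n_atoms < 1:
        raise ValueError(f"n_atoms must be >= 1, got {n_atoms}")
    rng = np.random.default_rng(seed)
    elements = list(rng.choice(_COIL_ELEMENTS, size=n_atoms, p=_COIL_WEIGHTS))
    coords = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        anchor = coords[i - 1]
        tries = 0
        while True:
            tries += 1
            if tries > max_tries:
                # walk trapped: branch from a random earlier atom
                anchor = coords[rng.integers(i)]
                tries = 0
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            trial = anchor + step * direction
            if np.min(np.linalg.norm(coords[:i] - trial, axis=1)) > min_dist:
                coords[i] = trial
                break
    return Geometry(elements, coords, label=f"random coil N={n_atoms} seed={seed}")
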