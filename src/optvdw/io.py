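"""Readers and writers: XYZ (standard + extended force columns) and a PDB subset.

All file coordinates are in angstrom. The PDB reader covers ATOM/HETATM
records only, with explicit policies for alternate locations, waters, and
hetero groups; elements come from columns 77-78 with an atom-name fallback.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Geometry

__all__ = ["read_xyz", "write_xyz", "read_pdb"]


def read_xyz(path) -> Geometry:
    """Read a standard XYZ file (count line, comment, element x y z in angstrom)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}, line 1: expected an atom count, got {lines[0]!r}") from None
    if len(lines) < n + 2:
        raise ValueError(f"{path}: atom count {n} on line 1 but only {len(lines) - 2} atom lines")
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i in range(n):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise ValueError(f"{path}, line {lineno}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ValueError(f"{path}, line {lineno}: unparseable coordinates") from None
    return Geometry(elements, coords, label=comment.strip())


def write_xyz(geometry: Geometry, path, extra_columns: np.ndarray | None = None, comment: str | None = None):
    """Write XYZ; ``extra_columns`` (N, m) appends per-atom values (e.g. forces)."""
    path = Path(path)
    if extra_columns is not None:
        extra_columns = np.atleast_2d(np.asarray(extra_columns, float))
        if extra_columns.shape[0] != geometry.n_atoms:
            raise ValueError("extra_columns row count must equal the atom count")
    lines = [str(geometry.n_atoms), comment if comment is not None else geometry.label]
    for i, (el, xyz) in enumerate(zip(geometry.elements, geometry.coords)):
        row = f"{el:<3s} " + " ".join(f"{v: .10f}" for v in xyz)
        if extra_columns is not None:
            row += " " + " ".join(f"{v: .10e}" for v in extra_columns[i])
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def _element_from_record(line: str, lineno: int, path) -> str:
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # atom-name heuristic: strip digits, take leading alphabetic characters
        name = line[12:16].strip()
        letters = "".join(ch for ch in name if ch.isalpha())
        if letters[:2].capitalize() in ("Cl", "Br", "Na", "Mg", "Zn", "Fe", "Ca", "Mn", "Cu", "Se"):
            element = letters[:2]
        elif letters:
            element = letters[0]
    if not element:
        raise ValueError(f"{path}, line {lineno}: cannot resolve the element for atom {line[12:16].strip()!r}")
    return element.capitalize()


_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_pdb(path, altloc: str = "A", keep_water: bool = False, keep_hetero: bool = True) -> Geometry:
    """Read ATOM/HETATM records from a PDB file.

    ``altloc`` keeps atoms whose alternate-location indicator is blank or
    equals the given letter. ``keep_water`` / ``keep_hetero`` control
    whether water residues and (non-water) HETATM records are retained.
    """
    path = Path(path)
    elements: list[str] = []
    coords: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        resname = line[17:20].strip().upper()
        if resname in _WATER_RESNAMES and not keep_water:
            continue
        if record == "HETATM" and resname not in _WATER_RESNAMES and not keep_hetero:
            continue
        loc = line[16:17]
        if loc not in (" ", "") and loc != altloc:
            continue
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError:
            raise ValueError(f"{path}, line {lineno}: unparseable coordinates") from None
        elements.append(_element_from_record(line, lineno, path))
        coords.append(xyz)
    if not elements:
        raise ValueError(f"{path}: no ATOM/HETATM records kept under the given policy")
    return Geometry(elements, np.array(coords), label=path.stem)
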