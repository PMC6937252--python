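"""Molecular geometry I/O and the internuclear distance matrix.

Geometries are plain XYZ files (count line, comment line, then
``symbol x y z`` in Angstrom).  Atom order is file order and all
downstream outputs are reported in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, InvalidElementError, XYZParseError

__all__ = ["Atom", "Molecule", "read_xyz", "write_xyz", "distance_matrix"]

# minimum credible internuclear separation; below this two atoms are coincident
_MIN_SEPARATION = 1e-6  # Angstrom


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Molecule:
    """An ordered list of atoms with an integer net charge.

    The molecule's total electron count is sum of neutral-atom counts minus
    ``net_charge``; a neutral molecule (the default) satisfies sum(q) = 0.
    """

    atoms: list[Atom]
    net_charge: int = 0
    name: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in molecule {self.name!r}")
        _check_no_coincident(coords)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def total_electrons(self, element_table) -> float:
        """N = sum of neutral electron counts minus the net charge."""
        return sum(element_table[e].N0 for e in self.elements) - self.net_charge


def _check_no_coincident(coords: np.ndarray) -> None:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < _MIN_SEPARATION:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise DegenerateGeometryError(
            f"atoms {i} and {j} are coincident (separation {d[i, j]:.2e} A)"
        )


def _normalize_symbol(raw: str, line: int) -> str:
    # real symbols plus letter-initial labels for fictitious species
    if not (raw[:1].isalpha() and raw.isalnum() and len(raw) <= 4):
        raise XYZParseError(f"invalid element symbol {raw!r}", line)
    return raw.capitalize()


def read_xyz(path: str | Path, *, net_charge: int = 0,
             known_elements=None) -> Molecule:
    """Parse a standard XYZ file into a Molecule.

    Parameters
    ----------
    known_elements : optional collection of str
        Accepted element symbols.  Defaults to the packaged element table;
        pass an explicit collection (e.g. toy-system labels) to override.

    Raises
    ------
    XYZParseError
        On header/atom-count mismatch or a malformed line (with line number).
    InvalidElementError
        For a symbol absent from ``known_elements``.
    """
    path = Path(path)
    if known_elements is None:
        from .element_params import load_element_table

        known_elements = load_element_table().keys()
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError("empty file", 1)
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"expected atom count, got {lines[0]!r}", 1) from None
    comment = lines[1] if len(lines) > 1 else ""
    atoms = []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"expected 'symbol x y z', got {line!r}", ln)
        sym = _normalize_symbol(parts[0], ln)
        if sym not in known_elements:
            raise InvalidElementError(
                f"line {ln}: element {sym!r} not in the element table"
            )
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise XYZParseError(f"non-numeric coordinate in {line!r}", ln) from None
        atoms.append(Atom(sym, x, y, z))
    if len(atoms) != count:
        raise XYZParseError(
            f"header declares {count} atoms but file contains {len(atoms)}", 1
        )
    return Molecule(atoms, net_charge=net_charge, name=comment.strip() or path.stem)


def write_xyz(mol: Molecule, path: str | Path) -> None:
    lines = [str(len(mol)), mol.name]
    lines += [f"{a.element:2s} {a.x: .6f} {a.y: .6f} {a.z: .6f}" for a in mol.atoms]
    Path(path).write_text("\n".join(lines) + "\n")


def distance_matrix(mol: Molecule) -> np.ndarray:
    """Symmetric matrix of internuclear distances R_ij (Angstrom).

    R_ij = |r_i - r_j|; zero diagonal.  Raises DegenerateGeometryError if
    any off-diagonal distance is (numerically) zero.
    """
    coords = mol.coords
    _check_no_coincident(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
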