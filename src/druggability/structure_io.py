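"""Protein structure I/O and atom annotation.

Reads PDB files (via gemmi), optionally strips cofactors (all HETATM
records, waters included), resolves alternate locations to the
highest-occupancy conformer, and flags atoms as hydrophobic for the
pocket-descriptor computations.

Coordinates are Angstroms throughout; no unit conversion happens anywhere
in the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError

__all__ = [
    "Atom",
    "ProteinStructure",
    "read_structure",
    "write_structure",
    "flag_hydrophobic_atoms",
    "HYDROPHOBIC_ELEMENTS",
]

#: Coarse element rule: carbon and sulfur are apolar, everything else polar.
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})

#: Van der Waals radii (A) used for grids and SASA; fixed for reproducibility.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70


@dataclasses.dataclass(frozen=True)
class Atom:
    """A single atom with the annotations the descriptors need."""

    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_number: int
    chain_id: str
    is_hetero: bool = False
    is_hydrophobic: bool = False
    name: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW)


@dataclasses.dataclass
class ProteinStructure:
    """An ordered collection of atoms plus an identifier."""

    atoms: list[Atom]
    identifier: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) float64 array of atomic coordinates in A."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def hydrophobic_mask(self) -> np.ndarray:
        return np.array([a.is_hydrophobic for a in self.atoms], dtype=bool)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [a.residue_key for a in self.atoms]

    def subset(self, indices: Iterable[int], identifier: str | None = None) -> "ProteinStructure":
        idx = list(indices)
        return ProteinStructure(
            atoms=[self.atoms[i] for i in idx],
            identifier=identifier if identifier is not None else self.identifier,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigid-body transform: x -> R x + t. Used for invariance checks."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_xyz = self.coords() @ R.T + t
        atoms = [
            dataclasses.replace(a, coords=tuple(float(v) for v in xyz))
            for a, xyz in zip(self.atoms, new_xyz)
        ]
        return ProteinStructure(atoms=atoms, identifier=self.identifier)


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = by_name.get(at.name)
        if prev is None or at.occ > prev.occ:
            by_name[at.name] = at
    return list(by_name.values())


def read_structure(
    path: str | Path,
    strip_cofactors: bool = True,
    chains: Sequence[str] | None = None,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        PDB file path.
    strip_cofactors:
        When True (default) all HETATM records — cofactors, ligands and
        waters — are removed so the bare protein is analyzed.
    chains:
        Optional chain-id whitelist; by default all chains are kept.

    Raises
    ------
    EmptyStructureError
        If no atoms remain after stripping.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    atoms: list[Atom] = []
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            is_het = residue.het_flag == "H"
            if strip_cofactors and is_het:
                continue
            for at in _resolve_altlocs(residue):
                element = at.element.name.upper()
                if element == "H" or element == "D":
                    continue  # X-ray structures analyzed heavy-atom only
                atoms.append(
                    Atom(
                        element=element,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        is_hetero=is_het,
                        name=at.name,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"no atoms left in {path} (strip_cofactors={strip_cofactors})")
    return flag_hydrophobic_atoms(ProteinStructure(atoms=atoms, identifier=path.stem))


def flag_hydrophobic_atoms(structure: ProteinStructure) -> ProteinStructure:
    """Return a structure whose atoms all carry ``is_hydrophobic``.

    The rule is deterministic and element-based: carbon and sulfur atoms
    are hydrophobic; N, O, P, halogens and metals are not.
    """
    atoms = [
        dataclasses.replace(a, is_hydrophobic=a.element.upper() in HYDROPHOBIC_ELEMENTS)
        for a in structure.atoms
    ]
    return ProteinStructure(atoms=atoms, identifier=structure.identifier)


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as minimal wwPDB v3.3 ATOM/HETATM records."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name or a.element
        # PDB atom-name column convention: pad 1-char elements into col 14.
        name_field = f" {name:<3s}" if len(a.element) == 1 and len(name) < 4 else f"{name:<4s}"
        x, y, z = a.coords
        lines.append(
            f"{record}{i % 100000:5d} {name_field} "
            f"{a.residue_name:<3s} {a.chain_id[:1]}{a.residue_number % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
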