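"""Synthetic inputs for every pipeline stage, plus packaged table fixtures.

Generators are pure functions of their seed: hollow-sphere pseudo-protein
structures with engineered cavities of controllable size, mouth aperture
and lining composition; random per-target score tables over the observed
score ranges of the three druggability methods; and docking tables with
a planted hit tail and molecules shared across targets by construction.

``load_fixture`` returns the packaged machine-readable copies of the
published summary tables (druggability descriptors, SiteMap metrics,
normalized composite scores, per-target docking results), transcribed
verbatim with typographic variants of target/molecule ids unified; each
file's SHA-256 is pinned so any drift from the transcribed values fails
loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .structure_io import Atom, ProteinStructure, flag_hydrophobic_atoms

__all__ = [
    "CavitySpec",
    "make_cavity_structure",
    "make_helix_structure",
    "make_score_table",
    "make_docking_tables",
    "load_fixture",
    "FIXTURE_SHA256",
]

# Observed raw score ranges of the three methods (used as uniform bounds):
# best-pocket DLID spans about [-1.5, 2.1], SiteMap DScore [0.38, 1.24],
# SPIDER possibility [0.085, 0.089].
DLID_RANGE = (-1.5, 2.1)
DSCORE_RANGE = (0.38, 1.24)
SPIDER_RANGE = (0.085, 0.089)

_LAYER_GAP = 1.6  # A radial gap between shell layers (vdW spheres overlap)
_LATERAL_SPACING = 1.6  # A target spacing between atoms within a layer
_CARBON_VDW = 1.7

FIXTURE_SHA256 = {
    "table1": "e6e935c8feebc10f638242fc224e723dec34078d372c3bea8e14764e6b54ebc7",
    "table2": "210cdc4adc68c9788260873c7620d61a261d0ac687a118a621bc03875112d294",
    "table3": "54b44d69236df6ee96b2e6c604281decdd030645b5cac53d6cd7fb4e4686dd5e",
    "table4": "e2e563121daae1262ae65e15ccbb4f33a1c285c201da65d79ec65f7bb86ad9fc",
    "table5": "1e49292304e0556d4bd73a3058c27dcd5fbc2a4861f0cb682c826a1f05436662",
    "table6": "b96cb553ef864e41dd499b1713bc6a74a24b53970536a92aecef6cad30b33de9",
    "table7": "4c7c0e49d3047eefd9f5ef4f2ce71c72edba6e99577c2ea84452dd4bcde2cc2f",
    "table8": "206e59546755877030484f7934716d15c94aca723d69ff371808fc1e4c429fee",
}


@dataclasses.dataclass(frozen=True)
class CavitySpec:
    """Geometry of an engineered hollow-sphere cavity.

    ``mouth_aperture`` is the solid-angle fraction of the shell removed
    around +z (0 = fully closed); ``lining_composition`` the fraction of
    shell atoms that are hydrophobic (carbon; the rest oxygen).
    """

    inner_radius: float = 6.0
    shell_thickness: float = 4.8
    mouth_aperture: float = 0.0
    lining_composition: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius <= 1.4:
            raise ValueError("inner_radius must exceed the 1.4 A probe radius")
        if self.shell_thickness <= 0:
            raise ValueError("shell_thickness must be positive")
        if not 0.0 <= self.mouth_aperture <= 1.0:
            raise ValueError("mouth_aperture is a solid-angle fraction in [0, 1]")
        if not 0.0 <= self.lining_composition <= 1.0:
            raise ValueError("lining_composition is a fraction in [0, 1]")


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def make_cavity_structure(spec: CavitySpec) -> ProteinStructure:
    """Pseudo-atom shell of a hollow sphere with a spherical-cap mouth.

    Atoms form concentric quasi-uniform layers dense enough that the
    1.4 A water probe cannot leak between them; the inner layer sits at
    ``inner_radius + r_vdw`` so the empty interior has roughly the
    requested radius. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_layers = max(1, round(spec.shell_thickness / _LAYER_GAP))
    cos_cap = 1.0 - 2.0 * spec.mouth_aperture  # atoms with cos(theta) > this removed
    positions: list[np.ndarray] = []
    for k in range(n_layers):
        r = spec.inner_radius + _CARBON_VDW + k * _LAYER_GAP
        n_atoms = int(np.ceil(4.0 * np.pi * r**2 / _LATERAL_SPACING**2))
        dirs = _fibonacci_directions(n_atoms)
        if spec.mouth_aperture > 0:
            dirs = dirs[dirs[:, 2] <= cos_cap]
        positions.append(r * dirs)
    xyz = np.vstack(positions)
    if len(xyz) < 4:
        raise ValueError("spec leaves too few atoms to form a shell")
    n_total = len(xyz)
    n_hydrophobic = round(spec.lining_composition * n_total)
    elements = np.array(["O"] * n_total, dtype=object)
    order = rng.permutation(n_total)
    elements[order[:n_hydrophobic]] = "C"
    atoms = [
        Atom(
            element=str(elements[i]),
            coords=(float(xyz[i, 0]), float(xyz[i, 1]), float(xyz[i, 2])),
            residue_name="CAV",
            residue_number=i + 1,
            chain_id="A",
            name=str(elements[i]),
        )
        for i in range(n_total)
    ]
    return flag_hydrophobic_atoms(
        ProteinStructure(atoms=atoms, identifier=f"cavity_seed{spec.seed}")
    )


def make_helix_structure(n_residues: int = 20) -> ProteinStructure:
    """Ideal poly-alanine-like alpha helix backbone: an open surface, no cavity."""
    atoms = []
    rise, twist, radius = 1.5, np.deg2rad(100.0), 2.3
    offsets = {  # crude in-residue offsets, enough for surface geometry
        "N": (0.0, 0.0, -0.5), "CA": (0.0, 0.0, 0.0),
        "C": (0.5, 0.0, 0.6), "O": (1.2, 0.5, 0.9), "CB": (-1.0, 0.8, 0.2),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for i in range(n_residues):
        ang = i * twist
        base = np.array([radius * np.cos(ang), radius * np.sin(ang), i * rise])
        for name, off in offsets.items():
            atoms.append(Atom(
                element=elements[name],
                coords=tuple(float(v) for v in base + np.asarray(off)),
                residue_name="ALA", residue_number=i + 1, chain_id="A", name=name,
            ))
    return flag_hydrophobic_atoms(ProteinStructure(atoms=atoms, identifier="ideal_helix"))


def make_score_table(
    n_targets: int,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random per-target raw method scores over the observed score ranges.

    Returns a frame indexed by target id with columns dlid_raw, spider_raw,
    dscore_raw; each cell is independently missing with ``missing_fraction``
    probability.
    """
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    rng = np.random.default_rng(seed)
    targets = [f"T{i + 1:02d}" for i in range(n_targets)]
    df = pd.DataFrame(
        {
            "dlid_raw": rng.uniform(*DLID_RANGE, n_targets),
            "spider_raw": rng.uniform(*SPIDER_RANGE, n_targets),
            "dscore_raw": rng.uniform(*DSCORE_RANGE, n_targets),
        },
        index=pd.Index(targets, name="target"),
    )
    if missing_fraction > 0:
        mask = rng.random((n_targets, 3)) < missing_fraction
        df = df.mask(mask)
    return df


def make_docking_tables(
    n_targets: int = 5,
    n_molecules: int = 40,
    planted_shared: int = 0,
    hit_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-target docking tables with a planted hit tail and shared molecules.

    Per-target molecules get target-prefixed ids (so there is no accidental
    cross-target overlap); ``hit_fraction`` of them score in the likely-binder
    tail below -20 kcal/mol, the rest around -15. ``planted_shared`` extra
    molecules are inserted into the top-10 of two targets each with scores
    below every background score, so the expected top-10 overlap is exactly
    ``planted_shared``.
    """
    if planted_shared > n_molecules:
        raise ValueError("planted_shared cannot exceed n_molecules")
    if n_targets < 2 and planted_shared > 0:
        raise ValueError("sharing needs at least 2 targets")
    rng = np.random.default_rng(seed)
    targets = [f"T{i + 1:02d}" for i in range(n_targets)]
    tables: dict[str, pd.DataFrame] = {}
    n_hits = round(hit_fraction * n_molecules)
    for t in targets:
        scores = np.concatenate([
            rng.uniform(-35.0, -20.2, n_hits),
            rng.uniform(-19.8, -8.0, n_molecules - n_hits),
        ])
        rng.shuffle(scores)
        tables[t] = pd.DataFrame({
            "target": t,
            "molecule": [f"{t}_m{i + 1:03d}" for i in range(n_molecules)],
            "score": scores,
        })
    for s in range(planted_shared):
        pair = rng.choice(n_targets, size=2, replace=False)
        score = float(rng.uniform(-40.0, -36.0))
        for ti in pair:
            t = targets[ti]
            tables[t] = pd.concat([
                tables[t],
                pd.DataFrame({"target": [t], "molecule": [f"shared{s + 1:03d}"],
                              "score": [score]}),
            ], ignore_index=True)
    return tables


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table fixture ('table1' ... 'table8'), verbatim values.

    The file's SHA-256 must match the pinned checksum; a mismatch raises.
    """
    if name not in FIXTURE_SHA256:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_SHA256)}")
    data = resources.files("druggability").joinpath(f"fixtures/{name}.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"fixture {name} drifted from its transcribed values "
            f"(sha256 {digest} != {FIXTURE_SHA256[name]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(data))
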