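"""Pocket detection and descriptor behavior on engineered cavities."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from druggability import (
    CavitySpec,
    ProteinStructure,
    find_pockets,
    make_cavity_structure,
    make_helix_structure,
)
from druggability.errors import DegenerateInputError, UndefinedDescriptorError
from druggability.pockets import (
    Pocket,
    assign_shell,
    compute_buriedness,
    compute_hydrophobicity,
    compute_sitemap_descriptors,
)
from druggability.structure_io import Atom, flag_hydrophobic_atoms


def test_closed_sphere_yields_one_pocket_with_analytic_volume(closed_polar_cavity):
    _, pockets = closed_polar_cavity
    assert len(pockets) == 1
    analytic = 4.0 / 3.0 * np.pi * 6.0**3
    assert abs(pockets[0].volume - analytic) / analytic < 0.25


def test_volume_is_exactly_cell_count_times_spacing_cubed(closed_polar_cavity):
    _, pockets = closed_polar_cavity
    p = pockets[0]
    assert p.volume == pytest.approx(len(p.cells) * p.spacing**3, rel=1e-12)


def test_helix_has_no_enclosed_pockets():
    assert find_pockets(make_helix_structure(20)) == []


def test_two_disjoint_cavities_found_in_decreasing_volume_order():
    big = make_cavity_structure(CavitySpec(inner_radius=6.0, seed=3))
    small = make_cavity_structure(
        CavitySpec(inner_radius=4.5, shell_thickness=3.2, seed=4)
    ).transformed(np.eye(3), np.array([30.0, 0.0, 0.0]))
    both = ProteinStructure(atoms=big.atoms + small.atoms, identifier="two-cavities")
    pockets = find_pockets(both)
    assert len(pockets) == 2
    assert pockets[0].volume > pockets[1].volume


def test_too_few_atoms_is_degenerate():
    atoms = [
        Atom(element="C", coords=(float(i), 0.0, 0.0), residue_name="GLY",
             residue_number=1, chain_id="A")
        for i in range(3)
    ]
    with pytest.raises(DegenerateInputError):
        find_pockets(ProteinStructure(atoms=atoms))


def _single_point_pocket(surface_point):
    return Pocket(
        cells=np.zeros((1, 3), dtype=int),
        surface_points=np.asarray([surface_point], dtype=float),
        volume=0.512, spacing=0.8, origin=np.zeros(3),
    )


@pytest.mark.parametrize("z,expected", [(3.4, True), (3.6, False)])
def test_shell_cutoff_is_3_5_angstroms(z, expected):
    pocket = _single_point_pocket([0.0, 0.0, 0.0])
    st = flag_hydrophobic_atoms(ProteinStructure(atoms=[
        Atom(element="C", coords=(0.0, 0.0, z), residue_name="LEU",
             residue_number=7, chain_id="A"),
    ]))
    shell = assign_shell(pocket, st)
    assert (("A", 7, "LEU") in shell) is expected


def test_shell_matches_brute_force_distance_scan(closed_polar_cavity):
    structure, pockets = closed_polar_cavity
    pocket = pockets[0]
    shell = pocket.shell_residues
    coords = structure.coords()
    expected = set()
    for atom, xyz in zip(structure.atoms, coords):
        d = np.linalg.norm(pocket.surface_points - xyz, axis=1).min()
        if d <= 3.5:
            expected.add(atom.residue_key)
    assert shell == expected


def test_empty_surface_warns_and_gives_empty_shell(closed_polar_cavity):
    structure, _ = closed_polar_cavity
    pocket = Pocket(cells=np.zeros((0, 3), int), surface_points=np.zeros((0, 3)),
                    volume=0.0, spacing=0.8, origin=np.zeros(3))
    with pytest.warns(UserWarning):
        assert assign_shell(pocket, structure) == set()


def test_sealed_cavity_lining_is_fully_buried(closed_polar_cavity):
    structure, pockets = closed_polar_cavity
    assert compute_buriedness(pockets[0], structure) == pytest.approx(1.0)


def test_fully_exposed_shell_has_zero_buriedness():
    # shell covers the whole structure, so context equals isolation exactly
    atoms = [
        Atom(element="C", coords=(1.8 * i, 1.8 * j, 0.0), residue_name="GLY",
             residue_number=1 + i * 2 + j, chain_id="A")
        for i in range(2) for j in range(2)
    ]
    st = flag_hydrophobic_atoms(ProteinStructure(atoms=atoms))
    pocket = _single_point_pocket([0.9, 0.9, 1.0])
    shell = assign_shell(pocket, st)
    assert len(shell) == len(atoms)
    assert compute_buriedness(pocket, st) == pytest.approx(0.0, abs=1e-9)


def test_buriedness_strictly_decreases_with_mouth_aperture():
    values = []
    for aperture in (0.024, 0.0265, 0.029, 0.0315, 0.034):
        st = make_cavity_structure(
            CavitySpec(mouth_aperture=aperture, lining_composition=0.0, seed=0))
        pockets = find_pockets(st)
        assert len(pockets) == 1
        assign_shell(pockets[0], st)
        values.append(compute_buriedness(pockets[0], st))
    assert all(a > b for a, b in zip(values, values[1:]))


@pytest.mark.parametrize("fraction,expected,tol", [(1.0, 1.0, 0.0), (0.0, 0.0, 0.0), (0.5, 0.5, 0.1)])
def test_hydrophobicity_tracks_lining_composition(fraction, expected, tol):
    st = make_cavity_structure(CavitySpec(lining_composition=fraction, seed=2))
    pockets = find_pockets(st)
    assign_shell(pockets[0], st)
    value = compute_hydrophobicity(pockets[0], st)
    assert value == pytest.approx(expected, abs=tol)


def test_hydrophobicity_matches_brute_force_nearest_atom(closed_polar_cavity):
    structure, pockets = closed_polar_cavity
    pocket = pockets[0]
    idx = [i for i, a in enumerate(structure.atoms) if a.residue_key in pocket.shell_residues]
    coords = structure.coords()[idx]
    phobic = structure.hydrophobic_mask()[idx]
    hits = []
    for pt in pocket.surface_points:
        d = np.linalg.norm(coords - pt, axis=1)
        if d.min() <= 4.5:
            hits.append(phobic[d.argmin()])
    assert compute_hydrophobicity(pocket, structure) == pytest.approx(np.mean(hits))


def test_fully_enclosed_small_cavity_has_enclosure_one(small_cavity):
    structure, pocket = small_cavity
    desc = compute_sitemap_descriptors(pocket, structure)
    assert desc.enclosure == pytest.approx(1.0)
    assert desc.site_point_count > 0
    assert desc.hydrophobic_score == pytest.approx(0.0)  # all-polar lining


def test_sitemap_descriptors_bit_identical_across_runs(small_cavity):
    structure, pocket = small_cavity
    d1 = compute_sitemap_descriptors(pocket, structure)
    d2 = compute_sitemap_descriptors(pocket, structure)
    assert (d1.enclosure, d1.hydrophilic_score, d1.site_point_count) == (
        d2.enclosure, d2.hydrophilic_score, d2.site_point_count)


def test_descriptors_invariant_under_rigid_motion():
    st = make_cavity_structure(CavitySpec(mouth_aperture=0.03, lining_composition=0.4, seed=5))
    moved = st.transformed(
        Rotation.from_euler("xyz", [31, -47, 113], degrees=True).as_matrix(),
        np.array([3.3, -7.7, 11.1]),
    )
    results = []
    for s in (st, moved):
        pockets = find_pockets(s)
        assert len(pockets) == 1
        assign_shell(pockets[0], s)
        results.append((
            pockets[0].volume,
            compute_buriedness(pockets[0], s),
            compute_hydrophobicity(pockets[0], s),
        ))
    (v0, b0, h0), (v1, b1, h1) = results
    assert abs(v1 - v0) / v0 < 0.10
    assert abs(b1 - b0) < 0.05
    assert abs(h1 - h0) < 0.05


def test_descriptor_fractions_lie_in_unit_interval(small_cavity):
    structure, pocket = small_cavity
    b = compute_buriedness(pocket, structure)
    h = compute_hydrophobicity(pocket, structure)
    desc = compute_sitemap_descriptors(pocket, structure)
    assert 0.0 <= b <= 1.0 and 0.0 <= h <= 1.0
    assert 0.0 <= desc.enclosure <= 1.0
    assert desc.hydrophilic_score >= 0.0 and desc.balance >= 0.0
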