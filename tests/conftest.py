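"""Shared synthetic fixtures: structures built from internal coordinates."""

from __future__ import annotations

import numpy as np
import pytest

from thermoscreen.geometry import place_atom
from thermoscreen.structure import Atom, Structure

# ideal disulfide internal coordinates used to construct fixtures
SS = 2.02
CB_SG = 1.81
CB_SG_SG = 104.15
CA_CB_SG = 114.0
CHI_SS = -87.0
CHI1 = -60.0


def make_residue(atoms_spec, res_id, chain="A", res_name="ALA", serial_start=1):
    """Build Atom objects from (name, element, coords) triples."""
    return [
        Atom(serial_start + k, name, el, res_name, res_id, chain, np.asarray(xyz, float))
        for k, (name, el, xyz) in enumerate(atoms_spec)
    ]


def ideal_disulfide_residues(res_id_i=1, res_id_j=5, offset=np.zeros(3)):
    """Two backbone+Cβ residues whose Sγ atoms (at χ1 = −60°) would form a
    geometrically perfect disulfide: S–S 2.02 Å, Cβ–Sγ–Sγ′ 104.15°,
    χss = −87°. Constructed outward from the bond via NeRF placement."""
    sg1 = np.zeros(3)
    sg2 = np.array([SS, 0.0, 0.0])
    a = np.deg2rad(CB_SG_SG)
    cb1 = sg1 + CB_SG * np.array([np.cos(a), np.sin(a), 0.0])
    cb2 = place_atom(cb1, sg1, sg2, CB_SG, CB_SG_SG, CHI_SS)
    ca1 = place_atom(sg2, sg1, cb1, 1.53, CA_CB_SG, 180.0)
    n1 = place_atom(sg1, cb1, ca1, 1.46, 110.4, CHI1)
    c1 = place_atom(cb1, n1, ca1, 1.52, 111.0, 122.0)
    ca2 = place_atom(sg1, sg2, cb2, 1.53, CA_CB_SG, 180.0)
    n2 = place_atom(sg2, cb2, ca2, 1.46, 110.4, CHI1)
    c2 = place_atom(cb2, n2, ca2, 1.52, 111.0, 122.0)
    res = []
    serial = 1
    for rid, (n, ca, c, cb) in ((res_id_i, (n1, ca1, c1, cb1)), (res_id_j, (n2, ca2, c2, cb2))):
        res += make_residue(
            [("N", "N", n + offset), ("CA", "C", ca + offset),
             ("C", "C", c + offset), ("CB", "C", cb + offset)],
            rid, serial_start=serial,
        )
        serial += 4
    return res


@pytest.fixture
def ideal_pair_structure():
    """4-residue structure containing exactly one ideal disulfide pair
    (residues 1 and 5); residues 20 and 30 are copies displaced 50 Å away
    from the pair and from each other, too far for any candidate."""
    atoms = ideal_disulfide_residues(1, 5)
    far1 = ideal_disulfide_residues(20, 99, offset=np.array([50.0, 0.0, 0.0]))[:4]
    far2 = ideal_disulfide_residues(30, 99, offset=np.array([0.0, 80.0, 0.0]))[:4]
    for k, a in enumerate(far1):
        a.res_id = 20
        a.serial = 9 + k
    for k, a in enumerate(far2):
        a.res_id = 30
        a.serial = 13 + k
    return Structure(atoms + far1 + far2)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def rigid_transform_structure(structure, rotation, translation):
    coords = structure.coords @ rotation.T + translation
    return structure.with_coords(coords)


def cylinder_pore_structure(ring_radius=4.0, n_rings=9, ring_spacing=1.5, n_per_ring=24):
    """Open-ended cylindrical pore built from rings of carbon atoms along z.

    The clearance at the axis is ring_radius − vdw(C) = ring_radius − 1.7,
    which a widest-path search must recover as the bottleneck when the
    start point is inside the tube.
    """
    atoms = []
    serial = 1
    for iz in range(n_rings):
        z = iz * ring_spacing
        for k in range(n_per_ring):
            phi = 2 * np.pi * k / n_per_ring
            xyz = np.array([ring_radius * np.cos(phi), ring_radius * np.sin(phi), z])
            atoms.append(Atom(serial, "C1", "C", "POR", iz + 1, "A", xyz, hetero=True))
            serial += 1
    return Structure(atoms)


@pytest.fixture
def pore_wide():
    return cylinder_pore_structure(ring_radius=4.0)


@pytest.fixture
def pore_narrow():
    return cylinder_pore_structure(ring_radius=3.4)
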