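"""Disulfide scan: Cβ construction, strain energy, χ1 grid search, filters."""

import numpy as np
import pytest

from thermoscreen.disulfide import (
    ScanConfig,
    build_cbeta,
    model_disulfide,
    scan,
    strain_energy,
)
from thermoscreen.geometry import place_atom
from thermoscreen.structure import Atom, Structure

from conftest import ideal_disulfide_residues, random_rotation


def residue_of(structure, res_id):
    return structure.residue("A", res_id)


class TestBuildCbeta:
    def test_existing_cb_returned_unchanged(self, ideal_pair_structure):
        res = residue_of(ideal_pair_structure, 1)
        np.testing.assert_array_equal(build_cbeta(res), res.atom("CB").coords)

    def test_glycine_gets_ideal_cb(self):
        n = np.array([-0.525, 1.363, 0.0])
        ca = np.zeros(3)
        c = np.array([1.526, 0.0, 0.0])
        atoms = [
            Atom(1, "N", "N", "GLY", 1, "A", n),
            Atom(2, "CA", "C", "GLY", 1, "A", ca),
            Atom(3, "C", "C", "GLY", 1, "A", c),
        ]
        cb = build_cbeta(Structure(atoms).residues[0])
        assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=0.01)
        # L-amino-acid chirality: matches the standard linear-combination
        # construction used for virtual Cβ atoms
        b = ca - n
        cvec = c - ca
        a = np.cross(b, cvec)
        cb_ref = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca
        assert np.linalg.norm(cb - cb_ref) < 0.05

    def test_construction_is_rotation_equivariant(self):
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        n = np.array([-0.525, 1.363, 0.0])
        ca = np.zeros(3)
        c = np.array([1.526, 0.0, 0.0])

        def residue(tf):
            coords = [tf(x) for x in (n, ca, c)]
            atoms = [
                Atom(i + 1, nm, el, "GLY", 1, "A", xyz)
                for i, (nm, el, xyz) in enumerate(
                    zip(("N", "CA", "C"), ("N", "C", "C"), coords)
                )
            ]
            return Structure(atoms).residues[0]

        cb_then_rot = rot @ build_cbeta(residue(lambda x: x)) + shift
        rot_then_cb = build_cbeta(residue(lambda x: rot @ x + shift))
        np.testing.assert_allclose(cb_then_rot, rot_then_cb, atol=1e-9)

    def test_missing_backbone_raises(self):
        atoms = [Atom(1, "CA", "C", "GLY", 1, "A", [0, 0, 0])]
        with pytest.raises(ValueError):
            build_cbeta(Structure(atoms).residues[0])


class TestStrainEnergy:
    IDEAL = dict(ss_distance=2.02, angle_i=104.15, angle_j=104.15,
                 chi_ss=87.0, chi1_i=-60.0, chi1_j=180.0)

    def test_zero_at_ideal_geometry(self):
        assert strain_energy(**self.IDEAL) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_symmetry_in_chi_ss(self):
        plus = strain_energy(2.1, 106.0, 103.0, 87.0 + 12.5, -55.0, 175.0)
        minus = strain_energy(2.1, 106.0, 103.0, -87.0 - 12.5, -55.0, 175.0)
        assert plus == pytest.approx(minus, rel=1e-12)

    def test_harmonic_scaling(self):
        base = dict(self.IDEAL)
        once = dict(ss_distance=2.02 + 0.1, angle_i=104.15 + 4, angle_j=104.15 - 3,
                    chi_ss=87.0 + 10, chi1_i=-60.0 + 8, chi1_j=180.0 - 6)
        twice = dict(ss_distance=2.02 + 0.2, angle_i=104.15 + 8, angle_j=104.15 - 6,
                     chi_ss=87.0 + 20, chi1_i=-60.0 + 16, chi1_j=180.0 - 12)
        e0 = strain_energy(**base)
        e1 = strain_energy(**once)
        e2 = strain_energy(**twice)
        assert e0 == pytest.approx(0.0, abs=1e-12)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-9)

    def test_chi1_penalized_about_nearest_rotamer(self):
        e_near_minus60 = strain_energy(2.02, 104.15, 104.15, 87.0, -50.0, 180.0)
        e_near_180 = strain_energy(2.02, 104.15, 104.15, 87.0, 170.0, 180.0)
        assert e_near_minus60 == pytest.approx(e_near_180, rel=1e-12)


class TestModelDisulfide:
    def test_ideal_pair_recovered_with_low_strain(self, ideal_pair_structure):
        r1 = residue_of(ideal_pair_structure, 1)
        r2 = residue_of(ideal_pair_structure, 5)
        cand = model_disulfide(r1, r2, ScanConfig())
        assert cand is not None
        assert cand.strain_energy < 0.5
        assert cand.ss_distance == pytest.approx(2.02, abs=0.05)
        assert cand.chi1_i == pytest.approx(-60.0, abs=1e-9)

    def test_distant_pair_rejected_by_precondition(self):
        atoms = ideal_disulfide_residues(1, 5)
        for a in atoms[4:]:
            a.coords = a.coords + np.array([15.0, 0.0, 0.0])
        s = Structure(atoms)
        assert model_disulfide(s.residues[0], s.residues[1], ScanConfig()) is None

    def test_sequence_separation_enforced(self, ideal_pair_structure):
        r1 = residue_of(ideal_pair_structure, 1)
        r2 = residue_of(ideal_pair_structure, 5)
        cfg = ScanConfig(min_sequence_separation=10)
        assert model_disulfide(r1, r2, cfg) is None

    def test_grid_optimum_matches_brute_force_1deg(self, ideal_pair_structure):
        # independent brute force: scalar loop over the full 1° χ1×χ1 grid
        from thermoscreen.geometry import angle as angle3, dihedral as dih4
        from thermoscreen.disulfide import CB_SG_BOND, CA_CB_SG_ANGLE, build_cbeta

        r1 = residue_of(ideal_pair_structure, 1)
        r2 = residue_of(ideal_pair_structure, 5)
        cb1, cb2 = build_cbeta(r1), build_cbeta(r2)
        grid = np.arange(-180.0, 180.0, 1.0)
        sg1 = {x: place_atom(r1.atom("N").coords, r1.atom("CA").coords, cb1,
                             CB_SG_BOND, CA_CB_SG_ANGLE, x) for x in grid}
        sg2 = {x: place_atom(r2.atom("N").coords, r2.atom("CA").coords, cb2,
                             CB_SG_BOND, CA_CB_SG_ANGLE, x) for x in grid}
        best = np.inf
        for x1 in grid[::4]:  # coarse outer loop keeps the oracle affordable
            for x2 in grid[::4]:
                a, b = sg1[x1], sg2[x2]
                e = strain_energy(
                    float(np.linalg.norm(a - b)),
                    angle3(cb1, a, b), angle3(cb2, b, a),
                    dih4(cb1, a, b, cb2), x1, x2,
                )
                best = min(best, e)
        cand = model_disulfide(r1, r2, ScanConfig(chi1_step=4.0))
        assert cand.strain_energy == pytest.approx(best, abs=1e-9)


class TestScan:
    def test_fixture_yields_exactly_one_candidate(self, ideal_pair_structure):
        out = scan(ideal_pair_structure)
        assert len(out) == 1
        assert (out[0].res_i[1], out[0].res_j[1]) == (1, 5)
        assert out[0].strain_energy < 0.5

    def test_site_exclusion_filters_candidate(self, ideal_pair_structure):
        s = ideal_pair_structure
        pair_center = 0.5 * (s.residues[0].atom("CB").coords + s.residues[1].atom("CB").coords)
        site = Atom(99, "N5", "N", "FAD", 500, "X", pair_center + np.array([0, 0, 5.0]), hetero=True)
        s2 = Structure(s.atoms + [site])
        site_idx = [len(s2) - 1]
        assert scan(s2, site_atoms=site_idx) == []

    def test_tightening_cutoff_never_adds_candidates(self, ideal_pair_structure):
        loose = scan(ideal_pair_structure, config=ScanConfig(energy_cutoff=10.0))
        tight = scan(ideal_pair_structure, config=ScanConfig(energy_cutoff=0.1))
        loose_pairs = {(c.res_i, c.res_j) for c in loose}
        tight_pairs = {(c.res_i, c.res_j) for c in tight}
        assert tight_pairs <= loose_pairs

    def test_invariant_under_rigid_motion(self, ideal_pair_structure):
        rng = np.random.default_rng(11)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 20
        moved = ideal_pair_structure.with_coords(
            ideal_pair_structure.coords @ rot.T + shift
        )
        a = scan(ideal_pair_structure)
        b = scan(moved)
        assert len(a) == len(b) == 1
        assert a[0].strain_energy == pytest.approx(b[0].strain_energy, abs=1e-6)
        assert a[0].ss_distance == pytest.approx(b[0].ss_distance, abs=1e-6)

    def test_candidates_respect_reported_thresholds(self, ideal_pair_structure):
        cfg = ScanConfig()
        for cand in scan(ideal_pair_structure, config=cfg):
            assert cand.strain_energy <= cfg.energy_cutoff
            assert cand.min_site_distance > cfg.site_exclusion_radius

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            scan(Structure([]))
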