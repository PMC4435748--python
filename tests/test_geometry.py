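"""Donor angles, geometry templates, dihedrals, Ramachandran windows."""

import math

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral

from nicoord.coordination import find_metal_sites
from nicoord.errors import NotClassifiableError, ValidationError
from nicoord.geometry import (
    GEOMETRY_LABELS,
    TEMPLATE_ANGLES,
    TEMPLATE_DIRECTIONS,
    DihedralPair,
    backbone_dihedrals,
    classify_geometry,
    dihedral,
    donor_angles,
    ramachandran_region,
    residue_denticity,
    secondary_structure_label,
)
from nicoord.structure_model import StructureModel
from nicoord.synthetic_data import SiteSpec, make_ideal_site

from conftest import make_atom


def site_from_directions(directions, bond=2.1):
    model = StructureModel("GEO")
    model.add_atom(make_atom(1, "NI", "Ni", "NI", "A", 500, (0, 0, 0), is_het=True))
    for i, d in enumerate(directions):
        unit = np.asarray(d, float)
        unit = unit / np.linalg.norm(unit)
        model.add_atom(
            make_atom(i + 2, "NE2", "N", "HIS", "A", 10 + 2 * i, unit * bond)
        )
    return find_metal_sites(model)[0]


class TestDonorAngles:
    def test_right_angle(self):
        site = site_from_directions([(1, 0, 0), (0, 1, 0)])
        assert donor_angles(site) == [pytest.approx(90.0)]

    def test_trans_pair(self):
        site = site_from_directions([(1, 0, 0), (-1, 0, 0)])
        assert donor_angles(site) == [pytest.approx(180.0)]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_vector_algebra_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        dirs = rng.normal(size=(4, 3))
        site = site_from_directions(dirs)
        contacts = site.donor_atoms()
        expected = []
        for i in range(len(contacts)):
            for j in range(i + 1, len(contacts)):
                u = contacts[i].atom.xyz - site.metal.xyz
                v = contacts[j].atom.xyz - site.metal.xyz
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                expected.append(math.degrees(math.acos(np.clip(cosang, -1, 1))))
        assert np.allclose(sorted(donor_angles(site)), sorted(expected), atol=1e-9)

    def test_single_donor_rejected(self):
        site = site_from_directions([(1, 0, 0)])
        with pytest.raises(ValidationError):
            donor_angles(site)


def brute_force_label(site):
    """Independent exhaustive template scan (plain loops, no shortcuts)."""
    observed = sorted(donor_angles(site))
    best, best_rmsd = None, float("inf")
    for label, variants in TEMPLATE_ANGLES.items():
        if len(TEMPLATE_DIRECTIONS[label]) != len(site.donor_atoms()):
            continue
        for ideal in variants:
            sq = sum((a - b) ** 2 for a, b in zip(observed, sorted(ideal)))
            rmsd = (sq / len(observed)) ** 0.5
            if rmsd < best_rmsd:
                best, best_rmsd = label, rmsd
    return best


class TestClassifyGeometry:
    @pytest.mark.parametrize("label", GEOMETRY_LABELS)
    def test_ideal_templates_recovered_exactly(self, label):
        site = site_from_directions(TEMPLATE_DIRECTIONS[label])
        assignment = classify_geometry(site)
        assert assignment.label == label
        assert assignment.angular_rmsd < 1e-6
        assert not assignment.distorted

    def test_see_saw_with_reported_angles(self):
        # trans pair at 176.76 deg, cis angles near 94 deg
        theta = math.radians(176.76 / 2)
        dirs = [
            (math.sin(theta), 0, math.cos(theta)),
            (-math.sin(theta), 0, math.cos(theta)),
            (0, math.sin(math.radians(50)), -math.cos(math.radians(50))),
            (0, -math.sin(math.radians(50)), -math.cos(math.radians(50))),
        ]
        site = site_from_directions(dirs)
        assert classify_geometry(site).label == "see_saw"

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_tetrahedron_matches_template_scan(self, seed):
        model = make_ideal_site(
            SiteSpec(geometry_label="tetrahedral", noise_sigma=0.05, seed=seed)
        )
        site = find_metal_sites(model)[0]
        assignment = classify_geometry(site)
        assert assignment.label == brute_force_label(site)
        assert assignment.label == "tetrahedral"

    def test_rotation_translation_scale_invariance(self):
        model = make_ideal_site(
            SiteSpec(geometry_label="square_pyramidal", noise_sigma=0.03, seed=5)
        )
        theta = 1.1
        rot = np.array(
            [[1, 0, 0],
             [0, math.cos(theta), -math.sin(theta)],
             [0, math.sin(theta), math.cos(theta)]]
        )
        moved = model.transformed(1.7 * rot, np.array([3.0, 4.0, -2.0]))
        a = classify_geometry(find_metal_sites(model)[0])
        # scaled site needs a wider shell to recapture donors
        b = classify_geometry(find_metal_sites(moved, cutoff=6.0)[0])
        assert a.label == b.label
        assert a.angular_rmsd == pytest.approx(b.angular_rmsd, abs=1e-6)

    def test_noise_increases_mean_rmsd(self):
        def mean_rmsd(sigma):
            vals = []
            for seed in range(30):
                model = make_ideal_site(
                    SiteSpec(geometry_label="octahedral", noise_sigma=sigma, seed=seed)
                )
                vals.append(
                    classify_geometry(find_metal_sites(model)[0]).angular_rmsd
                )
            return float(np.mean(vals))

        assert mean_rmsd(0.0) <= mean_rmsd(0.03) <= mean_rmsd(0.1)

    def test_too_few_donors(self):
        site = site_from_directions([(1, 0, 0)])
        with pytest.raises(NotClassifiableError):
            classify_geometry(site)

    def test_more_than_six_donors_irregular(self):
        dirs = np.random.default_rng(0).normal(size=(7, 3))
        site = site_from_directions(dirs)
        assert classify_geometry(site).label == "irregular"


class TestResidueDenticity:
    def _site(self):
        model = StructureModel("DENT")
        model.add_atom(make_atom(1, "NI", "Ni", "NI", "A", 500, (0, 0, 0), is_het=True))
        model.add_atom(make_atom(2, "OE1", "O", "GLU", "A", 30, (2.1, 0, 0)))
        model.add_atom(make_atom(3, "OE2", "O", "GLU", "A", 30, (0, 2.3, 0)))
        model.add_atom(make_atom(4, "NE2", "N", "HIS", "A", 40, (0, 0, 2.1)))
        return find_metal_sites(model)[0]

    def test_bidentate_glutamate(self):
        assert residue_denticity(self._site(), ("A", 30, "")) == "bi"

    def test_monodentate_histidine(self):
        assert residue_denticity(self._site(), ("A", 40, "")) == "mono"

    def test_tridentate(self):
        model = StructureModel("TRI")
        model.add_atom(make_atom(1, "NI", "Ni", "NI", "A", 500, (0, 0, 0), is_het=True))
        for i, pos in enumerate([(2.1, 0, 0), (0, 2.1, 0), (0, 0, 2.1)]):
            model.add_atom(make_atom(i + 2, f"N{i}", "N", "HIS", "A", 30, pos))
        site = find_metal_sites(model)[0]
        assert residue_denticity(site, ("A", 30, "")) == "tri"

    def test_absent_residue_raises(self):
        with pytest.raises(LookupError):
            residue_denticity(self._site(), ("A", 99, ""))


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_mirroring_negates_sign(self):
        pts = [(0.3, 1.0, 0.2), (0.0, 0.0, 0.0), (1.0, 0.1, -0.2), (1.4, -0.8, 0.9)]
        mirrored = [(x, y, -z) for x, y, z in pts]
        assert dihedral(*pts) == pytest.approx(-dihedral(*mirrored))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        theta = 0.9
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        rotated = [rot @ p for p in pts]
        assert dihedral(*pts) == pytest.approx(dihedral(*rotated))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_biopython_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        ours = dihedral(*pts)
        oracle = math.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
        assert ours == pytest.approx(oracle, abs=1e-9)


def tripeptide_with_phi_psi(phi_deg: float, psi_deg: float) -> StructureModel:
    """Build N-CA-C backbones for residues 1–3 such that residue 2 has the
    requested φ/ψ, by rotating the flanking atoms about the φ/ψ bonds."""
    # residue 2 core geometry (idealised, in plane)
    n2 = np.array([0.0, 0.0, 0.0])
    ca2 = np.array([1.46, 0.0, 0.0])
    c2 = ca2 + 1.52 * np.array([math.cos(math.radians(69)), math.sin(math.radians(69)), 0.0])

    def place(p1, p2, p3, length, bond_angle_deg, torsion_deg):
        # position p4 with given internal coordinates relative to p1-p2-p3
        b1 = p2 - p1
        b2 = p3 - p2
        b2n = b2 / np.linalg.norm(b2)
        n = np.cross(b1, b2)
        n = n / np.linalg.norm(n)
        m = np.cross(n, b2n)
        ang = math.radians(180.0 - bond_angle_deg)
        tor = math.radians(torsion_deg)
        d = np.array(
            [-length * math.cos(math.radians(bond_angle_deg)),
             length * math.sin(math.radians(bond_angle_deg)) * math.cos(tor),
             length * math.sin(math.radians(bond_angle_deg)) * math.sin(tor)]
        )
        frame = np.column_stack([b2n, m, n])
        return p3 + frame @ d

    c1 = place(c2, ca2, n2, 1.33, 122.0, phi_deg)       # φ = C(i-1)-N-CA-C read backwards
    n3 = place(n2, ca2, c2, 1.33, 114.0, psi_deg)
    ca1 = c1 + np.array([-1.0, -1.0, 0.5])
    n1 = ca1 + np.array([-1.0, 0.5, 0.0])
    ca3 = n3 + np.array([1.2, 0.8, -0.3])
    c3 = ca3 + np.array([1.0, -0.7, 0.4])

    model = StructureModel("PEP")
    coords = {
        1: {"N": n1, "CA": ca1, "C": c1},
        2: {"N": n2, "CA": ca2, "C": c2},
        3: {"N": n3, "CA": ca3, "C": c3},
    }
    serial = 1
    for seq, atoms in coords.items():
        for name, pos in atoms.items():
            model.add_atom(
                make_atom(serial, name, "N" if name == "N" else "C",
                          "ALA", "A", seq, pos)
            )
            serial += 1
    return model


class TestBackboneDihedrals:
    @pytest.mark.parametrize("phi,psi", [(-60, -45), (-120, 130), (95, 30)])
    def test_constructed_torsions_recovered(self, phi, psi):
        model = tripeptide_with_phi_psi(phi, psi)
        pair = backbone_dihedrals(model, ("A", 2, ""))
        assert pair.phi == pytest.approx(phi, abs=1e-6)
        assert pair.psi == pytest.approx(psi, abs=1e-6)

    def test_terminal_residue_undefined(self):
        model = tripeptide_with_phi_psi(-60, -45)
        first = backbone_dihedrals(model, ("A", 1, ""))
        last = backbone_dihedrals(model, ("A", 3, ""))
        assert first.phi is None
        assert last.psi is None

    def test_unknown_residue(self):
        model = tripeptide_with_phi_psi(-60, -45)
        with pytest.raises(LookupError):
            backbone_dihedrals(model, ("A", 99, ""))


class TestRamachandranRegion:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [(-60, -45, "A"), (-120, 130, "B"), (95, 30, "E"),
         (-100, -150, "B"),   # sheet window wraps through -180
         (-60, 59.9, "A"), (-60, 60, "B"),
         (150, -100, "other"),
         (None, 30, "undefined")],
    )
    def test_windows(self, phi, psi, expected):
        assert ramachandran_region(DihedralPair(("A", 1, ""), phi, psi)) == expected


class TestSecondaryStructureLabel:
    def test_helix_sheet_turn_mapping(self):
        from nicoord.coordination import toy_loop

        loop = toy_loop([("H", 10), ("D", 12), ("H", 14)])
        dihedrals = [
            DihedralPair(("A", 10, ""), -60, -45, region="A"),
            DihedralPair(("A", 12, ""), -120, 130, region="B"),
            DihedralPair(("A", 14, ""), 150, -100, region="other"),
        ]
        assert secondary_structure_label(loop, dihedrals) == "HST"

    def test_all_helix(self):
        from nicoord.coordination import toy_loop

        loop = toy_loop([("H", 1), ("H", 4), ("H", 8)])
        dihedrals = [DihedralPair(("A", p, ""), -60, -45, region="A") for p in (1, 4, 8)]
        assert secondary_structure_label(loop, dihedrals) == "HHH"
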