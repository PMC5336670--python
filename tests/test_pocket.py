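"""Pocket geometry: residue finding, contact classification, occlusion."""

import math

import numpy as np
import pytest

from erlbd.errors import ValidationError
from erlbd.pocket import (
    VDW_RADII,
    analyze_pocket,
    detect_hbonds,
    detect_vdw_contacts,
    fibonacci_sphere,
    find_pocket_residues,
    occlusion_score,
)
from erlbd.structures import Atom, Structure
from erlbd.synth import make_contact_scene, make_pocket_scene, random_rotation


def _atom(name, element, resname, resnum, pos, chain="A", hetero=False):
    return Atom(name, element, resname, resnum, chain,
                np.asarray(pos, float), is_hetero=hetero)


def point_ligand(element="C", pos=(0.0, 0.0, 0.0)):
    return Structure([_atom("L1", element, "LIG", 1, pos, chain="L", hetero=True)])


class TestPocketResidues:
    def test_single_residue_within_cutoff(self):
        receptor = Structure([
            _atom("CB", "C", "ALA", 7, (3.0, 0.0, 0.0)),
            _atom("CB", "C", "VAL", 8, (20.0, 0.0, 0.0)),
        ])
        found = find_pocket_residues(receptor, point_ligand(), cutoff=4.5)
        assert [r.residue_number for r in found] == [7]

    def test_everything_far_gives_empty_list(self):
        receptor = Structure([_atom("CB", "C", "ALA", 1, (12.0, 0.0, 0.0))])
        assert find_pocket_residues(receptor, point_ligand(), cutoff=4.5) == []

    def test_shell_of_eight_residues_all_found(self):
        dirs = fibonacci_sphere(8)
        receptor = Structure([
            _atom("CB", "C", "ALA", i + 1, 4.0 * d) for i, d in enumerate(dirs)
        ])
        found = find_pocket_residues(receptor, point_ligand(), cutoff=4.5)
        assert len(found) == 8

    def test_matches_brute_force_all_pairs(self, rng):
        receptor = Structure([
            _atom("CB", "C", "ALA", i + 1, p)
            for i, p in enumerate(rng.uniform(-8, 8, size=(40, 3)))
        ])
        lig = Structure([
            _atom(f"L{i}", "C", "LIG", 1, p, chain="L", hetero=True)
            for i, p in enumerate(rng.uniform(-2, 2, size=(4, 3)))
        ])
        found = {r.residue_number for r in find_pocket_residues(receptor, lig, 4.5)}
        brute = set()
        for a in receptor.atoms:
            for b in lig.atoms:
                if np.linalg.norm(a.position - b.position) <= 4.5:
                    brute.add(a.residue_number)
        assert found == brute

    def test_empty_ligand_rejected(self):
        receptor = Structure([_atom("CB", "C", "ALA", 1, (1.0, 0.0, 0.0))])
        with pytest.raises(ValidationError):
            find_pocket_residues(receptor, Structure([]), 4.5)


class TestHbonds:
    def test_carboxylate_to_hydroxyl_near_linear(self):
        receptor = Structure([
            _atom("OE1", "O", "GLU", 1, (2.9, 0.0, 0.0)),
            _atom("CD", "C", "GLU", 1, (4.15, 0.0, 0.0)),
        ])
        ligand = Structure([
            _atom("O1", "O", "LIG", 1, (0.0, 0.0, 0.0), chain="L", hetero=True),
            _atom("C1", "C", "LIG", 1, (-1.4, 0.0, 0.0), chain="L", hetero=True),
        ])
        found = detect_hbonds(receptor, ligand)
        assert len(found) == 1
        assert found[0].kind == "hbond"
        assert found[0].distance == pytest.approx(2.9)
        assert found[0].angle == pytest.approx(180.0)

    def test_distance_beyond_cutoff_rejected(self):
        receptor = Structure([_atom("OE1", "O", "GLU", 1, (5.0, 0.0, 0.0))])
        assert detect_hbonds(receptor, point_ligand("O")) == []

    def test_carbon_pairs_excluded_by_typing(self):
        receptor = Structure([_atom("CB", "C", "ALA", 1, (2.9, 0.0, 0.0))])
        assert detect_hbonds(receptor, point_ligand("C")) == []

    def test_bent_geometry_rejected(self):
        # antecedent on the same side as the partner: angle ~0
        receptor = Structure([
            _atom("OG", "O", "SER", 1, (2.9, 0.0, 0.0)),
            _atom("CB", "C", "SER", 1, (1.5, 0.0, 0.0)),
        ])
        assert detect_hbonds(receptor, point_ligand("O")) == []

    def test_distance_only_when_no_antecedent(self):
        receptor = Structure([_atom("O", "O", "HOH", 1, (2.9, 0.0, 0.0))])
        found = detect_hbonds(receptor, point_ligand("N"))
        assert len(found) == 1
        assert found[0].angle is None


class TestVdwContacts:
    def test_carbon_pair_inside_threshold(self):
        receptor = Structure([_atom("CB", "C", "ALA", 1, (3.6, 0.0, 0.0))])
        found = detect_vdw_contacts(receptor, point_ligand("C"), slack=0.5)
        assert len(found) == 1  # threshold 1.7 + 1.7 + 0.5 = 3.9

    def test_pair_outside_threshold(self):
        receptor = Structure([_atom("CB", "C", "ALA", 1, (4.5, 0.0, 0.0))])
        assert detect_vdw_contacts(receptor, point_ligand("C"), slack=0.5) == []

    def test_hbond_pair_not_double_counted(self):
        receptor = Structure([
            _atom("OE1", "O", "GLU", 1, (2.9, 0.0, 0.0)),
            _atom("CD", "C", "GLU", 1, (4.15, 0.0, 0.0)),
        ])
        ligand = Structure([
            _atom("O1", "O", "LIG", 1, (0.0, 0.0, 0.0), chain="L", hetero=True),
            _atom("C1", "C", "LIG", 1, (-1.4, 0.0, 0.0), chain="L", hetero=True),
        ])
        hbonds = detect_hbonds(receptor, ligand)
        vdws = detect_vdw_contacts(receptor, ligand, hbonds=hbonds)
        hb_pairs = {(c.receptor_atom, c.ligand_atom) for c in hbonds}
        vdw_pairs = {(c.receptor_atom, c.ligand_atom) for c in vdws}
        assert hb_pairs and not (hb_pairs & vdw_pairs)

    def test_unknown_element_falls_back_to_default_radius(self, caplog):
        receptor = Structure([_atom("X1", "Xx", "UNK", 1, (3.0, 0.0, 0.0))])
        found = detect_vdw_contacts(receptor, point_ligand("C"), slack=0.5)
        assert len(found) == 1

    def test_designed_scene_counts(self):
        receptor, ligand = make_contact_scene()
        hbonds = detect_hbonds(receptor, ligand)
        vdws = detect_vdw_contacts(receptor, ligand, hbonds=hbonds)
        assert len(hbonds) == receptor.metadata["designed_hbonds"] == 1
        assert len(vdws) == receptor.metadata["designed_vdw"] == 1


class TestOcclusion:
    def test_no_receptor_is_fully_open(self):
        assert occlusion_score(Structure([]), point_ligand()) == 0.0

    def test_closed_shell_fully_occluded(self):
        receptor, ligand = make_pocket_scene(coverage=1.0, seed=1)
        occ = occlusion_score(receptor, ligand, seed=1)
        assert occ >= 1.0 - 1.0 / 512

    def test_half_cap_near_half(self):
        receptor, ligand = make_pocket_scene(coverage=0.5, seed=2)
        assert occlusion_score(receptor, ligand, seed=2) == pytest.approx(0.5, abs=0.05)

    def test_literal_hemisphere_matches_analytic_inflation(self):
        """A z>0 hemisphere blocks (1+sin α)/2 with α the inflation angle."""
        R = 8.0
        dirs = fibonacci_sphere(2000)
        cap = dirs[dirs[:, 2] > 0]
        receptor = Structure([
            _atom("C1", "C", "SPH", i + 1, R * d) for i, d in enumerate(cap)
        ])
        alpha = math.asin((VDW_RADII["C"] + 1.4) / R)
        expected = (1.0 + math.sin(alpha)) / 2.0
        occ = occlusion_score(receptor, point_ligand(), seed=0)
        assert occ == pytest.approx(expected, abs=0.05)

    def test_monotone_in_coverage(self):
        occs = []
        for cov in (0.0, 0.25, 0.5, 0.75, 1.0):
            receptor, ligand = make_pocket_scene(coverage=cov, seed=5)
            occs.append(occlusion_score(receptor, ligand, seed=5))
        assert occs == sorted(occs)
        assert occs[0] == 0.0

    def test_per_atom_origin_agrees_on_point_ligand(self):
        receptor, ligand = make_pocket_scene(coverage=0.7, seed=4)
        a = occlusion_score(receptor, ligand, seed=4, origin="centroid")
        b = occlusion_score(receptor, ligand, seed=4, origin="per_atom")
        assert a == pytest.approx(b)


class TestRigidInvariance:
    def test_classifications_and_scores_survive_rigid_motion(self, rng):
        receptor, ligand = make_contact_scene()
        report = analyze_pocket(receptor, ligand, seed=9)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        report2 = analyze_pocket(
            receptor.transformed(R, t), ligand.transformed(R, t), seed=9
        )
        assert [r for r in report.pocket_residues] == [r for r in report2.pocket_residues]
        assert [(c.kind, c.receptor_atom) for c in report.contacts] == [
            (c.kind, c.receptor_atom) for c in report2.contacts
        ]
        for c1, c2 in zip(report.contacts, report2.contacts):
            assert c1.distance == pytest.approx(c2.distance, abs=1e-8)
        assert report.occlusion == pytest.approx(report2.occlusion, abs=0.02)


class TestContactReport:
    def test_every_contacting_residue_listed_in_pocket(self):
        receptor, ligand = make_contact_scene()
        report = analyze_pocket(receptor, ligand)
        pocket = set(report.pocket_residues)
        for c in report.contacts:
            assert any(
                r.chain_id == c.receptor_atom.chain_id
                and r.residue_number == c.receptor_atom.residue_number
                for r in pocket
            )

    def test_no_pair_is_both_hbond_and_vdw(self):
        receptor, ligand = make_contact_scene()
        report = analyze_pocket(receptor, ligand)
        seen = {}
        for c in report.contacts:
            key = (c.receptor_atom, c.ligand_atom)
            assert key not in seen
            seen[key] = c.kind
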