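"""Structure parsing and geometry: dihedrals, H-bonds, SASA, contacts."""
import math

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral

from pdzscan import fixtures
from pdzscan.structure import (
    EmptyBindingSiteError,
    HB_SC_MC_AMIDE,
    HB_SC_MC_CARBONYL,
    HB_SC_SC,
    StructureParseError,
    compute_phi,
    compute_sasa,
    contacting_residues,
    derive_core_positions,
    detect_hbonds,
    dihedral,
    parse_structure,
    shrake_rupley,
    sidechain_hbond_flags,
    sphere_points,
)
from conftest import build_structure

SPEC = fixtures.FixtureSpec(seed=0, n_domains=2)


def _ala_pdb(n_res=5, chain="A", model_lines=None):
    lines = model_lines or []
    serial = 1
    for i in range(n_res):
        for j, name in enumerate(("N", "CA", "C", "O")):
            x = 3.0 * i + 0.8 * j
            lines.append(fixtures._format_pdb_atom(
                serial, name, "ALA", chain, i + 1, (x, 0.0, 0.0), name[0]))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestParsing:
    def test_single_model_identity_parse(self):
        s = parse_structure(_ala_pdb(5))
        assert s.chains == {"A": 5}
        assert s.sequence("A") == "AAAAA"

    def test_multi_model_keeps_first_model_only(self):
        m1 = _ala_pdb(5).replace("END\n", "ENDMDL\n")
        m2 = _ala_pdb(7).replace("END\n", "ENDMDL\nEND\n")
        text = "MODEL        1\n" + m1 + "MODEL        2\n" + m2
        s = parse_structure(text)
        assert s.chains == {"A": 5}
        s2 = parse_structure(text, model_index=1)
        assert s2.chains == {"A": 7}

    def test_bound_peptide_chain_parsed_separately(self):
        # domain chain A with a bound 6-mer peptide chain B, as in a
        # PDZ/peptide complex whose ligand reads RRETQV
        pep = fixtures.build_backbone(
            [(fixtures.STRAND_PHI, fixtures.STRAND_PSI)] * 6)
        pep = [{k: v + np.array([0.0, 8.0, 0.0]) for k, v in r.items()}
               for r in pep]
        pep_lines, _ = fixtures.chain_to_pdb_lines(
            "RRETQV", pep, "B", serial_start=100, with_sidechains=False)
        text = _ala_pdb(5).replace("END\n", "TER\n") \
            + "\n".join(pep_lines) + "\nEND\n"
        s = parse_structure(text)
        assert set(s.chains) == {"A", "B"}
        assert s.sequence("B") == "RRETQV"

    def test_malformed_atom_record_names_line(self):
        text = _ala_pdb(3)
        lines = text.splitlines()
        lines[4] = lines[4][:30] + "   xx.yyy" + lines[4][39:]
        with pytest.raises(StructureParseError, match="line 5"):
            parse_structure("\n".join(lines))

    def test_hetatm_and_waters_discarded(self):
        text = _ala_pdb(3).replace(
            "END",
            "HETATM  900  O   HOH A 500      20.000  20.000  20.000"
            "  1.00  0.00           O\nEND")
        s = parse_structure(text)
        assert s.chains == {"A": 3}

    def test_altloc_highest_occupancy_wins(self):
        a = ("ATOM      1  CA AALA A   1       0.000   0.000   0.000"
             "  0.30  0.00           C")
        b = ("ATOM      2  CA BALA A   1       9.000   0.000   0.000"
             "  0.70  0.00           C")
        s = parse_structure("\n".join([a, b, "END"]) + "\n")
        (atom,) = s.atoms
        assert atom.coords[0] == pytest.approx(9.0)


class TestDihedrals:
    def test_planar_trans_is_180(self):
        # C(i-1), N, CA, C coplanar with the outer atoms on opposite sides
        s = build_structure([
            ("ALA", {"C": (0.0, 1.0, 0.0, "C")}),
            ("ALA", {"N": (1.0, 0.0, 0.0, "N"),
                     "CA": (2.0, 0.0, 0.0, "C"),
                     "C": (3.0, -1.0, 0.0, "C")}),
        ])
        phi = compute_phi(s, "A")
        assert phi[0] is None
        assert phi[1] == pytest.approx(180.0, abs=1e-9)

    def test_mirror_image_negates_phi(self):
        spec_coords = [
            ("ALA", {"C": (0.0, 1.0, 0.3, "C")}),
            ("ALA", {"N": (1.0, 0.0, 0.1, "N"),
                     "CA": (2.0, 0.2, 0.0, "C"),
                     "C": (3.0, -1.0, 0.4, "C")}),
        ]
        mirrored = [(r, {k: (x, y, -z, e) for k, (x, y, z, e) in am.items()})
                    for r, am in spec_coords]
        phi = compute_phi(build_structure(spec_coords), "A")[1]
        phi_m = compute_phi(build_structure(mirrored), "A")[1]
        assert phi_m == pytest.approx(-phi, abs=1e-9)

    def test_idealized_helix_has_negative_phi(self):
        s = parse_structure(fixtures.make_toy_domain(SPEC, 0))
        phi = compute_phi(s, "A")
        helix = phi[SPEC.strand_length + 1:]
        assert all(p is not None and -80 < p < -40 for p in helix)

    def test_agrees_with_independent_four_point_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 5
            ours = dihedral(*pts)
            ref = math.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
            delta = abs(ours - ref) % 360.0
            assert min(delta, 360.0 - delta) < 1e-9


def _ser_carbonyl_pair(distance):
    """SER whose OG sits ``distance`` from the backbone O of residue 0,
    with a wide antecedent angle."""
    return build_structure([
        ("GLY", {"N": (-1.4, 1.0, 0.0, "N"), "CA": (-0.7, 0.0, 0.0, "C"),
                 "C": (0.0, 1.0, 0.0, "C"), "O": (0.0, 2.2, 0.0, "O")}),
        ("SER", {"N": (1.2, 0.5, 0.0, "N"), "CA": (2.4, 1.2, 0.0, "C"),
                 "C": (3.6, 0.5, 0.0, "C"), "O": (3.6, -0.8, 0.0, "O"),
                 "CB": (0.8, 3.4 + distance, 0.0, "C"),
                 "OG": (0.0, 2.2 + distance, 0.0, "O")}),
    ])


class TestHBonds:
    def test_ser_og_to_backbone_carbonyl(self):
        bonds = detect_hbonds(_ser_carbonyl_pair(2.9))
        kinds = {b.kind for b in bonds}
        assert HB_SC_MC_CARBONYL in kinds
        (bond,) = [b for b in bonds if b.kind == HB_SC_MC_CARBONYL]
        assert bond.donor[2] == "OG" and bond.acceptor[2] == "O"
        assert bond.distance == pytest.approx(2.9)

    def test_beyond_cutoff_no_bond(self):
        assert detect_hbonds(_ser_carbonyl_pair(5.0)) == []

    def test_asp_arg_sidechain_sidechain(self):
        s = build_structure([
            ("ASP", {"CA": (0.0, 0.0, 0.0, "C"), "CB": (1.0, 0.5, 0.0, "C"),
                     "CG": (2.0, 1.0, 0.0, "C"), "OD1": (3.0, 1.5, 0.0, "O")}),
            ("ARG", {"CA": (8.0, 4.0, 0.0, "C"), "CZ": (6.5, 2.8, 0.0, "C"),
                     "NH1": (5.3, 2.3, 0.0, "N")}),
        ])
        bonds = detect_hbonds(s)
        assert any(b.kind == HB_SC_SC and b.donor[2] == "NH1"
                   and b.acceptor[2] == "OD1" for b in bonds)
        flags = sidechain_hbond_flags(s, bonds)
        assert flags[("A", 0)][HB_SC_SC] and flags[("A", 1)][HB_SC_SC]

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        s = parse_structure(fixtures.make_toy_domain(SPEC, 1))
        rot = Rotation.from_euler("zyx", [71.0, -15.0, 140.0],
                                  degrees=True).as_matrix()
        s2 = s.transformed(rot, np.array([3.0, -8.0, 2.0]))
        key = lambda b: (b.donor, b.acceptor, b.kind)
        b1 = sorted(detect_hbonds(s), key=key)
        b2 = sorted(detect_hbonds(s2), key=key)
        assert [key(b) for b in b1] == [key(b) for b in b2]
        assert np.allclose([b.distance for b in b1],
                           [b.distance for b in b2], atol=1e-9)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        areas = shrake_rupley(np.zeros((1, 3)), np.array([1.7]),
                              probe_radius=1.4, n_points=960)
        expected = 4 * math.pi * 3.1 ** 2
        assert areas[0] == pytest.approx(expected, rel=0.005)

    def test_occlusion_strictly_decreases_area(self):
        radii = np.array([1.7, 1.7])
        far = shrake_rupley(np.array([[0, 0, 0], [20, 0, 0]], float), radii)
        near = shrake_rupley(np.array([[0, 0, 0], [2.5, 0, 0]], float), radii)
        assert near.sum() < far.sum()
        assert far.sum() == pytest.approx(2 * 4 * math.pi * 3.1 ** 2, rel=0.005)

    def test_against_high_density_oracle(self):
        spec = fixtures.FixtureSpec(seed=3, n_domains=1, strand_length=3,
                                    helix_length=2, site_length=1)
        s = parse_structure(fixtures.make_toy_domain(spec, 0))
        res = compute_sasa(s, n_points=960)
        oracle = compute_sasa(s, n_points=9600)
        for key, area in res.residue_areas.items():
            assert area == pytest.approx(oracle.residue_areas[key], rel=0.05)
        assert res.total == pytest.approx(sum(res.residue_areas.values()))

    def test_bounded_by_isolated_sphere_sum(self):
        s = parse_structure(fixtures.make_toy_domain(SPEC, 0))
        res = compute_sasa(s)
        from pdzscan.tables import VDW_RADII
        heavy = [a for a in s.atoms if a.is_heavy()]
        upper = sum(4 * math.pi * (VDW_RADII[a.element] + 1.4) ** 2
                    for a in heavy)
        assert res.total < upper

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


def _toy_complex(contact_distance, n_res=4):
    domain = [("ALA", {"CA": (3.0 * i, 0.0, 0.0, "C")}) for i in range(n_res)]
    # peptide chain B: single residue near domain residue 1
    specs = domain + [("GLY", {"CA": (3.0, contact_distance, 0.0, "C")})]
    atoms = build_structure(specs[:-1]).atoms
    from pdzscan.structure import Atom, DomainStructure
    atoms = list(atoms) + [Atom(99, "CA", "C", 0, "GLY", "B",
                                np.array([3.0, contact_distance, 0.0]))]
    return DomainStructure(atoms)


class TestCorePositions:
    def test_single_contact_gives_length_one(self):
        s = _toy_complex(4.0)
        site = derive_core_positions([(s, "A", "B")])
        assert site.positions == [1]
        assert site.provenance == "derived"

    def test_exact_cutoff_excluded(self):
        s = _toy_complex(4.5)
        assert contacting_residues(s, "A", "B") == set()
        with pytest.raises(EmptyBindingSiteError):
            derive_core_positions([(s, "A", "B")])

    def test_min_structures_majority_vote(self):
        close = _toy_complex(4.0)
        far = _toy_complex(6.0)
        # column 1 contacts in only 1 of 3 complexes -> excluded at min 2
        with pytest.raises(EmptyBindingSiteError):
            derive_core_positions([(close, "A", "B"), (far, "A", "B"),
                                   (far, "A", "B")], min_structures=2)
        site = derive_core_positions(
            [(close, "A", "B"), (close, "A", "B"), (far, "A", "B")],
            min_structures=2)
        assert site.positions == [1]

    def test_invariant_to_complex_order(self):
        complexes = [(_toy_complex(4.0), "A", "B"),
                     (_toy_complex(3.0), "A", "B"),
                     (_toy_complex(4.2), "A", "B")]
        a = derive_core_positions(complexes)
        b = derive_core_positions(complexes[::-1])
        assert a.positions == b.positions
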