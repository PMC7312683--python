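"""Dihedrals, secondary-structure regions, H-bond/vdW modes, Kabsch."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from minorgroove.interactions_secondary import (
    assign_secondary_structure,
    classify_vdw_contacts,
    compute_backbone_dihedrals,
    detect_hbonds,
    import_dssp,
    kabsch_superpose,
    representative_step,
    _region_label,
)
from minorgroove.structure_io import AtomRecord, ChainRecord, ResidueRecord
from minorgroove.synthetic_data import build_peptide_with_dihedrals

from conftest import duplex_of


class TestDihedrals:
    @pytest.mark.parametrize(
        "phi, psi",
        [(-60.0, -45.0), (-120.0, 130.0), (-75.0, 150.0), (55.0, 40.0)],
    )
    def test_target_dihedrals_recovered(self, phi, psi):
        chain = build_peptide_with_dihedrals("AAAAA", [(phi, psi)] * 5)
        dihedrals = compute_backbone_dihedrals(chain)
        for d in dihedrals[1:-1]:
            assert d.phi == pytest.approx(phi, abs=1e-3)
            assert d.psi == pytest.approx(psi, abs=1e-3)

    def test_termini_undefined(self):
        chain = build_peptide_with_dihedrals("AAA", [(-60.0, -45.0)] * 3)
        dihedrals = compute_backbone_dihedrals(chain)
        assert dihedrals[0].phi is None and dihedrals[0].psi is not None
        assert dihedrals[-1].psi is None and dihedrals[-1].phi is not None

    def test_single_residue_all_undefined(self):
        chain = build_peptide_with_dihedrals("A", [(-60.0, -45.0)])
        d = compute_backbone_dihedrals(chain)[0]
        assert d.phi is None and d.psi is None


class TestSecondaryStructure:
    @pytest.mark.parametrize(
        "phi, psi, label",
        [
            (-60, -45, "α-helix"),
            (-70, 10, "3-10-helix"),
            (-120, 130, "β-strand"),
            (-160, -175, "β-strand"),
            (-75, 150, "polyproline-II"),
        ],
    )
    def test_region_examples(self, phi, psi, label):
        chain = build_peptide_with_dihedrals("AAAAA", [(phi, psi)] * 5)
        labels = assign_secondary_structure(compute_backbone_dihedrals(chain), chain)
        mid = [labels[("Q", str(i))] for i in (2, 3, 4)]
        assert mid[0] == label

    def test_terminus_unassigned(self):
        chain = build_peptide_with_dihedrals("AAAA", [(-60, -45)] * 4)
        labels = assign_secondary_structure(compute_backbone_dihedrals(chain), chain)
        assert labels[("Q", "1")] == "unassigned"
        assert labels[("Q", "4")] == "unassigned"

    def test_every_grid_point_gets_exactly_one_region(self):
        # the named phi/psi regions are mutually exclusive by construction
        for phi in range(-180, 181, 5):
            for psi in range(-180, 181, 5):
                label = _region_label(float(phi), float(psi))
                assert label in (None, "α-helix", "3-10-helix", "β-strand", "polyproline-II")

    def test_extended_unstructured_chain_is_others_or_curved(self):
        chain = build_peptide_with_dihedrals("AAAAAAA", [(80.0, -100.0)] * 7)
        labels = assign_secondary_structure(compute_backbone_dihedrals(chain), chain)
        assert labels[("Q", "4")] in ("others", "turn", "bend")


def _residue_at(name, seq, atoms):
    return ResidueRecord(
        name, seq, [AtomRecord(n, n[0], np.asarray(c, float)) for n, c in atoms], kind="protein"
    )


class TestHBonds:
    def _ser_near(self, model, acceptor_atom, distance, chain="A", seq="7"):
        """A serine whose OG sits at `distance` from the named DNA atom,
        with CB placed behind it (angle ~180, always valid)."""
        res = model.residue(chain, seq)
        target = res.coord(acceptor_atom)
        # extend away from the phosphorus so no other oxygen is closer
        out = target - res.coord("P")
        out = out / np.linalg.norm(out)
        og = target + distance * out
        cb = target + (distance + 1.5) * out
        ca = target + (distance + 3.0) * out
        return _residue_at(
            "SER", "1",
            [("N", ca + [1.2, 0, 0]), ("CA", ca), ("C", ca + [0, 1.4, 0]),
             ("O", ca + [0, 2.0, 1.0]), ("CB", cb), ("OG", og)],
        )

    def test_side_chain_to_phosphate_bond(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        ser = self._ser_near(model, "OP1", 2.9)
        bonds = detect_hbonds([("Q", ser)], duplex)
        hits = [b for b in bonds if b.donor_atom == "OG" and b.acceptor_atom == "OP1"]
        assert hits
        assert hits[0].distance == pytest.approx(2.9, abs=1e-6)
        assert hits[0].protein_side == "side-chain"
        assert hits[0].dna_target == "phosphate"

    def test_beyond_cutoff_no_bond(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        ser = self._ser_near(model, "OP1", 3.8)
        bonds = detect_hbonds([("Q", ser)], duplex)
        assert not [b for b in bonds if b.donor_atom == "OG" and b.acceptor_atom == "OP1"]

    def test_backbone_to_base_bond(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        # thymine O2 is the minor-groove acceptor of residue A:2 (sequence ATGC..)
        target = model.residue("A", "2").coord("O2")
        out = target / np.linalg.norm(target)
        n_pos = target + 3.0 * out
        ca = target + 4.4 * out
        gly = _residue_at("GLY", "1", [("N", n_pos), ("CA", ca), ("C", ca + [1.5, 0, 0]), ("O", ca + [2.1, 1.0, 0])])
        bonds = detect_hbonds([("Q", gly)], duplex)
        bb = [b for b in bonds if b.protein_side == "backbone" and b.dna_target == "base"]
        assert bb
        assert bb[0].acceptor_atom == "O2"

    def test_bad_angle_rejected(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        target = model.residue("A", "7").coord("OP1")
        out = target / np.linalg.norm(target)
        og = target + 2.9 * out
        # antecedent placed BEYOND the acceptor: angle CB-OG-OP1 near 0
        cb = target + 1.4 * out
        ca = target + 0.5 * out
        ser = _residue_at("SER", "1", [("N", ca), ("CA", ca + [0.1, 0, 0]), ("CB", cb), ("OG", og)])
        bonds = detect_hbonds([("Q", ser)], duplex)
        assert not [b for b in bonds if b.donor_atom == "OG"]

    def test_dna_donor_to_protein_acceptor(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        # adenine N6 (major-groove donor) of A:1 donating to a GLU carboxylate
        res = model.residue("A", "1")
        n6 = res.coord("N6")
        c6 = res.coord("C6")
        out = (n6 - c6) / np.linalg.norm(n6 - c6)
        oe1 = n6 + 2.9 * out
        glu = _residue_at("GLU", "1", [("N", oe1 + [4, 0, 0]), ("CA", oe1 + [5, 0, 0]), ("OE1", oe1)])
        bonds = detect_hbonds([("Q", glu)], duplex)
        assert any(b.donor_atom == "N6" and b.acceptor_atom == "OE1" for b in bonds)


class TestVdW:
    def test_contact_within_cutoff(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        target = model.residue("A", "7").coord("C1'")
        out = target / np.linalg.norm(target)
        cb = target + 3.7 * out
        ala = _residue_at("ALA", "1", [("N", cb + [3, 0, 0]), ("CA", cb + [2, 0, 0]), ("CB", cb)])
        contacts = classify_vdw_contacts([("Q", ala)], duplex)
        assert any(c.protein_atom == "CB" and c.distance == pytest.approx(3.7, abs=1e-6) for c in contacts)

    def test_no_contact_beyond_cutoff(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        target = model.residue("A", "7").coord("C1'")
        out = target / np.linalg.norm(target)
        cb = target + 4.5 * out
        ala = _residue_at("ALA", "1", [("CA", cb + [2, 0, 0]), ("CB", cb)])
        contacts = classify_vdw_contacts([("Q", ala)], duplex)
        assert not [c for c in contacts if c.protein_atom == "CB" and c.dna_atom == "C1'"]

    def test_hbonded_pair_excluded(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        target = model.residue("A", "7").coord("OP1")
        out = target / np.linalg.norm(target)
        og = target + 2.9 * out
        cb = target + 4.4 * out
        ca = target + 5.9 * out
        ser = _residue_at("SER", "1", [("N", ca + [1.2, 0, 0]), ("CA", ca), ("CB", cb), ("OG", og)])
        bonds = detect_hbonds([("Q", ser)], duplex)
        assert any(b.donor_atom == "OG" and b.acceptor_atom == "OP1" for b in bonds)
        contacts = classify_vdw_contacts([("Q", ser)], duplex, hbonds=bonds)
        assert not [
            c for c in contacts if c.protein_atom == "OG" and c.dna_atom == "OP1"
        ]


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_superposes_exactly(self, rng):
        pts = rng.normal(size=(10, 3)) * 4
        rot = Rotation.from_euler("xyz", [31, -57, 111], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(moved, pts)
        assert res.rmsd <= 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_always_proper_and_orthonormal(self, rng):
        for _ in range(25):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            res = kabsch_superpose(a, b)
            np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_matches_scipy_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(size=(7, 3)) * 3
            b = rng.normal(size=(7, 3)) * 3
            res = kabsch_superpose(a, b)
            # scipy aligns b onto a after centering; rssd is sqrt(sum sq)
            rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
            assert res.rmsd == pytest.approx(rssd / np.sqrt(7), abs=1e-8)

    def test_rmsd_invariant_under_prerotation(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        base = kabsch_superpose(a, b).rmsd
        rot = Rotation.from_euler("zyx", [17, 121, -45], degrees=True).as_matrix()
        assert kabsch_superpose(a, b @ rot.T).rmsd == pytest.approx(base, abs=1e-9)
        assert kabsch_superpose(a @ rot.T, b).rmsd == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRepresentativeStep:
    def test_single_step_is_itself(self, rng):
        assert representative_step([rng.normal(size=(5, 3))]) == 0

    def test_identical_steps_tie_break_to_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        assert representative_step([pts.copy() for _ in range(4)]) == 0

    def test_outlier_never_representative(self, rng):
        base = rng.normal(size=(6, 3)) * 3
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        similar1 = base @ rot.T + 2.0
        similar2 = base + rng.normal(size=(6, 3)) * 0.05
        outlier = rng.normal(size=(6, 3)) * 6
        steps = [similar1, outlier, similar2]
        idx = representative_step(steps)
        assert idx in (0, 2)
        # verify against exhaustive pairwise sums
        sums = []
        for i in range(3):
            s = 0.0
            for j in range(3):
                if i != j:
                    s += kabsch_superpose(steps[i], steps[j]).rmsd
            sums.append(s)
        assert idx == int(np.argmin(sums))

    def test_on_dinucleotide_steps(self, b_duplex):
        from minorgroove.helix_model import enumerate_steps

        model, _ = b_duplex
        duplex = duplex_of(model)
        steps = enumerate_steps(duplex)[2:6]
        idx = representative_step(steps)
        assert 0 <= idx < len(steps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            representative_step([])


class TestDsspImport:
    def test_classic_layout_parsed(self, tmp_path):
        text = (
            "==== Secondary Structure Definition by the program DSSP ====\n"
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
            "    1    4 A M              0   0  234\n"
            "    2    5 A K  H >>          0\n"
            "    3    6 A L  E             0\n"
            "    4    7 A G  S             0\n"
        )
        path = tmp_path / "x.dssp"
        path.write_text(text)
        labels = import_dssp(path)
        assert labels[("A", "4")] == "others"
        assert labels[("A", "5")] == "α-helix"
        assert labels[("A", "6")] == "β-strand"
        assert labels[("A", "7")] == "bend"
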