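"""Reference atoms, the 6 Å nearest-reference rule, step assignment, datasets."""

from __future__ import annotations

import numpy as np
import pytest

from minorgroove._tables import REFERENCE_ATOMS
from minorgroove.contact_detection import (
    ContactRecord,
    assign_dinucleotide_step,
    build_dataset,
    ds_prune,
    find_groove_contacts,
    read_dataset_tsv,
    reference_atoms,
    write_dataset_tsv,
)
from minorgroove.groove_analysis import categorize_width
from minorgroove.structure_io import AtomRecord, ChainRecord, ResidueRecord

from conftest import duplex_of


class TestReferenceAtoms:
    @pytest.mark.parametrize(
        "base, expected",
        [
            ("dA", ("N3", "N6")),
            ("dG", ("N3", "O6")),
            ("dT", ("O2", "O4")),
            ("dC", ("O2", "N4")),
        ],
    )
    def test_mapping(self, base, expected):
        assert reference_atoms(base) == expected

    def test_nonstandard_base_rejected(self):
        with pytest.raises(ValueError):
            reference_atoms("BRU")

    def test_reference_atoms_exist_in_generated_bases(self, b_duplex):
        model, _ = b_duplex
        for chain in model.chains:
            for res in chain.residues:
                minor, major = REFERENCE_ATOMS[res.name]
                assert res.coord(minor) is not None
                assert res.coord(major) is not None


class TestContactRule:
    def test_planted_probes_recovered_exactly(self, probed_complex):
        model, ledger = probed_complex
        duplexes = [duplex_of(model)]
        contacts = find_groove_contacts(model, duplexes)
        found = {c.residue_key: c for c in contacts}
        expected = {e.residue: e for e in ledger.contacts if e.expected_in_dataset}
        assert found.keys() == expected.keys()
        for key, contact in found.items():
            e = expected[key]
            assert (contact.nucleotide_chain, contact.nucleotide_seq) == e.nucleotide
            assert contact.distance == pytest.approx(e.distance, abs=1e-6)
            assert contact.groove == "minor"

    def test_probe_beyond_cutoff_not_detected(self, probed_complex):
        model, ledger = probed_complex
        contacts = find_groove_contacts(model, [duplex_of(model)])
        found = {c.residue_key for c in contacts}
        outside = {e.residue for e in ledger.contacts if not e.expected_in_dataset}
        assert found & outside == set()

    def test_contacts_symmetric_under_rigid_motion(self, probed_complex):
        import copy

        from minorgroove._geometry import rotation_about_axis

        model, _ = probed_complex
        moved = copy.deepcopy(model)
        rot = rotation_about_axis([1.0, 1.0, 0.0], 41.0)
        shift = np.array([3.0, -7.0, 11.0])
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.coords = rot @ atom.coords + shift
        d0 = sorted(round(c.distance, 9) for c in find_groove_contacts(model, [duplex_of(model)]))
        d1 = sorted(round(c.distance, 9) for c in find_groove_contacts(moved, [duplex_of(moved)]))
        assert d0 == d1

    def test_custom_cutoff(self, probed_complex):
        model, ledger = probed_complex
        # raising the cutoff to 7 Å admits the 6.1 and 6.5 Å minor probes
        contacts = find_groove_contacts(model, [duplex_of(model)], cutoff=7.0)
        minor_planted = {e.residue for e in ledger.contacts if e.groove == "minor"}
        assert {c.residue_key for c in contacts} == minor_planted


def _single_atom_protein(model, xyz, name="GLY", seq="1"):
    """Attach a one-atom probe residue (CA only) at an exact position."""
    import copy

    out = copy.deepcopy(model)
    chain = ChainRecord(
        "Q",
        [ResidueRecord(name, seq, [AtomRecord("CA", "C", np.asarray(xyz, float))], kind="protein")],
        kind="protein",
    )
    out.chains.append(chain)
    return out


def _minor_ref_coord(model, chain_id, seq_id):
    res = model.residue(chain_id, seq_id)
    return res.coord(REFERENCE_ATOMS[res.name][0])


class TestStepAssignment:
    def _contact_for(self, model, duplex, xyz, nucleotide):
        probed = _single_atom_protein(model, xyz)
        contact = ContactRecord(
            structure_id=model.structure_id,
            residue_chain="Q",
            residue_type="GLY",
            residue_seq="1",
            nucleotide_chain=nucleotide[0],
            nucleotide_seq=nucleotide[1],
            groove="minor",
            distance=0.0,
            duplex=duplex,
        )
        return probed, contact

    def test_closer_neighbor_wins(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        target = _minor_ref_coord(model, "A", "7")
        r5 = _minor_ref_coord(model, "A", "6")
        r3 = _minor_ref_coord(model, "A", "8")
        # place the probe outside the helix, biased toward the 3' neighbor
        out_dir = target / np.linalg.norm(target)
        xyz = target + 5.0 * out_dir + 0.8 * (r3 - r5) / np.linalg.norm(r3 - r5)
        probed, contact = self._contact_for(model, duplex, xyz, ("A", "7"))
        step = assign_dinucleotide_step(contact, duplex, probed)
        p = probed.residue("Q", "1").coord("CA")
        expected_neighbor = "6" if np.linalg.norm(p - r5) <= np.linalg.norm(p - r3) else "8"
        assert expected_neighbor == "8"  # geometry biased to 3'
        assert step == 6  # step joining levels 6 and 7 (0-based)
        assert contact.step_sequence == duplex.sequence[6:8]

    def test_terminal_nucleotide_uses_single_neighbor(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        target = _minor_ref_coord(model, "A", "1")
        xyz = target + 5.0 * np.array([0.0, 0.0, -1.0])
        probed, contact = self._contact_for(model, duplex, xyz, ("A", "1"))
        assert assign_dinucleotide_step(contact, duplex, probed) == 0

    def test_exact_tie_breaks_to_five_prime(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        r5 = _minor_ref_coord(model, "A", "6")
        r3 = _minor_ref_coord(model, "A", "8")
        # a point on the perpendicular bisector plane of the two neighbors
        mid = 0.5 * (r5 + r3)
        diff = r3 - r5
        perp = np.cross(diff, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        xyz = mid + 6.0 * perp
        d5 = np.linalg.norm(xyz - r5)
        d3 = np.linalg.norm(xyz - r3)
        assert d5 == pytest.approx(d3, abs=1e-9)
        probed, contact = self._contact_for(model, duplex, xyz, ("A", "7"))
        assert assign_dinucleotide_step(contact, duplex, probed) == 5  # 5' neighbor

    def test_strand2_five_prime_convention(self, b_duplex):
        model, _ = b_duplex
        duplex = duplex_of(model)
        # strand-2 residue B:7 pairs level 7 (seq ids run antiparallel)
        r5 = _minor_ref_coord(model, "B", "6")  # 5' neighbor on strand 2
        r3 = _minor_ref_coord(model, "B", "8")
        mid = 0.5 * (r5 + r3)
        perp = np.cross(r3 - r5, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        xyz = mid + 6.0 * perp
        probed, contact = self._contact_for(model, duplex, xyz, ("B", "7"))
        step = assign_dinucleotide_step(contact, duplex, probed)
        # B:7 is level 7; its 5' neighbor B:6 is level 8 -> step 7
        assert step == 7


class TestDatasetAssembly:
    def _table(self, probed_complex, blacklist=None):
        model, _ = probed_complex
        duplexes = [duplex_of(model)]
        contacts = find_groove_contacts(model, duplexes)
        for c in contacts:
            assign_dinucleotide_step(c, c.duplex, model)
        return build_dataset(contacts, blacklist=blacklist)

    def test_all_planted_contacts_tabulated(self, probed_complex):
        _, ledger = probed_complex
        table = self._table(probed_complex)
        assert len(table) == sum(1 for e in ledger.contacts if e.expected_in_dataset)

    def test_blacklist_removes_records(self, probed_complex):
        table_full = self._table(probed_complex)
        first = table_full.records[0]
        table = self._table(probed_complex, blacklist={first.residue_id})
        assert len(table) == len(table_full) - 1
        assert first.residue_id not in {r.residue_id for r in table.records}

    def test_widths_and_categories_consistent(self, probed_complex):
        table = self._table(probed_complex)
        for rec in table.records:
            assert rec.minor_groove_width is not None
            assert rec.width_category == categorize_width(rec.minor_groove_width)

    def test_shared_step_keeps_both_records(self, b_duplex):
        from minorgroove import synthetic_data as synth

        model, ledger = b_duplex
        plans = [
            synth.ProbeSpec("ALA", "A", "7", "minor", 5.0),
            synth.ProbeSpec("GLY", "B", "8", "minor", 5.0),
        ]
        probed, led = synth.plant_probe_residues(model, plans, ledger, seed=5)
        duplex = duplex_of(probed)
        contacts = find_groove_contacts(probed, [duplex])
        for c in contacts:
            assign_dinucleotide_step(c, c.duplex, probed)
        table = build_dataset(contacts)
        assert len(table) == 2
        steps = {r.step_index for r in table.records}
        e_steps = {e.expected_step_index for e in led.contacts}
        assert steps == e_steps

    def test_undefined_width_records_dropped(self, b_duplex):
        from minorgroove import synthetic_data as synth

        model, ledger = b_duplex
        # a probe on the terminal nucleotide maps to step 0, which has no width
        probed, _ = synth.plant_probe_residues(
            model, [synth.ProbeSpec("SER", "A", "1", "minor", 5.0)], ledger, seed=2
        )
        duplex = duplex_of(probed)
        contacts = find_groove_contacts(probed, [duplex])
        for c in contacts:
            assign_dinucleotide_step(c, c.duplex, probed)
        assert len(contacts) == 1
        table = build_dataset(contacts)
        assert len(table) == 0
        assert "undefined-width" in table.provenance[0]


class TestDsPrune:
    def _table(self):
        recs = [
            ContactRecord("S", "P", aa, str(i), "A", "5", "minor", 5.0,
                          step_index=4, step_sequence="AT",
                          minor_groove_width=12.0, width_category="standard")
            for i, aa in enumerate(["ALA", "GLY", "SER", "LEU", "THR"])
        ]
        from minorgroove.contact_detection import DatasetTable

        return DatasetTable(records=recs, label="DS1")

    def test_annotated_records_removed(self):
        table = self._table()
        annotations = {("S", "P", "0"): "PF00505", ("S", "P", "1"): "PF00352"}
        pruned = ds_prune(table, annotations)
        assert len(pruned) == 3
        assert {r.residue_type for r in pruned.records} == {"SER", "LEU", "THR"}

    def test_unlisted_family_retained(self):
        table = self._table()
        pruned = ds_prune(table, {("S", "P", "0"): "PF99999"})
        assert len(pruned) == 5

    def test_empty_family_set_is_identity(self):
        table = self._table()
        pruned = ds_prune(table, {("S", "P", "0"): "PF00505"}, excluded_families=frozenset())
        assert [r.residue_id for r in pruned.records] == [r.residue_id for r in table.records]

    def test_idempotent(self):
        table = self._table()
        annotations = {("S", "P", "0"): "PF00505"}
        once = ds_prune(table, annotations)
        twice = ds_prune(once, annotations)
        assert [r.residue_id for r in twice.records] == [r.residue_id for r in once.records]


class TestSerialization:
    def test_tsv_round_trip(self, probed_complex, tmp_path):
        model, _ = probed_complex
        duplexes = [duplex_of(model)]
        contacts = find_groove_contacts(model, duplexes)
        for c in contacts:
            assign_dinucleotide_step(c, c.duplex, model)
        table = build_dataset(contacts)
        path = tmp_path / "ds1.tsv"
        write_dataset_tsv(table, path)
        back = read_dataset_tsv(path)
        assert len(back) == len(table)
        for a, b in zip(table.records, back.records):
            assert a.residue_id == b.residue_id
            assert a.step_index == b.step_index
            assert a.width_category == b.width_category
            assert b.minor_groove_width == pytest.approx(a.minor_groove_width, abs=1e-4)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("foo\tbar\n")
        with pytest.raises(ValueError, match="header"):
            read_dataset_tsv(path)
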