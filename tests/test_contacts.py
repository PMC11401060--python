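import numpy as np
import pytest

from mutstruct.contacts import (
    CLASS_ABBREV,
    CLASS_ORDER,
    InteractionProfile,
    PharmacophoreMap,
    build_mutant_model,
    contact_delta,
    default_cutoff_grid,
    graph_signature,
    load_pharmacophore_map,
    pharmacophore_change,
    type_contacts,
)
from mutstruct.core_io import AA1, Atom, MutationRecord, ONE_TO_THREE, ProteinRecord
from mutstruct.fixtures import build_ideal_helix


def _record(sequence, atom_spec):
    """Minimal ProteinRecord from {position: [(name, element, xyz), ...]}."""
    atoms = []
    for pos, specs in sorted(atom_spec.items()):
        res3 = ONE_TO_THREE[sequence[pos - 1]]
        for name, element, xyz in specs:
            atoms.append(Atom(name, element, pos, res3, *xyz))
    return ProteinRecord("T", sequence, atoms, np.full(len(atom_spec), 90.0))


class TestPharmacophoreMap:
    def test_total_over_canonical_residues(self, helix):
        pmap = load_pharmacophore_map()
        for aa in AA1:
            rec = build_ideal_helix(("G" if aa != "G" else "A") * 4 + aa * 4)
            for atom in rec.residue_atoms(6):
                assert pmap.classes(atom.res_name, atom.name), (atom.res_name, atom.name)

    def test_proline_backbone_n_not_donor(self):
        pmap = load_pharmacophore_map()
        assert "HydrogenDonor" not in pmap.classes("PRO", "N")
        assert "HydrogenDonor" in pmap.classes("ALA", "N")


class TestBuildMutantModel:
    def test_g_to_a_adds_one_cb(self, helix):
        rec = build_ideal_helix("A" * 10 + "G" + "A" * 10, protein_id="GG")
        mut = build_mutant_model(rec, MutationRecord("GG", 11, "G", "A"))
        added = len(mut.atoms) - len(rec.atoms)
        assert added == 1
        assert mut.atom(11, "CB") is not None
        # all other coordinates bit-identical
        others = [(a.name, a.res_index, a.x, a.y, a.z) for a in rec.atoms]
        kept = [(a.name, a.res_index, a.x, a.y, a.z) for a in mut.atoms if not (a.res_index == 11 and a.name == "CB")]
        assert kept == others

    def test_to_gly_strips_sidechain(self):
        rec = build_ideal_helix("A" * 5 + "W" + "A" * 5, protein_id="WW")
        mut = build_mutant_model(rec, MutationRecord("WW", 6, "W", "G"))
        assert {a.name for a in mut.residue_atoms(6)} == {"N", "CA", "C", "O"}

    def test_residue_name_updated(self):
        rec = build_ideal_helix("A" * 11, protein_id="AA")
        mut = build_mutant_model(rec, MutationRecord("AA", 6, "A", "K"))
        assert all(a.res_name == "LYS" for a in mut.residue_atoms(6))
        assert mut.sequence[5] == "K"

    def test_backbone_unchanged(self):
        rec = build_ideal_helix("A" * 11, protein_id="AA")
        mut = build_mutant_model(rec, MutationRecord("AA", 6, "A", "F"))
        for name in ("N", "CA", "C", "O"):
            assert np.allclose(rec.atom(6, name).coord, mut.atom(6, name).coord)

    def test_unmapped_mutation_error(self):
        rec = build_ideal_helix("A" * 11, protein_id="AA")
        with pytest.raises(ValueError, match="does not map"):
            build_mutant_model(rec, MutationRecord("AA", 6, "P", "L"))

    def test_external_structure_takes_precedence(self):
        rec = build_ideal_helix("A" * 11, protein_id="AA")
        external = build_ideal_helix("A" * 5 + "F" + "A" * 5, protein_id="AA")
        mut = build_mutant_model(rec, MutationRecord("AA", 6, "A", "F"), mutant_structure=external)
        assert mut is external


class TestTypeContacts:
    def test_helix_backbone_hydrogen_bond(self, helix):
        # i -> i+4 CO..NH pairs sit at ~3 A in an ideal helix
        profile = type_contacts(helix, 10)
        assert profile["HydrogenBond"] >= 1
        # geometric oracle for one specific pair
        o = helix.atom(10, "O").coord
        n = helix.atom(14, "N").coord
        assert np.linalg.norm(o - n) <= 3.5

    def test_empty_neighborhood_zero_profile(self):
        rec = _record(
            "AGA",
            {
                1: [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))],
                2: [("CA", "C", (6, 0, 0))],
                3: [("CA", "C", (20, 0, 0)), ("CB", "C", (21.5, 0, 0))],
            },
        )
        profile = type_contacts(rec, 1)
        assert all(v == 0 for v in profile.counts.values())

    def test_hydrophobic_pair_at_4A(self):
        rec = _record(
            "AGA",
            {
                1: [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))],
                2: [("CA", "C", (30, 0, 0))],
                3: [("CA", "C", (7.0, 0, 0)), ("CB", "C", (5.5, 0, 0))],
            },
        )
        profile = type_contacts(rec, 1)
        assert profile["Hydrophobic"] >= 1  # CB..CB at 4.0 A
        assert profile["Ionic"] == 0

    def test_adjacent_residues_excluded(self):
        rec = _record(
            "AAG",
            {
                1: [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))],
                2: [("CA", "C", (3.8, 0, 0)), ("CB", "C", (2.5, 0, 0))],
                3: [("CA", "C", (30, 0, 0))],
            },
        )
        profile = type_contacts(rec, 1)
        assert all(v == 0 for v in profile.counts.values())

    def test_order_invariance(self, helix):
        shuffled_atoms = list(helix.atoms)
        rng = np.random.default_rng(3)
        rng.shuffle(shuffled_atoms)
        shuffled = ProteinRecord(helix.protein_id, helix.sequence, shuffled_atoms, helix.plddt)
        assert type_contacts(helix, 12).counts == type_contacts(shuffled, 12).counts


class TestContactDelta:
    def test_identity_is_zero(self):
        p = InteractionProfile({"HydrogenBond": 2, "Polar": 1, "WeakPolar": 3, "Hydrophobic": 0, "Aromatic": 0, "Ionic": 1})
        assert all(v == 0 for v in contact_delta(p, p).values())

    def test_sign_convention(self):
        wt = InteractionProfile({"HydrogenBond": 0, "Polar": 5, "WeakPolar": 3, "Hydrophobic": 0, "Aromatic": 0, "Ionic": 0})
        mt = InteractionProfile({"HydrogenBond": 0, "Polar": 5, "WeakPolar": 1, "Hydrophobic": 0, "Aromatic": 0, "Ionic": 0})
        delta = contact_delta(wt, mt)
        assert delta["WeakPolar"] == -2
        assert wt["Polar"] == 5  # WT profile untouched by the delta


class TestGraphSignature:
    def test_single_aro_sul_pair(self):
        pmap = PharmacophoreMap(
            {
                ("MET", "SD"): frozenset({"Sulfur"}),
                ("PHE", "CZ"): frozenset({"Aromatic"}),
            }
        )
        rec = _record(
            "MGF",
            {
                1: [("SD", "S", (0, 0, 0))],
                2: [("CA", "C", (40, 0, 0))],
                3: [("CZ", "C", (5.0, 0, 0))],
            },
        )
        sig = graph_signature(rec, 1, pmap)
        assert sig["Aro:Sul-11.00"] == 1
        assert sig["Aro:Sul-4.50"] == 0
        assert sig["Aro:Sul-5.00"] == 1

    def test_empty_class_pair_zero_everywhere(self, helix):
        sig = graph_signature(helix, 10)
        for c in default_cutoff_grid():
            assert sig[f"Pos:Neg-{c:.2f}"] == 0

    def test_cumulative_monotonicity(self, helix):
        sig = graph_signature(helix, 12)
        grid = default_cutoff_grid()
        pairs = sorted({k.rsplit("-", 1)[0] for k in sig if ":" in k})
        for pair in pairs:
            counts = [sig[f"{pair}-{c:.2f}"] for c in grid]
            assert counts == sorted(counts)

    def test_neg_change_for_d_to_a(self):
        rec = build_ideal_helix("A" * 5 + "D" + "A" * 5, protein_id="DD")
        mut = build_mutant_model(rec, MutationRecord("DD", 6, "D", "A"))
        change = pharmacophore_change(rec, mut, 6)
        assert change["Neg"] == -2.0  # OD1 + OD2

    def test_signature_includes_change_components(self):
        rec = build_ideal_helix("A" * 5 + "D" + "A" * 5, protein_id="DD")
        mut = build_mutant_model(rec, MutationRecord("DD", 6, "D", "A"))
        sig = graph_signature(rec, 6, mutant=mut)
        assert sig["Neg"] == -2.0
        assert set(CLASS_ABBREV.values()) <= set(sig)

    def test_order_invariance(self, helix):
        rng = np.random.default_rng(5)
        shuffled_atoms = list(helix.atoms)
        rng.shuffle(shuffled_atoms)
        shuffled = ProteinRecord(helix.protein_id, helix.sequence, shuffled_atoms, helix.plddt)
        assert graph_signature(helix, 9) == graph_signature(shuffled, 9)
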