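import numpy as np
import pytest

import myoconf as mc
from myoconf.errors import AlignmentError, ComparabilityError
from myoconf.contacts import _is_polar_protein_atom


def _complex_with_plan(model, plan):
    cx = mc.make_ligand_complex(model, plan)
    return cx, mc.find_contacts(cx, "resname LIG")


def brute_force_contacts(structure, lig_mask, polar_cutoff=3.5,
                         apolar_cutoff=3.9):
    """O(n²) oracle: scan every (ligand, protein) atom pair directly."""
    found = []
    xyz = structure.xyz(0)
    for i in range(structure.n_atoms):
        if not lig_mask[i]:
            continue
        for j in range(structure.n_atoms):
            if lig_mask[j]:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            el_i = str(structure.element[i])
            polar_j = _is_polar_protein_atom(str(structure.resname[j]),
                                             str(structure.atname[j]),
                                             str(structure.element[j]))
            if el_i in "NOS" and polar_j and d <= polar_cutoff:
                found.append((i, j, "polar", round(d, 9)))
            if el_i == "C" and str(structure.element[j]) == "C" \
                    and d <= apolar_cutoff:
                found.append((i, j, "apolar", round(d, 9)))
    return sorted(found)


class TestFindContacts:
    def test_single_constructed_polar_contact(self):
        atoms = [
            ("A", 168, "", "ASP", "CA", "C"),
            ("A", 168, "", "ASP", "OD1", "O"),
            ("L", 900, "", "LIG", "N1", "N"),
        ]
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [4.4, 0, 0]])[None]
        st = mc.Structure.from_atoms("toy", atoms, coords)
        recs = mc.find_contacts(st, "resname LIG", polar_cutoff=3.5,
                                apolar_cutoff=3.9)
        assert len(recs) == 1
        assert recs[0].contact_class == "polar"
        assert recs[0].distance == pytest.approx(2.9, abs=1e-9)
        assert recs[0].protein_atom == ("A", 168, "OD1")

    def test_far_ligand_gives_empty_set(self):
        atoms = [
            ("A", 1, "", "ALA", "CA", "C"),
            ("A", 1, "", "ALA", "O", "O"),
            ("L", 900, "", "LIG", "C1", "C"),
        ]
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [6.5, 0, 0]])[None]
        st = mc.Structure.from_atoms("toy", atoms, coords)
        assert mc.find_contacts(st, "resname LIG") == []

    def test_seven_planted_contacts_match_brute_force_oracle(self,
                                                             default_model):
        plan = [
            mc.PlannedContact("polar", 2.8, 20),
            mc.PlannedContact("polar", 3.1, 60),
            mc.PlannedContact("polar", 3.4, 120),
            mc.PlannedContact("apolar", 3.3, 30),
            mc.PlannedContact("apolar", 3.6, 100),
            mc.PlannedContact("apolar", 3.8, 140),
            mc.PlannedContact("polar", 2.9, 80),
        ]
        cx, recs = _complex_with_plan(default_model, plan)
        assert len(recs) == 7
        assert sorted(r.contact_class for r in recs) == sorted(
            p.contact_class for p in plan)
        planted = sorted(round(p.distance, 9) for p in plan)
        assert sorted(round(r.distance, 9) for r in recs) == planted

        lig_mask = cx.chain.astype(str) == "L"
        oracle = brute_force_contacts(cx, lig_mask)
        assert sorted((o[2], o[3]) for o in oracle) == sorted(
            (r.contact_class, round(r.distance, 9)) for r in recs)

    def test_matches_oracle_on_dense_random_instance(self):
        """Spatial shortcuts may never change semantics: a dense random
        ≤500-atom instance must agree pairwise with the O(n²) scan."""
        rng = np.random.default_rng(12)
        n_prot, n_lig = 450, 12
        atoms = []
        # random protein carbons/oxygens/nitrogens with plausible names
        names = [("CA", "C"), ("CB", "C"), ("O", "O"), ("N", "N")]
        for i in range(n_prot):
            nm, el = names[i % 4]
            atoms.append(("A", i // 4 + 1, "", "ALA", nm, el))
        for j in range(n_lig):
            el = "N" if j % 3 == 0 else "C"
            atoms.append(("L", 900, "", "LIG", f"{el}{j}", el))
        coords = np.vstack([
            rng.uniform(0, 22, (n_prot, 3)),
            rng.uniform(8, 14, (n_lig, 3)),
        ])[None]
        st = mc.Structure.from_atoms("dense", atoms, coords)
        recs = mc.find_contacts(st, "resname LIG")
        lig_mask = np.array([str(c) == "L" for c in st.chain])
        oracle = brute_force_contacts(st, lig_mask)
        assert len(recs) == len(oracle)
        got = sorted((r.contact_class, round(r.distance, 9)) for r in recs)
        exp = sorted((o[2], o[3]) for o in oracle)
        assert got == exp

    def test_cutoff_monotonicity(self, default_model):
        plan = [mc.PlannedContact("polar", 3.0, 40),
                mc.PlannedContact("apolar", 3.5, 130)]
        cx = mc.make_ligand_complex(default_model, plan)
        small = mc.find_contacts(cx, "resname LIG", polar_cutoff=3.2,
                                 apolar_cutoff=3.6)
        big = mc.find_contacts(cx, "resname LIG", polar_cutoff=4.5,
                               apolar_cutoff=4.5)
        small_keys = {(r.ligand_atom, r.protein_atom, r.contact_class)
                      for r in small}
        big_keys = {(r.ligand_atom, r.protein_atom, r.contact_class)
                    for r in big}
        assert small_keys <= big_keys

    def test_contacts_just_beyond_cutoff_are_dropped(self, default_model):
        plan = [mc.PlannedContact("polar", 3.51, 40),
                mc.PlannedContact("apolar", 3.91, 90)]
        cx = mc.make_ligand_complex(default_model, plan)
        assert mc.find_contacts(cx, "resname LIG") == []


class TestPocketProfile:
    def test_min_distance_over_multiple_contacts(self):
        recs = [
            mc.ContactRecord(("L", 900, "N1"), ("A", 168, "OD1"), "ASP",
                             3.2, "polar"),
            mc.ContactRecord(("L", 900, "N2"), ("A", 168, "OD2"), "ASP",
                             2.8, "polar"),
            mc.ContactRecord(("L", 900, "C1"), ("A", 168, "CB"), "ASP",
                             3.7, "apolar"),
        ]
        profile = mc.pocket_residues(recs)
        assert profile.residues == [("A", 168, "ASP")]
        assert profile.min_distance[("A", 168, "ASP")] == pytest.approx(2.8)
        assert ("A", 168, "ASP") in profile.polar_residues

    def test_planted_residue_set_recovered(self, default_model):
        plan = [mc.PlannedContact("polar", 2.9, 120),
                mc.PlannedContact("polar", 3.0, 60),
                mc.PlannedContact("apolar", 3.5, 30)]
        cx = mc.make_ligand_complex(default_model, plan)
        recs = mc.find_contacts(cx, "resname LIG")
        profile = mc.pocket_residues(recs)
        assert profile.residue_numbers() == {30, 60, 120}

    def test_empty_records_give_valid_empty_profile(self):
        profile = mc.pocket_residues([])
        assert profile.residues == []


class TestComparePockets:
    def _profile(self, nums, cutoffs=(3.5, 3.9)):
        residues = [("A", n, "ALA") for n in nums]
        return mc.PocketProfile(
            structure_id="x", ligand_id="LIG", residues=residues,
            min_distance={r: 3.0 for r in residues},
            polar_residues=set(), cutoffs=cutoffs,
        )

    def test_identical_profiles(self):
        cmp_ = mc.compare_pockets(self._profile([1, 2, 3]),
                                  self._profile([1, 2, 3]))
        assert cmp_.jaccard == 1.0
        assert cmp_.unique_to_a == [] and cmp_.unique_to_b == []

    def test_disjoint_profiles(self):
        cmp_ = mc.compare_pockets(self._profile([1, 2]),
                                  self._profile([3, 4]))
        assert cmp_.jaccard == 0.0

    def test_partial_overlap_jaccard_half(self):
        cmp_ = mc.compare_pockets(self._profile([1, 2, 3]),
                                  self._profile([2, 3, 4]))
        assert cmp_.jaccard == pytest.approx(0.5)
        assert [r[1] for r in cmp_.unique_to_a] == [1]
        assert [r[1] for r in cmp_.unique_to_b] == [4]

    def test_symmetry_up_to_swapping_uniques(self):
        a, b = self._profile([1, 2, 3]), self._profile([2, 3, 4])
        ab, ba = mc.compare_pockets(a, b), mc.compare_pockets(b, a)
        assert ab.jaccard == ba.jaccard
        assert ab.unique_to_a == ba.unique_to_b
        assert ab.shared == ba.shared

    def test_cutoff_mismatch_raises(self):
        with pytest.raises(ComparabilityError):
            mc.compare_pockets(self._profile([1]),
                               self._profile([1], cutoffs=(3.0, 3.9)))


class TestMapDeterminants:
    def _msa(self, tmp_path, records):
        path = tmp_path / "msa.fasta"
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return path

    def _profile(self, nums):
        residues = [("A", n, "XXX") for n in nums]
        return mc.PocketProfile("s", "LIG", residues,
                                {r: 3.0 for r in residues}, set(),
                                (3.5, 3.9))

    def test_identical_sequences_all_conserved(self, tmp_path):
        msa = self._msa(tmp_path, [("card", "MKYLVNT"), ("skel", "MKYLVNT"),
                                   ("smooth", "MKYLVNT")])
        report = mc.map_determinants(msa, "card", self._profile([2, 5]))
        assert all(e.conserved for e in report.entries)

    def test_single_substitution_flagged(self, tmp_path):
        msa = self._msa(tmp_path, [("card", "MKYLVNT"), ("skel", "MKFLVNT")])
        report = mc.map_determinants(msa, "card", self._profile([3, 6]))
        flags = {e.residue[1]: e.conserved for e in report.entries}
        assert flags == {3: False, 6: True}
        entry = next(e for e in report.entries if e.residue[1] == 3)
        assert entry.reference_identity == "Y"
        assert entry.aligned == {"skel": "F"}

    def test_gapped_reference_mapping(self, tmp_path):
        # reference has a gap: residue numbers map to ungapped positions
        msa = self._msa(tmp_path, [("card", "MK-YL"), ("skel", "MKAYL")])
        report = mc.map_determinants(msa, "card", self._profile([3]))
        entry = report.entries[0]
        assert entry.reference_identity == "Y"
        assert entry.conserved

    def test_cardiac_vs_skeletal_pocket_determinants(self, tmp_path):
        """A two-sequence cardiac/skeletal alignment over a pocket region:
        exactly the Y164/F and N711/S direct-binding positions differ."""
        # positions (1-based): 1..8 ~ residues 161..168, 9..12 ~ 709..712
        card = "LDIYGFEI" + "LSNL"
        skel = "LDIFGFEI" + "LSSL"
        msa = self._msa(tmp_path, [("cardiac", card), ("skeletal", skel)])
        profile = self._profile([164, 168, 711, 712])

        def renum(n):  # map author numbers onto the toy concatenated region
            return n - 160 if n < 700 else n - 708 + 8

        toy = self._profile([renum(n) for n in (164, 168, 711, 712)])
        report = mc.map_determinants(msa, "cardiac", toy)
        non_conserved = {e.residue[1] for e in report.non_conserved()}
        assert non_conserved == {renum(164), renum(711)}

    def test_missing_reference_raises(self, tmp_path):
        msa = self._msa(tmp_path, [("a", "MKY"), ("b", "MKY")])
        with pytest.raises(AlignmentError):
            mc.map_determinants(msa, "nope", self._profile([1]))

    def test_unmappable_residue_flagged_not_fatal(self, tmp_path):
        msa = self._msa(tmp_path, [("a", "MKY"), ("b", "MKY")])
        report = mc.map_determinants(msa, "a", self._profile([99]))
        assert report.entries[0].column is None
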