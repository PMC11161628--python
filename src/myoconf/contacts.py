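"""Ligand–protein contact detection, pocket profiling, and sequence
determinants.

Contacts are typed geometrically, without hydrogens (crystal structures at
this resolution lack them): a *polar* contact is a pair of donor/acceptor
atoms (N/O/S, with protein side-chain atoms validated against a small
residue dictionary) within the polar cutoff; an *apolar* contact is a
carbon–carbon pair within the apolar cutoff.  The pocket profile is the set
of residues contributing at least one contact, with per-residue minimum
distances — the mechanized form of a manual ligand-pocket analysis.

Determinant mapping projects pocket residues onto a multiple sequence
alignment of class-2 myosins to find the sequence differences that explain
drug specificity (e.g. the cardiac-vs-skeletal Y164/F and N711/S swaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, ComparabilityError, SelectionError
from .structio import Selection, Structure, select

DEFAULT_POLAR_CUTOFF = 3.5   # Å
DEFAULT_APOLAR_CUTOFF = 3.9  # Å

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

# side-chain donor/acceptor atoms per residue; backbone N and O are always
# donors/acceptors for any amino acid
_POLAR_SIDECHAIN = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1", "ND2"}, "GLN": {"OE1", "NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "CYS": {"SG"}, "MET": {"SD"}, "TRP": {"NE1"},
}
_BACKBONE_POLAR = {"N", "O", "OXT"}


@dataclass(frozen=True)
class ContactRecord:
    """One typed ligand–protein atom contact."""

    ligand_atom: tuple[str, int, str]   # (chain, resnum, atom name)
    protein_atom: tuple[str, int, str]
    protein_resname: str
    distance: float                     # Å
    contact_class: str                  # 'polar' | 'apolar'


@dataclass
class PocketProfile:
    """Residues defining a ligand pocket, with per-residue minimum distance."""

    structure_id: str
    ligand_id: str
    residues: list[tuple[str, int, str]]      # (chain, resnum, resname), sorted
    min_distance: dict[tuple[str, int, str], float]
    polar_residues: set[tuple[str, int, str]]
    cutoffs: tuple[float, float]              # (polar, apolar)

    def residue_numbers(self) -> set[int]:
        return {r[1] for r in self.residues}


def _is_polar_protein_atom(resname: str, atname: str, element: str) -> bool:
    if element not in {"N", "O", "S"}:
        return False
    if atname in _BACKBONE_POLAR:
        return True
    return atname in _POLAR_SIDECHAIN.get(resname, set())


def find_contacts(
    structure: Structure,
    ligand_selection: Selection | str,
    polar_cutoff: float = DEFAULT_POLAR_CUTOFF,
    apolar_cutoff: float = DEFAULT_APOLAR_CUTOFF,
    model: int = 0,
    exclude_waters: bool = True,
) -> list[ContactRecord]:
    """All typed ligand–protein contacts at the given cutoffs.

    The protein side is everything outside the ligand selection (waters
    excluded by default).  Each (ligand atom, protein atom) pair is reported
    at most once, with its distance and class.  Enlarging either cutoff can
    only add contacts, never remove them.
    """
    lig_idx = select(structure, ligand_selection)
    if len(lig_idx) == 0:
        raise SelectionError("ligand selection matched no atoms")
    lig_set = set(int(i) for i in lig_idx)
    prot_idx = np.array(
        [i for i in range(structure.n_atoms)
         if i not in lig_set
         and not (exclude_waters and str(structure.resname[i]) in _WATER_NAMES)],
        dtype=int,
    )
    if len(prot_idx) == 0:
        return []

    xyz = structure.xyz(model)
    d = cdist(xyz[lig_idx], xyz[prot_idx])

    lig_el = structure.element[lig_idx].astype(str)
    prot_el = structure.element[prot_idx].astype(str)
    lig_polar = np.isin(lig_el, ["N", "O", "S"])
    lig_carbon = lig_el == "C"
    prot_polar = np.array([
        _is_polar_protein_atom(str(structure.resname[i]),
                               str(structure.atname[i]),
                               str(structure.element[i]))
        for i in prot_idx
    ])
    prot_carbon = prot_el == "C"

    polar_pairs = lig_polar[:, None] & prot_polar[None, :] & (d <= polar_cutoff)
    apolar_pairs = lig_carbon[:, None] & prot_carbon[None, :] & (d <= apolar_cutoff)

    records: list[ContactRecord] = []
    for cls, pairs in (("polar", polar_pairs), ("apolar", apolar_pairs)):
        for il, ip in zip(*np.nonzero(pairs)):
            i, j = int(lig_idx[il]), int(prot_idx[ip])
            dist = float(d[il, ip])
            if dist <= 0:
                raise SelectionError(
                    "zero-distance contact: ligand and protein selections overlap"
                )
            records.append(ContactRecord(
                ligand_atom=(str(structure.chain[i]), int(structure.resnum[i]),
                             str(structure.atname[i])),
                protein_atom=(str(structure.chain[j]), int(structure.resnum[j]),
                              str(structure.atname[j])),
                protein_resname=str(structure.resname[j]),
                distance=dist,
                contact_class=cls,
            ))
    records.sort(key=lambda r: (r.protein_atom, r.ligand_atom, r.contact_class))
    return records


def pocket_residues(
    records: list[ContactRecord],
    structure_id: str = "",
    ligand_id: str = "",
    cutoffs: tuple[float, float] = (DEFAULT_POLAR_CUTOFF, DEFAULT_APOLAR_CUTOFF),
) -> PocketProfile:
    """Collapse contact records into a pocket residue profile.

    Deterministic ordering by (chain, residue number); an empty record list
    yields a valid empty profile.
    """
    min_d: dict[tuple[str, int, str], float] = {}
    polar: set[tuple[str, int, str]] = set()
    for r in records:
        key = (r.protein_atom[0], r.protein_atom[1], r.protein_resname)
        min_d[key] = min(min_d.get(key, np.inf), r.distance)
        if r.contact_class == "polar":
            polar.add(key)
    residues = sorted(min_d, key=lambda k: (k[0], k[1]))
    return PocketProfile(
        structure_id=structure_id,
        ligand_id=ligand_id,
        residues=residues,
        min_distance=min_d,
        polar_residues=polar,
        cutoffs=cutoffs,
    )


@dataclass
class PocketComparison:
    shared: list[tuple[str, int, str]]
    unique_to_a: list[tuple[str, int, str]]
    unique_to_b: list[tuple[str, int, str]]
    jaccard: float


def compare_pockets(a: PocketProfile, b: PocketProfile) -> PocketComparison:
    """Shared and unique pocket residues plus a Jaccard index.

    Profiles must have been computed with identical cutoffs; residues are
    matched by (residue number, residue name) so the same pocket in two
    crystal forms (different chain ids) compares cleanly.
    """
    if a.cutoffs != b.cutoffs:
        raise ComparabilityError(
            f"profiles computed at different cutoffs: {a.cutoffs} vs {b.cutoffs}"
        )

    def keyset(p: PocketProfile) -> dict[tuple[int, str], tuple[str, int, str]]:
        return {(r[1], r[2]): r for r in p.residues}

    ka, kb = keyset(a), keyset(b)
    shared_keys = sorted(set(ka) & set(kb))
    only_a = sorted(set(ka) - set(kb))
    only_b = sorted(set(kb) - set(ka))
    union = len(set(ka) | set(kb))
    return PocketComparison(
        shared=[ka[k] for k in shared_keys],
        unique_to_a=[ka[k] for k in only_a],
        unique_to_b=[kb[k] for k in only_b],
        jaccard=(len(shared_keys) / union) if union else 1.0,
    )


# ---------------------------------------------------------------------------
# sequence determinants


@dataclass
class DeterminantEntry:
    residue: tuple[str, int, str]       # pocket residue (chain, resnum, resname)
    reference_identity: str             # one-letter
    aligned: dict[str, str]             # homolog id → one-letter (or '-')
    conserved: bool
    column: int | None                  # 0-based MSA column, None if unmappable


@dataclass
class DeterminantReport:
    reference_id: str
    entries: list[DeterminantEntry]

    def non_conserved(self) -> list[DeterminantEntry]:
        return [e for e in self.entries if e.column is not None and not e.conserved]


def map_determinants(
    alignment,
    reference_id: str,
    profile: PocketProfile,
    ref_start: int = 1,
) -> DeterminantReport:
    """Project pocket residues onto an MSA and flag conservation.

    ``alignment`` is a FASTA path or a Bio.Align.MultipleSeqAlignment; the
    reference sequence must be present by id.  Residue numbers are mapped to
    ungapped reference positions via ``ref_start`` (the author number of the
    first reference residue).  Pocket residues outside the alignment are
    flagged unmappable, not fatal.
    """
    from Bio import AlignIO

    if isinstance(alignment, (str, Path)):
        alignment = AlignIO.read(str(alignment), "fasta")
    ref_rec = next((r for r in alignment if r.id == reference_id), None)
    if ref_rec is None:
        raise AlignmentError(
            f"reference {reference_id!r} absent from alignment "
            f"(ids: {[r.id for r in alignment]})"
        )

    # ungapped reference position (1-based) → alignment column
    col_of_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(str(ref_rec.seq)):
        if ch != "-":
            pos += 1
            col_of_pos[pos] = col

    others = [r for r in alignment if r.id != reference_id]
    entries: list[DeterminantEntry] = []
    for res in profile.residues:
        pos = res[1] - ref_start + 1
        col = col_of_pos.get(pos)
        if col is None:
            entries.append(DeterminantEntry(res, "?", {}, False, None))
            continue
        ref_aa = str(ref_rec.seq[col]).upper()
        aligned = {r.id: str(r.seq[col]).upper() for r in others}
        conserved = all(aa == ref_aa for aa in aligned.values())
        entries.append(DeterminantEntry(res, ref_aa, aligned, conserved, col))
    return DeterminantReport(reference_id=reference_id, entries=entries)
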