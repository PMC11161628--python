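"""Structure and trajectory I/O, atom selections, and residue pairing.

Structures are stored as flat atom tables with one or more coordinate sets
(models).  Author residue numbering is used throughout — the residue ranges
quoted in the literature for the myosin motor (motor domain 1–710, lever arm
711–806, HO-helix 419–445, ...) are author numbers, so mmCIF ``label_seq_id``
is ignored on read.  Alternate conformations are collapsed to the
highest-occupancy conformer (ties broken toward altloc ``A``) so that every
downstream analysis sees a deterministic single-conformer atom table.

File parsing and writing are delegated to :mod:`gemmi`; multi-model PDB is
the baseline trajectory dialect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    FormatError,
    PairingError,
    SelectionError,
    TopologyError,
)

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class Structure:
    """A flat atom table with one or more coordinate sets.

    All models share the same atom list; ``coords`` has shape
    ``(n_models, n_atoms, 3)`` in Å.
    """

    id: str
    chain: np.ndarray      # str per atom
    resnum: np.ndarray     # int, author numbering
    icode: np.ndarray      # str ('' if none)
    resname: np.ndarray    # 3-letter str
    atname: np.ndarray     # str
    element: np.ndarray    # str, capitalized symbol
    coords: np.ndarray     # (n_models, n_atoms, 3) float, Å
    occupancy: np.ndarray
    bfactor: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.n_atoms == 0:
            raise EmptyStructureError(f"structure {self.id!r} has zero atoms")
        if not np.isfinite(self.coords).all():
            raise FormatError(f"structure {self.id!r} has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def xyz(self, model: int = 0) -> np.ndarray:
        """Coordinates of one model, shape (n_atoms, 3)."""
        return self.coords[model]

    def atom_key(self, i: int) -> tuple:
        return (
            str(self.chain[i]),
            int(self.resnum[i]),
            str(self.icode[i]),
            str(self.atname[i]),
        )

    def residue_keys(self) -> list[tuple]:
        """Ordered unique (chain, resnum, icode) keys, in atom-table order."""
        seen: dict[tuple, None] = {}
        for c, n, ic in zip(self.chain, self.resnum, self.icode):
            seen.setdefault((str(c), int(n), str(ic)), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """A copy sharing the atom table but carrying new coordinates."""
        return Structure(
            id=id or self.id,
            chain=self.chain,
            resnum=self.resnum,
            icode=self.icode,
            resname=self.resname,
            atname=self.atname,
            element=self.element,
            coords=np.asarray(coords, dtype=float),
            occupancy=self.occupancy,
            bfactor=self.bfactor,
        )

    @classmethod
    def from_atoms(cls, id: str, atoms: list[tuple], coords: np.ndarray) -> "Structure":
        """Build from a list of (chain, resnum, icode, resname, atname, element)
        tuples plus a coordinate array of shape (n_models, n_atoms, 3) or
        (n_atoms, 3)."""
        n = len(atoms)
        return cls(
            id=id,
            chain=np.array([a[0] for a in atoms], dtype=object),
            resnum=np.array([a[1] for a in atoms], dtype=int),
            icode=np.array([a[2] for a in atoms], dtype=object),
            resname=np.array([a[3] for a in atoms], dtype=object),
            atname=np.array([a[4] for a in atoms], dtype=object),
            element=np.array([a[5] for a in atoms], dtype=object),
            coords=coords,
            occupancy=np.ones(n),
            bfactor=np.zeros(n),
        )

    def masses(self) -> np.ndarray:
        """Atomic masses (Da) from element symbols."""
        return np.array(
            [gemmi.Element(str(e)).weight for e in self.element], dtype=float
        )


@dataclass
class Trajectory:
    """Ordered frames over one topology; times in ns, strictly increasing."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray   # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise TopologyError("times and frames must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise TopologyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        """One frame as a single-model Structure."""
        return self.topology.with_coords(self.frames[i][None])


# ---------------------------------------------------------------------------
# reading / writing


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    s = str(path).lower()
    if s.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties break toward 'A'
    (then alphabetically), giving a deterministic single-conformer table."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        if atom.occ > prev.occ or (
            atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~")
        ):
            best[atom.name] = atom
    order: dict[str, int] = {}
    for atom in res:
        order.setdefault(atom.name, len(order))
    return sorted(best.values(), key=lambda a: order[a.name])


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All models are loaded; author residue numbering and insertion codes are
    preserved.  Raises :class:`FormatError` on parse failure and
    :class:`EmptyStructureError` if no atoms are present.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")

    atoms: list[tuple] = []
    model_coords: list[list[tuple]] = []
    for im, model in enumerate(st):
        xyz: list[tuple] = []
        keys: list[tuple] = []
        for chain in model:
            for res in chain:
                for atom in _collapse_altlocs(res):
                    key = (
                        chain.name,
                        res.seqid.num,
                        res.seqid.icode.strip(),
                        res.name,
                        atom.name,
                        atom.element.name,
                        atom.occ,
                        atom.b_iso,
                    )
                    keys.append(key)
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if im == 0:
            atoms = keys
        elif len(keys) != len(atoms) or [k[:5] for k in keys] != [
            k[:5] for k in atoms
        ]:
            raise TopologyError(
                f"{path}: model {im + 1} atom table differs from model 1"
            )
        model_coords.append(xyz)

    if not atoms:
        raise EmptyStructureError(f"{path} contains zero atoms")

    n = len(atoms)
    return Structure(
        id=st.name or path.stem,
        chain=np.array([a[0] for a in atoms], dtype=object),
        resnum=np.array([a[1] for a in atoms], dtype=int),
        icode=np.array([a[2] for a in atoms], dtype=object),
        resname=np.array([a[3] for a in atoms], dtype=object),
        atname=np.array([a[4] for a in atoms], dtype=object),
        element=np.array([a[5] for a in atoms], dtype=object),
        coords=np.array(model_coords, dtype=float),
        occupancy=np.array([a[6] for a in atoms], dtype=float),
        bfactor=np.array([a[7] for a in atoms], dtype=float),
    )


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    for im in range(structure.n_models):
        model = gemmi.Model(im + 1)
        chain_obj: gemmi.Chain | None = None
        res_obj: gemmi.Residue | None = None
        last = (None, None, None, None)
        for i in range(structure.n_atoms):
            ckey = str(structure.chain[i])
            rkey = (ckey, int(structure.resnum[i]), str(structure.icode[i]),
                    str(structure.resname[i]))
            if chain_obj is None or ckey != last[0]:
                chain_obj = gemmi.Chain(ckey)
                model.add_chain(chain_obj)
                chain_obj = model[-1]
                res_obj = None
            if res_obj is None or rkey != last[:4] or rkey[0] != last[0]:
                res = gemmi.Residue()
                res.name = str(structure.resname[i])
                res.seqid = gemmi.SeqId(int(structure.resnum[i]),
                                        str(structure.icode[i]) or " ")
                chain_obj.add_residue(res)
                res_obj = chain_obj[-1]
            atom = gemmi.Atom()
            atom.name = str(structure.atname[i])
            atom.element = gemmi.Element(str(structure.element[i]))
            atom.occ = float(structure.occupancy[i])
            atom.b_iso = float(structure.bfactor[i])
            x, y, z = structure.coords[im, i]
            atom.pos = gemmi.Position(x, y, z)
            res_obj.add_atom(atom)
            last = (ckey, *rkey[1:])
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path,
                    format: str | None = None) -> None:
    """Write a Structure (all models) as PDB or mmCIF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    st = _to_gemmi(structure)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def read_trajectory(
    topology_path: str | Path,
    traj_path: str | Path | None = None,
    format: str | None = None,
    stride_ns: float = 1.0,
) -> Trajectory:
    """Read a trajectory stored as a multi-model PDB (or mmCIF).

    If ``traj_path`` is omitted, ``topology_path`` itself is read and each of
    its models becomes one frame.  Times are ``frame index × stride_ns``;
    a single-model file yields a valid 1-frame trajectory.
    """
    topo = read_structure(topology_path, format)
    if traj_path is None or Path(traj_path) == Path(topology_path):
        frames = topo.coords
    else:
        tr = read_structure(traj_path, format)
        if tr.n_atoms != topo.n_atoms:
            raise TopologyError(
                f"{traj_path}: frame 0 has {tr.n_atoms} atoms, topology has "
                f"{topo.n_atoms}"
            )
        frames = tr.coords
    topo_single = topo.with_coords(frames[:1])
    times = np.arange(len(frames), dtype=float) * stride_ns
    return Trajectory(topology=topo_single, frames=frames, times=times)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write as a multi-model PDB."""
    write_structure(traj.topology.with_coords(traj.frames), path, format="pdb")


# ---------------------------------------------------------------------------
# selections

_CLAUSE_RE = re.compile(r"^(chain|resi|resname|name)\s+(\S.*)$")


@dataclass
class Selection:
    """Atom selection over chains, residue ranges, residue and atom names.

    The string grammar is a conjunction of clauses joined by ``and``::

        chain A,B and resi 711-806,90 and name CA and resname LIG

    Each clause restricts; omitted clauses match everything.  Residue ranges
    are inclusive author numbers; overlapping ranges select the union.
    """

    chains: frozenset[str] | None = None
    ranges: tuple[tuple[int, int], ...] | None = None
    resnames: frozenset[str] | None = None
    names: frozenset[str] | None = None
    expression: str = ""

    @classmethod
    def parse(cls, expression: str) -> "Selection":
        chains = ranges = resnames = names = None
        expr = expression.strip()
        if expr and expr.lower() != "all":
            for clause in re.split(r"\s+and\s+", expr):
                m = _CLAUSE_RE.match(clause.strip())
                if not m:
                    raise SelectionError(f"cannot parse clause {clause!r}")
                kind, arg = m.group(1), m.group(2)
                items = [a.strip() for a in arg.split(",") if a.strip()]
                if kind == "chain":
                    chains = frozenset(items)
                elif kind == "resname":
                    resnames = frozenset(i.upper() for i in items)
                elif kind == "name":
                    names = frozenset(i.upper() for i in items)
                else:  # resi
                    rs = []
                    for item in items:
                        if "-" in item[1:]:
                            lo, hi = item.rsplit("-", 1)
                            rs.append((int(lo), int(hi)))
                        else:
                            rs.append((int(item), int(item)))
                    ranges = tuple(rs)
        return cls(chains=chains, ranges=ranges, resnames=resnames,
                   names=names, expression=expression)

    @classmethod
    def ca(cls, ranges: list[tuple[int, int]] | None = None,
           chain: str | None = None) -> "Selection":
        """Convenience Cα-only selection over optional residue ranges."""
        return cls(
            chains=frozenset([chain]) if chain else None,
            ranges=tuple(ranges) if ranges else None,
            names=frozenset(["CA"]),
            expression="<ca>",
        )

    def resolve(self, structure: Structure) -> np.ndarray:
        """Indices of matching atoms, in topology order (stable)."""
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(structure.chain.astype(str), list(self.chains))
        if self.resnames is not None:
            mask &= np.isin(structure.resname.astype(str), list(self.resnames))
        if self.names is not None:
            mask &= np.isin(structure.atname.astype(str), list(self.names))
        if self.ranges is not None:
            rn = structure.resnum
            rmask = np.zeros_like(mask)
            for lo, hi in self.ranges:
                rmask |= (rn >= lo) & (rn <= hi)
            mask &= rmask
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            warnings.warn(
                f"selection {self.expression or self!r} matched no atoms",
                stacklevel=2,
            )
        return idx


def select(structure: Structure, selection: Selection | str) -> np.ndarray:
    """Resolve a selection (object or expression string) to atom indices."""
    if isinstance(selection, str):
        selection = Selection.parse(selection)
    return selection.resolve(structure)


# ---------------------------------------------------------------------------
# residue pairing

_THREE_TO_ONE = None


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def _chain_sequences(structure: Structure) -> dict[str, list[tuple]]:
    """Per chain: ordered residue keys (chain, resnum, icode, resname)."""
    out: dict[str, list[tuple]] = {}
    seen = set()
    for c, n, ic, rn in zip(structure.chain, structure.resnum,
                            structure.icode, structure.resname):
        key = (str(c), int(n), str(ic))
        if key in seen:
            continue
        seen.add(key)
        out.setdefault(str(c), []).append((*key, str(rn)))
    return out


@dataclass
class ResiduePairing:
    """One-to-one residue correspondence between two structures."""

    pairs: list[tuple[tuple, tuple]]  # ((chain,resnum,icode), (chain,resnum,icode))
    rule: str
    chain_map: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def _map_chains(a_seqs: dict, b_seqs: dict) -> dict[str, str]:
    """Identical chain ids first; leftovers matched by alignment score."""
    mapping = {c: c for c in a_seqs if c in b_seqs}
    left_a = [c for c in a_seqs if c not in mapping]
    left_b = [c for c in b_seqs if c not in mapping.values()]
    if left_a and left_b:
        from Bio import Align

        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=0, gap_score=-0.5)
        scored = []
        for ca in left_a:
            sa = "".join(_one_letter(r[3]) for r in a_seqs[ca])
            for cb in left_b:
                sb = "".join(_one_letter(r[3]) for r in b_seqs[cb])
                scored.append((aligner.score(sa, sb), ca, cb))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a, used_b = set(), set()
        for _, ca, cb in scored:
            if ca not in used_a and cb not in used_b:
                mapping[ca] = cb
                used_a.add(ca)
                used_b.add(cb)
    return mapping


def pair_residues(a: Structure, b: Structure,
                  rule: str = "by_number") -> ResiduePairing:
    """Establish a one-to-one residue correspondence.

    ``by_number`` pairs residues with identical author numbers (and insertion
    codes) within mapped chains; ``by_alignment`` pairs positions matched by
    a global sequence alignment of the extracted one-letter sequences.
    """
    a_seqs, b_seqs = _chain_sequences(a), _chain_sequences(b)
    chain_map = _map_chains(a_seqs, b_seqs)
    pairs: list[tuple[tuple, tuple]] = []

    for ca, cb in chain_map.items():
        ra, rb = a_seqs[ca], b_seqs[cb]
        if rule == "by_number":
            b_index = {(n, ic): (cb, n, ic) for _, n, ic, _ in rb}
            for _, n, ic, _ in ra:
                hit = b_index.get((n, ic))
                if hit is not None:
                    pairs.append(((ca, n, ic), hit))
        elif rule == "by_alignment":
            from Bio import Align

            aligner = Align.PairwiseAligner(mode="global", match_score=2,
                                            mismatch_score=-1,
                                            open_gap_score=-5,
                                            extend_gap_score=-0.5)
            sa = "".join(_one_letter(r[3]) for r in ra)
            sb = "".join(_one_letter(r[3]) for r in rb)
            aln = aligner.align(sa, sb)[0]
            for blk_a, blk_b in zip(aln.aligned[0], aln.aligned[1]):
                for ia, ib in zip(range(*blk_a), range(*blk_b)):
                    pairs.append((ra[ia][:3], rb[ib][:3]))
        else:
            raise ValueError(f"unknown pairing rule {rule!r}")

    if not pairs:
        raise PairingError(
            f"no common residues between {a.id!r} and {b.id!r} under {rule}"
        )
    return ResiduePairing(pairs=pairs, rule=rule, chain_map=chain_map)


def paired_atom_indices(
    a: Structure,
    b: Structure,
    pairing: ResiduePairing,
    atom_name: str = "CA",
) -> tuple[np.ndarray, np.ndarray]:
    """Atom index arrays (into a and b) for one named atom per paired residue.

    Pairs where either residue lacks the atom are dropped.
    """
    def index(s: Structure) -> dict[tuple, int]:
        out = {}
        for i in range(s.n_atoms):
            if str(s.atname[i]) == atom_name:
                out[(str(s.chain[i]), int(s.resnum[i]), str(s.icode[i]))] = i
        return out

    ia_map, ib_map = index(a), index(b)
    ia, ib = [], []
    for ka, kb in pairing.pairs:
        if ka in ia_map and kb in ib_map:
            ia.append(ia_map[ka])
            ib.append(ib_map[kb])
    return np.array(ia, dtype=int), np.array(ib, dtype=int)
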