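"""Geometric reporters of motor conformation.

These are the mechanistic time series used to characterize lever-arm
priming and motor-domain allostery: radius of gyration of the whole
fragment, vertex angles between three Cα anchors that track lever-arm
orientation (e.g. K803 < C705 > M90 — tip, base, and a motor-domain
reference), donor–acceptor distances for backdoor salt bridges such as
Switch-1 R243 / Switch-2 E466, and side-chain χ1 dihedrals whose rotamer
flips (F465) mark loss of connector communication.

All observables are invariant under global rigid motions of each frame;
angles are reported in degrees, distances in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MonitorError
from .series import ScalarSeries
from .structio import Structure, Trajectory

# χ1 rotamer wells: gauche−, trans, gauche+ with boundaries at 0° and ±120°
DEFAULT_CHI1_BOUNDARIES = (-120.0, 0.0, 120.0)

# terminal/basic nitrogens and carboxylate oxygens used for salt bridges
_BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",),
                "HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration in Å.

    Rg = sqrt( Σ mᵢ |rᵢ − r_com|² / Σ mᵢ ); uniform weights when ``masses``
    is omitted.
    """
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or len(xyz) == 0:
        raise ValueError("need a non-empty (n, 3) coordinate array")
    if masses is None:
        m = np.ones(len(xyz))
    else:
        m = np.asarray(masses, dtype=float)
        if (m <= 0).any():
            raise ValueError("masses must be positive")
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((xyz - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_series(traj: Trajectory, mass_weighted: bool = True,
              atom_indices: np.ndarray | None = None) -> ScalarSeries:
    """Per-frame radius of gyration over the whole topology (or a subset)."""
    idx = np.arange(traj.topology.n_atoms) if atom_indices is None else atom_indices
    masses = traj.topology.masses()[idx] if mass_weighted else None
    values = np.array([radius_of_gyration(f[idx], masses) for f in traj.frames])
    return ScalarSeries(times=traj.times, values=values, unit="angstrom",
                        label="rg")


# ---------------------------------------------------------------------------
# angle observables


@dataclass(frozen=True)
class AngleTripletSpec:
    """Three atom anchors defining a vertex angle.

    Each anchor is (chain, residue number, atom name); the angle is measured
    at the middle anchor.  ``atom name`` defaults to Cα.
    """

    first: tuple[str, int, str]
    vertex: tuple[str, int, str]
    third: tuple[str, int, str]
    label: str = "angle"

    @classmethod
    def ca_triplet(cls, chain: str, first: int, vertex: int, third: int,
                   label: str = "angle") -> "AngleTripletSpec":
        return cls((chain, first, "CA"), (chain, vertex, "CA"),
                   (chain, third, "CA"), label)


def _resolve_anchor(structure: Structure, anchor: tuple[str, int, str]) -> int:
    chain, resnum, atname = anchor
    hits = np.flatnonzero(
        (structure.chain.astype(str) == str(chain))
        & (structure.resnum == int(resnum))
        & (structure.atname.astype(str) == str(atname))
    )
    if len(hits) == 0:
        raise MonitorError(f"anchor {anchor} not found in {structure.id!r}")
    return int(hits[0])


def _vertex_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle ABC at vertex b, degrees in [0, 180]."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise MonitorError("coincident anchor atoms")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_series(traj: Trajectory, spec: AngleTripletSpec) -> ScalarSeries:
    """Per-frame vertex angle for an anchor triplet, in degrees."""
    ia = _resolve_anchor(traj.topology, spec.first)
    ib = _resolve_anchor(traj.topology, spec.vertex)
    ic = _resolve_anchor(traj.topology, spec.third)
    if len({ia, ib, ic}) != 3:
        raise MonitorError("the three anchors must be distinct atoms")
    values = np.array(
        [_vertex_angle(f[ia], f[ib], f[ic]) for f in traj.frames]
    )
    return ScalarSeries(times=traj.times, values=values, unit="degree",
                        label=spec.label)


def priming_angle(structure: Structure, spec: AngleTripletSpec,
                  model: int = 0) -> float:
    """Lever-arm priming angle (degrees) on a single coordinate set."""
    xyz = structure.xyz(model)
    ia = _resolve_anchor(structure, spec.first)
    ib = _resolve_anchor(structure, spec.vertex)
    ic = _resolve_anchor(structure, spec.third)
    if len({ia, ib, ic}) != 3:
        raise MonitorError("the three anchors must be distinct atoms")
    return _vertex_angle(xyz[ia], xyz[ib], xyz[ic])


# ---------------------------------------------------------------------------
# monitors: distances, salt bridges, χ1 dihedrals


@dataclass(frozen=True)
class MonitorSpec:
    """A per-frame geometric monitor.

    kind='distance'    anchors = two (chain, resnum, atom name) atoms
    kind='salt_bridge' anchors = two (chain, resnum) residues
                       (basic first, acidic second); min distance between the
                       basic side-chain nitrogens and the carboxylate oxygens,
                       with formed = (distance ≤ cutoff)
    kind='chi1'        anchors = one (chain, resnum) residue; N–CA–CB–CG
                       dihedral in (−180, 180]
    """

    kind: str
    anchors: tuple
    cutoff: float = 4.0
    label: str = ""


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (−180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def _salt_bridge_atoms(structure: Structure, chain: str, resnum: int,
                       table: dict) -> np.ndarray:
    mask = (structure.chain.astype(str) == str(chain)) & (
        structure.resnum == int(resnum)
    )
    hits = np.flatnonzero(mask)
    if len(hits) == 0:
        raise MonitorError(f"residue {chain}/{resnum} not found")
    resname = str(structure.resname[hits[0]])
    wanted = table.get(resname)
    if wanted is None:
        raise MonitorError(
            f"residue {chain}/{resnum} ({resname}) is not in the "
            f"salt-bridge dictionary {sorted(table)}"
        )
    idx = [i for i in hits if str(structure.atname[i]) in wanted]
    if not idx:
        raise MonitorError(
            f"residue {chain}/{resnum} ({resname}) lacks atoms {wanted}"
        )
    return np.array(idx, dtype=int)


def monitor_series(traj: Trajectory, spec: MonitorSpec) -> ScalarSeries:
    """Evaluate a monitor per frame.

    Distances and salt-bridge minimum distances are in Å (salt-bridge series
    carry a boolean ``formed`` array in ``meta``); χ1 dihedrals are degrees.
    """
    topo = traj.topology
    if spec.kind == "distance":
        ia = _resolve_anchor(topo, spec.anchors[0])
        ib = _resolve_anchor(topo, spec.anchors[1])
        values = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
        return ScalarSeries(traj.times, values, "angstrom",
                            spec.label or "distance")
    if spec.kind == "salt_bridge":
        (ch_b, rn_b), (ch_a, rn_a) = spec.anchors
        ib = _salt_bridge_atoms(topo, ch_b, rn_b, _BASIC_ATOMS)
        ia = _salt_bridge_atoms(topo, ch_a, rn_a, _ACIDIC_ATOMS)
        d = np.linalg.norm(
            traj.frames[:, ib, None, :] - traj.frames[:, None, ia, :], axis=-1
        )
        values = d.reshape(traj.n_frames, -1).min(axis=1)
        s = ScalarSeries(traj.times, values, "angstrom",
                         spec.label or "salt_bridge")
        s.meta["formed"] = values <= spec.cutoff
        s.meta["cutoff"] = spec.cutoff
        return s
    if spec.kind == "chi1":
        chain, resnum = spec.anchors[0]
        idx = []
        for name in ("N", "CA", "CB", "CG"):
            try:
                idx.append(_resolve_anchor(topo, (chain, resnum, name)))
            except MonitorError as exc:
                raise MonitorError(
                    f"residue {chain}/{resnum} lacks atom {name} needed for χ1"
                ) from exc
        values = np.array(
            [dihedral(f[idx[0]], f[idx[1]], f[idx[2]], f[idx[3]])
             for f in traj.frames]
        )
        s = ScalarSeries(traj.times, values, "degree", spec.label or "chi1")
        s.meta["rotamers"] = np.array([classify_rotamer(v) for v in values])
        return s
    raise MonitorError(f"unknown monitor kind {spec.kind!r}")


def classify_rotamer(chi1_deg: float,
                     boundaries: tuple = DEFAULT_CHI1_BOUNDARIES) -> str:
    """Rotamer well of a χ1 value: 'g-' (−120..0), 'g+' (0..120), or 't'."""
    lo, mid, hi = boundaries
    if lo < chi1_deg <= mid:
        return "g-"
    if mid < chi1_deg <= hi:
        return "g+"
    return "t"


def detect_chi1_flip(series: ScalarSeries,
                     boundaries: tuple = DEFAULT_CHI1_BOUNDARIES) -> int | None:
    """First frame index at which the χ1 rotamer well changes, else None."""
    wells = [classify_rotamer(v, boundaries) for v in series.values]
    for i in range(1, len(wells)):
        if wells[i] != wells[i - 1]:
            return i
    return None
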