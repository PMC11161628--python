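"""Synthetic motor-model and trajectory generator with exact ground truth.

This module builds simple two-domain Cα/backbone models — a rigid "motor
blob" of residues on a sphere plus an ideal α-helical lever arm — and
animates them by rigid hinge rotations with prescribed angle schedules,
optional Gaussian coordinate noise, two-state angle mixtures, and toy
ligand complexes with contacts planted at exact distances.  Every output
carries its generating parameters as machine-readable ground truth, so the
analysis stages (superposition, angle recovery, landscapes, contacts,
affinity series) can be tested against known answers.

Numbering follows the myosin-motor convention so literature residue ranges
apply verbatim: blob residues start at 1, the hinge analog of C705 sits at
residue 705, the lever occupies 706–806 (so the canonical lever selection
711–806 resolves to 96 residues), with the angle-anchor analogs of M90 and
K803 placed exactly on the hinge plane and the lever axis.  Because those
three anchors are exact, the vertex angle M90 < C705 > K803 equals the
schedule angle to machine precision at zero noise.

There is no physics here — no force field and no integrator; frames are
pure geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import SpecError
from .structio import Structure, Trajectory

_BACKBONE_OFFSETS = {
    # constant local offsets from Cα, Å; enough to give every residue
    # backbone N (donor) and O (acceptor) plus two carbons
    "N": np.array([-1.20, 0.70, 0.40]),
    "C": np.array([0.90, 1.00, -0.60]),
    "O": np.array([0.75, 2.20, -0.75]),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic motor model and its trajectories.

    Angles are in degrees, lengths in Å, times in ns.  ``theta0_deg`` is the
    resting lever angle measured at the hinge between the motor anchor and
    the lever tip; the defaults place it at the primed value observed for
    drug-bound pre-powerstroke myosin (~78°), with the two-state mixture
    separated by the ~36° swing amplitude seen without drug.
    """

    n_blob_residues: int = 150
    blob_radius: float = 18.0
    blob_center_x: float = -30.0
    anchor_resnum: int = 90       # motor-domain angle anchor (M90 analog)
    anchor_distance: float = 20.0
    hinge_resnum: int = 705       # lever base / angle vertex (C705 analog)
    lever_start: int = 706
    lever_end: int = 806
    tip_resnum: int = 803         # lever tip angle anchor (K803 analog)
    helix_rise: float = 1.5       # Å per residue
    helix_twist: float = 100.0    # degrees per residue
    helix_radius: float = 2.3
    theta0_deg: float = 78.0
    schedule_deg: np.ndarray | None = None
    n_frames: int = 200
    stride_ns: float = 1.0
    noise_sigma: float = 0.5
    populations: tuple[float, float] = (0.7, 0.3)
    state_angles_deg: tuple[float, float] = (78.0, 114.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be ≥ 0")
        if self.lever_end <= self.lever_start:
            raise SpecError("zero-length lever arm")
        if not np.isclose(sum(self.populations), 1.0):
            raise SpecError(f"populations {self.populations} must sum to 1")
        if not (0 < self.anchor_resnum <= self.n_blob_residues):
            raise SpecError("anchor residue must lie inside the blob numbering")
        if not (self.lever_start <= self.tip_resnum <= self.lever_end):
            raise SpecError("tip residue must lie on the lever arm")

    def truth(self) -> dict:
        d = asdict(self)
        if d["schedule_deg"] is not None:
            d["schedule_deg"] = np.asarray(d["schedule_deg"]).tolist()
        return d


@dataclass
class SyntheticTrajectory:
    """A generated trajectory together with its ground truth."""

    trajectory: Trajectory
    truth: dict = field(default_factory=dict)

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)


def _lever_direction(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.array([-np.cos(t), np.sin(t), 0.0])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def make_motor_model(spec: SyntheticSpec | None = None) -> Structure:
    """Build the two-domain model at the resting angle ``theta0_deg``.

    Deterministic closed-form geometry: blob residues on a quasi-uniform
    sphere, lever residues as an ideal helical Cα trace about the lever
    axis, and the three angle-anchor atoms placed exactly so that the
    M90 < C705 > K803 analog angle equals ``theta0_deg``.
    """
    spec = spec or SyntheticSpec()
    atoms: list[tuple] = []
    coords: list[np.ndarray] = []
    blob_center = np.array([spec.blob_center_x, 0.0, 0.0])
    sphere = _fibonacci_sphere(spec.n_blob_residues) * spec.blob_radius

    def add_residue(resnum: int, resname: str, ca: np.ndarray) -> None:
        for name in ("N", "CA", "C", "O"):
            pos = ca if name == "CA" else ca + _BACKBONE_OFFSETS[name]
            atoms.append(("A", resnum, "", resname, name, _ELEMENT[name]))
            coords.append(pos)

    # motor blob, residues 1..n_blob; the M90-analog anchor is exact
    for k in range(spec.n_blob_residues):
        resnum = k + 1
        if resnum == spec.anchor_resnum:
            ca = np.array([-spec.anchor_distance, 0.0, 0.0])
            resname = "MET"
        else:
            ca = blob_center + sphere[k]
            resname = "ALA"
        add_residue(resnum, resname, ca)

    # hinge (C705 analog) exactly at the origin
    add_residue(spec.hinge_resnum, "CYS", np.zeros(3))

    # lever arm helix along u(theta0); the K803-analog tip is exactly on axis
    u = _lever_direction(spec.theta0_deg)
    n1 = np.array([np.sin(np.radians(spec.theta0_deg)),
                   np.cos(np.radians(spec.theta0_deg)), 0.0])
    n2 = np.array([0.0, 0.0, 1.0])
    for resnum in range(spec.lever_start, spec.lever_end + 1):
        k = resnum - spec.hinge_resnum
        axial = spec.helix_rise * k * u
        if resnum == spec.tip_resnum:
            ca = axial
            resname = "LYS"
        else:
            phase = np.radians(spec.helix_twist * k)
            ca = axial + spec.helix_radius * (np.cos(phase) * n1
                                              + np.sin(phase) * n2)
            resname = "LEU"
        add_residue(resnum, resname, ca)

    return Structure.from_atoms("synthetic-motor", atoms,
                                np.asarray(coords)[None])


def _rotate_lever(model: Structure, spec: SyntheticSpec,
                  theta_deg: float) -> np.ndarray:
    """Coordinates with the lever rigidly rotated from theta0 to theta."""
    xyz = model.xyz(0).copy()
    alpha = np.radians(spec.theta0_deg - theta_deg)
    c, s = np.cos(alpha), np.sin(alpha)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    lever = model.resnum >= spec.lever_start
    xyz[lever] = xyz[lever] @ rot.T
    return xyz


def _default_schedule(spec: SyntheticSpec) -> np.ndarray:
    """Back-and-forth triangular swing covering exactly 36° above the
    resting angle (both extremes are sampled frames)."""
    n = spec.n_frames
    if n == 1:
        return np.array([spec.theta0_deg])
    up = np.linspace(spec.theta0_deg, spec.theta0_deg + 36.0,
                     (n + 1) // 2 + (n % 2 == 0))
    return np.concatenate([up, up[-2::-1]])[:n]


def make_swing_trajectory(
    model: Structure, spec: SyntheticSpec
) -> SyntheticTrajectory:
    """Animate the lever along an angle schedule with Gaussian noise.

    Each frame is the rigid hinge rotation of the lever to θ(t) plus i.i.d.
    isotropic noise of ``noise_sigma`` Å on every atom; noise streams are
    spawned per frame from the root seed, so identical specs are
    bit-identical and frame noise is independent.
    """
    schedule = (np.asarray(spec.schedule_deg, dtype=float)
                if spec.schedule_deg is not None else _default_schedule(spec))
    seeds = np.random.SeedSequence(spec.seed).spawn(len(schedule))
    frames = np.empty((len(schedule), model.n_atoms, 3))
    for i, theta in enumerate(schedule):
        xyz = _rotate_lever(model, spec, float(theta))
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(seeds[i])
            xyz = xyz + rng.normal(0.0, spec.noise_sigma, xyz.shape)
        frames[i] = xyz
    times = np.arange(len(schedule)) * spec.stride_ns
    traj = Trajectory(topology=model.with_coords(frames[:1]),
                      frames=frames, times=times)
    truth = {"kind": "swing", "schedule_deg": schedule.tolist(),
             "spec": spec.truth()}
    return SyntheticTrajectory(trajectory=traj, truth=truth)


def make_two_state_trajectory(
    model: Structure, spec: SyntheticSpec
) -> SyntheticTrajectory:
    """Two-state angle mixture: each frame is drawn i.i.d. from
    ``state_angles_deg`` with probabilities ``populations``.

    The per-frame state labels are stored as ground truth, so population
    and free-energy recovery tests are self-checking.
    """
    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = label_rng.choice(2, size=spec.n_frames, p=list(spec.populations))
    schedule = np.array([spec.state_angles_deg[l] for l in labels])
    sub = SyntheticSpec(**{**spec.truth(), "schedule_deg": schedule,
                           "seed": spec.seed + 1})
    out = make_swing_trajectory(model, sub)
    out.truth = {"kind": "two_state", "labels": labels.tolist(),
                 "populations": list(spec.populations),
                 "state_angles_deg": list(spec.state_angles_deg),
                 "spec": spec.truth()}
    return out


# ---------------------------------------------------------------------------
# ligand complexes


@dataclass(frozen=True)
class PlannedContact:
    """One contact to plant: class, exact distance, and the protein target."""

    contact_class: str          # 'polar' | 'apolar'
    distance: float             # Å
    target_resnum: int
    target_atom: str | None = None  # default: 'O' for polar, 'CA' for apolar

    def resolved_atom(self) -> str:
        if self.target_atom:
            return self.target_atom
        return "O" if self.contact_class == "polar" else "CA"


_CLASH_LIMIT = 2.0  # Å


def make_ligand_complex(
    model: Structure,
    plan: list[PlannedContact],
    ligand_resname: str = "LIG",
    ligand_chain: str = "L",
    ligand_resnum: int = 900,
) -> Structure:
    """Place one ligand atom per planned contact at exactly the planned
    distance from the named protein atom, along the outward normal of the
    local neighborhood (to avoid incidental contacts).

    Polar plants get a nitrogen ligand atom; apolar plants get a carbon.
    Raises :class:`SpecError` for infeasible plans (distance below the clash
    limit, missing target residue, or a placement that lands closer to a
    non-target atom than planned).
    """
    xyz = model.xyz(0)
    atoms = [(str(model.chain[i]), int(model.resnum[i]), str(model.icode[i]),
              str(model.resname[i]), str(model.atname[i]),
              str(model.element[i])) for i in range(model.n_atoms)]
    new_coords = [xyz[i] for i in range(model.n_atoms)]
    new_atoms = list(atoms)

    for j, pc in enumerate(plan):
        if pc.distance < _CLASH_LIMIT:
            raise SpecError(
                f"planned distance {pc.distance} Å below the {_CLASH_LIMIT} Å "
                "clash limit"
            )
        atname = pc.resolved_atom()
        hits = np.flatnonzero((model.resnum == pc.target_resnum)
                              & (model.atname.astype(str) == atname))
        if len(hits) == 0:
            raise SpecError(
                f"target residue {pc.target_resnum} atom {atname} not found"
            )
        target = xyz[int(hits[0])]
        # deterministic search over candidate outward directions: keep the
        # placement that maximizes clearance from every non-target atom the
        # ligand atom could form a same-class contact with (other polar
        # atoms for a polar plant, other carbons for an apolar plant).
        # Clearance must exceed both the planned distance and the 4 Å scale
        # of typical contact cutoffs, so the planted pair is the only
        # contact this ligand atom can make at default-scale cutoffs.
        from .contacts import _is_polar_protein_atom

        if pc.contact_class == "polar":
            eligible = np.array([
                _is_polar_protein_atom(str(model.resname[i]),
                                       str(model.atname[i]),
                                       str(model.element[i]))
                for i in range(model.n_atoms)])
        else:
            eligible = model.element.astype(str) == "C"
        eligible[int(hits[0])] = False
        required = max(4.0, pc.distance)
        best_pos, best_clearance = None, -np.inf
        for direction in _fibonacci_sphere(180):
            cand = target + pc.distance * direction
            d_el = np.linalg.norm(xyz[eligible] - cand, axis=1)
            clearance = float(d_el.min()) if len(d_el) else np.inf
            if clearance > best_clearance:
                best_clearance, best_pos = clearance, cand
        if best_pos is None or best_clearance <= required:
            raise SpecError(
                f"plan entry {j}: best placement clears same-class atoms by "
                f"only {best_clearance:.2f} Å (need > {required:.2f} Å); "
                "the target is too buried for an incidental-contact-free plant"
            )
        pos = best_pos
        element = "N" if pc.contact_class == "polar" else "C"
        new_atoms.append((ligand_chain, ligand_resnum, "", ligand_resname,
                          f"{element}{j + 1}", element))
        new_coords.append(pos)

    return Structure.from_atoms(f"{model.id}+{ligand_resname}", new_atoms,
                                np.asarray(new_coords)[None])


def make_release_trajectory(
    complex_structure: Structure,
    n_frames: int,
    release_frame: int,
    ligand_chain: str = "L",
    displacement: float = 100.0,
    noise_sigma: float = 0.0,
    stride_ns: float = 1.0,
    seed: int = 0,
) -> SyntheticTrajectory:
    """Rigid trajectory of a complex whose ligand leaves the pocket.

    Frames before ``release_frame`` repeat the bound pose; from
    ``release_frame`` on, the ligand is translated ``displacement`` Å away
    (unbound).  Ground truth stores the release frame.
    """
    xyz = complex_structure.xyz(0)
    lig = complex_structure.chain.astype(str) == ligand_chain
    seeds = np.random.SeedSequence(seed).spawn(n_frames)
    frames = np.empty((n_frames, complex_structure.n_atoms, 3))
    for i in range(n_frames):
        f = xyz.copy()
        if i >= release_frame:
            f[lig] += np.array([0.0, 0.0, displacement])
        if noise_sigma > 0:
            rng = np.random.default_rng(seeds[i])
            f += rng.normal(0.0, noise_sigma, f.shape)
        frames[i] = f
    traj = Trajectory(topology=complex_structure.with_coords(frames[:1]),
                      frames=frames,
                      times=np.arange(n_frames) * stride_ns)
    return SyntheticTrajectory(
        trajectory=traj,
        truth={"kind": "release", "release_frame": release_frame,
               "displacement": displacement, "seed": seed},
    )


# ---------------------------------------------------------------------------
# scripted side-chain flip


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d given a-b-c."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d2 = bond * np.array([-np.cos(ang),
                          np.sin(ang) * np.cos(dih),
                          np.sin(ang) * np.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_chi1_trajectory(
    chi1_schedule_deg: np.ndarray,
    resnum: int = 465,
    noise_sigma: float = 0.0,
    stride_ns: float = 1.0,
    seed: int = 0,
) -> SyntheticTrajectory:
    """Single-residue trajectory with a scripted χ1 rotation.

    Builds an isolated Phe-like residue (N, CA, CB, CG) and sets the
    N–CA–CB–CG dihedral per frame from the schedule — the synthetic analog
    of a side-chain rotamer flip breaking connector communication.
    """
    schedule = np.asarray(chi1_schedule_deg, dtype=float)
    n_pos = np.array([1.45, 0.0, 0.0])
    ca = np.zeros(3)
    cb = np.array([-0.53, 1.43, 0.0])  # ~111° N-CA-CB angle
    atoms = [("A", resnum, "", "PHE", n, _ELEMENT.get(n, n[0]))
             for n in ("N", "CA", "CB")]
    atoms.append(("A", resnum, "", "PHE", "CG", "C"))
    seeds = np.random.SeedSequence(seed).spawn(len(schedule))
    frames = np.empty((len(schedule), 4, 3))
    for i, chi in enumerate(schedule):
        cg = _place_atom(n_pos, ca, cb, 1.52, 114.0, float(chi))
        f = np.array([n_pos, ca, cb, cg])
        if noise_sigma > 0:
            rng = np.random.default_rng(seeds[i])
            f = f + rng.normal(0.0, noise_sigma, f.shape)
        frames[i] = f
    topo = Structure.from_atoms("synthetic-chi1", atoms, frames[:1])
    traj = Trajectory(topology=topo, frames=frames,
                      times=np.arange(len(schedule)) * stride_ns)
    return SyntheticTrajectory(
        trajectory=traj,
        truth={"kind": "chi1", "schedule_deg": schedule.tolist(),
               "seed": seed},
    )
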