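"""Rigid-body superposition and RMSD analytics.

The core is a weighted Kabsch least-squares fit (SVD with reflection
correction), wrapped by an iterative outlier-rejection variant that mirrors
the "RMSD over N of M Cα" convention used when reporting crystal-structure
superpositions: atom pairs deviating more than ``sigma_cutoff`` times the
current RMS deviation are discarded and the fit repeated, so the final RMSD
is quoted over the surviving subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, RejectionCollapseError, SelectionError
from .series import ScalarSeries
from .structio import (
    ResiduePairing,
    Selection,
    Structure,
    Trajectory,
    pair_residues,
    paired_atom_indices,
    select,
)


@dataclass
class SuperpositionResult:
    """Outcome of a (possibly iterative) least-squares superposition.

    ``rotation`` and ``translation`` map mover coordinates onto the
    reference frame: ``x_fit = x_mov @ rotation.T + translation``.
    """

    rotation: np.ndarray          # 3×3 proper rotation
    translation: np.ndarray       # Å
    rmsd: float                   # Å, over the final matched set
    n_matched: int
    n_input: int
    rejected: list[tuple[int, int]] = field(default_factory=list)  # (pair index, cycle)
    per_cycle_rmsd: list[float] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def _check_geometry(ref: np.ndarray, mov: np.ndarray) -> None:
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise DegenerateGeometryError("paired (n, 3) coordinate arrays required")
    if len(ref) < 3:
        raise DegenerateGeometryError(f"need ≥3 pairs, got {len(ref)}")
    c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-8) < 2:
        raise DegenerateGeometryError("reference points are collinear")


def kabsch(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares rigid superposition of mover onto reference.

    Minimizes the weighted RMSD over all pairs; the rotation is always a
    proper rotation (reflections corrected by sign-flipping the smallest
    singular vector).  RMSD is reported over every input pair.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    _check_geometry(ref, mov)
    n = len(ref)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()

    c_ref = (wn[:, None] * ref).sum(axis=0)
    c_mov = (wn[:, None] * mov).sum(axis=0)
    p = ref - c_ref
    q = mov - c_mov
    h = (q * wn[:, None]).T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    trans = c_ref - rot @ c_mov

    fitted = mov @ rot.T + trans
    dev2 = ((fitted - ref) ** 2).sum(axis=1)
    rmsd = float(np.sqrt((wn * dev2).sum()))
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        n_matched=n,
        n_input=n,
        per_cycle_rmsd=[rmsd],
    )


def iterative_reject(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    cycles: int = 5,
    sigma_cutoff: float = 2.0,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Kabsch with per-cycle rejection of outlier pairs.

    Each cycle fits the surviving pairs, then rejects pairs whose post-fit
    Euclidean deviation exceeds ``sigma_cutoff`` × the root-mean-square
    deviation of the cycle (the structure-viewer convention: at the default
    2.0, pairs worse than twice the current RMSD are discarded).  Stops when
    no pair is rejected or ``cycles`` is reached.  The returned RMSD is over
    the survivors; ``rejected`` lists (original pair index, rejection cycle).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    _check_geometry(ref, mov)
    n = len(ref)
    alive = np.ones(n, dtype=bool)
    rejected: list[tuple[int, int]] = []
    per_cycle: list[float] = []
    result: SuperpositionResult | None = None

    for cycle in range(1, max(1, cycles) + 1):
        idx = np.flatnonzero(alive)
        if len(idx) < 3:
            raise RejectionCollapseError(
                f"rejection left {len(idx)} pairs; raise sigma_cutoff "
                f"(currently {sigma_cutoff})"
            )
        w = None if weights is None else weights[idx]
        fit = kabsch(ref[idx], mov[idx], w)
        per_cycle.append(fit.rmsd)
        result = fit
        if cycle == max(1, cycles):
            break
        dev = np.linalg.norm(fit.transform(mov[idx]) - ref[idx], axis=1)
        sigma = float(np.sqrt((dev**2).mean()))
        # a spread below numerical noise (~1e-10 Å) is a perfect match,
        # not a population of outliers
        if sigma < 1e-10 or not np.isfinite(sigma):
            break
        out = dev > sigma_cutoff * sigma
        if not out.any():
            break
        for i in idx[out]:
            rejected.append((int(i), cycle))
        alive[idx[out]] = False

    assert result is not None
    survivors = int(alive.sum())
    if survivors == 0:
        raise RejectionCollapseError("all pairs rejected; raise sigma_cutoff")
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_matched=survivors,
        n_input=n,
        rejected=rejected,
        per_cycle_rmsd=per_cycle,
    )


def align_reject(
    ref: Structure,
    mov: Structure,
    pairing: ResiduePairing | None = None,
    cycles: int = 5,
    sigma_cutoff: float = 2.0,
    atom_name: str = "CA",
    model_ref: int = 0,
    model_mov: int = 0,
) -> SuperpositionResult:
    """Superpose two structures over paired Cα (or other named) atoms with
    iterative outlier rejection.

    ``pairing`` defaults to by-number residue pairing.  The reported RMSD
    follows the crystallographic "x Å on N Cα" convention: it is evaluated
    over the pairs surviving rejection.
    """
    if pairing is None:
        pairing = pair_residues(ref, mov, rule="by_number")
    ia, ib = paired_atom_indices(ref, mov, pairing, atom_name=atom_name)
    if len(ia) < 3:
        raise DegenerateGeometryError(
            f"pairing yields {len(ia)} {atom_name} pairs; need ≥3"
        )
    return iterative_reject(
        ref.xyz(model_ref)[ia],
        mov.xyz(model_mov)[ib],
        cycles=cycles,
        sigma_cutoff=sigma_cutoff,
    )


def rmsd_series(
    traj: Trajectory,
    fit_selection: Selection | str,
    measure_selection: Selection | str,
    reference: int = 0,
) -> ScalarSeries:
    """Per-frame RMSD after superposing each frame onto a reference frame.

    Each frame is rigid-fitted to the reference over ``fit_selection``
    (the motor backbone, typically), then the RMSD is evaluated over
    ``measure_selection`` without refitting — so motion of the measured
    region relative to the fitted region is what the series reports.
    """
    fit_idx = select(traj.topology, fit_selection)
    mea_idx = select(traj.topology, measure_selection)
    if len(fit_idx) == 0 or len(mea_idx) == 0:
        raise SelectionError("fit and measure selections must be non-empty")
    ref = traj.frames[reference]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        fit = kabsch(ref[fit_idx], frame[fit_idx])
        moved = fit.transform(frame[mea_idx])
        values[i] = np.sqrt(((moved - ref[mea_idx]) ** 2).sum(axis=1).mean())
    return ScalarSeries(times=traj.times, values=values, unit="angstrom",
                        label="rmsd")
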