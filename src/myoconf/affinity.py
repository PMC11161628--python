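"""Binding free energy ↔ dissociation constant, and per-frame affinity
series over a trajectory.

The thermodynamic link is ΔG = R·T·ln(K_D) at the 1 M standard state
(R = 8.314 J·mol⁻¹·K⁻¹), so a K_D of 1 µM at 25 °C corresponds to about
−34 kJ/mol.  Per-frame binding free energies come from a configurable
linear model over typed contact counts,

    ΔG = intercept + Σ_class  coef_class × count_class ,

the functional form used by contact-count affinity predictors; its
coefficients are user configuration, never baked in.  Frames where the
ligand makes no contacts are flagged unbound and excluded from the mean K_D
(the mean is taken over K_D values, not over ΔG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import contacts as _contacts
from .errors import ConfigError, SelectionError
from .structio import Selection, Structure, Trajectory, select

R_GAS = 8.314            # J·mol⁻¹·K⁻¹
DEFAULT_TEMPERATURE = 298.15  # K (25 °C)


def dg_to_kd(dg_kj_mol: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (mol/L, 1 M standard state) from ΔG in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg_kj_mol * 1000.0 / (R_GAS * temperature))


def kd_to_dg(kd_mol: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy (kJ/mol) from K_D in mol/L; exact inverse of
    :func:`dg_to_kd`."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if kd_mol <= 0:
        raise ValueError("K_D must be positive")
    return R_GAS * temperature * math.log(kd_mol) / 1000.0


@dataclass(frozen=True)
class ContactCountModel:
    """Linear ΔG model over typed contact counts.

    ``coefficients`` maps contact class name → kJ/mol per contact;
    ``intercept`` is kJ/mol.  ``classes`` names the classes the model is
    responsible for; each must have a coefficient.
    """

    coefficients: dict[str, float]
    intercept: float = 0.0
    polar_cutoff: float = _contacts.DEFAULT_POLAR_CUTOFF
    apolar_cutoff: float = _contacts.DEFAULT_APOLAR_CUTOFF
    classes: tuple[str, ...] = ("polar", "apolar")

    def __post_init__(self) -> None:
        for cls in self.classes:
            if cls not in self.coefficients:
                raise ConfigError(
                    f"missing coefficient for contact class {cls!r} "
                    f"(have {sorted(self.coefficients)})"
                )


def contact_count_dg(
    structure: Structure,
    ligand_selection: Selection | str,
    model: ContactCountModel,
    model_index: int = 0,
) -> tuple[float, dict[str, int]]:
    """ΔG (kJ/mol) of one coordinate set under the contact-count model.

    Returns (ΔG, per-class contact counts).  Deterministic: identical
    structure and cutoffs give bit-identical ΔG.
    """
    records = _contacts.find_contacts(
        structure, ligand_selection,
        polar_cutoff=model.polar_cutoff,
        apolar_cutoff=model.apolar_cutoff,
        model=model_index,
    )
    counts = {cls: 0 for cls in model.classes}
    for r in records:
        if r.contact_class in counts:
            counts[r.contact_class] += 1
    dg = model.intercept + sum(
        model.coefficients[cls] * counts[cls] for cls in model.classes
    )
    return float(dg), counts


@dataclass
class AffinitySeries:
    """Per-frame ΔG / K_D with unbound frames flagged.

    ``kd_uM`` is NaN on unbound frames (zero contacts); ``mean_kd_uM`` is the
    arithmetic mean of K_D over bound frames only.
    """

    times: np.ndarray        # ns
    dg_kj_mol: np.ndarray
    kd_uM: np.ndarray
    bound: np.ndarray        # bool per frame
    temperature: float
    counts: list[dict[str, int]] = field(default_factory=list)

    @property
    def mean_kd_uM(self) -> float:
        vals = self.kd_uM[self.bound]
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def mean_dg_kj_mol(self) -> float:
        """ΔG-averaged alternative summary (over bound frames)."""
        vals = self.dg_kj_mol[self.bound]
        return float(vals.mean()) if len(vals) else float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ns": self.times,
            "dG_kJ_mol": np.where(self.bound, self.dg_kj_mol, np.nan),
            "Kd_uM": self.kd_uM,
            "bound": self.bound,
        })


def kd_series(
    traj: Trajectory,
    ligand_selection: Selection | str,
    model: ContactCountModel,
    temperature: float = DEFAULT_TEMPERATURE,
) -> AffinitySeries:
    """Per-frame affinity series over a trajectory.

    Each frame's typed contact counts feed the linear ΔG model; K_D follows
    from ΔG = RT·ln(K_D).  Frames with zero contacts of every class are
    flagged unbound (K_D undefined) and excluded from the mean.
    """
    lig_idx = select(traj.topology, ligand_selection)
    if len(lig_idx) == 0:
        raise SelectionError("ligand absent from topology")
    n = traj.n_frames
    dg = np.empty(n)
    kd = np.full(n, np.nan)
    bound = np.zeros(n, dtype=bool)
    counts_per_frame: list[dict[str, int]] = []
    for i in range(n):
        frame = traj.frame_structure(i)
        g, counts = contact_count_dg(frame, ligand_selection, model)
        counts_per_frame.append(counts)
        dg[i] = g
        if sum(counts.values()) > 0:
            bound[i] = True
            kd[i] = dg_to_kd(g, temperature) * 1e6  # mol/L → µM
    return AffinitySeries(
        times=traj.times, dg_kj_mol=dg, kd_uM=kd, bound=bound,
        temperature=temperature, counts=counts_per_frame,
    )
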