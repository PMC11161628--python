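"""Probability-density and Gibbs free-energy surfaces over two collective
variables.

A trajectory projected onto two CVs — here typically the lever-arm Cα RMSD
and the radius of gyration of the whole fragment — is binned into a 2D
histogram; Boltzmann inversion of the normalized density gives the free
energy relative to the most populated bin:

    G(bin) = −R·T·ln( p(bin) / p_max )      [kJ/mol]

so the global minimum of the landscape is 0 by construction and unoccupied
bins are undefined (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyLandscapeError, SeriesError, UndefinedBasinError
from .series import ScalarSeries

R_KJ = 8.314e-3  # gas constant, kJ·mol⁻¹·K⁻¹
DEFAULT_TEMPERATURE = 310.15  # K
KCAL_PER_KJ = 1.0 / 4.184


@dataclass
class FESGrid:
    """2D histogram over two collective variables, with optional free energy.

    ``prob`` sums to 1 over all bins; ``free_energy`` is kJ/mol with NaN in
    unoccupied bins and minimum 0 at the most populated bin.
    """

    cv1_name: str
    cv2_name: str
    cv1_unit: str
    cv2_unit: str
    edges1: np.ndarray  # length n1+1
    edges2: np.ndarray  # length n2+1
    prob: np.ndarray    # (n1, n2)
    n_samples: int
    temperature: float | None = None
    free_energy: np.ndarray | None = None  # (n1, n2), kJ/mol, NaN unoccupied
    meta: dict = field(default_factory=dict)

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])

    def to_frame(self):
        """Long-format export: one row per bin with centers, probability and
        free energy (empty string where undefined)."""
        import pandas as pd

        c1, c2 = np.meshgrid(self.centers1, self.centers2, indexing="ij")
        g = (np.full_like(self.prob, np.nan)
             if self.free_energy is None else self.free_energy)
        return pd.DataFrame({
            f"{self.cv1_name}_center": c1.ravel(),
            f"{self.cv2_name}_center": c2.ravel(),
            "probability": self.prob.ravel(),
            "G_kJ_mol": g.ravel(),
        })


def density2d(
    x: ScalarSeries | np.ndarray,
    y: ScalarSeries | np.ndarray,
    n1: int = 32,
    n2: int = 32,
    padding: float = 0.02,
    names: tuple[str, str] = ("cv1", "cv2"),
    units: tuple[str, str] = ("", ""),
) -> FESGrid:
    """Normalized 2D histogram of two equal-length CV series.

    Bin edges span the data range padded by ``padding`` × range per side
    (degenerate ranges are widened symmetrically so single-valued series
    still occupy one bin).
    """
    if isinstance(x, ScalarSeries):
        names = (x.label or names[0], names[1])
        units = (x.unit, units[1])
        x = x.values
    if isinstance(y, ScalarSeries):
        names = (names[0], y.label or names[1])
        units = (units[0], y.unit)
        y = y.values
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SeriesError(f"series lengths differ: {x.shape} vs {y.shape}")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 bins per axis")

    def edges(v: np.ndarray, n: int) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = padding * span if span > 0 else max(0.5, abs(hi) * 0.01)
        return np.linspace(lo - pad, hi + pad, n + 1)

    e1, e2 = edges(x, n1), edges(y, n2)
    counts, _, _ = np.histogram2d(x, y, bins=[e1, e2])
    prob = counts / counts.sum()
    return FESGrid(
        cv1_name=names[0], cv2_name=names[1],
        cv1_unit=units[0], cv2_unit=units[1],
        edges1=e1, edges2=e2, prob=prob, n_samples=len(x),
        meta={"bins": (n1, n2), "padding": padding},
    )


def fes_from_density(grid: FESGrid,
                     temperature: float = DEFAULT_TEMPERATURE) -> FESGrid:
    """Fill the Gibbs free-energy surface by Boltzmann inversion.

    Occupied bins get G = −RT·ln(p/p_max) in kJ/mol (min 0 at the most
    populated bin); unoccupied bins stay NaN.  The input grid is not
    modified.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    pmax = grid.prob.max()
    if pmax <= 0:
        raise EmptyLandscapeError("density grid carries no probability mass")
    g = np.full(grid.prob.shape, np.nan)
    occ = grid.prob > 0
    g[occ] = -R_KJ * temperature * np.log(grid.prob[occ] / pmax)
    return FESGrid(
        cv1_name=grid.cv1_name, cv2_name=grid.cv2_name,
        cv1_unit=grid.cv1_unit, cv2_unit=grid.cv2_unit,
        edges1=grid.edges1, edges2=grid.edges2, prob=grid.prob,
        n_samples=grid.n_samples, temperature=temperature, free_energy=g,
        meta=dict(grid.meta),
    )


def basin_delta_g(
    grid: FESGrid,
    region_a: np.ndarray,
    region_b: np.ndarray,
    temperature: float | None = None,
) -> float:
    """Free-energy difference −RT·ln(p_a/p_b) between two disjoint bin
    regions, in kJ/mol (negative when region a is more populated).

    Regions are boolean masks over the grid bins; their summed probability
    masses must both be nonzero.
    """
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != grid.prob.shape or b.shape != grid.prob.shape:
        raise ValueError("region masks must match the grid shape")
    if (a & b).any():
        raise ValueError("basin regions must be disjoint")
    t = temperature or grid.temperature or DEFAULT_TEMPERATURE
    pa, pb = float(grid.prob[a].sum()), float(grid.prob[b].sum())
    if pa <= 0 or pb <= 0:
        raise UndefinedBasinError(
            f"zero-mass basin (p_a={pa}, p_b={pb}); enlarge the region"
        )
    return float(-R_KJ * t * np.log(pa / pb))
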