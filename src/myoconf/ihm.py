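"""Interacting-heads-motif (IHM) compatibility assessment.

The IHM is the autoinhibited, sequestered state of two-headed myosin in
which a blocked head (BH) and a free head (FH) pack against each other.
Whether a drug-stabilized motor conformation can still form this motif is
assessed in two ways: (i) a superposition of the query onto a reference IHM
structure restricted to the head–head interface residue ranges, and (ii) a
comparison of the query's lever-arm priming angle against the angles the
reference's BH and FH adopt.  Because the lever arm of the blocked head is
kinked, its reference angle is measured with the last pre-kink residue
(L781 in β-cardiac myosin) in place of the usual lever-tip anchor.

The verdict combines both numbers under configurable tolerances and is a
heuristic label, always derivable from the stored numbers alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InterfaceError
from .observables import AngleTripletSpec, priming_angle
from .series import ScalarSeries
from .structio import Structure
from .superpose import SuperpositionResult, kabsch

DEFAULT_RMSD_TOL = 1.5   # Å
DEFAULT_ANGLE_TOL = 10.0  # degrees

# head-head interface residue ranges on the reference IHM (author numbers):
# the BH motor surface contacted by the FH, and the FH converter/lever region
DEFAULT_BH_RANGES = ((329, 447),)
DEFAULT_FH_RANGES = ((498, 518), (708, 780))


@dataclass
class IHMReference:
    """A reference sequestered-state structure with interface ranges and
    lever angles for both heads.

    Reference angles may be supplied directly or measured from the reference
    structure via :meth:`from_structure` (using a pre-kink lever anchor for
    the blocked head).
    """

    structure: Structure
    bh_chain: str
    fh_chain: str
    bh_ranges: tuple[tuple[int, int], ...] = DEFAULT_BH_RANGES
    fh_ranges: tuple[tuple[int, int], ...] = DEFAULT_FH_RANGES
    bh_angle: float | None = None   # degrees
    fh_angle: float | None = None

    def __post_init__(self) -> None:
        for ang in (self.bh_angle, self.fh_angle):
            if ang is not None and not (0.0 < ang < 180.0):
                raise ConfigError(f"reference angle {ang} outside (0, 180)")

    @classmethod
    def from_structure(
        cls,
        structure: Structure,
        bh_chain: str,
        fh_chain: str,
        bh_angle_spec: AngleTripletSpec,
        fh_angle_spec: AngleTripletSpec,
        bh_ranges: tuple = DEFAULT_BH_RANGES,
        fh_ranges: tuple = DEFAULT_FH_RANGES,
    ) -> "IHMReference":
        """Measure the BH/FH reference lever angles from the reference
        structure itself (the BH spec should use the pre-kink anchor)."""
        return cls(
            structure=structure,
            bh_chain=bh_chain,
            fh_chain=fh_chain,
            bh_ranges=tuple(bh_ranges),
            fh_ranges=tuple(fh_ranges),
            bh_angle=priming_angle(structure, bh_angle_spec),
            fh_angle=priming_angle(structure, fh_angle_spec),
        )


def _range_ca_pairs(
    query: Structure, query_chain: str,
    ref: Structure, ref_chain: str,
    ranges: tuple[tuple[int, int], ...],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cα index pairs over the ranges, matched by author residue number.

    Returns (query indices, ref indices, n dropped from the nominal ref set).
    """
    def ca_index(s: Structure, chain: str) -> dict[int, int]:
        out = {}
        for i in range(s.n_atoms):
            if (str(s.atname[i]) == "CA" and str(s.chain[i]) == chain
                    and not str(s.icode[i])):
                out.setdefault(int(s.resnum[i]), i)
        return out

    qmap, rmap = ca_index(query, query_chain), ca_index(ref, ref_chain)
    iq, ir, dropped = [], [], 0
    for lo, hi in ranges:
        for n in range(lo, hi + 1):
            if n in rmap:
                if n in qmap:
                    iq.append(qmap[n])
                    ir.append(rmap[n])
                else:
                    dropped += 1
    return np.array(iq, dtype=int), np.array(ir, dtype=int), dropped


def superpose_on_interface(
    query: Structure,
    ref: IHMReference,
    which: str = "pair",
    query_bh_chain: str | None = None,
    query_fh_chain: str | None = None,
) -> SuperpositionResult:
    """Superpose a query onto the reference IHM over interface Cα only.

    ``which`` selects the BH ranges, the FH ranges, or (for ``pair``) a
    joint fit in which one query molecule is matched to the BH ranges and a
    second to the FH ranges — the natural mode for a two-copy query such as
    a crystal's asymmetric-unit pair.  Range residues missing from the
    query are dropped from the fit; the returned ``n_input`` counts the
    resolvable reference range residues, so ``n_matched`` < nominal range
    size reports the dropped count.
    """
    qb = query_bh_chain or ref.bh_chain
    qf = query_fh_chain or ref.fh_chain
    parts: list[tuple[np.ndarray, np.ndarray]] = []
    dropped_total = 0
    if which in ("BH", "pair"):
        iq, ir, dropped = _range_ca_pairs(query, qb, ref.structure,
                                          ref.bh_chain, ref.bh_ranges)
        parts.append((iq, ir))
        dropped_total += dropped
    if which in ("FH", "pair"):
        iq, ir, dropped = _range_ca_pairs(query, qf, ref.structure,
                                          ref.fh_chain, ref.fh_ranges)
        parts.append((iq, ir))
        dropped_total += dropped
    if which not in ("BH", "FH", "pair"):
        raise ValueError(f"which must be BH, FH or pair, not {which!r}")

    iq = np.concatenate([p[0] for p in parts])
    ir = np.concatenate([p[1] for p in parts])
    if len(iq) < 3:
        raise InterfaceError(
            f"only {len(iq)} interface Cα resolve on both structures"
        )
    fit = kabsch(ref.structure.xyz(0)[ir], query.xyz(0)[iq])
    fit.n_input = len(iq) + dropped_total
    return fit


@dataclass
class IHMCompatReport:
    """Interface RMSD, lever-angle deltas, and a heuristic verdict.

    The verdict is 'compatible' iff interface_rmsd ≤ rmsd_tol and the
    smaller of the two angle deltas ≤ angle_tol; it is recomputable from
    the stored numbers.
    """

    interface_rmsd: float | None
    interface_n_matched: int | None
    delta_bh: float | None       # degrees (single value or mean over frames)
    delta_fh: float | None
    fraction_within: float | None  # fraction of frames within tol of either
    rmsd_tol: float
    angle_tol: float
    verdict: str = ""
    note: str = "heuristic verdict; tolerances are configuration, not physics"
    per_frame: dict = field(default_factory=dict)


def angle_vs_ihm(
    series_or_value: ScalarSeries | float,
    ref: IHMReference,
    tolerance: float = DEFAULT_ANGLE_TOL,
) -> IHMCompatReport:
    """Compare a lever angle (value or per-frame series) to the BH/FH
    reference angles.

    Reports |angle − BH| and |angle − FH| (means over frames for a series)
    and the fraction of frames within ``tolerance`` of either reference
    angle; the tolerance bound is a closed interval, so a frame offset by
    exactly the tolerance counts as within.
    """
    if ref.bh_angle is None or ref.fh_angle is None:
        raise ConfigError(
            "reference BH/FH angles are unset; measure them from the "
            "reference structure or supply them explicitly"
        )
    if isinstance(series_or_value, ScalarSeries):
        values = series_or_value.values
    else:
        values = np.array([float(series_or_value)])
    d_bh = np.abs(values - ref.bh_angle)
    d_fh = np.abs(values - ref.fh_angle)
    within = (d_bh <= tolerance) | (d_fh <= tolerance)
    return IHMCompatReport(
        interface_rmsd=None,
        interface_n_matched=None,
        delta_bh=float(d_bh.mean()),
        delta_fh=float(d_fh.mean()),
        fraction_within=float(within.mean()),
        rmsd_tol=DEFAULT_RMSD_TOL,
        angle_tol=tolerance,
        per_frame={"delta_bh": d_bh, "delta_fh": d_fh, "within": within},
    )


def compat_report(
    query: Structure,
    ref: IHMReference,
    angle_spec: AngleTripletSpec,
    which: str = "pair",
    rmsd_tol: float = DEFAULT_RMSD_TOL,
    angle_tol: float = DEFAULT_ANGLE_TOL,
    query_bh_chain: str | None = None,
    query_fh_chain: str | None = None,
) -> IHMCompatReport:
    """Full compatibility assessment of a query structure.

    Bundles the interface-restricted superposition with the lever-angle
    comparison; compatible iff interface rmsd ≤ ``rmsd_tol`` AND the
    smaller angle delta ≤ ``angle_tol``.  Growing either tolerance can only
    move the verdict from incompatible to compatible.
    """
    fit = superpose_on_interface(query, ref, which=which,
                                 query_bh_chain=query_bh_chain,
                                 query_fh_chain=query_fh_chain)
    angle = priming_angle(query, angle_spec)
    ang_rep = angle_vs_ihm(angle, ref, tolerance=angle_tol)
    ok = (fit.rmsd <= rmsd_tol
          and min(ang_rep.delta_bh, ang_rep.delta_fh) <= angle_tol)
    return IHMCompatReport(
        interface_rmsd=fit.rmsd,
        interface_n_matched=fit.n_matched,
        delta_bh=ang_rep.delta_bh,
        delta_fh=ang_rep.delta_fh,
        fraction_within=ang_rep.fraction_within,
        rmsd_tol=rmsd_tol,
        angle_tol=angle_tol,
        verdict="compatible" if ok else "incompatible",
    )
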