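# Methods

This note documents the models and numerical choices behind `myoconf`, what
the synthetic generator does and does not emulate, and the decisions taken
where the design was genuinely open.

## Structures, numbering, selections

Atom tables use **author residue numbering** throughout; mmCIF
`label_seq_id` is ignored on read. The residue ranges conventional for the
β-cardiac myosin motor (motor domain 1–710, Converter + essential-light-chain
lever arm 711–806, HO-helix 419–445, head–head interface ranges) are author
numbers, so selections written against the literature resolve verbatim.
All such ranges are configuration, never hard-coded; in particular no
helix-turn-helix range ships as a constant, because the conventional
shorthand for it is inconsistent across sources.

Alternate conformations are collapsed on read to the highest-occupancy
conformer, ties broken toward altloc `A`, giving deterministic
single-conformer analytics. Insertion-coded residues keep their codes and
order; hydrogens are kept if present but excluded from Cα selections by
construction (`name CA`).

Selections are conjunctions of `chain` / `resi` / `resname` / `name`
clauses; ranges are inclusive and overlapping ranges select the union. A
selection that matches nothing warns rather than fails, except where an
operation requires non-empty input.

Residue pairing between two structures maps chains by identical id first,
remaining chains by best pairwise sequence-alignment score, then pairs
residues either by identical author number (`by_number`, the default — the
right choice when the two structures are the same protein) or via a global
sequence alignment (`by_alignment`, for homologs).

Multi-model PDB is the baseline trajectory dialect. Frame times default to
frame index × 1 ns, reflecting the nanosecond analysis stride typical for
long explicit-solvent trajectories; the stride is a flag.

## Superposition and outlier rejection

The core is a weighted Kabsch fit: SVD of the weighted covariance, with the
smallest singular direction sign-flipped when needed so the result is
always a proper rotation. Weights default to uniform (appropriate for
Cα-only fits); mass weighting is available.

Crystal-structure comparisons are conventionally quoted as an RMSD "over N
of M Cα", which implies outlier rejection. `align_reject` iterates
{fit → reject pairs with post-fit deviation > `sigma_cutoff` × RMS
deviation → refit} up to `cycles` times (defaults 5 cycles, cutoff 2.0,
both flags). The rejection statistic is deliberately the RMS deviation
rather than the standard deviation of the deviation magnitudes: deviation
magnitudes of well-fit pairs follow a Maxwell-like distribution whose mean
exceeds twice its spread, so a threshold of 2 × std would reject the bulk
of perfectly ordinary pairs and cascade to collapse on Gaussian-noise
inputs, whereas 2 × RMSD matches the rejection rule familiar from
structure-viewer alignment and is stable. A per-cycle RMS below 1e-10 Å is
treated as an exact match and stops rejection (numerical noise is not a
population of outliers). If rejection ever leaves fewer than three pairs,
the run fails with advice to raise the cutoff.

Trajectory RMSD series fit every frame onto a reference frame (the first,
by default) over a *fit* selection and then measure, without refitting,
over a *measure* selection — so fitting on the motor domain and measuring
over the lever arm isolates lever motion relative to the motor.

## Observables

- **Rg** is mass-weighted by element masses by default (the convention of
  the common trajectory-analysis tools); a uniform-weight flag covers
  Cα-only inputs.
- **Lever angles** are vertex angles over three Cα anchors, reported in
  degrees in [0, 180]. The two standard triplets place the vertex at the
  lever base (C705) with the lever tip (K803) and a motor-domain reference
  (M90 or, in the second plane, K103/M659) as arms. For the kinked
  blocked-head lever of the sequestered state the tip anchor is replaced by
  the last pre-kink residue (L781).
- **Salt bridges** report the minimum distance between the basic residue's
  side-chain nitrogens (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) and the acidic
  residue's carboxylate oxygens (Asp OD1/OD2, Glu OE1/OE2), plus a derived
  `formed` flag at a configurable cutoff (default 4.0 Å). The raw distance
  is always reported; the flag is a convenience.
- **χ1 dihedrals** use the standard N–CA–CB–CG convention (sign checked
  against an independent trajectory-analysis library), classified into
  rotamer wells g− (−120°, 0], g+ (0°, 120°] and t (elsewhere); flip
  detection reports the first frame whose well differs from its
  predecessor's. Well boundaries are configurable.

All observables are invariant under global rigid motion of each frame to
1e-9 (tested).

## Free-energy landscapes

Densities are plain 2D histograms: default 32 × 32 bins, edges spanning the
data range padded by 2 % per side (degenerate ranges are widened so
single-valued series still bin). Probability mass is normalized to 1.
Boltzmann inversion gives G = −RT·ln(p/p_max) in kJ/mol with
R = 8.314 × 10⁻³ kJ·mol⁻¹·K⁻¹; the most populated bin is 0 by construction
and unoccupied bins are NaN (`undefined` in exports), never a numeric
sentinel, to avoid false minima. The landscape temperature defaults to
310.15 K, the thermostat temperature typical for physiological-condition
simulations; the affinity module independently defaults to 298.15 K (25 °C)
because contact-based ΔG predictors are calibrated at room temperature.
Both are flags and both are logged. Histogram counts enter only as ratios,
so uniform rescaling of sample weights leaves G unchanged (tested).

Basin comparison sums probability mass over two disjoint bin regions and
reports −RT·ln(p_a/p_b); empty regions are an error, not a silent zero.

## Contacts and determinants

Contact typing is geometric and hydrogen-free, since the target structures
(~2–3 Å crystallography) lack hydrogens: a polar contact is a ligand N/O/S
atom within the polar cutoff of a protein donor/acceptor atom (backbone
N/O of any residue, plus a residue dictionary of side-chain N/O/S atoms);
an apolar contact is a C–C pair within the apolar cutoff. Defaults (3.5 /
3.9 Å) follow the conventions of the standard ligand-interaction schematic
tools; both are flags and are recorded in every profile, and profiles
computed at different cutoffs refuse to be compared. π-stacking and halogen
bonds are not typed. Detection is an exhaustive distance-matrix scan —
exact by construction and fast enough at crystal-structure sizes; tests pin
it to an independent O(n²) per-pair oracle.

Determinant mapping projects pocket residue numbers onto ungapped positions
of a reference sequence in a user-supplied FASTA MSA (`ref_start` gives the
author number of the reference's first residue) and reports each homolog's
aligned identity plus a conserved flag. Residues outside the alignment are
flagged unmappable, not fatal.

## Affinity

ΔG = RT·ln(K_D) with R = 8.314 J·mol⁻¹·K⁻¹ at the 1 M standard state;
conversion and inverse round-trip exactly. Per-frame binding free energies
come from a linear model over typed contact counts,
ΔG = intercept + Σ coef_class × count_class — the functional form of
contact-count affinity predictors. The coefficients are user configuration
loaded from a JSON file, deliberately not baked in: the package makes no
claim to reproduce any particular trained predictor, and the test suite is
independent of coefficient values. Frames with zero contacts are flagged
unbound, get no K_D, and are excluded from the mean. The summary statistic
is the arithmetic mean of per-frame K_D (matching the convention of
averaging K_D rather than ΔG); a ΔG-averaged summary is also exposed, since
the two differ under Jensen's inequality.

## IHM compatibility

The reference sequestered-state structure supplies both the interface
geometry and the lever-angle standards. Blocked-head/free-head reference
angles are *measured from the reference structure at load time* (with the
pre-kink L781 substitution for the blocked head) rather than hard-coded,
because no printed values exist for them. The interface fit is a plain
Kabsch over Cα of the configured ranges, matched by author number; range
residues missing from the query are dropped and counted, which is why a
matched count can fall below the nominal range size. The verdict —
compatible iff interface RMSD ≤ 1.5 Å and the smaller of the two angle
deltas ≤ 10° (both flags) — is labeled heuristic in every report and is
monotone in both tolerances. Angle-tolerance comparisons use closed
intervals: a frame exactly at the tolerance counts as within.

## Synthetic generator

The generator emulates the *geometry* of the analyses' inputs, not their
physics: a rigid motor blob (150 residues on a deterministic quasi-uniform
sphere of radius 18 Å, four backbone atoms per residue at fixed local
offsets) joined at a hinge (residue 705, at the origin) to an ideal
α-helical lever (residues 706–806, rise 1.5 Å, 100°/residue, helix radius
2.3 Å). Three designated anchor residues — the analogs of M90, C705 and
K803 — are placed exactly on the hinge plane and lever axis, so the anchor
vertex angle equals the hinge angle *exactly*, and a rigid in-plane hinge
rotation changes it by exactly the scheduled amount. This idealization is
what makes schedule-recovery tests exact at σ = 0; real side-chain anchors
carry no such guarantee.

Trajectories rotate the lever rigidly per an angle schedule and then add
i.i.d. isotropic Gaussian noise (default σ = 0.5 Å, roughly thermal-factor
scale) to every atom; noise streams are spawned per frame from a single
root seed, so outputs are bit-identical for identical (spec, seed) and the
seed changes noise realizations only, never topology. The default schedule
is a triangular sweep covering exactly 36° above the resting angle — the
swing amplitude characteristic of the drug-free motor — and the resting
angle defaults to 78°, the primed lever angle of the drug-bound states
(the drug-free crystal value is ~69°). The two-state mixture defaults to
populations 0.7/0.3 over angles 78°/114° (the same 36° separation), drawn
i.i.d. per frame with ground-truth labels stored.

Ligand complexes place one ligand atom per planned contact at *exactly* the
planned distance from the named protein atom (backbone O for polar plants,
Cα for apolar), choosing among a fixed set of candidate directions the one
maximizing clearance from every atom that could form a same-class contact,
and requiring that clearance to exceed max(4.0 Å, planned distance). Plans
whose targets are too buried fail loudly rather than plant incidental
contacts. This guarantees the planted pairs are the *only* contacts at
default-scale cutoffs (≤ ~4 Å); it is not a pose generator.

What the generator does **not** emulate: force fields, solvent, thermal
correlation between frames (noise is white), realistic side chains, B
factors, or crystal packing. Tests passing on synthetic data therefore
validate the *analytics* — geometry, statistics, bookkeeping — not any
claim about real myosin dynamics.

## Problem sizes and determinism

The default test and acceptance runs use the synthetic model (~1000 atoms),
trajectories of 30–200 frames for geometric checks, and 10⁴ frames for the
two-state free-energy recovery, which lands the statistical checks at a
3-standard-error resolution of ~0.17 kJ/mol; these sizes make the full
suite run in well under a minute while leaving the Monte-Carlo bands
meaningful. Every stochastic test fixes its seed; hypothesis-based property
tests are derandomized. The acceptance script derives all sub-seeds from
its single `--seed` argument.

## Known limitations

- The three published-number checks require the deposited structures and
  therefore network access once; they fail (with instructions) when the
  files are absent rather than silently passing.
- Rejection-parameter choices (cycles, cutoff) behind published
  "N of M Cα" subsets are not standardized; reproduction bands are
  correspondingly tolerant (±0.05 Å, ±5 % of the matched count).
- `by_alignment` pairing uses a fixed, reasonable scoring scheme
  (match 2 / mismatch −1 / gap −5/−0.5); it is not tuned for remote
  homology.
- Binary trajectory formats are not read; convert to multi-model PDB
  upstream. The Trajectory contract is format-agnostic, so a binary reader
  can be added behind it without touching the analyses.
- The IHM verdict is a screening heuristic over two numbers; it does not
  score clashes or interface energetics.
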