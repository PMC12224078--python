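# Methods

This note documents the models, numerical choices and limitations behind
`mrensemble`, in the order the analysis chain uses them.

## Coordinate models and consensus sets

Structures are ordered lists of heavy atoms keyed by
`(chain, author residue number, PDB v3 atom name)`.  Author numbering is
authoritative throughout — residue ranges and per-residue exclusions are
expressed in it, and no renumbering ever happens.  Hydrogens are dropped
on read (a `keep_hydrogens` flag restores them); alternate locations
other than blank/'A' are rejected rather than silently collapsed, because
every downstream comparison assumes single-conformer models.

A *consensus set* is the intersection of atom keys over an ensemble,
optionally restricted to a residue range, minus explicit exclusion rules
of the form (residue name or number, atom name).  Waters and common
co-solvent molecules are excluded by default.  The canonical rule set
shipped as `DEFAULT_CONSENSUS_RULES` removes arginine Nη1/Nη2, tyrosine Oη
and the ζ-nitrogens of lysines 29 and 56 — atom classes whose positions
are weakly determined at ~2 Å (terminal atoms of long, often disordered
side chains) or absent from some predictors' output.  The ordering of a
consensus set is deterministic (chain, residue, canonical atom-name
order), so it is invariant to model order.

## Search-model preparation

Confidence trimming handles two score kinds.  pLDDT (0–100, higher =
better): atoms *below* the threshold are removed, at atom granularity by
default, since predictors typically lose confidence on single side-chain
tips.  Estimated coordinate error in Å (lower = better): atoms *above*
the threshold are removed at residue granularity by default, matching the
typical removal of whole low-confidence termini.  Both granularities are
exposed for both kinds, since upstream tools differ on this point.

B-factor protocols:

- **constant** — one value everywhere (default 20 Å²; the choice is
  immaterial to downstream likelihood scoring).
- **asa_based** — `B = 5 + 25·(ASA / ASA_iso)` where `ASA_iso =
  4π(r_vdw + 1.4)²` is the atom's own isolated-sphere area.  Only the
  monotonicity of this map is scientifically meaningful; the affine
  constants are a documented, replaceable convention.
- **confidence_based** — pLDDT is mapped to a coordinate error
  `err = 1.5·exp(4·(0.7 − pLDDT/100))` clamped to [0.1, 10] Å, then
  `B = (8π²/3)·err²` (the isotropic ADP equivalent of an isotropic
  Gaussian positional error).  The exponential map is a minimal monotone
  default anchored at err(70) = 1.5 Å; it is deliberately pluggable, as
  published pLDDT→error calibrations differ.

Solvent accessibility uses Shrake–Rupley point sampling with a Fibonacci
sphere (default 960 points, probe 1.4 Å) and a fixed van der Waals radius
table (C 1.70, N 1.55, O 1.52, S 1.80 Å…).  The implementation was
validated against closed forms: a free atom reproduces 4π(r+1.4)² and a
two-sphere system the analytic spherical-cap area, both to <2%; doubling
the point count moves no atom by more than 1% of its full-sphere area.

## Superposition and comparison metrics

Rigid superposition is the SVD form of the Kabsch solution with the
determinant correction that forbids reflections; degenerate (collinear or
coincident) selections are rejected.  The unit tests cross-check it
against an independent quaternion-grid + simplex-polish minimizer to
1e-6 Å.

GDT-HA uses thresholds {0.5, 1, 2, 4} Å on Cα atoms by default.  The
superposition search is approximated by seeding a Kabsch fit from **every
contiguous fragment of ≥3 selected atoms** and keeping, per threshold,
the best fraction over all seeds.  This is not the full LGA algorithm;
for the near-identical structures this package targets the difference is
immaterial, and the approximation is exactly reproducible.

lDDT is superposition-free: over all pairs of selected atoms from
different residues with reference distance < 15 Å, the score is the mean
over thresholds {0.5, 1, 2, 4} Å of the fraction of pairs whose distance
change stays below the threshold.  It is computed on all non-hydrogen
atoms of the selection (not Cα only), with same-residue pairs excluded.

RMSD values are reported to 2 decimals in CSV outputs and kept at full
precision internally.

## Ensemble PCA

Models are flattened to 3N-vectors over the consensus selection after
Kabsch pre-alignment to the first model (exposed as a flag; without
alignment, rigid-body motion contaminates the internal modes).  The SVD
of the centered m×3N matrix gives ≤ m−1 components; eigenvalues use the
1/(m−1) normalization so their sum equals the total centered variance,
and scores preserve pairwise 3N distances exactly.  Component signs are
fixed by making each component's largest-magnitude element positive.
PCA is unweighted (no masses).  Displacement structures are the mean plus
`amplitude × component`, mapped back onto the template atom records.

## Rotamer classification

χ angles follow the IUPAC definitions (Glu: χ1 N-CA-CB-CG, χ2
CA-CB-CG-CD, χ3 CB-CG-CD-OE1), reported in (−180°, 180°]; a missing
defining atom yields an explicit undefined value, never a silent zero.

States are assigned by binning χ1 and χ2 into p (0°..120°), t (|χ|>120°)
and m (−120°..0°) — idealized centers +65°, 180°, −65° — and selecting,
among the canonical states of that bin pair, the one with the nearest
terminal χ on the circle.  The glutamate table carries the eight named
states tt 0°, mm-40°, mt-10°, pm0°, tm-20°, pt-20°, tp10° and mp0°
(every bin combination except pp); a bin pair with no named state falls
back to the globally nearest state and is flagged.  Because the
carboxylate is two-fold symmetric, glutamate/aspartate terminal χ is
compared modulo 180°.  The canonical table uses idealized bin centers
rather than library modal angles; nearest-bin classification is
insensitive to this distinction, and the table is user-replaceable.

Torus histograms bin (χ1, χ2) on [0°, 360°)² after periodic wrapping and
normalize to unit integral (density per square degree), so mass is
conserved under any bin count.

## Structure factors and R factors

Direct summation over atoms and symmetry operators:

    F(hkl) = Σ_ops Σ_atoms occ · f_el(s) · exp(−B·s²/4) · exp(2πi·h·(R·x + t)),

with s = 1/d from the reciprocal metric tensor and 4-Gaussian
international-tables X-ray form factors (taken from gemmi's coefficient
table).  Reflections are enumerated over the full index box and reduced
to one Friedel mate (first nonzero index positive); there is no
asymmetric-unit reduction of atoms — symmetry is handled by summing over
operators, which is simple and fast enough at mini-protein scale
(vectorized over reflections, chunked at 8192 to bound memory).
F(000) is excluded.  Friedel symmetry holds to machine precision and
screw-axis absences emerge from the operator sum rather than from rules.

Ensemble averaging is performed on **complex** structure factors, per
reflection, with non-negative weights summing to 1 — this is the physical
model of a crystal whose unit cells contain a conformer mixture, and it
retains interference between conformer contributions (the amplitude of
the average is strictly below the average amplitude wherever phases
differ).

Scaling and R: `k = Σ|Fo||Fc| / Σ|Fc|²` minimizes the working-set squared
amplitude residual in closed form; R is computed separately on working
and free reflections with k fit on the working set only.  Free flags are
a seeded Bernoulli selection (default 5%).  Two-conformer population
fitting is a grid search (default step 0.01) over the weight of the first
conformer, minimizing R_work of the ensemble average.

Out of scope by design: bulk-solvent correction, anisotropic scaling,
twinning, σA/likelihood weighting, map synthesis, refinement, and the MR
search itself.  Consequently absolute R values from this engine are not
comparable to deposited refinement statistics; all conclusions are drawn
from *differences* between models evaluated on the same data.

## The synthetic study system

`make_helix_protein(58)` builds an idealized three-helix bundle from
internal coordinates (NeRF chain construction): helices at
(φ, ψ) = (−57°, −47°), ideal bond lengths/angles, side chains built from
a per-residue z-matrix with ideal internal coordinates and common helix
rotamers.  The two inter-helix loops (residues 21–24 and 42–44) use fixed
torsion sets chosen once, by a one-off geometric optimization, to produce
a compact antiparallel bundle (adjacent helix axes at ~150–160°, centroid
separations 11–13 Å) with no non-bonded contact below 2.9 Å; the values
are frozen in the source.  The default 58-residue sequence places the
residue types the consensus rules and rotamer analysis need at fixed
surface positions (Ser2, Tyr12, Lys29, Arg41, Asn43, Glu46, Arg49, Arg52,
Glu53, Lys56, Arg57), with Glu53 as the dynamic surface glutamate
defaulting to "tt 0°".

Solution ensembles (`make_solution_ensemble`) model the converged
multi-start regime: per-model iid Gaussian coordinate noise (default
σ = 0.07 Å, giving all-atom pairwise RMSD ≈ σ√6 ≈ 0.17 Å, inside the
0.10–0.25 Å band typical of independent solutions at ~2 Å), optional
programmed backbone modes (a sine-windowed outward *loop shift* and a
rigid *helix translation*, with per-model coefficients uniform in
[−amplitude, amplitude]), and per-model side-chain rotamer rebuilds from
a rotamer plan.  Rebuilds that create contacts closer than 2 Å are
flagged with a warning, not rejected.  Everything is bit-reproducible
given (spec, seed).

Simulated observations (`simulate_observed`) take the complex
population-weighted average of per-conformer structure factors as truth
and apply relative Gaussian noise to the amplitudes (noise on amplitudes,
not intensities — a simplification).  The canonical two-conformer pair
(`rotamer_flipped_conformers`) differs at three surface side chains —
Glu53 (tt 0° → mm-40°), Lys29 (χ1 m → t) and an Arg49 χ4 flip — matching
the regime where several surface side chains are solved in different
rotamers; with a single flipped side chain the model-error signal would
sit too close to a 5% noise floor to be cleanly separable.

What the generator does *not* emulate: crystal packing and lattice
contacts, bulk solvent and disordered solvent channels, twinning,
resolution-dependent noise, radiation damage, or realistic thermal-motion
correlations.  Tests passing on this system therefore demonstrate the
internal consistency and the mixture-recovery logic of the method, not
its performance on real diffraction data.

## Problem sizes and tolerances

The standard analyses run on the 58-residue system (~450 atoms, P1 box
with 5 Å padding, ≈ 17 000 Friedel-unique reflections to 2.1 Å); each
structure-factor evaluation takes ~1 s and the full acceptance pipeline
well under a minute.  Oracle agreements asserted in the tests: Kabsch vs
quaternion search ≤ 1e-6 Å (unit) / 1e-4 Å (acceptance); direct sum vs
naive double loop ≤ 1e-10 relative; Friedel symmetry ≤ 1e-10 relative;
PCA trace identity ≤ 1e-8; torus-histogram normalization ≤ 1e-9.
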