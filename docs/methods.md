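# Methods

## Scope and model

The package analyses receptor–ligand trajectories of a class-A GPCR bound
to a zwitterionic morphinan agonist (protonated ring amine, secondary
amine, carboxylate, phenol). It covers four computations: per-frame
geometric interaction fingerprints aggregated into occurrence-frequency
tables across replicates; interaction-distance quality profiles; rescoring
and ranking of externally generated docking poses against a reference
interaction pattern; and activation-state classification from the TM6
deflection. A synthetic generator supplies systems with known ground truth
so each stage has exact expected values.

## Geometric interaction criteria

Published dynophore tables rarely state the geometric definitions used by
the underlying pharmacophore software, so the detectors here use explicit,
configurable stand-ins drawn from common pharmacophore-toolkit
conventions (`GeometricCriteria`, all boundaries inclusive):

| detector | criterion | default |
|---|---|---|
| ionic | min heavy-atom distance between charged groups | ≤ 4.5 Å |
| hydrogen bond | donor–acceptor heavy-atom distance; angle | ≤ 3.5 Å; ≥ 130° |
| water bridge | both H-bond legs to the *same* water, same frame | legs ≤ 3.5 Å |
| hydrophobic | min apolar (C/S) distance | ≤ 4.5 Å |
| cation–π | cation–ring-centroid distance; offset from ring normal | ≤ 6.0 Å; ≤ 30° |
| clash | vdW-radius-sum minus distance | ≥ 0.4 Å |

The hydrogen-bond angle is measured at the donor hydrogen when hydrogens
exist; otherwise a heavy-atom surrogate (root–donor–acceptor) is used,
since production trajectories frequently strip hydrogens. When neither is
available (e.g. water legs) the criterion is distance-only. Ring normals
come from an SVD plane fit; rings whose RMS out-of-plane deviation exceeds
0.3 Å are rejected. Charged groups for standard residues are the
formally charged side-chain atoms (Asp OD1/OD2/CG, Glu OE1/OE2/CD, Lys NZ,
Arg guanidinium). These defaults are stand-ins, not reconstructions of any
particular toolkit's internals; every cutoff is exposed in the YAML
criteria block.

## Occurrence statistics

A frame counts as positive for a monitored row when at least one event of
that row's kind occurs — no multiplicity weighting, matching
percentage-of-trajectory semantics. Frequencies are per replicate;
the headline number is the unweighted arithmetic mean over replicates
(replicates share `n_frames` by design; a pooled-frames mode exists behind
a flag for unequal lengths). Distance profiles are single-atom-pair
Euclidean distances per frame summarised by linear-interpolation quartiles
(min, Q1, median, Q3, max); outputs round percentages to one decimal while
full precision is retained internally.

## Pose rescoring

The score of a pose is the unweighted count of matched reference entries:
the published procedure rescued poses by presence/absence of listed
interactions, not by magnitudes, and the tie granularity of that count is
an explicit stand-in where the original rule was unstated. Water-bridge
entries match against *any* retained water, because reference tables list
waters without stable identity. The 5.5 Å amine-N–D3.32-γC constraint is
inclusive; ranking sorts by descending score, then ascending constraint
distance, then pose id (total, deterministic order). An inactive-state
fingerprint (a PI entry plus hydrophobic entries) is expressed as just
another `ReferenceFingerprint`, not special-cased.

## Activation-state metric

The TM6 deflection is the distance between residues 6.31 (bottom of TM6)
and 4.40 (bottom of TM4). The measured atom is Cα by default — the
standard choice for GPCR activation metrics — with the backbone carbonyl C
available behind `measure_atom="C"` because source descriptions vary
between the two. Active/inactive reference distances are user inputs
measured from the appropriate active- and inactive-state crystal
structures; the package never downloads structures. The default tolerance
is 0 Å: the open interval between the references is `intermediate`, and
frames exactly at a reference belong to the end states. Fractions are
pooled over replicates, matching single-percentage reporting. If a user
supplies references in the wrong order the classifier swaps them with a
logged warning, since outward TM6 movement always increases the distance.

## Synthetic generator

`generate_template` builds a toy 7-helix scaffold: seven straight Cα
traces (40 residues each, 11 Å circle radius, 1.4 Å per-residue rise)
with hand-placed side chains for the named residues — D3.32, Y3.33,
K5.39 (side-chain NZ plus the backbone carbonyl O that coordinates the
bridging water), the variable 6.58 position rendered as Lys, Trp or Glu,
the 6.31/4.40 deflection anchors, an N-terminal aspartate and ECL2/ECL3
charged residues — a four-feature ligand in the pocket, and two optional
water sites. Atom order is canonicalised (chain, residue) so PDB output,
CSV frames and the in-memory table agree atom-for-atom.

`render_trajectory` keeps the ligand fixed and moves each scheduled
receptor side-chain tip along its own axis (ligand-group centroid through
the residue's home position): the key charged atom is placed exactly
`bound_dist` (mask true) or `unbound_dist` (mask false) from the nearest
ligand-group atom, secondary group atoms are offset perpendicular to the
axis, so the minimum inter-group distance equals the scheduled distance
exactly at zero noise (the axes point outward, making the anchor atom the
projection maximum). Receptor–receptor rows (the TM5–TM6 bridge) are
placed after ligand rows, relative to the partner's current position.
Water-bridge rows move the water oxygen onto the two-sphere intersection
point with 2.8 Å legs (bound) or 12 Å away (unbound). Per-frame TM6
deflection is set by moving the 6.31 anchor along the 6.31–4.40 axis to
the state target.

Schedules: `exact` mode places `floor(p·n + 0.5)` positive frames (round
half up, so occupancies printed to three decimals are hit exactly at
n = 1000) at seeded-shuffled positions; `bernoulli` mode draws i.i.d.
The spec validator enforces the separation invariant
`bound + 3σ < cutoff < unbound − 3σ` per scheduled row (and its analogue
for deflection targets), so Gaussian jitter cannot flip a scheduled frame.
Defaults: 1000 frames per replicate at a 100 ps recording interval, five
replicates (replicate *r* uses seed + *r*), noise σ = 0.05 Å, bound 3.0 Å,
unbound 8.0 Å, toy deflection references 12.0/8.0 Å with state targets
12.5/10.0/7.5 Å. The receptor condition factories (`mor_spec`,
`dor_spec`, `kor_spec`) carry the published occupancies and state
fractions as their schedules, with the correct 6.58 variant (K/W/E) and
receptor-specific auxiliary contacts (N-terminal aspartate at MOR,
ECL3 arginine at DOR, ECL2 lysine/glutamate and the TM5–TM6 bridge at
KOR); remaining state mass sits in the active-like band since the
inactive-like fraction was not reported separately.

What the generator does **not** emulate: force-field physics, membrane and
solvent, correlated motions, rotamer realism, conformational kinetics, or
real morphinan geometry. Passing recovery tests therefore demonstrates
that the *analysis layer* is correct and exactly calibrated — not that the
detectors would reproduce any particular published table from real MD
coordinates, for which the original geometric definitions are unknown.

## Numerical and design choices

* Round half up via `floor(p·n + 0.5)`; double rounding artefacts are
  irrelevant at the three-decimal occupancies used.
* Quantiles: numpy linear interpolation; the dashed quantile lines in
  violin-style figures are taken to be quartiles.
* BW labels are constant offsets from x.50 anchors; intra-TM insertions/
  deletions are unsupported (class-A convention).
* Sequence identity/similarity: one optimal global alignment
  (Biopython PairwiseAligner, BLOSUM62, gap open 10 / extend 0.5 by
  default); identity counts identical pairs over non-gap columns,
  similarity additionally counts substitution scores > 0. The similarity
  rule and matrix are configurable because source methods are typically
  unstated. The position-3.33 tyrosine of the NOP receptor is numbered
  inconsistently across sources (130 vs 131); the residue number is
  user-supplied configuration, never hard-coded.
* Degenerate inputs fail loudly: empty groups, non-planar rings, unknown
  elements, non-finite coordinates and inconsistent specs raise typed
  errors listing the offending item.

## Problem sizes

Tests and the acceptance script run the generator at the study scale —
5 replicates × 1000 frames for frequency tables, 1000-frame single
trajectories for occupancy and state recovery — which completes in a few
seconds; unit tests use 40–300-frame renders where full scale adds
nothing.

## Known limitations

Water-bridge detection considers single-water bridges only (no two-water
chains). Hydrophobic detection treats all C/S atoms as apolar without
hybridisation checks. The pose evaluator assumes the pose shares the
receptor topology used to resolve the fingerprint. The scheduler cannot
drive cation–π rows (no charged-group definition for aromatic rings);
cation–π occupancy on synthetic systems is only meaningful as a negative
control.
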