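# Methods

## The census model

The package treats each protein fold (CATH topology, the C.A.T level) as a
population of experimentally resolved domain instances and asks how that
population distributes around a single predicted reference conformation.
The unit of measurement is the CA-RMSD between one experimental instance
and its reference counterpart after optimal rigid superposition; the unit
of reporting is the fold, summarized by robust statistics of its RMSD
distribution. The key modelling assumptions are:

- **Residue correspondence by sequence, not structure.** Instances are
  mapped to the full-length reference by a glocal pairwise alignment
  (global in the domain, free end gaps in the protein; BLOSUM62, affine
  gap cost `open + k·extend` with open 10 and extend 0.2; `X` scores 0
  against everything). Only matched columns whose reference residue has a
  CA atom enter the superposition, so unresolved experimental residues and
  reference gaps are handled by intersection rather than imputation.
- **Rigid-body comparison.** The Kabsch superposition is computed once over
  the full mapped core; region RMSDs are read off under that fixed frame
  without refitting, so a region that swings away keeps its full
  displacement (an open switch can legitimately reach many Å). A refit
  mode exists but is not the default.
- **CA-only deviations.** RMSD uses CA atoms only: robust to side-chain
  noise and sufficient for fold-level claims; backbone mode is available.
- **Robust aggregation.** Per fold: median, MAD scaled by 1.4826 (the
  normal-consistency constant, making MAD a robust standard deviation),
  IQR, min/max, and tier fractions at 2.5/5.0 Å. Aggregation weights
  instances equally by default; a sub-cluster-median mode damps
  over-represented near-duplicate structures.

## Curation

Instances enter the census only if: their protein has at least 10 distinct
source structures; the domain has more than 10 residues; percent identity
to the reference is ≥ 99 (computed over matched columns only, gaps
ignored); resolution, where known, is ≤ 3 Å; and neither terminus is
"extended" — flagged when all `terminus_window` (default 5) mapped residues
at an end deviate by more than `terminus_dev` (default 5 Å) after
superposition on the remaining core. The exact published form of the
terminus rule is not available, so this conservative stand-in is exposed in
`CurationConfig`; it only flags gross arms, and a rigid-body copy of the
reference can never be flagged. Rejections carry exactly one primary
reason, evaluated in the fixed order counts → length → PID → resolution →
termini, so curation reports are reproducible. Predicted models pass a
separate confidence filter (≥ 90% of residues with pLDDT > 80) which gates
only the secondary-structure comparison, not the RMSD census.

## Geometry and secondary structure

SASA is a deterministic Shrake–Rupley: 960 golden-spiral points per heavy
atom at radius vdW + 1.4 Å, a point being accessible when outside every
neighbour's expanded sphere (coincident spheres are counted once via an
index tie-break). Volume is the union of vdW spheres by voxel counting at
a 0.5 Å grid with first-order surface antialiasing (each voxel carries the
maximum over spheres of `clip((r−d)/grid + ½, 0, 1)`), accurate to ~2% on
single spheres at the default grid. A residue is buried when its SASA is
below 0.25 of the Tien et al. theoretical maximum for its residue type.
Metals are identified by element against a fixed list; any non-water
hetero group that is not a metal counts as ligand; water is excluded
everywhere. Secondary structure uses the Kabsch–Sander electrostatic
hydrogen-bond energy (amide H placed 1.01 Å from N opposite the preceding
carbonyl; bond when E < −0.5 kcal/mol): helix from pairs of consecutive
i→i+4 turns, sheet from parallel/antiparallel bridge patterns with
single-residue strands suppressed, everything else coil.

## Grouping

Sequences cluster greedily at 95% identity (CD-HIT-style: length-sorted,
join the first cluster whose representative matches at ≥ threshold;
identity = identical matched columns / shorter length, computed as an LCS).
Within a cluster, members split into sub-clusters first by topology code,
then by single-linkage on resolved-window overlap (link when the mutual
overlap covers ≥ 0.9 of the shorter window). This reproduces the two
motivating cases exactly: one region annotated to several topologies gives
one sub-cluster per topology, and differently resolved windows of one
topology give separate sub-clusters. Both thresholds are configurable; the
linkage choice is the package's own, made for order independence.

## Downstream analyses

The two-region analysis computes, per conformer, the RMSD of two named
residue windows (reference numbering) under the whole-domain superposition,
then clusters conformers in that 2D plane with Ward/Euclidean agglomerative
clustering; with automatic k the silhouette over k = 2..min(10, n−1)
decides, coincident points collapse to k = 1, and labels are renumbered by
ascending cluster mean so they are permutation invariant. Enrichment
compares proteins owning a fold group with median RMSD > 2.5 Å
("heterogeneous"; a protein with both a rigid and a flexible domain counts
here) against proteins owning a group from the lowest decile of group
medians (boundary ties included). Each annotation term gets a one-sided
hypergeometric tail in each direction over the universe het ∪ con, plus
Benjamini–Hochberg adjusted values.

## The synthetic-data generator

The generator emulates the *statistical* structure of multi-conformer
studies, not protein physics:

- **Templates** are ideal-geometry backbones (N, CA, C, O, CB) built by
  natural-extension from φ/ψ plans (helix −57/−47, strand −119/113, flat
  sheet −140/135 for the hydrogen-bonded sheet fixture), with deterministic
  sequences drawn from a 14-letter pool (no Gly/Pro edge cases).
- **Ensembles**: each conformer rotates an internal hinge segment about the
  CA–CA axis at the segment start by an angle drawn from N(0, σ), then adds
  iid N(0, noise) displacement to every atom. Defaults: 60-residue domains,
  a 12-residue hinge segment starting at the midpoint, noise 0.1 Å,
  12 conformers. The hinge segment is internal and modest (~20% of the
  domain) so that the fixed majority anchors the superposition and genuine
  hinge motion is never mistaken for an extended terminus by curation — the
  heterogeneity signal and the curation filters stay orthogonal. Loop
  closure at the segment ends is deliberately ignored.
- **References**: `pick_one` deep-copies one seeded-random conformer
  (a predictor locked to a single experimental state — every fold then
  keeps one instance at the thermal floor while its far edge grows with σ);
  `average` takes the per-atom coordinate mean (a hypothetical
  conformational-average predictor — its arm shrinks by ≈ (1 − E[cos θ]),
  so at large σ, top quartile of a 0–30° ramp, it sits measurably off
  every conformer). Mock pLDDT is `clip(90 − 8 · s, 50, 99)` with `s` the
  per-residue CA ensemble spread — purely synthetic, defined only so the
  confidence filter is testable.
- **Studies**: the default σ-ramp study uses ten folds with σ linearly
  spaced over 0–30° and a single template kind, so the hinge lever is
  constant and amplitude is the only varying factor. The switch study
  plants six two-region archetypes at hinge angles 0/8/16°, calibrated so
  the region RMSD levels (≈ 0/2.5/5 Å) fall in the range reported for real
  GTPase switch ensembles, with 1° within-pattern jitter. Annotation tables
  plant a configurable term on every fold with σ ≥ 15°.

What passing tests on these fixtures show: the measurement chain (read →
align → extract → curate → superpose → aggregate → cluster → test) recovers
planted ground truth quantitatively. What they do not show: performance on
real crystallographic artefacts (alternate conformers, crystal contacts,
missing loops beyond simple gaps), real predictor error modes (the
generator's single-state reference cannot overestimate secondary structure
the way real predictors do), or realistic B-factors.

## Numerical choices and degenerate inputs

- RMSD100 is undefined for n ≤ 13 (non-positive denominator) and returned
  as an absent value rather than a negative number.
- Kabsch rejects < 3 points and collinear point sets; reflections are
  corrected to proper rotations.
- The MAD-based amplitude recovery is estimator-noise limited at small
  ensembles: with 12 conformers per fold the sample MAD carries ~30%
  relative error, so rank correlations between planted amplitude and fold
  MAD of ~0.85 are expected at that size; the max-RMSD ranking is tighter.
  Larger ensembles sharpen both.
- Alignment traceback uses the aligner's deterministic canonical path;
  all clustering orderings carry explicit lexicographic tie-breaks, so
  every pipeline output is bit-reproducible for a given config and inputs,
  and each output table carries the config hash (analysis parameters only,
  I/O paths excluded).
- NMR multi-model files contribute their first model; alternate-location
  atoms keep the highest-occupancy copy; nonstandard residues map to `X`
  (retained in coordinates, excluded from identity).

## Known limitations

- No flexible/hinge-aware structural alignment; large motions are measured,
  not decomposed.
- Side chains beyond CB are absent in synthetic fixtures, so absolute
  SASA/volume values on fixtures are not comparable to full-atom
  structures (ratios and trends are).
- Annotation terms are taken as given — no ontology traversal or
  propagation.
- The enrichment analysis is underpowered at desk-scale studies (tens of
  proteins); the planted-term recovery demonstrates correctness of the
  tail computation, not statistical power.
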