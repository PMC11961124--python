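# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `redoxstruct`, module by module. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model and parsing

Coordinates (PDB or mmCIF, parsed through gemmi) are held as
model → chain → residue → atom with author residue numbering. Three
normalizations happen at parse time:

* **Hydrogens are dropped.** The crystal structures this package targets
  (~3 Å resolution) contain none, and accessible surface area is defined
  over heavy atoms.
* **Alternate locations are resolved** to the highest-occupancy conformer;
  ties keep the first record in the file. A `first` policy is available.
* **Non-amino-acid residues go to `solvent`** (waters, ions, ligands).
  Polymer censuses therefore never count solvent, while a catalytic-pocket
  water or a bound substrate stays addressable by residue number
  (`select_atom("A:401:O")`, ligand ids like `B:401:FBP`).

PDB writing is hand-rolled with fixed column widths (3-decimal coordinates,
2-decimal b-factors), so parse→write→parse preserves the census exactly and
coordinates to 5·10⁻⁴ Å. Multi-model PDB is the trajectory carrier; the
format has no time axis, so frame stamps come from the caller (uniform
spacing over a stated duration, in µs). Chromatograms are two-column
delimited text; the volume axis must be strictly increasing.

## Superposition and RMSD

The Kabsch SVD solution with the determinant correction guarantees a proper
rotation (never a reflection). Near-collinear point sets leave a rotation
degree of freedom unconstrained; the fit is still returned, flagged
`degenerate`.

Published cross-structure RMSDs of the kind this package reproduces are
protocol-sensitive (atom selection, pairing, outlier rejection differ
between tools and are rarely stated). The default protocol is: CA atoms
only, residue pairing by global sequence alignment (biopython
`PairwiseAligner`, match 2 / mismatch −1 / open −5 / extend −0.5 — any
sensible scheme pairs near-identical chains identically), iterative
rejection of pairs with residual > 2·RMSD of the current fit, at most 5
cycles. Both the trimmed RMSD and the all-pair RMSD under the final motion
are reported, so no comparison hinges on the trim. Superposition RMSD is
invariant under rigid pre-motion of either input (property-tested to
10⁻⁹ Å).

Radius of gyration is √(Σwᵢ|rᵢ−r̄|²/Σwᵢ), mass-weighted by default
(standard atomic masses), uniform weighting available for comparison with
geometric oracles.

## Accessible surface area

Shrake–Rupley with a deterministic golden-spiral lattice: for a fixed point
count the lattice is fixed, so results are exactly reproducible and
independent of any random state. Defaults: probe 1.4 Å, 960 points/atom
(doubling the count moves totals by <0.5 % on test fixtures; the quality
floor rejects counts below 100). Van der Waals radii follow a
NACCESS-style table (C 1.70, N 1.55, O 1.52, S 1.80 Å), swappable per
call; an element missing from the table is an error, not a silent default.

Exposure classification is a strict threshold on a scoped area (SG atom,
side chain, or whole residue). The SG scope with a 0.05 Å² threshold is
the default: solution titrations report thiols with areas well under 1 Å²
as reactive, so any resolvable nonzero SG area counts as exposed. For
interface-forming proteins the classification context matters: computing
the table on the biological dimer (partner chain present) matches what a
titration of the native protein sees; single-chain mode is available.

## Cysteine redox census

Disulfides: SG–SG pairs within 2.3 Å (covalent S–S ≈ 2.05 Å plus
coordinate error at ~3 Å resolution), paired greedily nearest-first so each
SG joins at most one bridge. Classes — `disulfide`, `exposed_free`,
`buried_free`, `unresolved` (SG not modeled) — are mutually exclusive and
exhaustive.

Exchange-candidate tiers for free thiols are this package's construction
(the literature describes such pairs qualitatively): *direct* ≤ 5 Å covers
thiol pairs that can exchange with side-chain motion alone;
*rearrangement* ≤ 11 Å covers pairs needing main-chain movement. Both
cutoffs are configurable and every candidate carries its raw distance, so
conclusions survive a different choice of tier boundary.

Titration arithmetic: thiols/monomer = A₄₁₂/(ε·l·c) with
ε(TNB⁻) = 14.15 mM⁻¹cm⁻¹; consistency with the structure-predicted
reactive count (= number of exposed free thiols) uses a measured ± 2·SD
interval. Coupled-assay specific activity is
(ΔA₃₄₀/min)/(ε·l) · V / m in µmol·min⁻¹·mg⁻¹ with ε(NADPH) =
6.22 mM⁻¹cm⁻¹ by default.

## Active-site mapping

The pocket is inherited from a substrate-bound homolog: superpose the holo
chain onto the target (default protocol above), carry the ligand atoms
through the fitted motion, and report every target residue with a heavy
atom within the cutoff (default 4 Å) of any ligand atom. Residue identity
travels through the chain alignment, never through raw numbering, so
homolog numbering offsets cannot corrupt the reported set. Shrinking the
cutoff can only shrink the set (tested), and membership is invariant under
joint rigid motion.

Distances from named residue groups (e.g. phosphosite clusters) to a
reference atom are summarized min/mean/max over CA atoms. The choice of CA
is deliberate: when a published distance does not state its reference atom,
a range over the group is more honest than a single assertable number;
missing residues are reported and excluded.

## Interfaces and assemblies

Buried area follows the PISA convention, ASA_A + ASA_B − ASA_AB (summed
over both chains), computed with identical SASA parameters for the three
terms and clipped at zero against quadrature noise. Assembly inference
thresholds pairwise buried area at 500 Å² — far below a genuine oligomer
interface (thousands of Å²), above incidental crystal-packing contacts —
and labels connected components by size. Raising the threshold can only
split components, never merge them.

## SEC

Calibration fits log₁₀(mass/kDa) against elution volume directly, or
against K_av = (Ve−V0)/(Vc−V0) when both column volumes are given (an
affine change of axis; predictions are identical, but K_av transfers
between columns). A positive slope — larger species eluting later — is
flagged as a warning, not an error.

Deconvolution models the trace as a sum of symmetric Gaussians plus a
constant baseline, solved by bounded least squares (non-negative areas,
positive widths). The baseline is co-fitted by default: a design study
during development showed an estimate-then-fix baseline (moving-average
minimum) biases small-peak areas low by several percent, while the
co-fitted constant is the maximum-likelihood treatment. Peak tailing is
modeled as a second species rather than an asymmetric peak shape, matching
the interpretation of a dimer peak with a monomer shoulder; an
exponentially-modified Gaussian was considered and deferred. Species
repartition uses fitted *areas* (mass-proportional for equal-extinction
species), not heights; percentages are areaᵢ/Σarea·100. Non-convergence is
flagged on the result object, never raised, so a pipeline run always
produces a report.

Sequence-derived quantities: average mass = Σ residue average masses + one
water; ε₂₈₀ = 5500·nTrp + 1490·nTyr, with a cystine variant adding 125 per
oxidized pair. Both ε variants are reported because the redox state of a
purified protein is generally unknown at the spectrophotometer.

## Trajectory analytics

All analyses assume a *core-aligned* trajectory: every frame is superposed
onto frame 0 over core CA atoms, by default every CA outside residues
109–148 (the mobile motif plus its flanking helices), so motif RMSD
measures internal motion, not tumbling. Frame 0 — the crystallographic
starting conformation — is the default RMSD reference.

Change points use binary segmentation on per-residue RMSD series: the split
minimizing the piecewise-constant squared error is accepted when the mean
shift is at least `min_jump` (default 1 Å) with segments of at least
`min_segment` frames (default 5), then recursion on both sides. The method
is deterministic and matches the visual identification of abrupt jumps; a
Bayesian online detector was considered unnecessary. Transition times
across residues cluster into events by a gap rule (`concert_window`,
default 0.5 µs), and an event is *concerted* when its participants are at
least `concert_fraction` (default 0.75) of the series' residues — encoding
"nearly the whole motif moves at once" while tolerating anchored flank
residues.

RMSF is per-atom RMS deviation from the window-mean position, averaged per
residue; for isotropic per-coordinate jitter σ it converges to σ√3 (the
calibration the acceptance script recomputes). Block representatives are
exact medoids under pairwise heavy-atom RMSD within a time window, ties to
the earliest frame; the O(n²) cost is acceptable for the block sizes used
(equilibrated tail of a trajectory).

## Synthetic data

The generators produce every input class the pipeline consumes, with the
planted truth echoed in `metadata["truth"]` and bit-identical output for a
given seed (one private `numpy` Generator per call; no global state).

* **Toy structures** are poly-alanine chains on a wide helical curve
  (~3.8 Å CA spacing) with five heavy atoms per residue. Cysteine pairs are
  realized *exactly* at the requested SG–SG distance by placing both SG
  atoms on the CA–CA axis; when the base curve holds the two CA atoms too
  far apart, the intervening residues are re-laid on a hairpin arc first —
  the natural geometry of a loop-closing disulfide. Buried thiols are
  realized by a 40-atom carbon cage at 3 Å around the SG. The geometry is
  plausible but not physically minimized, and a folded hairpin leaves a
  discontinuity where the chain rejoins the base curve: adequate for
  geometry/accessibility/classification code paths, not for force-field
  work.
* **Homolog pairs** apply a rigid motion plus i.i.d. Gaussian coordinate
  noise; the truth records the planted motion and the realized
  optimal-superposition RMSD computed at generation time.
* **Loop trajectories** plant an abrupt concerted transition: a 20-residue
  motif (residues 112–131 by default) on a rigid flanking core steps along
  fixed random directions at the transition time (default 6 µs on a
  20 µs-scale clock), with amplitudes graded 3–15 Å across the motif and
  zero at its two anchored flanks, plus isotropic jitter everywhere
  (default σ 0.1 Å). Optional per-frame global rotation/translation
  exercises the core-superposition step.
* **Chromatograms** are sums of Gaussians plus baseline and noise (default
  1 % of the maximum signal). The default composition plants areas in the
  10:53:37 tetramer:dimer:monomer proportion of an oxidized wild-type-like
  mixture, with the monomer as a shoulder one peak-width after the dimer.

What passing synthetic tests does **not** show: correctness against real
crystallographic disorder, radiation damage, alternative conformations
beyond alt-locs, non-Gaussian SEC peak shapes, or force-field-realistic
dynamics. The deposited-entry regression test covers the real-data path
when the public structure archive is reachable.

## Problem sizes in the acceptance script

The acceptance script uses 100 seeded trajectories of 150 frames for
change-point recovery, 50 chromatograms (compositions Dirichlet-sampled
with α = 35·(0.10, 0.53, 0.37) — a spread matching the variability between
measured oligomer repartitions — and every species ≥ 9 % of total area,
the smallest fraction observed in such mixtures), 2000 frames for the RMSF
calibration, 100 random instances for the Kabsch/quaternion agreement, and
a ~2.4·10⁶-sample common-random-number Monte-Carlo oracle for buried area.
These sizes give stable statistics while keeping the full script under a
minute on one CPU.

## Known limitations

* No relative-ASA normalization (Gly-X-Gly reference states) and no
  Lee–Richards slicing variant.
* No crystallographic symmetry expansion: assemblies are inferred within
  the deposited asymmetric unit only.
* No mmCIF writing; no binary trajectory formats (DCD/XTC).
* Sequence alignment assumes globally alignable (orthologous) chains;
  unrelated chains will pair poorly and superposition will report it.
* The SEC model assumes symmetric Gaussian peaks and a constant baseline;
  strongly tailing columns need the two-species interpretation or an
  external baseline estimate (`estimate_baseline` on clean flanks).
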