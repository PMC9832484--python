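# Methods

This note documents the models implemented in `elphase`, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Sequence tools

Block grammars are expanded innermost-first; validation restricts
residues to the 20 canonical letters and repeats to positive integers.
Molecular mass uses **average** (isotope-abundance-weighted) residue
masses from the standard ExPASy table plus one water (18.015 Da),
because intact LC-MS of an expressed construct reports the average
mass.  Monoisotopic masses would be systematically low by ~0.06 % and
are not offered.

Hydropathy profiles use the Kyte–Doolittle scale with a sliding window
(default 9, the classic choice for soluble proteins).  Edge positions
use truncated windows — the mean over the residues actually present —
rather than padding, so terminal scores are real data, just noisier.
Window-1 profiles reduce to the raw per-residue scale values.

## Trajectory featurization

Units are Å, ns, kcal/mol and degrees throughout; atom and residue
indices are 0-based in memory and 1-based on file I/O.

* **Hydrogen bonds** use the geometric criteria of the common MD
  analysis tools: donor–acceptor distance ≤ 3.5 Å and a D–H–A angle
  within 30° of linearity.  The angle convention is stated precisely
  because "D–H–A angle cutoff" is ambiguous: we require the angle at
  the hydrogen between H→D and H→A to be ≥ 150°.  Donor heavy atoms
  without an attached polar hydrogen cannot donate and are skipped with
  a warning.
* **SASA** is Shrake–Rupley with a 1.4 Å water probe and a
  golden-section spiral of test points (default 256 per atom; doubling
  changes totals by < 1 % on test systems).  An isolated atom returns
  exactly 4π(r+p)².  Test points landing exactly on a neighbour's
  surface are assigned to the lower-index atom so coincident duplicate
  atoms jointly expose one sphere, not zero or two.  The
  hydrophobic/hydrophilic partition is residue-level by Kyte–Doolittle
  sign (KD > 0 → hydrophobic); an atom-level partition would need
  per-atom hydrophobicity assignments that are themselves conventions.
* **Hydration shell** waters are those whose oxygen lies within 3.15 Å
  of any backbone atom, each water counted once.
* **Secondary structure** is assigned from backbone hydrogen-bond
  patterns using the Kabsch–Sander electrostatic criterion
  (E < −0.5 kcal/mol; amide H taken explicitly when present, otherwise
  reconstructed along the preceding C=O direction) combined with φ/ψ
  gates: helix needs two consecutive i→i+4 bonds and helical dihedrals,
  sheet needs parallel/antiparallel bridge patterns between residues ≥3
  apart and extended dihedrals, turns are i→i+3/i+4 bonds outside
  helical runs, and everything else (including residues with missing
  backbone atoms, which are flagged) is coil.  This is a DSSP/STRIDE-
  style pattern assigner, not a reimplementation of either program;
  on idealized geometry it recovers helix fractions ≥ 0.8 for a
  12-residue α-helix and pure coil for an isolated extended chain.
  The assigner is pluggable through the descriptor registry.
* **Nonbonded energies** are molecular-mechanics sums: Coulomb
  332.0636·qᵢqⱼ/r and Lennard-Jones ε[(r_min/r)¹² − 2(r_min/r)⁶] with
  arithmetic r_min/2 and geometric ε combination, both multiplied by
  the CHARMM switching function between 10 and 12 Å.  Pairs separated
  by one or two bonds are excluded, as in standard force fields.
  Analysis-time settings deliberately mirror typical simulation
  settings (12/10 Å); PME reciprocal-space contributions are not
  recomputed.
* **Periodicity**: when per-frame box lengths are present the
  minimum-image convention is applied to every pairwise computation
  (implemented with periodic k-d trees); otherwise boundaries are open.
* Neighbor searches use scipy `cKDTree` rather than hand-rolled cell
  lists; correctness is established by exact equality against O(N²)
  brute-force oracles on ≤200-atom systems in the test suite.

### The 27-descriptor registry

The default registry covers seven hydrogen-bond counts (intra-chain
total/backbone/sidechain, chain–solvent total/backbone/sidechain,
chain–hydration-shell), four geometric descriptors (Rg, backbone Rg,
backbone RMSD to the sampling-window start, end-to-end distance), five
SASA terms (total, hydrophobic, hydrophilic, backbone, sidechain), the
hydration-shell water count, four secondary-structure fractions and six
energy terms (electrostatic and vdW for chain–chain, chain–solvent and
chain–shell).  The registry is an ordered list of named entries, so a
user with a different property panel can swap their own in; every
downstream stage is keyed by column name.

Sampling takes one record at start + k·stride (k ≥ 1): a 100–150 ns
window at the default 0.2 ns stride yields exactly 250 records per
replica.  The stride must be commensurate with the frame spacing, and a
trajectory shorter than the sampling start is rejected with the
available span in the message.  Featurization is deterministic: no
randomness enters after the trajectory is fixed.

## Phase-behavior classifier

X is autoscaled (column mean 0, population-sd 1; constant columns are
dropped with a warning and recorded).  PCA is computed by SVD and kept
for exploration; the invariant X = TP′ + E holds to < 1e−8 for any
component count.

PLS-DA is PLS1 by NIPALS: per component, w ∝ X′y normalized, t = Xw,
p = X′t/(t′t), b = y′t/(t′t), then X and y are deflated.  Because the
extraction is sequential, the a-component model is a prefix of the
k-component model, which the component-selection loop exploits (one fit
per fold, nested predictions for all component counts).

**Intercept.**  Predictions are ŷ = ½ + Σₐ bₐ tₐ.  With centered X the
intercept choice affects only this constant.  The usual regression
intercept ȳ is deliberately *not* used: in leave-one-ELP-out folds the
training labels are unbalanced (3:4 or 2:4), and a ȳ intercept drags
every held-out prediction toward the training majority class — on
signal-free data that artifact produces systematically *wrong*
classifications rather than coin flips.  The midpoint of the 0/1 codes
is the natural intercept for a discriminant thresholded at 0.5.

**Aggregation.**  An ELP's continuous prediction is the arithmetic mean
of its row predictions over all replicas and time points.  Mean (rather
than median or vote) keeps the aggregate linear in the row predictions
and makes the confidence-interval arithmetic transparent.

**Component selection.**  The inner loop picks the smallest component
count that classifies the validation ELP correctly, capped at k_max
(default 10, further capped by column count and rank).  If no count
succeeds, the fallback is the count whose validation prediction is
closest to the correct class value, and the fold is flagged.

**Confidence intervals.**  The outer predictions per ELP (n = 7 for an
8-member library) are summarized as mean ± t(0.995, n−1)·s/√n.  An ELP
is "confidently classified" when this interval lies entirely on the
correct side of 0.5.  Exact ties at 0.5 classify as 0.

Folds whose training set contains a single class are skipped with a
warning; an ELP that ends up with no predictions is excluded from the
accuracy denominator (also with a warning) rather than crashing.

## Hydrogel calculations

* Mesh size: ξ = (k_B·T/G′)^{1/3}, k_B = 1.380649×10⁻²³ J/K.  The
  estimate assumes an affine network of flexible chains with thermal
  energy per strand, so it is an effective, not literal, pore size.
* Stokes–Einstein: D₀ = k_B·T/(6πηr), defaults η = 0.692 mPa·s (water
  at 37 °C).  **Temperature convention:** 37 °C is converted as
  310.15 K everywhere.  The 0.15 K matters at the last printed digit of
  D₀ (72.95 → 73.0 μm²/s for r = 4.5 nm; a 310 K convention gives
  72.9); mesh sizes are insensitive at 0.1 nm resolution.
* FRAP: full-scale normalization divides the bleach-ROI trace by the
  whole-field trace (correcting laser drift and acquisition bleaching),
  then rescales so the pre-bleach mean (default: 10 baseline frames) is
  1 and the first post-bleach point is 0, which also defines t = 0.
  The recovery is fitted by unweighted least squares to
  I(t) = A(1 − e^{−kt}) with A ∈ (0, 1.5], k > 0, initialized from the
  late-time plateau and the half-recovery time; standard errors come
  from the fit covariance.  In-gel diffusivity assumes D ∝ k·L² at the
  fixed 37.5 μm bleach size, so only the rate ratio enters:
  D_gel = D₀·k_gel/k_solution.
* Probe bound: a hindered probe of hydrodynamic radius r implies meshes
  below its diameter; the bound is 2·min(hindered radii), and no
  hindered probe yields an explicit null.
* Amide I: the window 1595–1705 cm⁻¹ is normalized to its maximum and
  fitted with five Gaussians (Levenberg–Marquardt) whose centers are
  box-constrained to ±4 cm⁻¹ of 1620, 1645, 1660, 1670 and 1700 cm⁻¹.
  Widths are parameterized as standard deviations, started at window
  width/20 (5.5 cm⁻¹) and bounded positive; band amplitudes are seeded
  from the measured absorbance at each canonical center.  Area
  fractions use the analytic Gaussian areas and sum to 1.  The
  **ordered fraction** is defined as β-sheet (1620) + β-turn (1700),
  since the three central bands pool random coil and helix; the
  definition is a package convention, recorded in the output.
  *Identifiability:* the 1645/1660/1670 bands overlap so strongly that
  their individual areas are not stable under realistic noise — the
  identifiable quantities are the assignment-pooled fractions (β-sheet,
  coil/helix pool, β-turn), which parameter-recovery tests hold to
  within 5 % at 1 % noise.  A fit whose covariance is singular from
  this degeneracy is accepted when its residual is small; only a
  genuinely poor residual raises a non-convergence error.

## Synthetic generators

All generators take an explicit seed and are bit-reproducible.

* **Descriptor datasets** mirror the MD study design: 8 pseudo-ELPs
  (4 per class), 3 replicas × 250 time points, 27 columns named after
  the default registry.  Six columns carry a between-class mean shift
  of Δ = 4 within-class standard deviations; within a replica every
  column is a stationary AR(1) series (ρ = 0.5) because consecutive MD
  frames are correlated.  Each ELP additionally carries its own random
  offset per column (sd 0.5, with the AR(1) noise rescaled so the total
  within-class variance stays 1): replicas of one ELP share
  sequence-driven systematic differences, and without this ELP-level
  heterogeneity every ELP of a class would be statistically identical —
  leave-one-ELP-out validation would then be degenerate (its null
  distribution collapses onto the fold-composition artifact instead of
  chance).  What the generator does *not* emulate: cross-descriptor
  correlation structure, heavy-tailed fluctuations, replica-length
  imbalance, or any physical coupling between descriptors.  Passing
  tests therefore demonstrate the statistics of the pipeline, not MD
  realism.
* **Chain trajectories** build a pseudo-peptide (backbone N/HN/CA/C/O
  plus one CB bead per residue, idealized bond geometry, explicit amide
  hydrogens) whose φ/ψ interpolate between extended-strand (−135°,
  135°) and helical (−60°, −45°) values as compactness goes 0 → 1, with
  per-frame jitter; waters are placed uniformly in the box with
  excluded volume (2.5 Å from the chain, 2.4 Å between oxygens) and
  random rigid orientations.  Collapsed chains have systematically
  smaller radii of gyration (checked over seeds).  Frames are
  independent samples around a per-trajectory base conformation, not a
  dynamical trajectory; RMSD between frames is meaningful as a spread
  measure only.  Nonbonded parameters are simple per-atom-type
  constants (TIP3P-like waters, peptide-like charges summing to ~0 per
  residue), adequate for exercising the energy code, not for
  reproducing any force field's energetics.
* **FRAP traces** are exact single exponentials plus i.i.d. Gaussian
  noise; **amide-I spectra** are sums of the five canonical Gaussians
  on the instrument-like 650–4000 cm⁻¹ grid at 2 cm⁻¹ spacing.

## Problem sizes and determinism

The test suite runs the full classifier conditions (8 × 3 × 250 × 27)
for the headline check and the 20-seed permutation null; trajectory
featurization tests use small systems (≤ ~200 atoms, ≤ 10 frames) where
the brute-force oracles are exact and fast.  The acceptance script
regenerates the synthetic dataset from its `--seed` and recomputes all
reported quantities at run time; everything except the synthetic
dataset is deterministic.

## Known limitations

* The secondary-structure assigner approximates STRIDE/DSSP; absolute
  fractions on real proteins will differ near helix/turn boundaries.
* Interaction energies omit reciprocal-space electrostatics and any
  bonded terms; they are analysis descriptors, not total energies.
* The rubber-elasticity mesh size inherits the ideal-network
  assumptions (affine deformation, flexible strands); for stiff or
  heterogeneous networks it is an order-of-magnitude estimate.
* FRAP analysis assumes a single mobile species and a single
  exponential; anomalous diffusion or immobile fractions bias A and k.
* Double cross-validation with very small libraries (< 3 per class) has
  folds without both classes; these are skipped and flagged, shrinking
  the number of predictions per ELP.
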