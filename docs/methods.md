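# Methods

## The register model

A β-helix (solenoid) winds the chain into stacked rungs of short β-strands.
A *register* is the assignment of sequence positions to this geometry: named
faces (amphipathic, alkaline, hydrophobic, NT/CT bases) given as disjoint
residue-number ranges; optional rungs (one range per coil); and *stacked
pairs* — residue `i` on one rung sitting directly below residue `j` on the
next, with a burial state shared along the whole stacked column.  Residue
numbering is 1-based full-length α-synuclein numbering everywhere, including
truncated constructs (the NAC construct spans 30–99 and keeps those
numbers), because that is how α-synuclein mutations are universally named
(K43D, A53T, …).

The packaged NAC register encodes six stacked pairs: 43/58 and 58/76
(alkaline face, exposed), 48/63, 63/81 and 50/65 (amphipathic face, buried),
and 34/51 (exposed; its lower residue sits on the NT base, whose exact rung
boundary is not established — we encode an NT-base face at 30–36).  Face
segments follow the published face assignments except that the hydrophobic
face is trimmed to end at residue 92: the printed approximate boundaries
overlap the alkaline face at 93–94, and the register validator deliberately
enforces that face assignment is a partition.  No stacked pair touches
93–95, so the trim has no effect on any score.

## Stacking propensities and the packaged exemplar table

Scores are conditional stacking propensities keyed by
`(aa_lower, aa_upper, burial)`, directional from lower to upper rung.  The
packaged table stores the published exemplar values exactly as printed
(28, 7, 25.4, 5.8, 5.8, 0.7) without asserting their unit ("published units");
every headline quantity built on them is either a stored value or a
unit-free ratio.  Two further groups of entries complete the table for the
NAC register:

* *derived-ratio* entries, back-constructed so the published ratios hold
  (Q50 twice H50 toward buried N65; D51 six times G51 toward exposed K) —
  the absolute values are not published, only the ratios are meaningful;
* *synthetic-neutral* fillers for register pairs with no published value
  ((K,K)/(D,P) exposed for 43/58, (V,T)/(R,T) buried for 63/81), chosen
  equal for wildtype and mutant so they contribute a factor of exactly 1 to
  designed fold-changes.

A register scores the product of its pair propensities, accumulated in log
space.  A mutation set's fold-change is computed only over pairs whose
residues change — untouched pairs cancel algebraically — so the DNAC
fold-change is the product of the two printed ratios,
(25.4/5.8) × (5.8/0.7) ≈ 36.3, comfortably beyond the 6-fold design
threshold.  Whether the original design aggregated pairs as a product, a
minimum, or otherwise is not documented; the product is the natural choice
for a product-form score and is what we implement.  Missing lookups return
a pseudocount floor, `pseudocount/(20 + total_count)` in percent, with a
warning, keeping products strictly positive.

## Table derivation from structure libraries

`derive_table` re-derives a propensity table from structures: stacked pairs
are detected when Cα–Cα ≤ 5.5 Å, sequence separation ≥ 10, and the local
backbone directions (central differences of the Cα trace, one-sided at
chain ends) have a normalized dot product > 0.5.  Burial uses Shrake–Rupley
solvent accessibility (biotite implementation, probe 1.4 Å, single-element
radii, 200 sphere points) of the side-chain pseudo-atom (CB, falling back
to CA), normalized by an isolated carbon sphere; a pair is buried when the
partners' mean relative accessibility is below 20 % (configurable).  Counts
receive a Laplace pseudocount (default 1) over the 20-letter alphabet and
normalize to conditional percentages, so each (lower, burial) row sums to
100.  Reproducing any historical published table exactly is out of scope —
it would depend on the PDB snapshot it was derived from; the derivation is
validated against planted synthetic libraries instead.

## Synthetic solenoids and planted libraries

The parametric solenoid is a Cα trace on a helical coil of 18
residues/coil (three 6-residue faces) with 4.8 Å rise per coil and a mean
ring radius of 11 Å — left-handed-β-helix-like dimensions giving a
realistic ~3.8 Å consecutive-Cα spacing — with a gentle (±10 %) three-fold
radius modulation for a rounded-triangular cross-section.  Each residue
carries one side-chain pseudo-atom named CB: exposed columns (odd indices)
point it 3 Å outward; buried columns (even indices) point it inward to a
fixed 2 Å core radius, emulating side chains packing the solenoid core.
The core radius was chosen so the two burial classes separate cleanly under
the 20 % accessibility criterion (interior buried pseudo-atoms sit below
~15 % relative accessibility, exposed ones above ~44 %); only the two
terminal rungs are ambiguous, and pairs touching them may classify as
exposed — a letter-independent loss that leaves planted conditionals
unbiased.  By construction residue `i` stacks exactly on `i + 18` at the
coil rise, and stack detection at default thresholds finds exactly those
pairs (the ring radius is large enough that the nearest off-column
candidates, `i ± 17`, fall outside the 5.5 Å cutoff).

Planted libraries thread each stacked column as a Markov chain: the rung-0
residue is uniform over the planted lower-alphabet of the column's burial
class and each next rung is drawn from the planted conditional
P(upper | lower, burial), so realized pair statistics converge to the
planted table.  The default planted table is two asymmetric 4×4 matrices
(buried alphabet AILV, exposed EGKS, rows like 0.40/0.30/0.20/0.10).  The
recovery analysis uses 200 structures of 16 coils — about 6 700 transitions
per table row, putting the two-percentage-point recovery criterion at
roughly 3 standard errors for the worst row — and runs in a few seconds.

These fixtures idealize heavily: no side-chain atoms beyond one
pseudo-atom, no backbone N/C/O, no loops or irregular rungs, and geometry
identical across the library.  Passing the recovery tests therefore shows
the counting, burial-classification and normalization machinery is correct,
not that the method would reproduce a table derived from real,
heterogeneous β-helix crystal structures.

## Restraint satisfaction

A restraint (res_i, res_j, atom mode, upper bound; default heavy atoms and
6 Å, the convention for unambiguous ssNMR carbon contacts) is satisfied
when the minimal distance over all atom pairs in the mode *and over all
chain-copy combinations* is within the bound: fibril-derived restraints do
not say which molecular copy each partner occupies, so intra- and
intermolecular contacts are both admissible (an intra-only switch exists).
"Coincidence" of a restraint list with a structure is simply the satisfied
fraction under the same criterion.  Restraints referencing residues absent
from the model count as unsatisfied and are flagged (configurable to
raise).  Properties guaranteed by construction and enforced by tests: the
fraction is monotone in the bound, invariant under rigid motion, and can
only grow as chains are added.  Restraint lists are plain CSV; NMR-STAR
ingestion is out of scope, as is scoring any structure we cannot obtain —
the published two-stranded-fiber restraint list is not reproduced here, so
desk-scale validation uses planted synthetic restraint sets.

## Assembly geometry

Fibers are screw assemblies about +z: copy k is the subunit rotated by
k·twist and raised by k·rise; negative twist is left-handed; pitch =
rise × 360/|twist|.  `measure_pitch` re-estimates the screw from subunit
centroids alone: the axis is the null direction of the second differences
of the centroid sequence (successive displacements of a screw have constant
axial projection), the twist comes from unwrapped in-plane angles about an
algebraically fitted circle center, and handedness from the twist sign with
the axis oriented along positive rise.  Degenerate inputs — pure
translation, or centroids on the axis (a subunit centered on the screw
axis leaves its centroid twist-blind) — report "flat"; the CLI's default
synthetic subunit is therefore offset from the axis before assembly.

Toroids replicate an arc segment about z; closure is verified by the RMSD
between the would-be segment n and segment 0 (tolerance 0.5 Å), so six
6-subunit 60° arcs close into the 36-mer annulus model and a 61° arc fails.
Two-stranded ribbons pair a translational stack with its C2 mate — rotated
about the fiber axis for the parallel configuration, about a transverse
axis for the antiparallel one.

Macrodipoles use integer side-chain charges (D/E −1, K/R +1, H neutral by
default with a +0.5 option) at CB sites (CA for glycine), plus optional ±1
terminal charges per chain, converted at 4.8032 D per e·Å.  The origin is
the center of absolute charge, which makes net-charged systems well defined
and reduces to the standard origin-independent dipole for neutral ones.
Because antiparallel C2 partners flip the axial dipole component and keep
one transverse component, antiparallel ribbons grow their orthogonal dipole
linearly in copy number while axial terms cancel pairwise, and parallel
ribbons do the opposite — the qualitative strand-configuration signature
the package tests.  The published absolute values (~5 000 D for a 20-mer,
~86 000 D for the CT-decorated toroid) are not reproducible here: they were
computed on refined all-atom model coordinates that were never deposited,
so the package treats them, like the published pitch bands (LHH 81–141 nm,
RHH ~45 nm) and the 3.5 nm fibril height, as read-only reference bands for
in/out-of-range flagging, never as targets.

Substrate height is the smallest extent of the atom cloud along its
principal axes (no atom radii added), i.e. the thickness the assembly
presents lying flat on a substrate.

## AFM morphometry

The pipeline is the standard particle-analysis recipe: 3×3 median despeckle
(edge-value-repeating reflection), threshold (Otsu by default; a fixed
height stands in for manual adjustment, which published protocols leave
unspecified), 8-connected labeling, ellipse fit from second central mask
moments.  Circularity is 4π·area/perimeter² with the perimeter taken from
the marching-squares contour of the mask, clipped to [0, 1].  Because the
moment ellipse of a rod overestimates its length by √(4/3), reported
`length`/`width` rescale the moment axes by √12/4 — unbiased for a uniform
rod, so a ridge thresholded at half maximum reports its drawn length and
FWHM width.  The per-particle height statistic defaults to the 95th
percentile of in-mask heights, a robust apex estimate: on a Gaussian
transverse profile the top 5 % of mask pixels hug the crest, so the
statistic sits within ~0.05 nm of the apex while ignoring noise maxima
(the mask max would be biased upward by roughly 2.5 noise standard
deviations).  Means/medians over particles are flagged against the
3.5 ± 0.5 nm band reported for NAC fibrils on mica.

The synthetic generator draws non-overlapping straight segments with
Gaussian transverse profiles (apex rescaled to the requested height
exactly), additive Gaussian noise, and salt-and-pepper speckle, on a
512-pixel grid at 10 nm/pixel by default (25 fibrils of ~500 nm, 80 nm
FWHM, 3.5 nm apex, 0.1 nm noise — surface-grown NAC fibril imaging
conditions at typical tapping-mode scan scales).  Real AFM images add tip
convolution, substrate tilt and scan-line artifacts that the generator does
not emulate, so pipeline tests validate the measurement chain, not
instrument realism.  No tip deconvolution is applied anywhere, matching
the published height-analysis protocol.

## ThT kinetics

Traces are fit to the 4-parameter logistic F(t) = F₀ + A/(1+e^(−k(t−t₅₀)))
by bounded least squares (trust-region reflective).  Initial guesses: F₀ =
minimum, A = range, t₅₀ = first half-range crossing, k = 4/(t₉₀−t₁₀) —
exact for a noiseless logistic, which the fit then recovers to machine-ish
precision.  The half-max time t₅₀ operationalizes the K_M of a fibrillation
curve; whether published half-times came from a fit or a visual half-max
reading is not documented, so the package claims only the
parameter-recovery form (a planted 75-minute half-max is recovered within
5 % at 2 % amplitude noise on a 96-point, 8-hour trace).  A run classifies
as fibrillating only if the fit converged, A ≥ 0.5·F₀ (strict boundary),
and t₅₀ lies inside the observation window; this presumes a genuinely
positive ThT baseline, which real plate-reader data has.  Default
simulation conditions (F₀ = 100, A = 1000, k = 0.1 min⁻¹, t₅₀ = 75 min)
emulate a rapidly fibrillating NAC run; a flat noisy baseline emulates the
non-fibrillating designed mutant.

## Numerical choices and limitations

* Coordinates ride on biotite's float32 AtomArray; centroid and pitch
  algebra promote to float64 (pitch round-trips recover to ~10⁻⁵ relative,
  well inside the 0.1 % tolerance we test).
* Closure tolerance 0.5 Å RMSD; clash cutoff 2.2 Å between heavy atoms of
  distinct copies; both configurable.
* Stacking tables are directional (lower→upper); nothing assumes symmetry.
* The register scorer and mutation scanner only see residues that belong to
  stacked pairs; mutations elsewhere (e.g. A53T, E46K, which act through
  pairs absent from the packaged register) scan against the pseudocount
  floor and should be interpreted with that caveat.
* Sequence handling covers the 20 canonical residues only; no PTMs, no
  di-tyrosine crosslink modeling.
* Structure parsing takes the first model and highest-occupancy altlocs;
  hetero records are dropped.
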