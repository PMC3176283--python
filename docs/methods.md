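# Methods

## The search model

`gridlock` performs exhaustive rigid-body docking over the product of a
discrete rotation set and a 3D translation lattice.  Molecules are treated
as rigid atom clouds; conformational change, solvent and energetics beyond
shape complementarity are out of scope (the multi-channel interface admits
additional score grids, but only the shape channel is parameterized).

For each rotation `R` of the rotating molecule, both molecules are
discretized onto complex grids and the translational score

    S(t) = Re Σ_x F(x) · L(x − t)

is evaluated for every cyclic translation `t` at once via
`ifftn(fftn(F) · fftn(L_rev))`, where `L_rev` is the circular index
reversal of `L`.  Transform dimensions are at least the per-dimension sum
of the two grid sizes, so every translation with grid overlap is free of
wrap-around aliasing and the cyclic correlation equals the linear one; the
test suite verifies both the equivalence with direct summation (relative
error ≤ 1e-4 in single precision) and invariance under extra zero padding.
All grids and transforms are single precision.

## Scoring channel

Cells within the stamp radius (default 1.8 Å, ≈ heavy-atom van der Waals)
of an atom receive the channel's surface or core value; core stamps are
applied after surface stamps and override them where they overlap.
Default values:

| grid | surface | core |
|---|---|---|
| fixed molecule | `1+0j` | `0+9j` |
| rotating molecule | `1+2j` | `0+3j` |

Under `Re(F·L)` this scores +1 per surface–surface cell pair, −18 per
rotating-surface cell on fixed core, and −27 per core–core pair.  The
asymmetry is deliberate and classical: the fixed molecule's interior is
forbidden volume for *any* part of the partner.  A symmetric
core–core-only penalty was evaluated and rejected: a small molecule whose
discretized body is mostly surface cells can then bury itself inside the
partner's interior at a profit, and planted complexes are not recovered.
Blocked residues (e.g. antibody framework) are stamped with the core value
regardless of surface flags, which suppresses favorable scoring without
pretending the atoms are absent.  Channels, values, radii and weights are
configurable through a YAML file.

## Surface marking

An atom is a surface atom iff at most `neighbor_max` other atoms lie
within `neighbor_radius` (defaults 6 Å / 24, chosen for heavy-atom protein
density; both configurable).  This neighbor-count proxy is deterministic
and dependency-free but is blind to concavity: atoms lining a deep pocket
keep many neighbors and are marked buried.  It is not claimed to match
any solvent-accessibility definition.

## Grid-efficiency machinery

* **Fixed-molecule grid.**  Per axis, `fft_friendly_size(ceil(extent /
  spacing) + 2·margin)` where extents are measured on the *rotated*
  coordinates about the rotated bounding-box center; FFT-friendly means
  all prime factors ≤ 7.  The margin (2 cells) guarantees atom stamps up
  to two cell widths never touch the border.
* **Rotating-molecule grid.**  A cube with edge
  `fft_friendly_size(ceil(2R/spacing) + 2·margin)`, where `R` is the
  enclosing-sphere radius about the chosen center — by construction
  rotation-independent, so one grid size serves the whole sweep.
* **Centering.**  The rotating molecule is centered on whichever of
  Ritter's bounding sphere or the center of mass gives the smaller
  enclosing radius (ties keep the center of mass).  The Ritter first pass
  uses the farthest-point chain (min-x point → farthest point Q → point R
  farthest from Q; initial sphere on the QR diameter), then grows the
  sphere once per remaining outside point; containment is exact, radius
  near-minimal (≤ 1.2× minimal on the unit-cube test against an
  exhaustive oracle).
* **Receptor rotation.**  The full rotation set is scanned and the
  rotation minimizing the fixed molecule's cell count is selected; ties
  break to the lowest index.  The selected grid is never larger than the
  identity-rotation grid because the built-in sets contain the identity
  at index 0.
* **Switching.**  The combined metric — the per-dimension sum of the
  fixed shape and the cubic edge, rounded friendly, then multiplied out —
  is evaluated for both role assignments and the smaller wins; ties keep
  the input roles.  The chosen metric is exactly
  `min(original, switched)`, which the tests assert.

Default cell size is 1.2 Å (the traditional docking grid spacing),
configurable.

## Rotation sets

Euler angles are intrinsic z–x–z in degrees, `R = Rz(φ)·Rx(θ)·Rz(ψ)`;
any self-consistent convention yields identical poses since search,
output and reconstruction share it.  The built-in sets cross `n_ψ` equal
spins about z with a golden-angle spiral of `n_sphere` axis directions
(cos θ uniform, φ stepped by ≈137.508°), pinned so index 0 is the
identity: 150×24 = 3,600 at 15°, 900×60 = 54,000 at 6°.  The construction
is deterministic; no external angle table is required, and a user file
(three whitespace-separated degrees per line) overrides it.  The set is
near-uniform rather than optimal-covering; symmetry-aware reduction is a
non-goal.

## Output and reconstruction

The text output format (`#gridlock v1`) stores, in order: the transform
shape, spacing and switch flag; the rotation applied to the fixed
molecule; the pre-rotation applied to the rotating molecule; and the two
molecule paths with their grid centers — followed by one line per pose
(angles, integer cell translation, score).  The stored translation is the
displacement of the rotating molecule's center from the fixed molecule's
grid center, in cells, which makes the header sufficient to reconstruct
any pose without rerunning the search.  Angles are written with two
decimals and scores with four; numeric round-trip is exact to 1e-4.

`create_complex` inverts every internal transform so the returned
receptor is bit-identical to the input file's coordinates and the ligand
is posed accordingly; when roles were switched the inverse of the
rotating-molecule transform is applied to both, which pins the receptor
exactly.  A seeded random pre-rotation (the optional ligand
randomization) applies to whichever molecule rotates after the switch
decision and is recorded in the header.

## Evaluation

The bound reference defines the interface: residues of either molecule
with any atom within 10 Å of the partner (cutoff configurable).  The
interface Cα RMSD spans both molecules' interface residues with the
receptor frames superposed and no further fitting — when the predicted
receptor already carries the reference coordinates, as reconstruction
guarantees, no superposition is performed.  A prediction is a hit at
RMSD ≤ 2.5 Å; success rate is the fraction of cases with a hit in the
top N, hit count the mean number of hits in the top N, both
non-decreasing in N.

## Synthetic fixtures and what they show

Fixtures are jittered cubic-lattice clouds (2 Å sites, ±0.1 Å jitter) of
pseudo-atoms named CA, one per residue, in globular / rod / L-shaped /
knob shapes.  Surface marking uses lattice-matched parameters (3.7 Å,
≤ 21 neighbors: a radius between the second and third neighbor shells and
a count cut between face and interior atoms), which yields exactly one
surface layer over a solid core.  The planted complex buries a three-lobe
knob (5 Å head, 3 Å inner lobe on the burial axis, 3 Å lateral bump — a
shape with no rotational symmetry about any axis) at the receptor's +x
apex, carving the receptor with a clearance just below the lattice
spacing so the bound interface is a packed lattice continuation; atoms
exposed by carving are flagged surface explicitly because concave linings
defeat any neighbor-count criterion.  The receptor default of 700 atoms
keeps a solid core ring around the socket.

Plant-and-recover tests run the full pipeline (rotation selection and
switching enabled) with a rotation set that is a closed group — the 24
spins about z — containing the planted spin; closure matters because the
engine composes the searched rotation with its internally selected
receptor rotation, so an arbitrary sparse set need not contain the
required relative rotation even when it contains the planted one.  Under
these conditions the top-ranked pose reconstructs the bound complex with
median interface Cα RMSD ≈ 0.4 Å over seeded repeats, and the receptor
coordinates are bit-identical to the input.

These fixtures demonstrate internal consistency — correlation
correctness, transform bookkeeping, reconstruction exactness, and that
the grid optimizations do not alter what the search finds.  They do not
demonstrate accuracy on real proteins: toy molecules lack side-chain
detail, realistic packing density and conformational change, and at this
scale the receptor side of the interface is large relative to the ligand,
so the both-chain RMSD understates ligand displacement by roughly
`sqrt((n_rec + n_lig) / n_lig)`; recovered toy poses at median 0.4 Å
correspond to ligand placements within about one grid cell.

## Numerical choices and degenerate inputs

Single-precision grids and transforms; score comparisons at 1e-4 relative
tolerance.  Extent-to-cell conversions subtract 1e-9 before the ceiling
to absorb binary representation error (12/1.2 is not exactly 10).
Tie-breaks are everywhere deterministic: lowest rotation index, first
maximum in row-major order for translations, stable sort (rotation order)
for equal scores, center-of-mass on centering ties, original roles on
switch ties.  Empty molecules, empty rotation sets, out-of-grid
molecules, malformed angle/output/block files and out-of-range prediction
indices raise `ValueError`/`IndexError` with specific messages.  A
single-atom molecule is valid everywhere: its bounding sphere has radius
zero and its grids are the minimum friendly sizes implied by the margins.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
fixtures: molecules of tens to ~700 atoms, grids up to ~48³, rotation
sets of 24 elements for full docking sweeps and the full 3,600-element
set for rotation-selection and switching scans.  These sizes exercise
every code path (including FFT sizes with every allowed prime factor)
while keeping a full run in tens of seconds.
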