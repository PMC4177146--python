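# Methods

## Element data

The element table (`src/molforge/data/elements.csv`, loaded by
`molforge.elements`) carries, per element H–Rn: the covalent radius in Å
from the Cordero 2008 compilation, the Jmol display color, the main-group
valence-electron count (s+p electrons; stored as 0 for d/f-block, which
never query it), the atomic mass in u, and a p-block flag (groups 13–18
minus helium). Colors follow the standard Jmol scheme; the CPK-classic
eight (C, H, N, O, S, P, F, Cl) are treated as contractual and asserted in
tests. The table is a plain CSV so it can be inspected or swapped via
`ElementTable.from_csv(path)`.

Because published covalent-radii compilations differ by a few hundredths
of an Å, every bond-length statement in the package (perception cutoffs,
construction lengths, optimizer targets, fixture geometry) is defined
*relative to the shipped table*, never as an absolute literature constant.

## Bond perception

Connectivity is inferred from geometry alone: atoms *i*, *j* are bonded
iff `‖p_i − p_j‖ < f·(r_i + r_j)` with factor `f = 1.2` by default. The
inequality is strict; a pair exactly at the cutoff is not bonded. All
pairs are examined (O(n²) via a vectorized distance matrix); no special
case exists for H–H contacts. Perception replaces the bond set wholesale,
runs automatically after XYZ loads (XYZ carries no connectivity) and not
after MOL loads (MOL supplies bonds), and is idempotent.

Ring membership of a bond is decided per query: delete the edge and test
whether its endpoints remain connected. Molecules in scope are small
(tens to a few hundred atoms), so no ring-set precomputation is worth its
complexity.

## Measurement conventions

Angles are computed as `arccos` of the clamped normalized dot product and
reported in degrees; dihedrals use the two-argument arctangent form, are
signed by the right-hand rule about the central bond, and live in
(−180°, 180°] with −180° normalized to +180°. Mirroring therefore maps a
dihedral *d* to −*d* modulo 360°, with the single fixed point at ±180°.
Whole-molecule axis rotations pivot about the centroid (the pivot is a
free choice for a headless tool; an explicit anchor can be supplied).

## Hydrogen autocompletion

For p-block elements the number of hydrogens to add to an atom with *B*
existing bonds is `clamp(8 − V − B, 0, 3)` — the octet rule capped at
three. Non-p-block elements (including hydrogen itself, which is s-block)
receive none. Placement is deterministic:

* one existing bond — hydrogens at the hybridization's ideal angle from
  the bond direction, azimuthally spaced by `360°/(max_neighbors − 1)`,
  the first in the plane of the bond and a fixed reference vector
  (global z, falling back to x when parallel);
* two existing bonds, two hydrogens — the pair straddles the plane of the
  existing bonds symmetrically about the in-plane open direction, at half
  the ideal angle out of plane (exact for an ideal tetrahedral pair);
* otherwise — the open direction: the negative normalized sum of existing
  unit bond vectors, or, when that degenerates (e.g. trans-collinear
  bonds), a deterministic 2000-point Fibonacci-sphere search maximizing
  the minimum angular separation.

Single-hydrogen addition uses the same open-direction rule at distance
`r_X + r_H`; existing atoms never move, so the result on a crowded or
strained center is deliberately imperfect — that is what the optimizer is
for.

## Editing semantics

Changing an element with ≥2 bonds touches only the symbol. With exactly
one bond the atom is repositioned along its bond at the new radii-sum
distance and then hydrogen-completed. Deleting an atom also removes its
directly bonded hydrogens (only hydrogens; no deeper cascade) and
compacts indices preserving order. Fragment rotation about a non-ring
bond moves the smaller of the two components (tie: the component holding
the second bond index). Edits never re-perceive bonds; connectivity is
maintained explicitly so that hand-built cages (e.g. unit-cell corner
"bonds") survive editing.

Undo/redo is a pair of bounded snapshot stacks, capacity 10 each, full
deep copies (molecules are small; structural sharing would buy nothing).
The oldest snapshot is evicted on overflow and any new edit clears the
redo stack, so 15 edits admit exactly 10 undos.

## Crude optimization

The optimizer is intentionally not molecular mechanics: no electrostatics,
van der Waals terms or force constants. Each iteration applies three
damped correction passes in a fixed order —

1. **bond pass** (sequential, ascending bond order): both atoms of each
   bond move symmetrically along the bond axis toward the radii-sum
   length;
2. **angle pass** (Jacobi): for every angle at every center the two arm
   atoms are rotated in the angle's plane toward the center's VSEPR ideal
   (from its hybridization assignment, default sp³); corrections are
   computed against the iteration's starting coordinates and each atom
   then moves by the *mean* of its accumulated corrections. Sequential
   application is unstable here — centers that share arm atoms pump each
   other's corrections and the iteration slowly diverges;
3. **torsion pass**: for each non-ring bond with substituents on both
   ends, the mean signed deviation of all substituent dihedrals from the
   nearest staggered value (60° + n·120°) is computed and the smaller
   fragment rotated to reduce it. Exactly eclipsed conformations sit at
   the deviation-function boundary (+60°) and break toward −60° rotation
   deterministically. Ring bonds are excluded; ring strain is handled by
   the angle pass only.

All corrections are scaled by `step_fraction` (default 0.5). Convergence
is declared when the largest per-atom displacement over a full iteration
drops below `coordinate_tolerance` (default 10⁻⁴ Å); the cap is
`max_iterations` (default 200), and non-convergence is reported via a
flag, never an exception. The monitored surrogate
`E = Σ(len − ideal)² + Σ(θ − ideal)²` (lengths in Å, angles in radians so
the two terms are commensurate) decreases monotonically on the fixture
set; this is an empirical property of the damped scheme, not a guarantee
of the pass structure. Heavily perturbed larger molecules can need more
than the default 200 iterations (ideal-geometry 2-butanol perturbed by
0.15 Å converges in ~300).

## Rendering

Orthographic projection (x, y to canvas with y flipped, z as depth;
viewer looks along +z), centered on the molecular centroid. Atoms are
drawn back-to-front (stable sort on z); each atom contributes its circle
(radius = `sphere_scale × covalent radius × scale`, default sphere_scale
0.5 — the on-screen sphere factor is a free styling choice) and then one
line per bond to each bonded atom in front of it, starting at the 3-D
intersection of the bond with the back atom's drawn sphere and ending at
the front atom's projected center. Radial gradients (off-center highlight
at 35 %/35 %, rim darkened 45 %) fake sphere shading; above 250 atoms
circles use flat fills, since gradient shading is the expensive part of
drawing large structures. Spheres are assumed not to overlap — there is
no occlusion clipping beyond the painter's order. Highlighted atoms get a
light-yellow halo circle behind them; labels are `<symbol><1-based
index>`. Output is SVG for headless, byte-stable testability; atom
circles carry `data-atom`/`data-z` attributes so documents are
machine-checkable.

## Fixtures and what they do and do not show

All test molecules are generated programmatically from the shipped radii
table: ideal tetrahedral methane, staggered/eclipsed ethane, planar
hexagonal benzene (geometric only — no bond orders, consistent with the
connectivity-only bond model), a 7-carbon methyl-cyclohexane skeleton for
ring queries, S-2-butanol with ideal sp³ geometry (the S configuration
was verified against an independent cheminformatics toolkit during
development), unit-cell corner atoms, and seeded uniform random clouds.
Fixtures are exact constructions, so tests establish the *constructive
rules* (cutoffs, counts, ideal angles, determinism), not agreement with
experimental structures: real molecules have unequal bond lengths,
non-ideal angles and conformational diversity that these fixtures
deliberately lack.

## Numerical choices

Coordinates are float64 Å throughout. Dot products are clamped to [−1, 1]
before arc-cosines. Degenerate geometry (zero-length arms, collinear
dihedral frames) raises a dedicated error in measurement, and is skipped
with a fallback axis in optimization passes. All tie-breaks (first-H
azimuth, fragment choice, eclipsed-torsion direction, stable depth sort)
are deterministic; the only randomness in the package is the seeded
random-cloud fixture.

## Known limitations

No bond orders, aromaticity, formal charges or isotopes; MOL writing and
V3000 are unsupported; the optimizer has no notion of non-bonded
repulsion, so atoms unconnected in the graph can pass close in space;
hybridization is a per-atom user assignment, not perceived from geometry;
d-block centers are rendered and measured but never hydrogen-completed
and have no VSEPR ideal beyond the sp³ default.
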