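# molforge

A headless library and command-line tool for building, editing, measuring,
optimizing and rendering small 3-D molecular structures — the engine of a
lightweight ball-and-stick molecular editor, usable from scripts and
pipelines instead of a pointing device. The intended audience is anyone who
needs programmatic construction and clean-up of small organic or inorganic
molecules: teaching material generation, quick structure sketches as input
for quantum-chemistry codes, or geometry sanity checks in a test suite.

## What it does

* **I/O** — reads and writes XYZ coordinate files (whitespace-tolerant),
  and reads a preliminary subset of MDL MOL V2000 (atoms + bonds; bond
  order is discarded — bonds are plain connectivity).
* **Bond perception** — after an XYZ load, a bond is created between two
  atoms whenever their separation is strictly less than
  `1.2 × (r_i + r_j)`, with covalent radii *r* from the shipped element
  table (Cordero 2008 compilation).
* **Measurement** — bond distances, bond angles (arc-cosine of the
  normalized dot product), and signed dihedrals
  `φ(i,j,k,l) ∈ (−180°, 180°]` by the right-hand rule about *j→k*.
* **Editing** — add/change/delete atoms and bonds; octet-rule hydrogen
  autocompletion for p-block elements, `n_H = clamp(8 − V − B, 0, 3)` where
  *V* is the valence-electron count and *B* the existing bond count, with
  hydrogens placed at the ideal angle of the chosen hybridization
  (sp³ 109.471°, sp² 120°, sp 180°) and at covalent-radii-sum bond
  lengths; rotation of fragments about any non-ring bond; a 10-deep
  undo/redo snapshot stack.
* **Optimization** — a deliberately crude, force-field-free relaxation:
  bond lengths toward radii sums, angles toward VSEPR ideals, dihedrals
  toward the staggered arrangement, iterated with damped corrections until
  the largest per-atom displacement falls below a tolerance.
* **Rendering** — depth-sorted (painter's algorithm) ball-and-stick SVG:
  atoms back-to-front as radial-gradient-shaded circles sized by covalent
  radius and colored by the Jmol scheme, bonds as lines from the back
  atom's sphere surface to the front atom's center; gradients are dropped
  above 250 atoms.

## Worked example

```sh
$ molforge fixture methane -o methane.xyz
$ molforge info methane.xyz
atoms: 5
bonds: 4
formula: CH4
molecular weight: 16.043
$ molforge measure methane.xyz --atoms 2 1 3
angle: 109.471°
```

The fixture generator builds an ideal tetrahedral methane with C–H bond
length `r_C + r_H = 1.07 Å`; `info` perceives the four C–H bonds from the
distance rule and sums the atomic masses; the H–C–H angle is the exact
tetrahedral angle `arccos(−1/3) = 109.471°`.

Editing and optimization from Python:

```python
from molforge import make, optimize, dihedral

ethane = make("ethane_eclipsed")
relaxed, iterations, converged = optimize(ethane)
print(round(dihedral(relaxed, 2, 0, 1, 5), 2))   # 60.01 — staggered
```

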