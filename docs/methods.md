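# Methods

## Scope and data flow

The package covers three computations that together support
structure-guided design of ligands for a single well-defined binding site:
probe affinity maps over the site, association constants from equilibrium
binding experiments, and rigid-body comparison of crystal structures. All
inputs can be produced synthetically (`pocketprobe.synthetic`), so every
result in `results/` and every test is reproducible offline from seeds.

## Affinity maps

### Energy model

The map value at a grid point is the interaction energy of an idealized
probe placed there with the whole receptor, summed per atom:

* **Lennard-Jones 12-6.** `ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]` with
  `R_ij = radius_i + rmin_probe` and `ε_ij = √(ε_i·ε_probe)`. The per-atom
  radius comes from the input PQR; the per-element well depths
  (H 0.016, C 0.086, N 0.17, O 0.21, S 0.25, P 0.20 kcal/mol, 0.10
  otherwise) are package defaults chosen in the range force fields assign
  to those elements. Using the PQR radius as the atomic size avoids a
  full force-field dependency and keeps the map consistent with the
  electrostatics, which use the same file's charges.
* **Coulomb.** `332.0636·q_p·q_i/(ε(r)·r)` kcal/mol with charges in e and
  r in Å. The default dielectric is distance-dependent, ε(r) = 4r, the
  classic implicit-screening choice for interaction fields computed
  without explicit solvent; a constant-ε model is available
  (`DielectricModel("constant", value)`).
* **Hydrogen bond.** A 6-4 radial well scaled by an angular weight,
  `E_hb = [2E_min(r₀/d)⁶ − 3E_min(r₀/d)⁴]·cos^m(180°−θ)`, zero for
  θ < 90°, with defaults E_min = 4.0 kcal/mol, r₀ = 2.8 Å, m = 2. The
  6-4 form is smooth, has its minimum exactly at (r₀, 180°) with depth
  −E_min by construction of the two coefficients, and is the standard
  compromise in the interaction-field literature between the hard 12-10
  and purely radial forms. All three parameters are per-probe
  configurable.

Receptor donor/acceptor typing is geometric: an N or O with a hydrogen
within 1.2 Å donates (the hydrogen's file position defines the D–H···A
angle); any O, and any N without an attached hydrogen, accepts. When the
probe donates, its hydrogen is taken as ideally oriented and directionality
comes from the angle at the acceptor's antecedent heavy atom (the nearest
non-hydrogen neighbour within 1.9 Å), optimal when the probe sits
antiperiplanar to it. Input structures must therefore already contain
hydrogens (PQR preparation servers add them); the package never places
hydrogens itself.

Energies are capped at +5 kcal/mol after summation. The cap only affects
points inside clash distance of an atom and exists to keep maps
contourable; it is why map additivity over receptor unions holds only
below the cap.

### Grid

The default grid is a cube of 50×50×50 points at 0.5 Å spacing (24.5 Å
edge), centred wherever the caller puts it — typically the centroid of a
bound ligand (`--center-from-ligand`). Point (i,j,k) sits at
`center + spacing·((i,j,k) − (n−1)/2)`; arrays are indexed `[ix,iy,iz]`
and OpenDX output uses the standard z-fastest ordering, so maps load
directly into PyMOL/VMD.

### Regions

`find_regions` thresholds the map and returns 26-connected components
sorted by depth, each with centroid, volume (points × spacing³) and
deepest point. The default contour of −2.5 kcal/mol is a package choice:
deep enough to suppress the diffuse dispersion background of a concave
site, shallow enough to keep genuine polar hotspots. For shallow probes
the analysis drivers also use a relative half-depth contour.

### Per-residue decomposition

`residue_decomposition` splits the receptor–ligand interaction energy into
per-residue LJ + Coulomb sums with the same parameters and dielectric as
the maps, and conserves the total exactly. It deliberately contains **no
desolvation term**: it ranks which residues the ligand presses against,
but its absolute values are not solvation-corrected binding energies and
should not be compared against methods that include them.

## Binding equilibria

All concentrations are molar internally; CSV I/O uses µM columns with
explicit `_uM` suffixes.

* `solve_single` uses the closed-form root of the 1:1 binding quadratic,
  guarded at the stoichiometric limit.
* `solve_competition` finds free receptor Tf as the unique root of
  `Tf·(1 + K_A·A_f(Tf) + K_B·B_f(Tf)) = Tt` (strictly increasing in Tf) by
  Brent bracketing on (0, Tt] followed by Newton polish to a receptor-
  balance residual ≤ 10⁻¹⁴ relative; bound fractions are computed directly
  from the isotherm (`L_t·K·Tf/(1+K·Tf)`) rather than by subtraction, which
  cancels badly for weak binding. Mass balance holds to 10⁻¹² relative
  across eight orders of magnitude of inputs, and inverting the
  competition estimator recovers the input constant to 10⁻⁹.
* The fluorescence fits model intensity as linear in species
  concentrations, F = α·Cf + β·Cb + γ. For each candidate Kb the linear
  coefficients are profiled out by least squares; Kb itself is found by a
  log-spaced multistart grid plus a bounded 1-D minimization. The direct
  fit refuses flat signals and spectrally identical free/bound states
  (α ≈ β), both of which make Kb unidentifiable.
* **Saturation flag.** Beyond the titration design's dynamic range the
  displacement curve collapses to the stoichiometric limit and becomes
  independent of the competitor's Kb, so the likelihood is flat upward.
  The fit is flagged `saturated` when reducing Kb by 10× costs less than
  5 % of the signal variance in fit quality; the value is then a lower
  bound, which is exactly the situation that motivates switching to the
  centrifugation method.
* `estimate_kb_centrifugation` applies the competition ratio
  `Kb_x = Kb_ref·(Cf_ref/Cb_ref)/(Cf_x/Cb_x)` per replicate and reports
  mean ± SD over replicates, pooling both pre-incubation orders;
  replicates with non-positive measured fractions are excluded with a
  warning.

## Synthetic data

The generators define the study conditions; they are pure functions of
(spec, seed).

* **Toy pockets** are rings of neutral carbons (cavity) plus optional
  feature atoms. With a single feature atom the exact probe field is the
  closed-form pair potential, which the map tests exploit as analytic
  ground truth. They emulate the geometry and chemistry of a small binding
  site, not protein topology, flexibility or solvent — map tests passing
  here validate the energy arithmetic and grid conventions, not predictive
  power on real receptors.
* **Displacement titrations** use the standard design: 0.2 µM receptor,
  0.2 µM reporter (Kb 5.1×10⁶ M⁻¹) and competitor totals
  0, 0.05, 0.2, 0.5, 2, 5, 10, 30, 50, 70 µM.
* **Centrifugation competitions** use 10 µM receptor with 15 µM each of
  reference (Kb 9.1×10⁷ M⁻¹) and test ligand (Kb 2.87×10⁸ M⁻¹), both
  pre-incubation orders per replicate. Since only the equilibrium state is
  simulated, the order is a label; generating both mirrors the
  experimental check that equilibrium was reached.
* **Noise** is multiplicative lognormal, applied independently to every
  measured quantity (free and bound fractions come from different tube
  fractions; intensities are detector readings with proportional error).
  The default σ = 0.10 is a declared assumption of plausible HPLC /
  plate-reader precision, not a fitted value. Under it, the delta-method
  CV of the four-factor Kb ratio is √4·σ = 20 %, which the simulated
  replicate SD reproduces.

## Structure comparison

Cα atoms are paired by equal residue number and name across an explicit
chain mapping (insertion codes ignored); mismatched or missing residues
drop out. Superposition is the Kabsch least-squares rigid transform over
all matched pairs, no outlier trimming — implemented through
`scipy.spatial.transform.Rotation.align_vectors`, with the RMSD recomputed
from actual residuals (the library's internal residual norm loses
precision near zero). Contact inventories class a residue as hydrogen
bonding when complementary N/O atoms lie within 3.5 Å and, if the donor
hydrogen is present, the D–H···A angle is ≥ 120°; hydrogen-free crystal
structures fall back to the distance criterion. Both cutoffs are the
conventional geometric defaults.

## Numerical choices & degenerate inputs

* Grid points coincident with an atom are clamped to r = 10⁻⁶ Å and land
  on the +5 kcal/mol cap.
* Superposition rejects < 3 pairs and rank-deficient (collinear) point
  sets.
* PQR parsing accepts both the chain-id and chainless whitespace dialects;
  numeric errors report the offending line.
* Alternate locations in PDB input resolve to the highest occupancy, ties
  to the first altloc letter; only model 1 is read.
* Every stochastic routine takes an explicit seed; equal seeds give
  byte-identical outputs.

## Problem sizes used in the shipped analyses

The analysis drivers and the acceptance script use 31³–50³ grids on
≤ 20-atom toy receptors, 8–10 seeds per displacement-regime cell, and 100
replicates (200 experiments) for noisy-recovery statistics — sizes chosen
so the full set of tables regenerates in about a minute on a laptop while
keeping Monte-Carlo error well inside the tolerances asserted.

## Known limitations

* Probe and hydrogen-bond parameters are package defaults, not fitted to
  any reference field implementation; maps are qualitatively, not
  numerically, comparable to other GRID-family programs.
* No desolvation, polarization or entropic water-displacement terms; the
  HYDROPHOBIC probe is simply the CH3 probe with electrostatics disabled.
* One-site 1:1 binding only: no cooperativity, no kinetics, no
  temperature correction between assay conditions.
* The displacement fit models a single emission intensity, not full
  spectra; inner-filter and background corrections are assumed done
  upstream.
* Chain matching requires consistent author numbering; no sequence
  alignment is attempted for non-isomorphous chains.
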