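# Methods

`snarepb` computes electrostatic interaction free energies between elongated
charged protein bundles (SNARE-like four-helix complexes) and charged lipid
bilayers by solving the nonlinear Poisson–Boltzmann equation (PBE) on
focused finite-difference grids, and converts the dependence of that
repulsion on vesicle curvature into a Helfrich-elasticity estimate of how
much local membrane bending the repulsion can sustain.

## Continuum model

The solute (protein and membrane interior) is a low-dielectric region
(ε_in = 2) embedded in solvent (ε_s = 78.54) carrying a symmetric 1:1
electrolyte at 135 mM (Debye length ≈ 8.3 Å) at 298.15 K. With lengths in
Å and the potential φ in kT/e the solver discretizes

    ∇·(ε ∇φ) − κ̄²(r) sinh φ = −4π C ρ_f ,   C = e²/(4π ε₀ k_B T · 1 Å),

with κ̄² = ε_s κ_D² inside the ion-accessible region and zero elsewhere.
The dielectric boundary is the van der Waals surface inflated by a 1.4 Å
water probe for atoms, and an analytic surface for membranes (below). Ion
accessibility excludes atom spheres inflated by a 2.0 Å Stern width and the
membrane region up to a Stern layer above its charged surface. Charges are
spread to the eight surrounding nodes with trilinear weights (exact charge
conservation); face dielectrics are harmonic means of the adjacent nodes.

### Solver

The 7-point variable-coefficient stencil is solved by damped inexact
Newton iteration: each cycle linearizes sinh about the current iterate and
applies one geometric-multigrid V(2,2) cycle (red–black Gauss–Seidel
smoothing, full-weighting restriction, trilinear prolongation,
rediscretized coarse coefficients). Cold-started nonlinear solves first run
a cheap linear solve as the initial guess; Newton steps in the
ion-accessible region are capped at 3 kT/e per cycle so the sinh term
cannot run away around bare charges. Convergence demands a maximum nonlinear
residual below 1e−6 of the source scale; interaction energies are stable to
well under 0.01 kJ/mol against this tolerance.

### Focusing

Boundary conditions follow the classic focusing scheme: the outermost grid
spans `coarse_margin_factor` (default 7×) times the model extent with
single Debye–Hückel boundary values (screened-Coulomb superposition over
the source charges; large source sets are binned into 3 Å cells first,
which is exact to well below the solver tolerance at several Debye
lengths). Each inner grid takes Dirichlet values and its initial guess from
the previous solution. By default a three-level cascade (coarse →
intermediate 2 Å grid padded ≳20 Å beyond the system → fine grid that just
spans the system) is used: at desk scale the outer grid's spacing can reach
~10 Å, and interpolating fine boundary values directly from it would
contaminate them with the coarse grid's own point-charge self-potentials.
The intermediate level removes that artifact; `focus_levels=2` restores the
classic two-level scheme. Doubling the outer margin changes benchmark
interaction energies by < 0.001 kJ/mol.

### Energies

The total grid free energy is ½Σρφ in linear mode and the full functional
Σρφ − (8πC)⁻¹∫ε|∇φ|² − (4πC)⁻¹∫κ̄²(cosh φ − 1) in nonlinear mode. Grid
self-energies are huge but cancel exactly in the interaction energy

    ΔG_int(A,B) = G(A+B) − G(A) − G(B),

because all component solves run on byte-identical grids; by default the
single-component solves zero the partner's charges but retain its
dielectric cavity and ion exclusion (`retain_partner_dielectric=False`
gives the other convention). Positive ΔG means repulsion. The nonlinear
functional integrates over the fine box only; the neglected exterior
contributes a few percent of a small interaction energy and cancels almost
entirely in the differences the pipeline reports (orientation contrasts,
composition/curvature deltas, explicit-vs-implicit comparisons); tests of
the weak-field linear/nonlinear identity therefore use boxes several Debye
lengths wide, where the truncation vanishes.

Grid registration matters at O(h) for absolute surface potentials: the
Gouy–Chapman validation registers the charged plane midway between grid
planes so the discrete diffuse layer starts exactly at the surface; with
that registration the computed nonlinear profile matches the analytic
solution to 0.35 % at h = 1 Å. Interaction-energy differences share one
grid and are insensitive to registration.

## Membranes

A bilayer patch is parameterized by geometry (planar or spherical cap),
extents, thickness (default 60 Å, full bilayer), PS fraction (default 1/3,
i.e. 2:1 PC/PS), and area per lipid (65 Å², a typical fluid-phase value;
not stated by the underlying study). Headgroup sites sit on a jittered
(±0.5 Å, seeded) hexagonal lattice trimmed to exactly
`round(area/area_per_lipid)` sites per leaflet. PS carries −1 e at the
surface plane; PC carries a +1/−1 pair (choline at the surface, phosphate
4 Å inward). PS sites are placed by a seeded stride so composition is
quasi-uniform across the patch, emulating the regular PC/PS mixtures of
atomic bilayer models; random placement is available but makes small-patch
energies depend strongly on the local composition realization (±20 %
fluctuations in the few lipids nearest the probe).

The low-dielectric, ion-excluded interior is the hydrocarbon core: the
slab between the two phosphate planes (`headgroup_depth` = 4 Å inside each
charged surface). The 4 Å headgroup layers are high-dielectric but
ion-free up to a Stern width above the charge plane. Burying the phosphate
in the low-dielectric core instead produces an unphysically asymmetric
screened dipole and was rejected.

Curved v-membranes are built by Lambert equal-area projection of the same
planar lattice onto the outer/inner leaflet spheres: lipid count (±0) and
per-lipid charges match the planar patch exactly, the planar limit is
recovered as R → ∞ (positions converge within 0.1 Å at R = 10⁶ Å), and
area density is preserved exactly — a Fibonacci sphere lattice satisfies
none of these. Implicit membranes replace the lattice with a uniform
surface charge density σ = −ps_fraction/area_per_lipid per face, realized
as an equal-area sample sheet, with the identical dielectric/ion geometry,
so explicit-vs-implicit comparisons isolate charge discreteness.

Membranes must extend at least four Debye lengths beyond the protein
footprint in all lateral directions; placement raises an error otherwise.
The protein–membrane distance is the nearest vertical gap between the
protein's van der Waals spheres and the analytic membrane surface; the
default separation is 3 Å (one water layer).

## Geometry conventions

Membranes are normal to z (t-membrane side +z, v-membrane side −z).
`align_preferred_orientation` rotates the anchor pair (by default the
Cα-level "vamp_cterm" → "syx_cterm" axis, i.e. the Lys93→Ser259 direction
of a neuronal SNARE bundle) onto +z; in-plane spin is fixed by bringing
the longitudinal principal axis into the xz-plane pointing +x (identity if
the axis already lies on z), and the centroid is recentred in x, y. The
orientation sweep rotates about the structure's recorded longitudinal axis
(defaulting to +z for bare structures), so angle 0 is the structurally
preferred orientation.

## Synthetic fixtures

`make_rod` generates an n-start helical site lattice (default 4 starts,
120 Å long, 5 Å helix radius) with controllable charge patterns: uniform
negative, cylindrically symmetric (twisted lattice), a 120° lateral
negative sector ("dipolar"), or a C-terminal positive cluster over the
last 20 % of the length. Sector patterns use straight rows so the azimuth
of the asymmetry is exact; the generator guarantees the declared net
charge to 1e−9 e and is a pure function of spec + seed.

The benchmark suite used by the validation tests is deliberately compact —
a 40 Å, 96-site rod of −8 e between ~114×82×30 Å membrane patches — so
0.5 Å focused grids (~7M nodes) remain tractable on one CPU; all
qualitative features of the study geometry (charge signs, lateral
asymmetry, 2:1 PC/PS, 4-Debye-length margins, 3 Å contact distance) are
preserved, but absolute energies are not those of a 120 Å complex. The
cylindrically-symmetric fixture uses 8 starts with an incommensurate
(52 Å) twist so its azimuthal envelope is near-continuous; its orientation
scan is then flat to < 0.1 kJ/mol, while a 4-start lattice retains a real
~1 kJ/mol fourfold modulation.

With the dipolar fixture between a 40 nm vesicle cap (below) and a planar
patch (above), the computed orientation landscape has its minimum exactly
at the anchor-aligned angle, ~9 kJ/mol below ±45°, the distance decay of
|ΔG| follows the Debye slope within ~5 %, repulsion grows monotonically
with PS fraction (pure PC is near zero), and curvature reduces repulsion
monotonically toward the planar limit — the qualitative phenomenology the
pipeline is meant to expose on real structures. Passing these tests
validates the machinery, not any biological quantity: the fixtures contain
no atomic detail, protonation, or membrane undulations.

## Bending estimate

For a vesicle of resting radius R whose lower hemisphere bends to local
radius r, the harmonic Helfrich penalty is ΔF(r) = 4π κ R² (1/r − 1/R)²
(area 2πR² × energy density 2κ(1/r − 1/R)²), κ in kT (default 20 kT,
configurable; every report echoes the κ used). The Gaussian modulus is
carried for bookkeeping but, by Gauss–Bonnet, never enters a computed
number. `solve_bending` interpolates the curvature standard curve
(monotone cubic in 1/r, the planar point mapping to 0) and returns the
smallest r with ΔF(r) ≤ N·(dG_v(R) − dG_v(r)), located by a coarse scan
plus bisection to 0.1 Å; N = 0, an unbracketed inequality, or κ → ∞ yield
r\* = R with a no-bending flag. Degenerate one-point curves are accepted
by the sweep code but flagged unusable for interpolation.

## Numerical defaults

| parameter | default | note |
|---|---|---|
| ionic strength | 0.135 M | physiological KCl |
| ε_in / ε_s | 2 / 78.54 | two-dielectric model |
| solvent probe | 1.4 Å | water |
| Stern width | 2.0 Å | added to atom radii and membrane faces |
| fine spacing | 0.5 Å | focusing target resolution |
| coarse margin | 7× model extent | doubling changes ΔG < 0.001 kJ/mol |
| fine pad | 6 Å | box beyond the system bbox |
| residual tolerance | 1e−6 (relative) | energies stable ≪ 0.01 kJ/mol |
| area per lipid | 65 Å² | configurable |
| κ (bending) | 20 kT | configurable |

Validation tests run the analytic oracles at 0.25–1 Å spacing and the
sweep suite at 1.5 Å; the precision checks compare 0.5 Å against 1.0 Å
directly. These sizes were chosen so the full suite completes on a single
CPU in well under half an hour.

## Known limitations

- Absolute nonlinear energies carry a few-percent domain-truncation bias
  (see Energies); all reported scientific quantities are differences in
  which it largely cancels.
- The bundled parameter table is a simplified united-charge set (formal
  charges on ionizable sidechains, element radii); energies on real PDB
  inputs shift by a few kJ/mol against any specific force-field
  parameterization, and protonation prediction is out of scope.
- Membrane headgroups are 1–2-bead caricatures; lipid tails, undulations
  and PIP2 microdomains are not modeled.
- The solver is serial; grids much beyond ~10⁷ nodes are impractical.
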