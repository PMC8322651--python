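# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `cgsterol`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Composition arithmetic

Sterol lipidomics is normalized to lipid phosphate: S pmol sterol per
nmol lipid P corresponds, per 1000 pmol phospholipid, to a mole fraction
S/(1000 + S); the converter returns 100·S/(1000+S) mol% and refuses
negative content. The membrane is treated as phospholipid + sterol only,
so these mol% values are upper bounds for real membranes containing other
lipid classes.

The builder fills the phospholipid remainder R = 100 − CHOL − 7KC as
POPC = 0.8·0.7·R, DPPC = 0.2·0.7·R, SM = 0.3·R. Display rounding is
half-up to integer percent for the phospholipids and cholesterol and to
two decimals for trace 7KC, matching how such tables are conventionally
printed. The published control system pairs 40 mol% cholesterol with a
measured content (608 pmol/nmol) that the formula would place at 37.8 %;
the builder therefore takes mol% as explicit input and never silently
re-derives it.

Counts are realized by largest-remainder apportionment of half the total
over the species percentages, identically in both leaflets, with a floor
of one molecule per leaflet for any species present at a positive
percentage — at 0.04 mol% of ~4,200 molecules per leaflet the target is
~1.7 molecules, and without the floor the trace oxysterol could vanish
from the model entirely. Remainder ties break in the canonical species
order POPC, DPPC, SM, CHOL, 7KC. Realization is idempotent and exactly
conserving; totals too small to honor the floors are refused.

## Sterol topologies

The 7-ketocholesterol site table is the eight-site virtual-site
cholesterol topology with site 3 changed from an SC3 ring bead to an SNa
bead of 52.66 u (the C7 ketone: more polar, heavier by +O −2H ≈ 14 u).
Sites K1, K4 and K5 are massless virtual sites positioned geometrically.
The embedded cholesterol reference masses (ROH 77.22, R2 38.69,
R3 159.65, C1 39.44, C2 72.00 u) were chosen so the nonzero masses sum to
cholesterol's molecular mass (387.0 u) and the site-3 substitution
carries exactly the ketone mass shift; a user-supplied base model
overrides them.

Only the `[atoms]` block is authored here. Bond lengths, constraints and
virtual-site constructions live in the parent cholesterol model and are
inherited: `splice_into_base` rewrites the atom rows (and molecule name)
of a base ITP in place and keeps every bonded section verbatim. Masses
serialize to two decimals; the write→read round trip is exact at string
level.

The ring-axis ("tilt") vector is K5→KOH for 7KC and R5→ROH for
cholesterol, approximating the C17→C3 axis of the sterol ring system.

## Trajectory model and I/O

Internal containers hold positions in Å and times in ps, an orthorhombic
box per frame, and a per-site catalog (molecule id, species, site name)
constant across frames; times must be strictly increasing. File I/O uses
MDAnalysis: GRO for coordinates (nm on disk, three decimals → 0.01 Å
round-trip precision) and XTC for trajectories (10⁻³ nm coordinate
precision). Triclinic boxes, velocities and other topology formats are
out of scope; the bilayer normal is fixed to z, matching a semi-isotropic
NPT setup.

Leaflet assignment takes one reference site per species (PO4 for
phospholipids, ROH/KOH for sterols) and splits molecules at the median
reference z — invariant under rigid z-translation, and refused when all
reference sites coincide in z.

## Observables

* **Area per lipid** divides LxLy by the per-leaflet lipid count by
  default. The printed magnitudes of CG multicomponent bilayers (~44 Å²
  at ~8,400 total molecules in boxes of this lateral size) imply the
  per-leaflet denominator even where a caption says "total number of
  lipids"; a `convention="total"` flag exposes the literal reading.
* **Thickness** is the distance between mean phosphate planes, with the
  per-frame split at the median phosphate z.
* **Lateral MSD** unwraps reference-site xy coordinates by minimum-image
  displacement accumulation between consecutive frames (valid while no
  molecule moves more than half a box edge per frame interval — the
  generator enforces this) and averages over molecules and all time
  origins using the FFT autocorrelation formulation. Uniform frame
  spacing is required; optional per-leaflet center-of-mass drift removal.
  The default `max_lag_fraction` of 0.25 is the usual plotting range.
* **Diffusion** is slope/4 of an ordinary-least-squares fit to MSD(τ),
  by default over the 20–80 % band of the lag range, reported in Å²/ns
  (× 10⁻⁷ cm²/s) with the slope's standard error. The *recovery*
  protocol (`cgsterol.recovery`) instead fits lags up to 2 % of the
  trajectory: for Brownian motion the MSD is linear at every lag, so
  short-lag fitting is unbiased, while time-origin averaging has its
  smallest variance there; seeded Monte-Carlo trials of the estimator
  show ~1 % relative scatter at 150 molecules × 2,000 frames versus ~4 %
  when fitting to a quarter of the trajectory.
* **Sterol tilt** is arccos |v̂·ẑ| per molecule per frame, pooled across
  leaflets by the fold to [0°, 90°]; histograms use 2° bins by default
  and integrate to one.
* **Order parameters** are computed per tail pseudobond as the time- and
  ensemble-average of (3cos²θ − 1)/2. Both sign conventions are first
  class: `standard_P2` is the second-Legendre value (positive = aligned
  with the normal), `as_printed` its exact negative. The two appear
  inconsistently in the applied literature — a leading minus sign
  alongside the statement that decreasing values mean decreasing order —
  so neither is silently "corrected"; every result object carries both.
* **Group comparison** is the two-sided unpaired Student's t-test with
  pooled variance; p < 0.05 is flagged significant. Two zero-variance
  samples with equal means return (t, p) = (0, 1) by convention.

## Synthetic membrane generator

The generator emulates the statistical structure of a tensionless CG
bilayer NPT trajectory, not its physics: no force field, no thermostat or
barostat dynamics, no gel/liquid-ordered phase behavior, no flip-flop.

* **Geometry.** Two mirrored leaflets on a square lattice at spacing
  √(area per lipid); the box area is exactly N_leaflet · apl, and
  phosphate planes sit at ±thickness/2 with Gaussian z-roughness
  (default sd 1 Å). Species templates are minimal MARTINI-style bead
  chains (NC3/PO4/GL1/GL2 + two tails for the PCs, an AM backbone and
  asymmetric tails for SM, eight-site ring chains for the sterols); only
  site names, bond adjacency and marker sites matter to the analyzers —
  no claim is made about physical CG geometry.
* **Lateral dynamics.** Per species, molecule anchors follow 2D Brownian
  motion with per-frame step variance 4·D·Δt (2·D·Δt per axis), wrapped
  periodically; a precondition rejects step sizes approaching a quarter
  box edge. Default D values (0.6–1.0 Å²/ns ≈ 10⁻⁷ cm²/s) are CG-scale
  lateral diffusivities.
* **Orientations.** Tail bond directions are drawn each frame from the
  axial density p(u) ∝ exp(λu²), u = cosθ, with λ solved (bracketed
  root-finding on a quadrature of the moment) so ⟨(3u²−1)/2⟩ equals the
  per-bond target; sterol ring axes from p(θ) ∝ sinθ·exp(κ cos(θ−θ₀)) on
  [0°, 90°], whose mean and sd are computed by quadrature for oracle
  comparisons. Both are sampled by inverse-CDF interpolation on 32,769-
  point grids. Orientations are resampled independently every frame — no
  rotational dynamics — which is sufficient because all in-scope
  observables are static-distribution or lateral-dynamics quantities. A
  consequence: at D = 0 the marker sites freeze but internal beads still
  move frame to frame.
* **Box fluctuation.** The total lateral area fluctuates about
  N_leaflet·apl with default sd 0.1 % of the area, standing in for
  barostat noise.
* **Determinism.** All randomness derives from the ground-truth seed;
  identical `GroundTruth` inputs give bit-identical trajectories.
* **Default scale.** 512 lipids/leaflet and 2,000 frames at 100 ps
  (desk-scale stand-ins for the ~8,400-molecule, multi-microsecond
  systems such membranes are run at in production MD). The bundled
  recovery benchmark uses a balanced mixture (POPC 30 / DPPC 15 / SM 15 /
  CHOL 25 / 7KC 15 mol%) rather than a physiological composition: a
  trace species at 0.04–2 mol% has 2–21 molecules at this size, far too
  few for tight per-species diffusion recovery, whereas the balanced
  mixture gives every species ≥ 150 molecules. Physiological
  compositions remain the defaults everywhere else.

What passing recovery tests show — and what they do not: agreement
demonstrates that the analyzers measure exactly what the generator
encodes (correct estimators, unwrapping, averaging and conventions) at
known statistical power. It does not validate CG force-field physics, and
real trajectories add features the generator omits: correlated lipid
motion, rotational relaxation, undulations, leaflet asymmetry and
anomalous short-time diffusion.

## BAR estimator

Work convention: forward work W_F for 0→1 switching, reverse work W_R
for 1→0, both in kT; a dissipationless pair has W_F = ΔF, W_R = −ΔF
(Crooks-consistent). With M = ln(n_F/n_R) and Fermi function
f(x) = 1/(1+eˣ), ΔF solves

    Σ_i f(M + W_F,i − ΔF) = Σ_j f(−M + W_R,j + ΔF).

The left side is increasing and the right decreasing in ΔF, so the root
is bracketed from the work range (widening geometrically if needed) and
solved by Brent's method to 10⁻¹⁰ kT — bisection-grade robustness was
preferred over Newton iteration since the balance can be extremely flat
for poorly overlapping samples. The reported uncertainty is the standard
asymptotic estimate var = [⟨f²⟩/⟨f⟩² − 1]/n_F + [⟨f²⟩/⟨f⟩² − 1]/n_R at
the solution. kJ/mol conversion defaults to 310.15 K (kT = 2.579
kJ/mol). Published CG partition free energies for these sterols
(ΔG = 71.1 ± 1.0 kJ/mol for 7KC octanol–water vs. 86.7 ± 0.9 kJ/mol for
the parent cholesterol model) require alchemical MD sampling and are
documented reference constants, not quantities this package recomputes.

## Problem sizes used by the test suite

The recovery benchmark runs 512 lipids/leaflet × 2,000 frames (one seed,
~10 s); monotonicity sweeps use 48 lipids/leaflet × 300 frames × three
levels; the BAR checks use 10⁵ work samples per direction. Tolerances
asserted at the benchmark size: area per lipid within 0.5 %, thickness
within 0.5 Å, per-species D within 5 %, per-bond P2 within 0.02, tilt
mean within 1° of the sampling density's quadrature mean — each several
standard errors wide at that statistical power.

## Known limitations

* GRO/XTC only; no PDB/TPR/DCD, no triclinic boxes, no velocities.
* The bilayer normal is assumed to be z everywhere.
* MSD origin averaging requires uniform frame spacing.
* The generator's orientation model has no temporal correlation, so
  time-correlation observables (rotational relaxation, order-parameter
  autocorrelation) cannot be tested against it.
* `compare_groups` treats per-frame observable values as independent
  samples; for strongly autocorrelated series the t-test is
  anticonservative.
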