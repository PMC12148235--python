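# Methods

## Papilla geometry

The papilla is modelled as a surface of revolution around the z-axis with
z = 0 at the pole and z increasing towards the cell base; all lengths are
in micrometres. The radius profile is piecewise analytic:

* head, 0 ≤ z ≤ Lhead: an ellipsoid cap,
  `R(z) = (Whead/2)·sqrt(1 − (Lhead − z)²/Lhead²)`;
* shaft, z > Lhead:
  `R(z) = Whead/2 − Whead/(4·Lhead²)·w² + a1·w³/(a2 + w)`, `w = z − Lhead`.

The join at z = Lhead is continuous up to the second derivative by
construction, and the coefficients (a1, a2) are the closed-form solution
of the two neck conditions `R(Lneck) = Wneck/2` and `R′(Lneck) = 0`. All
derivatives used by the integrators are analytic, never finite-differenced.
The observable base sits at `z_base = 60 µm` (configurable); profiles are
validated to stay positive over (0, z_base].

**Default descriptors.** The packaged genotype means use the published
head and neck widths (WT: Whead = 16.50, Wneck = 14.40; *ktn1-5*:
Whead = 26.34, Wneck = 20.07 µm). The head and neck *lengths* are not
published as numbers, so the defaults are synthetic stand-ins chosen once
on morphological grounds: `Lhead = Whead/2` (the head is described and
drawn as near-hemispherical, which this makes exact) and `Lneck = 40 µm`
for both genotypes (a constriction about two-thirds of the way down the
observable cell, as in the published silhouettes). The fixture generator
(`papillasim.io.fixture_measurements`) samples reproducible per-papilla
tables around these means with the published SEMs for the widths and
comparable relative spreads for the lengths. Consequences of this choice
are noted under *Known limitations*.

**Pin surfaces.** Pin-like toy shapes are surfaces of revolution of a
clamped cubic B-spline profile N(u₁) (u₁ = 0 base, u₁ = 1 pole), scaled by
width W and height H (defaults 1 and 2 a.u.): `S(u₁,u₂) = (W·N·cos u₂,
W·N·sin u₂, H·u₁)`. The central control point sets the neck; the neck
diameter D is found by bounded minimisation of the profile near
mid-height. The original control-point table is not available, so the
family's fixed control values were calibrated once so that the two
published reference geodesics are reproduced: from a start at azimuth 0,
altitude −0.1 below the pole, aimed 28° below the circumferential
direction, the geodesic makes ≈1 turn at D = 0.43 and ≈3.5 turns at
D = 0.27. The second case sits close to the confinement threshold
(Clairaut constant just below the neck radius), which is what makes the
turn count so sensitive to the neck — the same sensitivity the published
shapes exhibit.

## Geodesics

Geodesics solve `d²uᵃ/ds² + Γᵃ_bc u̇ᵇ u̇ᶜ = 0` with the metric and
Christoffel symbols assembled numerically from scalar products of the
analytic first and second derivatives of the chart embedding. Integration
uses adaptive RK45 (rtol 1e-8, atol 1e-10) with dense output resampled on
a global arc-length grid (default δs = 0.1 µm on papillae). Termination:
crossing z_base ("reached_base"), or exhausting 20× the surface height
("confined", e.g. trapped above a narrow pin neck).

Near the pole the cylindrical chart (θ, z) degenerates, so papilla
integrations switch to a Cartesian Monge chart z = f(x, y) over the
ellipsoid head when z < 0.2·Lhead and back when z > 0.3·Lhead; the
hysteresis prevents chattering. On every surface of revolution the axial
angular momentum of the unit tangent, `x·v_y − y·v_x = R·sin φ`, is
Clairaut's invariant; its conservation (typically < 1e-6 relative,
asserted < 1e-4) is the primary correctness oracle and also fixes the
algebraic form of the tube equations below: with μ = 0 they conserve
R sin φ exactly, so the printed coupling term is implemented verbatim.

## Tube growth

The tube is an inextensible filament with bending rigidity χ whose tip
moves on the surface. State in the cylindrical chart is (θ, z, φ), φ being
the angle to the base-ward longitudinal tangent (φ = 0 base-ward, 90°
circumferential, 180° pole-ward; starts in [180°, 360°) are mirrored):

    dθ/ds = sin φ / R
    dz/ds = cos φ / sqrt(1 + R′²)
    dφ/ds = − sin φ · R′ / (R·sqrt(1 + R′²)) − (μ/ℓ)·sin 2φ·[z > z_c]

The torque `m·sin 2φ` (μ = mℓ/χ, ℓ = 2.5 µm) aligns growth with the long
axis — towards the base for φ < 90°, towards the pole for φ > 90° — and
acts only below the head (z_c = Lhead by default, where the spherical cap
meets the cylindrical shaft, the wall there being presumed isotropic).
Stepping is fixed-step RK4 at δs = 0.1 µm; in the pole cap the geodesic
equation is integrated in the Monge chart (the torque never acts there,
and z_c < 0.3·Lhead is rejected). A δs convergence check (halving /
doubling) changes turn numbers by far less than the 0.5-turn bin width.

**Self-avoidance.** The deposited tube is a capsule chain of radius
r = 2.4 µm sampled every δs; a proposed tip position is blocked if it
comes within 2r of any non-adjacent capsule (own path or other grains'
tubes). On a blocked step the growth direction is deflected in the tangent
plane: candidate headings are scanned in 1° increments outward from the
momentum-conservation direction (up to ±90°; the tip may turn up to
perpendicular but never reverses), and the feasible candidate of least
deflection wins, with the guidance potential −(μ/2ℓ)·cos 2φ breaking
left/right ties. This capsule-feasibility-plus-bending-cost rule is the
package's stand-in for the original contact-potential minimisation, whose
exact functional form is not published. If no candidate is feasible, or
the tube exceeds 15× z_base of arc length without reaching the base, the
outcome is "caged" (counted as T > 2.5).

The self-adjacency window excludes the most recent `ceil((2r + 1 µm)/δs)
+ 2` segments from collision tests. The bare value ceil(2r/δs) + 2 (the
arc a straight tube needs to clear its own neck) is insufficient on a
curved surface: while sliding along a contact the path bends at radii
down to ~2r, so the chord across exactly 2r of arc falls slightly short
of 2r and the window boundary would pin the tip against its own neck.
The 1 µm margin (plus a 4-segment-wider audit window for post-hoc checks)
guarantees every audited point/segment pair was enforced during growth.

**Turn counting.** The azimuth is tracked continuously (no mod-2π jumps);
T = |θ(end) − θ(0)|/2π evaluated at the (interpolated) first crossing of
z_base. Trajectories passing very near the pole have an intrinsic
half-turn ambiguity in the azimuth; they land in the T ≈ 0.5 category
either way.

## Ensembles

Phase diagrams run one deterministic tube per cell of the grid z₀ ∈
{0.5, 5, 10, …} µm (step 5 µm up to the landing limit 2·Lhead; the pole
value 0 is replaced by 0.5 µm to avoid the chart singularity) × φ₀ ∈
{0°, 5°, …, 180°}. Cumulative distributions F(T) at thresholds
{0, 0.5, …, 2.5, >2.5} weight each z₀ row by the analytic integral of the
surface-area element `dS = 2πR·sqrt(1 + R′²)·dz` over the row's z-band
(uniform attachment per unit area, up to 2·Lhead), or alternatively by the
projected annulus area `dS = 2πR·dR` over the head only; φ₀ is uniform.
Caged cells enter only the top bin. Experimental count tables
(T_bin, count) are converted to cumulative fractions with binomial SEM
`sqrt(F(1−F)/n)` for comparison.

## Wall mechanics

The tube of radius r grows between two thin elastic leaflets (thickness t
each) of a pressurised quasi-cylinder (radius R_p, turgor p). It bulges
the outer leaflet outward by r_out and the inner one inward by r_in, with
r_out + r_in = 2r; each bulge cross-section is a half-ellipse of width 2r.
Energies per unit tube length:

* cross-ridge stretching: the half-ellipse arc excess e(h) strains the
  fibres crossing the ridge against their prestress (linear, `N·e`) and
  modulus (quadratic, `Y·t·e²/(4r)`). For a longitudinal ridge these are
  hoop fibres (prestress `p·R_p/2` per leaflet); for a circumferential
  ridge, axial fibres (prestress `p·R_p/4`) — this factor-two asymmetry is
  what lets circumferential growth become *cheaper* in soft walls;
* along-ridge (circumferential growth only): the ridge wraps around the
  cylinder, changing the circumference of displaced material by
  ±(π/4)·h/R_p (outer stretched, inner compressed) against hoop prestress
  and modulus — the "two-direction" deformation of circumferential growth;
* volume work `p·(π/2)·r·r_in` against turgor.

Minimising over the partition (bounded scalar search, 1e-10 tolerance)
gives α = r_out/r_in and the energies f_lg, f_ci; then
μ = (f_ci − f_lg)·ℓ²/χ with the same ℓ and χ as the trajectory model, so
both modules share one guidance scale. Anisotropy enters as
direction-dependent moduli `Y_lg,ci = Y·(1 ± ν)` shared by both leaflets;
the rigidity-contrast mode instead solves (Y_in, Y_out) at fixed
Y_eff = (Y_in + Y_out)/2 for a target α by bracketing (α is monotone in
the contrast), flagging infeasible targets rather than clipping.

**Constants.** t = 0.6 µm (electron micrographs show a wall bilayer of
order a micrometre), effective p = 0.05 MPa, χ = 500 MPa·µm⁴
(= 5·10⁻¹⁶ N·m², the literature order of magnitude for pollen-tube
flexural rigidity). Within these physiological ranges the constants were
fixed once against the two published operating points, which the model
then reproduces: μ ≈ 0.041 for WT (α = 1, Y_eff = 18 MPa, R_p = 7 µm) and
μ ≈ 0.011 for *ktn1-5* (α = 3, Y_eff = 25 MPa, R_p = 10 µm).

## What the synthetic data do and do not show

The synthetic measurement tables emulate per-papilla descriptor
variability (normal, published SEMs) but not measurement covariance,
outliers, or shape features outside the four descriptors (bending of the
papilla axis, non-circular cross-sections). The simulated tube model has
no elongation-rate dynamics, no chemotropic gradients and no stochastic
tip wobble: phase diagrams are fully deterministic, so passing tests show
the geometry–mechanics pipeline is self-consistent and reproduces the
published morphological statistics approximately, not that real tubes are
deterministic.

## Known limitations

* With the synthetic Lhead/Lneck defaults, the zero-guidance *ktn1-5*
  area-weighted F(T ≤ 1) computes to ≈ 0.53, slightly above the published
  40–50% band (the hemisphere head gives the uniformly-low-T pole region a
  little more weight than the measured geometry would); the >2.5-turn
  fraction (≈ 0.25) and the whole qualitative phase-diagram structure do
  match.
* The area vs projected weighting choice shifts F by up to ≈ 0.2 at these
  head proportions (published: a small effect); both weightings preserve
  every qualitative conclusion, including the guidance ordering.
* In the anisotropy mode the model does not reproduce an indentation ratio
  of ≈ 3 for soft equal-leaflet walls (it yields α ≈ 1.04): with a
  half-ellipse membrane energy the equal-leaflet partition stays
  near-symmetric unless p is an order of magnitude larger, which would be
  inconsistent with the μ operating points. Large α here requires a
  genuine rigidity contrast. Relatedly, rigid-wall μ(ν) crosses 0.025
  already at ν ≈ −0.03 rather than staying below it on all of [−0.1, 0].
* Exactly circumferential guided growth (φ = 90°) is an unstable
  equilibrium and is deliberately left untied (no injected noise); grid
  cells at φ₀ = 90° can therefore cage even under strong guidance.
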