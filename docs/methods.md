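# Methods

This note documents the mechanics implemented in `aortatear`, the choices
made where the design was genuinely open, the calibration of the
reduced-order tear model, and what the synthetic fixtures can and cannot say
about real aortas.

## Constitutive model

Both wall layers are incompressible Gasser–Ogden–Holzapfel (GOH) solids with
two symmetric collagen-fibre families at ±θ from the circumferential
direction in the θ–z tangent plane (no radial fibre component, the standard
arterial convention).  The energy density (kPa) is

    Ψ = C10 (Ī₁ − 3) + k₁/(2k₂) Σ_{α=1,2} [exp(k₂⟨Ē_α⟩²) − 1]
    Ē_α = κ(Ī₁ − 3) + (1 − 3κ)(Ī₄α − 1)

with the Macaulay bracket ⟨·⟩ switching fibres off in compression; κ ∈
[0, 1/3] spans aligned to isotropically dispersed fibres.  Both families
share Ī₄ because they lie at ±θ in the same plane, so family-swap symmetry is
exact by construction.  A volumetric penalty (1/D)((J²−1)/2 − ln J) is
available as an optional evaluation mode, but every solver in the package
uses exact incompressibility (J = 1) with a Lagrange-multiplier reaction
pressure: this removes the unreported penalty parameter D from the model
entirely.

Layer parameters (media: C10 = 16 kPa, k1 = 901 kPa, k2 = 9, κ = 0.12,
θ = 41.6°, 1.5 mm; adventitia: C10 = 13.5 kPa, k1 = 370 kPa, k2 = 15.2,
κ = 0.25, θ = 54.8°, 0.5 mm) and the interface fracture parameters
(t_n^cr = 131 kPa, t_s^cr = 97 kPa, t_t^cr = 120 kPa, G = 50 N/m) ship as
YAML in `src/aortatear/data/` and can be replaced file-for-file.

An exp-overflow guard raises at k₂⟨Ē⟩² > 700 (double-precision limit) with
the offending strain in the message.  Stress correctness is enforced two
ways: central finite differences of Ψ over 100 seeded stretch states
(tolerance 1e−6 relative), and a work–energy identity on the vessel level
(external work along a quasi-static inflation path equals stored energy to
0.5%).  The latter caught a real factor-of-two inconsistency between two
stress evaluation paths during development and is kept as a regression
guard.

## Tube inflation

Vessels are straight two-layer thick-walled cylinders with restrained ends:
λ_z = 1 (plane strain) globally.  Axial prestretch and residual stress
(opening angle) are deliberately not modelled.  Incompressibility gives the
one-parameter radius map r² = r_i² + (R² − R_i²)/λ_z, so equilibrium is the
scalar condition

    P = ∫_{R_i}^{R_o} (σ_θθ − σ_rr) R / (λ_z r²) dR,

evaluated with 40-point Gauss–Legendre quadrature per layer (doubling the
grid changes P by < 1e−4 relative).  `inflate` brackets the loaded inner
radius in [R_i, 1.6 R_i] and solves with Brent's method to machine
tolerance; σ_rr is then integrated outward from −P at the lumen, and σ_θθ,
σ_zz follow from the deviatoric differences.  At 80 mmHg the deviatoric
stress state keeps Ē_α > 0 through the whole wall for the shipped
parameters, so the fibre recruitment discontinuity never activates along the
pressurisation paths used here.

Units: mm, kPa, and mmHg at interfaces (1 mmHg = 0.1333224 kPa).  kPa·mm
equals N/m, which makes the fracture-energy bookkeeping exact.

## Zero-load recovery

Imaged geometries are equilibria at the imaging pressure (80 mmHg diastole
for all catalogue fixtures; the pressure is an argument, not a constant).
The forward-and-backward fixed-point iteration X ← x_img − U(X) runs with
plain Picard updates (an optional under-relaxation factor exists for stiff
cases but defaults to 1), stops at a maximum nodal L2 residue ≤ 0.01 mm, and
aborts with the full residue history if the residue grows on three
consecutive iterations or the 50-iteration budget is exhausted.  The forward
solver is injected as a function on nodal coordinate arrays, so the driver
is agnostic to what produces the displacements; for cylinders the nodes are
the lumen, interface and outer radii.  On the catalogue fixtures the
iteration contracts by roughly an order of magnitude per step and converges
in 3–6 iterations.

Recovered zero-load vessels are narrower and thicker-walled than their
images (incompressibility under deflation); with the shipped parameters the
diastolic circumferential prestretch is 1.06–1.08 and the recovered wall
thickness differs by ~2% between the largest- and smallest-diameter Aorta-1
fixtures, from identical 2.0 mm loaded walls.

## Cohesive interface

Elastic response t = diag(K)δ with K_nn = K_ss = K_tt = 1e5 kPa/mm.  The
penalty stiffness is not a physical measurement; it must only dominate the
wall compliance, and the critical-pressure results move by ~0.1% when K is
varied tenfold either way (tested).  Onset follows the maximum-nominal-
stress ratio with Macaulay-bracketed normal traction; the shear components
enter by magnitude (the printed criterion assumes positive shear, but
physically either sign must initiate).

After onset a single scalar damage variable grows with the effective
separation δ_e = ‖(⟨δ_n⟩, δ_s, δ_t)‖ along a linear softening envelope whose
final separation δ_f = 2G/t_e0 is set from the effective traction at
initiation, so the dissipated energy at full decohesion equals G for any
fixed mode mix (pure modes included).  Unloading/reloading follows the
damaged secant through the origin; damage is irreversible; compression
always sees the full penalty stiffness (contact-like, no interpenetration,
no damage).  The mixed-mode interaction rule is this package's choice — the
per-mode critical tractions with a single G underdetermine it — and is the
simplest rule consistent with pure-mode energies.

## Reduced-order tear model

The deliberate central substitution: instead of XFEM displacement
enrichment, tears are explicit interfaces in an idealised geometry, and the
front traction is assembled from closed-form mechanisms evaluated with the
nonlinear tube solver.  Both lumens carry the same pressure (the true/false
lumen difference is a few mmHg in measurements and is neglected), starting
from the 80 mmHg diastolic baseline.

**θz tears** (normal radial; the propagation-phase geometry).  The tear
plane at depth d splits the wall into an inner flap (thickness h_f = d,
media only) and an outer shell.  Mechanisms:

1. *Prestretch release.*  Equal pressure on both flap faces unloads the
   flap, which springs back towards its stress-free radius.  The free
   mismatch is δ(P) = r_d(P) − R_d, the loaded-minus-zero-load tear-plane
   radius of the intact wall; it grows with pressure and with vessel
   diameter.
2. *Finite-size attenuation.*  A patch of half-extents a_θ, a_z transmits
   A = tanh(a_θ/ℓ)·tanh(a_z/ℓ) of the mismatch to its front, with the
   bending boundary-layer decay length ℓ = c√(r_d h_f).  Thin flaps
   (shallow tears) conform over short distances and transmit nearly the
   full mismatch at any size; thick flaps (deep tears) only when the tear
   is large.  This term is what makes short, deep tears the strongest
   configurations and makes deep tears size-sensitive while shallow ones
   are not.
3. *Front load path.*  The transmitted mismatch is forced through the
   cohesive spring in series with the through-thickness ground-matrix
   columns of the flap and the adventitia anchor, compliance
   C = 1/K_nn + h_f/(6C10_m) + t_a/(6C10_a).  Radial squeeze is carried by
   the matrix (the fibres are tangential), hence the small-strain
   neo-Hookean modulus E = 6C10.
4. *Face-pressure wedging.*  The pressurised false lumen wedges the faces
   apart; the front sees an additional w·P, attenuated by A.
5. *Clamping.*  The compressive intact-wall radial stress σ_rr(R_d, P)
   still acts over the un-opened fraction (1 − A).

Together: t_n = (1−A)σ_rr + A(δ/C + wP), plus a shear-lag estimate of the
circumferential shear from the released hoop prestretch (small; the normal
component limits every shipped case).  The axial shear vanishes in the
axisymmetric base state.

**θr tears** (normal axial; the entry-tear geometry) are radial slits from
the lumen to depth d.  The front traction is the largest intact-wall axial
Cauchy stress over the torn band plus the face pressure, t_n = max σ_zz + P.
Because σ_zz peaks at the lumen edge of the band, the result is
depth-insensitive — reproducing the observed near-constant critical
pressure of entry tears across depths — and diameter-sensitive through
σ_zz(P).

**Critical pressure** is found by bisection on [80, 400] mmHg to a bracket
width of 0.1 mmHg.  f ≥ 1 at the baseline is reported as immediate onset
(P_cr = 80); f < 1 at 400 mmHg returns a flagged sentinel rather than an
extrapolation.  With the shipped calibration all 228 default-sweep cases
converge inside the bracket.

### Calibration

The model has exactly two dimensionless calibration constants: the decay
coefficient c = 0.35 in ℓ = c√(r_d h_f) (same order as the classical
axisymmetric shell boundary-layer value (3(1−ν²))^(−1/4) ≈ 0.82 at ν = 1/2;
patch edges are not axisymmetric, so a shorter effective decay is expected)
and the wedge factor w = 3.5.  They were set, once, so that the default
sweep reproduces the study-scale critical-pressure envelope (≈80–300 mmHg)
with every case converging; they were not adjusted against the monotone
trends, which emerge from the mechanism structure above and were verified
after freezing.  The through-thickness layer count enters as the
element-centre grid that tear depths snap to (mirroring element-centre tear
placement in meshed models) and as the radial quadrature density; because
the integrands are smooth, the 3-versus-7-layer critical-pressure difference
is at the bisection-grid level (≪ 1%), i.e. the reduced model is mesh-
insensitive by construction rather than by refinement.

## Synthetic fixtures

The five-aorta catalogue stores loaded (80 mmHg) inner diameters at the
ascending and descending tear locations; diameters are interpreted as
*inner* because clinical segmentation captures the lumen (an outer
interpretation is a one-line change when building the imaged geometry).  The
arch maps to the descending-diameter cylinder: with branches removed, arch
and descending behaviour coincide at this level of idealisation.  Walls are
uniformly 2.0 mm (1.5 media + 0.5 adventitia) in the loaded configuration.
Tear depths default to {0.25, 0.75, 1.25} mm; the deepest value is quoted
inconsistently (1.25 vs 1.125 mm) in the source material, so 1.25 is the
default and any depth strictly inside the media is accepted.  The default
grid is 120 θz cases (4 sizes × 3 depths × 2 locations × 5 aortas) and 108
θr cases (4 sizes × 3 depths × 3 locations × 3 aortas).

`make_imaged_vessel` additionally samples cylinder surfaces with optional
seeded uniform radial noise to exercise the recovery driver's robustness;
all randomness in the package flows through explicit seeds and
`numpy.random.Generator` — there is no hidden global state, and sweeps are
bitwise reproducible.

What the fixtures do **not** emulate: curvature and tapering, branch
vessels, patient-specific cross-sections, wall-thickness variation, axial
prestretch, residual stress, intima, and any hemodynamics.  Passing tests on
these fixtures therefore demonstrates that the implemented mechanics
reproduce the study-scale *relations* (trends with depth, size, diameter,
orientation; pressure envelope; recovery behaviour) on idealised geometry —
not that the package predicts patient-specific critical pressures.

## Numerical choices

- Inflation root-find: Brent on [R_i, 1.6 R_i], xtol 1e−10; bracket failure
  raises with the bracket in the message.
- Radial quadrature: Gauss–Legendre, 40 points/layer for inflation and
  recovery; 2 points per through-thickness element (floor 6) inside the
  tear model.
- Bisection: 0.1 mmHg bracket; the returned value is the final midpoint.
- Recovery: tolerance 0.01 mm, max 50 iterations, divergence = 3 consecutive
  residue increases.
- Degenerate tears (zero extent) return the intact interfacial stress — the
  continuity limit — and never initiate.
- Serialisation: floats at 9 significant digits; results as CSV/JSON.

## Known limitations

- The tear-front traction is a closed-form reduced-order assembly, not a
  solution of the coupled flap/shell boundary-value problem; its two
  constants are calibrated to study-scale outputs (above), so absolute
  critical pressures inherit that calibration while trends are structural.
- At the strongest corner of the sweep (3 × 3 mm tears at 1.25 mm depth in
  the smallest vessels) critical pressures saturate near the top of the
  envelope and fixture-to-fixture differences fall to the bisection
  resolution (~0.2 mmHg), so strict trend inequalities degrade to ties
  there.
- Plane strain (λ_z = 1) is applied globally, not just at the restrained
  ends.
- The cohesive law is rate-independent and linear-softening only; no
  friction after decohesion beyond elastic contact.
- Post-onset propagation, re-entry tears and flap dynamics are out of scope:
  every computation stops at the onset of further propagation.
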