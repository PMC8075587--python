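# Methods

## Model

The flagellum is a composite of two slender structures sharing one
centerline-and-frame kinematics.

**Axoneme.** A special Cosserat rod: centerline r(s), 0 ≤ s ≤ L, with an
orthonormal material frame (d₁, d₂, d₃), d₃ = r′.  Strains are the frame
rotation rates U₁ = d₂′·d₃, U₂ = d₃′·d₁ (bending) and U₃ = d₁′·d₂ (twist);
equivalently the frame precesses with Darboux vector U₁d₁ + U₂d₂ + U₃d₃.
d₁ points from the axoneme center to doublet microtubule 2 (the middle of
the PFR bonding complex), fixing the spontaneous bending plane as d₁–d₃.
The nine doublets lie on the tube surface
C(s,φ) = r + ρ_a(cos φ d₁ + sin φ d₂ + (cos φ γ₁ + sin φ γ₂)d₃) at angles
φ_j = 2π(2−j)/9; the axial offset term is the collective sliding
(shear) γ₁ = ∫₀ˢU₂, γ₂ = −∫₀ˢU₁ that accompanies bending — the fundamental
sliding-to-bending coupling.  Passive energy: ½∫ B_a(U₁²+U₂²) + C_a U₃² ds.
Treating each doublet as an independent rod of modulus B_m and summing their
bending energies reproduces this form with B_a = 9B_m in the slender limit;
the package verifies this by brute-force summation over the nine discrete
centerlines (the ratio reaches 9 within 0.5% at ρ_a/L = 10⁻³).

**Actuation.** Dynein forces enter as cross-section resultants: distributed
shear forces H₁, H₂ and concentrated tip forces Ĥ₁, Ĥ₂ conjugate to γ₁, γ₂.
Completing the square shows they are equivalent to a *target bending*
U₁\* = (Ĥ₂ + ∫ₛᴸH₂)/B_a, U₂\* = −(Ĥ₁ + ∫ₛᴸH₁)/B_a: the rod-free axoneme
minimizes its energy exactly at U = U\*.  The inverse map
(H₁ = B_a ∂ₛU₂\*, Ĥ₁ = −B_a U₂\*(L), H₂ = −B_a ∂ₛU₁\*, Ĥ₂ = B_a U₁\*(L))
lets actuation be prescribed as a waveform.  Tip forces are kept as scalars
and handled analytically in boundary conditions and tail integrals — never
as grid deltas.  The sign of the active-energy functional is fixed by
variational consistency with the balance equations: the active energy equals
−B_a ∫ U·U\* ds, so the total energy is stationary at the equilibria and the
actuation that drives a circular arc (H₁ = 0, Ĥ₁ = −B_aK) lowers the energy
of that arc by B_aK²L relative to bookkeeping that would make the motors do
negative work.  (The conjugate-pair sign convention linking the resultants to
per-doublet motor forces is internal to the model; only this choice makes the
energy, the balance equations, and the target-bending decomposition agree.)

**Paraflagellar rod.** A passive shear-elastic rod attached along the
axonemal surface at angle φ_p (≈ −2π/9 in *E. gracilis*; sign and embedding
conventions below).  Its cross-section frame is slaved to the axoneme: g₁ is
the outer surface normal at φ_p, g₂ follows the tangent of the *material*
section (the curve of equal-arclength points across doublets) — this is how
microtubule sliding rotates the PFR cross sections.  Of its strains, the
in-plane shear V₂ ≈ −sin φ_p γ₁ + cos φ_p γ₂ dominates (V₁ and the stretch
V₃ are O(ρ) and dropped; the exact strains remain available as diagnostics);
bending and twist stiffness of the rod are neglected (they scale with the
fourth power of its radius).  PFR energy: ½∫ D_p V₂² ds.  The stiffness
ratio ν = D_p/(B_a L⁻²) is the control parameter.

**Equilibria.** δW = 0 gives B_a U′ − H_⊥ − D_p(e_p⊗e_p)∫₀ˢU = 0 with
C_a U₃′ = 0, B_a U(L) = −Ĥ_⊥, U₃(L) = 0, where U = (U₁,U₂),
e_p = (cos φ_p, sin φ_p), H_⊥ = (−H₂, H₁).  Twist decouples from actuation:
U₃ ≡ 0 always.  Torsion therefore reduces to the rotation rate of the
bending vector, τ = ∂ₛψ + U₃ with U₁ + iU₂ = κe^{iψ}.  For planar actuation
(H₂ = Ĥ₂ = 0, H₁ ≠ 0) the equilibrium is planar iff φ_p ∈ {0, π/2, π, 3π/2}:
otherwise the confinement of U to a line is incompatible with the rank-1
PFR term, and torsion with both signs appears — the structural-incompatibility
mechanism.  As ν grows, the U-trace migrates from the U₁ = 0 line toward the
line orthogonal to e_p (monotonically in the mean projection |e_p·U|/|U|).

**Dynamics.** Linearized force balance under local (resistive force theory)
drag: μ_⊥∂ₜU = −B_a∂ₛ⁴U + ∂ₛ³H_⊥ + D_p(e_p⊗e_p)∂ₛ²U, and
μ_r∂ₜU₃ = C_a∂ₛ²U₃ with zero forcing, with distal conditions
B_aU(L) = −Ĥ_⊥ and (B_a∂ₛU − H_⊥ − D_p(e_p⊗e_p)∫₀ˢU)|_L = 0, and proximal
force/moment conditions (B_a∂ₛ²U − ∂ₛH_⊥ − D_p(e_p⊗e_p)U)|₀ = 0,
(B_a∂ₛ³U − ∂ₛ²H_⊥ − D_p(e_p⊗e_p)∂ₛU)|₀ = 0.  The printed distal twist pair
(U₃ = ∂ₛU₃ = 0 at s = L) over-determines the second-order twist equation; we
impose U₃(L) = 0 with a torque-free base ∂ₛU₃(0) = 0 — immaterial, since
U₃ ≡ 0 is the attractor either way and the beat is twistless after a
transient.

**Swimming.** The converged beat (computed with a clamped base, the
trapped-cell viewpoint) is attached to a prolate ellipsoidal body.  At each
phase the 6×6 grand resistance (classical prolate-spheroid drag factors for
the body + RFT integrals for the frozen flagellar shape, symmetric positive
definite) balances the drag of the shape change; the per-beat pose increment
of a periodic beat is a fixed screw transformation, so the path is a
generalized helix along which the body completes exactly one rotation per
helix turn — an identity of screw composition that the package measures from
the integrated path rather than assuming.

## Numerics

* **Frame integration.** Per-cell exact rotations generated by the
  cell-averaged strain vector (matrix exponential via rotation vectors),
  with the matching closed-form helix chord for the centerline; preserves
  frame orthonormality to ~10⁻¹³ and is second-order accurate.  The inverse
  map uses centered differences (one-sided, second-order at the ends).
* **Torsion.** From strains: the quotient form
  ψ′ = (U₁U₂′ − U₂U₁′)/κ², not the derivative of the unwrapped angle — a
  planar inflection makes ψ jump by π within one cell while the quotient
  stays exact (and exactly zero for planar fields).  From centerlines: the
  vector forms κ = |r′×r″|/|r′|³, τ = det[r′,r″,r‴]/|r′×r″|², after
  uniform arc-length resampling; right-handed helices have τ > 0.  Torsion
  is reported only where κ exceeds a floor (default 10⁻³/L; undefined at
  inflections).  Beat kymographs use a floor of 10% of the beat's peak
  curvature instead, because τ ~ 1/κ diverges at the near-inflection nodes
  where the bending plane flips; a beat-scaled floor keeps the
  alternating-peak signature and its tracking well defined.
* **Equilibrium solver.** The substitution G = ∫₀ˢU turns the balance into a
  linear two-point BVP, solved by adaptive collocation
  (`scipy.integrate.solve_bvp`, tolerance 10⁻⁹); U = G′ is read off the
  collocation state, with no numerical differentiation.  ν = 0 is handled
  exactly by quadrature of the target bending.  An independent semi-analytic
  oracle decomposes G along e_p/e_p^⊥: double quadrature for the
  perpendicular part, sinh/cosh homogeneous solutions plus a
  variation-of-parameters particular solution (cumulative Simpson) for the
  parallel part.  The two routes agree to better than 10⁻⁶ relative at
  n = 400 across ν ∈ [0, 100]; a plain second-order finite-difference
  discretization cannot reach that (its truncation carries (2π)⁴-scale
  fourth derivatives), which is why collocation was chosen.
* **Quadrature.** Cumulative trapezoid for the sliding integrals (consistent
  with the second-order strain stencils); cumulative Simpson for the
  target-bending tail integrals, whose output feeds third-derivative
  operators downstream.
* **Dynamics.** Method of lines: centered stencils, fourth order in the deep
  interior and second order on the single row bordering each boundary block;
  boundary conditions occupy the two rows nearest each end, with sixth-order
  one-sided stencils (wavelike solutions carry (2π)⁵⁻⁷-scale derivatives, so
  boundary stencil order — not the interior — limited the global error at
  lower orders).  The distal integro-bracket uses the same trapezoid as the
  statics.  Time stepping is Crank–Nicolson with the boundary rows imposed
  at the new time level and two backward-Euler startup steps (the CN
  right-hand side applies the stiff generator to the initial data, which
  would amplify boundary-inconsistent or rough initial conditions); the
  twist relaxation uses backward Euler throughout.  Energy of unforced
  solutions is non-increasing for any step size; static actuation reproduces
  the equilibrium solver to < 10⁻⁴ relative at n = 256.
* **Defaults (study conditions).** Nondimensional units B_a = L = μ_⊥ = 1
  (time unit μ_⊥L⁴/B_a).  φ_p = −2π/9, ν = 3, target amplitudes
  A₀L = 2, A₁L = 2.5 (a visibly asymmetric, wave-bearing target; the
  amplitudes are modeling choices with no canonical values), one wavelength, actuation
  period set by the sperm-number-like group (μ_⊥(2π/T)L⁴/B_a)^{1/4} = 3
  (wave-like viscous regime), n = 256 nodes, 400 steps per period, 8
  periods with a last-two-periods relative L² mismatch below 10⁻³ as the
  periodicity criterion.  Drag: μ_∥/μ_⊥ = ½, μ_r = 10⁻³ (slender-body
  order of magnitude).  Body: semi-axes (1, 0.2, 0.2)·L, viscosity chosen
  so slender-body theory is consistent with μ_⊥ (η ≈ 0.46 nondimensional),
  attachment at the anterior pole with the base tilted 30° from the body
  axis.  All defaults are config-overridable.
* **Torsion-dipole fixture.** Three constant-curvature arcs whose bending
  plane ramps by +θ then −θ.  Each impulse is smeared over 8 grid cells
  (parameter): a one-cell jump is not recoverable by centered differences —
  its discrete torsion integral converges to ~92% of θ at any resolution —
  while an 8-cell ramp restores the integral to O((θ/8)²).

## Synthetic data and what the tests do not show

All inputs are generated: actuation waveforms are idealized smooth targets
(a mean curvature plus one traveling sine), fixtures are exact helices,
circles, torsion dipoles and planar beats.  Real reconstructed flagellar
waveforms carry tracking noise, non-uniform sampling, amplitude modulation
along the flagellum and beat-to-beat variability, none of which the
generator emulates; passing tests therefore validate the mechanics and the
discrete geometry pipeline, not robustness to measurement error.  Dynein
actuation is prescribed, not self-organized: the model cannot predict beat
frequencies or amplitudes, only the shape family that a given actuation
produces.  The beat is computed for a clamped base and not re-coupled to the
swimming motion (kinematic decoupling), and no body–flagellum or wall
hydrodynamic interactions are included.

## Chirality

Mirroring φ_p mirrors every result (the swim helix flips handedness
exactly).  The absolute handedness reported for the default parameters
depends on how the electron-microscopy frame convention (doublets numbered
clockwise seen from the distal end, d₁ toward doublet 2) is embedded in a
right-handed lab frame — a convention the model equations alone do not fix.
With this package's embedding and φ_p = −2π/9 the swimming helix is
left-handed; the chirally-invariant statements (one body rotation per turn,
alternating torsion signs, base-to-tip peak travel) are unaffected.

## Known limitations

* Linear (small-rotation) dynamics: the beat equations are valid for
  moderate curvature amplitudes; shapes are reconstructed a posteriori by
  exact frame integration, which can exaggerate large-amplitude features
  the linear dynamics was not entitled to.
* The equilibrium energy is assembled from independent quadrature routes;
  its discrete gradient at the collocation solution vanishes only to O(h²)
  (≈10⁻⁵ relative at n = 400), not to machine precision.
* Peak tracking follows the single dominant extremum of each sign per
  phase; beats with several comparable peaks per sign would need the full
  kymograph rather than the track summaries.
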