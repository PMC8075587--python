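# lassobeat

Mechanics of the *Euglena gracilis* flagellum: an active axoneme elastically
antagonized by the paraflagellar rod (PFR).

Unlike *Chlamydomonas* or sperm flagella, the euglenid flagellum beats in a
strongly non-planar pattern ("spinning lasso") whose geometric signature is a
pair of torsional peaks of alternating sign traveling from base to tip.
`lassobeat` implements a mechanical model in which this pattern emerges from
structural incompatibility between two components:

* the **axoneme** (Ax), an active Kirchhoff-type rod described by bending
  strains U₁, U₂ and twist U₃ of a material frame **d**₁, **d**₂, **d**₃,
  with passive energy ½∫ B_a(U₁² + U₂²) + C_a U₃² ds, driven by dynein shear
  forces H₁, H₂ (plus concentrated tip forces Ĥ₁, Ĥ₂) that act through the
  collective microtubule sliding γ₁ = ∫₀ˢU₂, γ₂ = −∫₀ˢU₁;
* the **PFR**, a passive shear-elastic rod glued to the axonemal surface at
  angle φ_p from the spontaneous bending plane, with energy
  ½∫ D_p(−sin φ_p γ₁ + cos φ_p γ₂)² ds.

Static equilibria solve the integro-differential torque balance

    B_a U′ − H_⊥ − D_p (e_p ⊗ e_p) ∫₀ˢ U = 0,   C_a U₃′ = 0,
    B_a U(L) + Ĥ_⊥ = 0,   U₃(L) = 0,

with U = (U₁, U₂), e_p = (cos φ_p, sin φ_p), H_⊥ = (−H₂, H₁).  Equilibria are
always twistless (U₃ ≡ 0), so centerline torsion τ = ∂ₛψ comes entirely from
rotations of the bending vector U = κ e^{iψ}.  The control parameter is
ν = D_p/(B_a L⁻²): for φ_p not a multiple of π/2 — in *E. gracilis*
φ_p ≈ −2π/9 — any planar actuation yields a non-planar shape.  The dynamic
beat follows the linearized elastohydrodynamics
μ_⊥ ∂ₜU = −B_a ∂ₛ⁴U + ∂ₛ³H_⊥ + D_p (e_p⊗e_p) ∂ₛ²U under resistive-force-theory
drag, and swimming couples the beat to a prolate cell body through the
force-free, torque-free RFT balance.

## Worked example

```sh
python examples/02_beating_flagellum.py
```

prints (exact numbers from a run of this repository):

```
with rod  converged=True (mismatch 6.9e-04)  tau*L range [-25.7, +24.1]  peak tracks: 2  speeds ['+12.4', '+12.7']
rod-free  converged=True (mismatch 8.1e-04)  tau*L range [+0.0, +0.0]  peak tracks: 0  speeds []
```

With the PFR attached (ν = 3, φ_p = −2π/9) the converged beat carries both
positive and negative torsion peaks (τ·L spanning roughly ±25) whose tracked
positions travel toward the tip at ≈ the actuation wave speed (L/T ≈ 12.9) —
the spinning-lasso signature.  The PFR-free control under identical forcing
is exactly planar.  The other examples cover the static equilibria
(`01_static_equilibrium.py`), the helical swimming path with its
one-body-rotation-per-helix-turn identity (`03_swimming_cell.py`), and the
curvature/torsion analysis of 3D waveform files
(`04_torsion_from_waveforms.py`).

A thin CLI wraps the same pipelines:

```sh
lassobeat equilibrium --config cfg.yaml --out out/eq
lassobeat dynamics    --config cfg.yaml --out out/beat
lassobeat swim        --config cfg.yaml --out out/swim
lassobeat torsion waveforms.csv --out torsion.csv --normalize
lassobeat fixtures helix --out fixtures/helix
```

Configs are YAML with nondimensional defaults; an empty config reproduces the
euglenid reference setting (φ_p = −2π/9, ν = 3, sperm-number group 3).

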