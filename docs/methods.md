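# Methods

## The model

A tubular knitted compression textile worn on a leg is treated as a thin
orthotropic membrane whose hoop (course) direction carries the load. With
relaxed tube circumference `C_F = 2πR_F` and worn circumference `C`, the
wear strain is `ε = (C − C_F)/C_F` (floored at zero — a slack tube exerts
nothing), the tension per unit length is `T = E_F ε h`, and Laplace's law
gives the interface pressure as tension times curvature, `P = T·κ`. For a
circular section `κ = 2π/C`; for irregular sections the local pressure
profile `P(s) = T·κ(s)` uses a discrete three-point curvature estimate,
clipped to radii in `[10⁻⁴, 10]` m so locally flat scan segments produce a
finite minimum pressure instead of zero.

The leg is homogeneous and isotropic. Soft tissue is neo-Hookean
(`C10 = S/2`, `D1 = B/2`, with shear and bulk moduli from the standard
linear isotropic relations; `D1 = +∞` flags the incompressible ν = 0.5
default). Tissue stiffness comes either from preset levels — 0.0014,
0.0022, 0.0030 MPa, spanning the physiological muscle range — or from
shear-wave elastography readings via `E_S = 3ρ_m v²` with
ρ_m = 1000 kg/m³. Rigid mannequins default to a printed-polymer modulus of
3 GPa with ν = 0.3.

## Worn equilibrium

The dynamic donning process is not simulated; pressure testing reads out
the worn steady state, so the solver computes it directly as a damped
fixed point on the worn girth:

    ε(C) → T → P = 2πT/C → w = λP → C ← C₀ − 2πw

`λ` is the foundation compliance. The Hertz foundation takes
`λ = (k_s + k_F)·π·a₀/4`, the Hertz surface displacement per unit pressure
at the contact-patch scale `a₀` (default 0.02 m, configurable); a Winkler
bed `λ = 1/K` is available for sensitivity analysis. Rigid legs
(rigidity flag, or any tissue at or above 1 GPa) take `λ = 0`: a mannequin
does not indent, and the solve reduces exactly to the closed form
`P = 2πE_F h (1/C_F − 1/C₀)`.

Numerical choices. The fixed-point map has derivative
`|g'| = 2πλ·2πE_F h/C²`, which exceeds 3 at the stiffest class III
fabrics on the softest, smallest legs; under-relaxation with damping
d = 0.35 keeps `|1 − d + d·g'| < 1` over the whole synthetic parameter
envelope (d is configurable; 100 seeded corner cases converge in under
40 iterations at the default 10⁻⁸ relative girth tolerance).
Non-convergence is flagged on the result, not raised. Degenerate inputs:
slack garments return a zero-pressure converged result; strains above the
80% design stretch band are computed but warned about, since the linear
fabric law is extrapolating there.

Because the foundation lets the leg yield, the solver predicts somewhat
lower pressures on softer legs (the indentation relaxes the hoop strain).
The magnitude of that effect scales with the arbitrary patch radius `a₀`;
absolute soft-leg indentations should therefore be read as
order-of-magnitude (they land in the low millimetres, 2–8 mm over the
cohort corners). The stiffness-insensitivity result below does not depend
on `a₀`.

## The pressure-diversity identity

The Hertz contact chain for one fabric–leg element uses the elastic
mismatch factors `k = (1 − ν²)/(πE)`:

    a = [3πF(k + k_F)·R·R_F / (4(R + R_F))]^(1/3)
    q = 3F/(2πa²)          (unit pressure)
    w(r) = (k + k_F)·(πq/4a)·(a² − r²)
    P = F/(2πa²)           (so q/P = 3 identically)

The displacement formula is implemented in the dimensionally consistent
form above (Pa⁻¹·Pa/m·m² = m); its full-contact value at the centre is
`w(0) = (k + k_F)πqa/4`. `P = F/(2πa²)` — half the conventional mean
contact pressure — is kept as defined; `mean_pressure = F/(πa²)` is
provided but unused.

The rigid-vs-soft pressure-diversity ratio is
`ΔP = (w_r/w_s)·(k_s + k_F)/(k_r + k_F)`. Since `w(0) ∝ (k + k_F)` at
matched `(q, a)`, the two ratios cancel and `ΔP = 1` to machine precision
for any pair of tissue stiffnesses: tissue stiffness moves the
indentation, not the delivered pressure. The pipeline evaluates this
chain at the per-element load `F = P·πa₀²` implied by the solved
interface pressure. This identity — not the foundation solver — is the
package's statement about stiffness insensitivity, and it is what the
statistics battery tests on the synthetic cohort.

## Synthetic cohort

The generators emulate a three-subject, two-class (I and III),
four-position pressure study, with all randomness fanned out from one
root seed by stable spawn keys (adding a subject never perturbs earlier
subjects).

* **Legs** — four labelled sections (B at 4 cm through D at 35 cm) as
  Fourier-perturbed ellipses (modes 2–4, total radial perturbation ≤ the
  `irregularity` parameter, default 0.1), scaled exactly to girths drawn
  per position: ankle 20–24 cm, B1 26–30 cm, calf 33–38 cm. The
  below-knee girth is drawn in [0.93, 1] × the calf girth, since D sits
  just below the calf bulge; the ankle girth is constrained at or below
  the calf girth.
* **Garments** — designed to pressure, the way standardized graduated
  hosiery is knitted: a target ankle pressure is drawn inside the class
  band (I: 18–21 mmHg; III: 34–40 mmHg, the mid-band where measured
  class III sets sit), tapered by degressive factors (B1 0.82, C 0.70,
  D 0.62 — matching reported below-knee/ankle ratios ≈ 0.64), and the
  rigid Laplace law inverted for the per-position wear strain and tube
  radius. One course modulus per garment (one yarn lot) is drawn from the
  feasible part of the class envelope (I: 0.33–0.38 MPa, III:
  0.33–0.76 MPa); if even the stiffest class fabric cannot reach the
  target inside the 15–80% stretch band, the whole profile is scaled
  down, preserving its shape. Thickness, Poisson ratio, mass density,
  wale and shear moduli are drawn inside the measured reference
  envelopes.
* **SWE readings** — per-site moduli `E_true·(1 + cv·z)` with standard
  normal `z` (clipped to stay positive), converted to velocities
  `v = √(E/3ρ_m)`; sites alternate between the ankle and calf windows.
  `cv` is defined on the modulus scale — the quantity the elastography
  map reports — so the mean-modulus estimate over n sites recovers
  `E_true` with relative error ~`cv/√n` (noise on the velocity scale
  would double the modulus error through squaring).
* **Pressure sensor** — uniform ±3 mmHg noise (the stated precision of
  pneumatic interface sensors; the precision statement does not fix a
  distribution, and a Gaussian alternative is configurable), floored at
  zero, rounded to the 1 mmHg instrument resolution.

What the generators do *not* emulate: real scanned morphology (bony
prominences, non-convex contours), heterogeneous tissue layers, fabric
viscoelasticity and wear history, sensor placement error. Passing tests
therefore demonstrate the internal consistency of the mechanical chain
and the statistical behaviour under the declared noise model — not
agreement with any particular subject.

## Comparison study and statistics

`run_comparison` solves, per subject × class × position: the rigid
mannequin arm (P_LM), an instrument-noise reading of it (the measured
arm), and each soft-tissue level (P_LS), then pushes the rigid/soft pairs
through the ΔP chain. Statistics per class: per-position DRO
(`|P_ref − P_sim|/P_ref·100`) with its mean, Shapiro–Wilk normality
(restricted to 3 ≤ n ≤ 50, the small-sample regime the test is meant
for), Pearson correlation of measured vs simulated, and pairwise paired
*t* tests across the stiffness levels with Bonferroni correction by the
number of comparisons actually run. All tests are two-sided at α = 0.05.
The stiffness comparison is run on stiffness-matched true pressures (the
ΔP = 1 physics) read independently through the instrument model per
level, so any detected "stiffness effect" is a false positive of the
noise; with three Bonferroni-corrected pairwise tests the family error is
bounded by α, and the long-run fraction of clean realisations measures
≈ 0.955 at n = 48 per group.

Problem sizes: the default cohort is 3 subjects × 2 classes ×
4 positions (mirroring the reference study layout; the stiffness screen
uses 12 subjects × 4 positions = 48 per group), 10⁴ random draws for the
ΔP identity, 200 Monte-Carlo draws for SWE recovery, and 100 noise
realisations for the significance screen.

## Known quirks and limitations

* The bundled reference SWE table's S1 mean is recorded as 0.002040 MPa
  while the plain mean of its two regional values is 0.002060 MPa;
  `mean_swe_modulus` computes the plain mean and does not special-case
  the row. (S2 and S3 means match exactly; S2's 0.002976 is the
  round-half-up of the exact 0.0029755.)
* `P = F/(2πa²)` is half the conventional Hertz mean pressure; it is kept
  as defined because the ΔP analysis only ever uses ratios, where the
  factor cancels.
* The solver's absolute soft-leg pressure reduction is a model artefact
  of the foundation coupling (scale set by `a₀`), not a prediction the
  ΔP analysis supports; use it for sensitivity, not calibration.
* Single homogeneous tissue, no bones or veins, uniform circumferential
  indentation, frictionless normal-only contact, linear elastic fabric:
  all inherited simplifications of the quasi-static membrane model.
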