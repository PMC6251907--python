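# Methods note

This note records the modeling choices behind `mitralmech`: what each model
assumes, where its default parameters come from, what the synthetic
generators do and do not emulate, and the numerical decisions that affect
results. Everything quantitative stated here is computed by the package
itself (tests or `scripts/acceptance.py`); nothing is an external empirical
claim.

## 1. Leaflet constitutive model

The leaflet is a nearly incompressible, anisotropic hyperelastic solid with
two symmetric collagen-fiber families. The strain energy is

W(F) = C10·[exp(C01·(Ī₁ − 3)) − 1]
     + k1/(2·k2) · Σᵢ₌₁,₂ [exp(k2·⟨κ·Ī₁ + (1 − 3κ)·Ī₄ᵢ − 1⟩²) − 1]
     + (1/D)·(J − 1)²,

where Ī₁ and Ī₄ᵢ = mᵢ·C̄·mᵢ are invariants of the deviatoric right
Cauchy–Green tensor C̄ = J^(−2/3)·FᵀF, κ ∈ [0, 1/3] is fiber dispersion
(κ = 1/3 recovers isotropy), and ⟨·⟩ denotes the tension-only switch: a
fiber family contributes only while its dispersed stretch measure is
positive, reflecting that wavy collagen bears no compressive load.

The analytic second Piola–Kirchhoff stress follows from the isochoric chain
rule,

S = 2·ψ₁·(J^(−2/3)·I − (Ī₁/3)·C⁻¹)
  + 2·Σᵢ ψ₄ᵢ·(J^(−2/3)·mᵢ⊗mᵢ − (Ī₄ᵢ/3)·C⁻¹)
  + (2/D)·(J − 1)·J·C⁻¹,

and the Cauchy stress is σ = J⁻¹·F·S·Fᵀ. Correctness is checked
continuously: `material-eval` and the test suite compare the analytic first
Piola–Kirchhoff stress P = F·S against a central finite-difference gradient
of W over random admissible deformation gradients (F = I + 0.25·N(0,1),
det F > 0.1, step h = 10⁻⁶·max(|F_ij|, 1)). The observed worst relative
error is ~10⁻⁹, against a tolerance of 10⁻⁵.

Example parameter set (`EXAMPLE_LEAFLET_PARAMS`): C10 = 0.05 MPa,
C01 = 10, k1 = 1 MPa, k2 = 5, κ = 0.1, D = 0.02 MPa⁻¹, fiber angle ±40°.
These are representative of the stiffening, strongly anisotropic response of
mitral leaflet tissue in the model's MPa/mm/N unit system; they are example
values for exercising the code, not a fit to any particular specimen.

## 2. Chordal tissue and network

### Material

Chordae follow an incompressible one-dimensional Ogden law,
W = Σ_p (2μ_p/α_p²)(λ₁^{α_p} + λ₂^{α_p} + λ₃^{α_p} − 3), giving the uniaxial
nominal stress P(λ) = Σ_p (2μ_p/α_p)(λ^{α_p−1} − λ^{−α_p/2−1}). The
convention is fixed by the one-term α = 2 case, which must reduce to the
neo-Hookean μ·(λ − λ⁻²) — a unit test pins this. Chord axial force is
nominal stress × undeformed cross-sectional area (MPa·mm² = N) and is
clamped to zero for λ ≤ 1.

Default cross-sectional areas per group: marginal 0.38 mm², strut 2.05 mm²,
basal 0.71 mm².

### Geometry

The network geometry is deliberately idealized: a D-shaped elliptical
annulus (semi-axes 19 × 15 mm), two papillary-muscle tips 22 mm below the
annular plane at the anterolateral and posteromedial positions, and chords
laid out by group-specific radial insertion fractions and angular spans over
the six scallops (A1–A3, P1–P3; the posterior scallops occupy fixed angular
sectors). The chord census is fixed: 17 papillary-muscle origins and, per
(group, papillary muscle): anterior marginal 8/6, anterior strut 3/4,
posterior marginal 7/6, posterior intermediate 7/1, posterior basal 5/6.
Each chord is discretized into at most 10 segments targeting 1.5 mm length;
a refinement-invariance test confirms tensions are insensitive to this
resolution.

### Rupture scenarios

Seven named scenarios besides control: isolated marginal+intermediate
rupture of P1, P2 or P3; partial ruptures (P2 plus the adjacent half of P1
or P3, split by insertion angle about the neighboring scallop's midline);
and total ruptures of P2+P1 or P2+P3, which additionally remove basal
chords of both scallops.

### Solver

Static equilibrium of the pinned tension-only truss is found by damped
Newton iteration:

- 10 uniform load steps; residual tolerance 10⁻⁸ × total applied load.
- Analytic tangent k_ax·ddᵀ + (T/ℓ)(I − ddᵀ) per segment; at λ = 1 exactly
  the tension-side modulus is used.
- Slack segments (λ < 1) carry a fictitious stiffness of 10⁻³ × their
  unit-stretch modulus, and a 10⁻⁸ transverse regularizer enters the
  Jacobian only — the residual is exact, so converged solutions satisfy the
  true equilibrium equations.
- A trust-region step cap (max nodal displacement increment 1.0 mm) keeps
  Newton stable through the large rigid rotations that follow rupture.
- Failure modes raise typed errors (`SingularityError`, `ConvergenceError`
  with residual history) rather than returning garbage.

Verification computed by the package: papillary-muscle reactions balance the
applied loads to ~10⁻⁹ relative; a symmetric two-chord "V" at half-angle θ
reproduces the closed form T = F/(2cosθ); force-distribution table rows sum
to 100 % to within 10⁻¹³.

Loads default to pressure × 20 mm² tributary area per insertion, directed
along the chord; this is a loading idealization, not a leaflet model.

## 3. Hemodynamic quantification

- The systolic window is detected from aortic flow: first strictly positive
  sample to the return to q_av ≤ 0.
- The reference closure time t_close is the control beat's first upward zero
  crossing of mitral flow after the retrograde closing wave, located by
  linear interpolation between samples.
- Closing volume integrates −min(q_mv, 0) from retrograde onset to t_close;
  leakage volume integrates it from t_close to the end of systole. Window
  endpoints are handled by interpolating the integrand, so the split is
  exactly conservative: closing + leakage = RV_MV.
- All quadrature is trapezoidal (`numpy.trapezoid`); a convergence test
  confirms the expected second-order behavior.
- Grading: mild < 30 %, moderate 30–50 %, severe > 50 % regurgitant
  fraction, plus a binary category at the 50 % threshold.

## 4. Energetics

- Stroke work is the shoelace (signed polygon) area of the sampled PV loop,
  converted at 1 mmHg·ml = 1.33322 × 10⁻⁴ J. Counter-clockwise orientation
  in (V, P) is positive; a clockwise loop is corrected with a
  `RuntimeWarning` rather than silently returning negative work.
- The end-systolic point is the sample maximizing p/(v − v0), the standard
  maximal-elastance proxy; v0 (the zero-pressure volume intercept) defaults
  to 0 ml, which makes PE = ½·p_es·v_es an upper-bound convention — callers
  with a calibrated intercept should pass it.
- Forward stroke work ∫max(q_av, 0)·p_ao dt requires a simultaneous flow +
  aortic-pressure record; PVA = PE + SW and efficiency = 100·fSW/PVA are
  assembled in `summarize_energetics`, with the PVA identity asserted.
- Efficiency here is *mechanical* transfer efficiency (useful aortic work /
  total mechanical energy), not metabolic efficiency — no oxygen-consumption
  model is included.

## 5. Synthetic waveform generator

### What it emulates

One cardiac cycle starting at systole, at default 75 bpm (0.8 s). Aortic
flow is a sin² pulse whose duration follows from the stroke-volume target
and peak flow (T_sys = 2·SV/peak; 0.281 s at the 58.22 ml / 414 ml/s
defaults), with a small end-systolic backflow pulse (default 4.27 ml).
Mitral flow has an E/A diastolic filling pattern (two Gaussians, default
E/A ratio 1.5), a retrograde closing spike at systole onset with shape
sin(πu)·e^(−2u) (default 8.65 ml over 60 ms) followed by a 0.02 ml positive
rebound blip — which provides the upward zero crossing the closure detector
keys on — and, for regurgitant beats, a trapezoidal leak plateau (10 ms
ramps) through systole. Optional pressures: constant or v-wave left atrium,
120/80 aortic. Optional additive Gaussian noise, off by default.

Every pulse is normalized *on the sampling grid* (its discrete trapezoidal
integral is scaled to the target volume), so injected volumes are exact
under the same quadrature the analysis uses; the recovery tests' 1 %
tolerance then measures window-detection error, not quadrature error.
Ground truth is returned alongside the record. The severity sweep
(`gen_severity_suite`) conserves total LV stroke volume by default, so leak
volume displaces forward volume — this is what makes regurgitant fraction
strictly increasing and efficiency strictly decreasing along the sweep.

### What it does not emulate

No chamber elastance or circulation model — pressures and flows are
independently shaped, not coupled through a circuit; no valve dynamics
(closure timing is imposed, not emergent); no beat-to-beat variability,
respiration, or arrhythmia; PV loops (`gen_pv_loop`) are geometric
(rounded-corner or rectangular) rather than simulated. The generator exists
to provide controlled, exactly-known inputs for the analysis pipeline, not
to predict patient hemodynamics.

## 6. Replay of reported component volumes

`published.py` ships one table of *inputs*: per-scenario aortic regurgitant,
mitral closing, mitral leakage and forward stroke volumes for the control
and seven rupture configurations. Everything derived — RV_MV, LVSV,
regurgitant fraction, grades, the severity ordering — is recomputed by the
hemodynamics code at call time. One internal consistency check is ledgered
in the development notes: for the total P2+P3 scenario the component
volumes imply RV_MV = 47.29 ml (RF 69.80 %); the package always reports the
value derived from components.

## 7. Determinism and problem sizes

All stochastic code paths take explicit seeds (`numpy.random.default_rng`);
CLI outputs embed a config hash, and byte-identical reproduction is tested.
Problem sizes used in verification (100 random deformation states, 20
random generator configurations, 3 scenario solves in the acceptance
script, ~170-node networks) are this package's own choices, balancing
coverage against a few-second runtime.

## 8. Limitations

- The chordal network is a static truss under idealized insertion loads;
  there is no leaflet membrane, no contact/coaptation mechanics, and no
  fluid coupling, so chordal tensions are comparative across scenarios, not
  patient predictions.
- The leaflet law is implemented and verified pointwise but is not coupled
  to the network; `region_average` and the stress utilities operate on
  user-supplied deformation fields.
- Hemodynamic quantification assumes a single clean systole per record and
  a control beat (or explicit t_close) for the closing/leakage split.
- The v0 = 0 default biases PE (and hence PVA) upward; efficiency values
  should be compared within a consistent v0 convention.
- Grading thresholds are fixed constants; no uncertainty is propagated.
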