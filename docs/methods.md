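# Methods

This note records the models behind `dipchar`, the assumptions they make,
the numerical choices that matter, and what the simulation-backed test
results do and do not establish about hardware behaviour.

## In-fluid compression metrology (`mechtest`)

**Model.** A construct printed at the meniscus is compressed in place by the
print head while submerged in unpolymerized resin. The measured load is the
sum of a structural term and a hydrostatic term that is linear in stage
height z over the travel range (the print head displaces fluid volume
proportionally to its immersion depth). The chain is:

1. *Calibration.* The load cell reports 24-bit ADC counts. A least-squares
   affine fit of calibration-mass data gives `mass_g = α·(D − β)` with α in
   g/count and β the zero-load count bias; force is `F = g·α·(D − β)·10⁻³` N.
   A held-out mass is checked against the fit at 0.05 % of full scale, the
   linearity of the sensor class.
2. *Hydrostatic regression.* Before printing, a no-contact vertical sweep —
   by default spanning 25 % of the container height — is regressed as
   `F̂(z) = β̂₀ + β̂₁z`. Since `β̂₁ ≈ ρ·g·A_p`, the formulation density ρ
   falls out given the wetted print-head cross-section `A_p`. Both this and
   the calibration fit are plain OLS; the test-suite pins them to the
   closed-form normal-equation solution.
3. *Subtraction.* `F_struct,j = F_meas,j − (β̂₀ + β̂₁z_j)` per sample. A
   `corrected` flag guards against double subtraction. For any trace
   constructed as structural + affine-in-z, the recovery is exact by
   construction, and `E_eff` is invariant to adding any affine-in-z term
   when the matching model is subtracted.
4. *Contact detection.* The measurement chain does not observe contact
   directly, so it is inferred from the corrected trace: the first index
   where |F| exceeds `k_σ·σ_noise` for `m` consecutive samples (defaults
   k_σ = 5, m = 5), with σ_noise estimated from the leading 10 % of samples
   when not supplied. The sustain requirement rejects single-sample spikes.
5. *Modulus.* Engineering quantities for a cylindrical footprint:
   `A₀ = π(D/2)²`, `ε = (z_contact − z)/H₀` (compression positive),
   `σ = F_struct/A₀`. `E_eff` is the OLS slope of σ on ε over the closed
   window [0.05, 0.10] — above contact nonlinearity, below
   geometry-driven effects such as buckling — with no smoothing. The
   estimate carries the window, the point count and R².

**Assumptions.** Linear elasticity inside the strain window; a hydrostatic
term that stays affine in z during compression; strain referenced to the
detected contact height. Viscoelasticity, cyclic loading and quantitative
buckling analysis are out of scope.

## Virtual material & printer (`photosim`)

The package must be testable closed-loop without a printer, so it ships a
simulator with three layers:

* **Kinetics.** Steady-state free-radical photopolymerization:
  `R_i = 2·f₀·φ·α·[PI]·I₀·e^{−α[PI]L/2}` evaluated mid-depth, and
  `R_p = k_p·[M]·√(R_i/2k_t)`. Only the scaling behaviour matters here
  (R_i linear in intensity, R_p ∝ √I₀); the default constants describe a
  generic dilute acrylate formulation.
* **Grayscale→modulus response.** Projected dose is linear in the 8-bit
  grayscale, `I₀(g) = (g/255)·I₀max`. The measured modulus is a saturating
  Hill function of the polymerization rate,
  `E(g) = E_sat·R_p(g)ⁿ/(half_rateⁿ + R_p(g)ⁿ)`, plus Gaussian noise with
  standard deviation `noise_sd_frac·E(g)`. The Hill link is an explicit
  stand-in for the unknown opto-mechanical response — it is *not* a claim
  about chemistry — chosen because it produces both near-linear and
  sigmoidal response regimes, the two shapes the optimizer must handle.
  Defaults: `E_sat` = 40 kPa, `half_rate` = R_p at g = 128, n = 4,
  2 % measurement noise. With these, moduli span ≈0–32 kPa over the
  printable grayscale range and a 25 kPa target sits mid-range on the
  sigmoid's upper shoulder.
* **Compression traces.** Raw force = hydrostatic background
  (`β₀ + β₁z` from a configurable `HydrostaticModel`; default ρ = 1000
  kg·m⁻³, A_p = 10⁻⁴ m²) + `A₀·E_true·ε` (optionally capped past a
  buckling strain) + Gaussian noise, with an approach segment before
  contact so detection and noise estimation are exercised. A no-contact
  density sweep is generated the same way.

One seeded `numpy` generator drives each simulation object; results are
reproducible for a fixed seed *and call order*.

**What the simulator does not emulate:** optical scattering in the resin,
dose cross-talk between layers, meniscus shape, viscoelastic creep during
the hold, thermal drift of the load cell. Passing the recovery tests
therefore demonstrates correctness of the estimation chain, not accuracy of
any physical prediction.

TPMS fixtures (gyroid, diamond, Split-P, and fluorite via Schoen's F-RD
level set) are voxelized from the standard implicit trigonometric equations
with 2/4/6 mm unit-cell presets. Voxel phases are reduced modulo the unit
cell so the thresholded grid is exactly periodic — without this, last-bit
phase differences flip voxels lying on the iso-surface.

## Stiffness seeking (`stiffseek`)

The loop treats each print-and-measure cycle as one oracle evaluation of an
unknown monotone response f(g) and seeks `|f(g*) − E_target|` minimal over
grayscale bounds [G_min, G_max] (from a print-fidelity sweep when
available, else [1, 255]).

Per iteration: evaluate → check convergence
(`|E_k − E_target|/E_target ≤ ε_tol`, boundary inclusive) → update the
gradient (mean finite-difference quotient over the most recent n admissible
pairs, EMA-smoothed) → bump confidence (`c ← min(1, c + Δc)`, only on a
successful gradient update) → propose the next grayscale.

Control is Newton-like, `g ← g + (E_target − E_k)/∇f`, when the gradient is
trusted (`c > c_min` **and** `|∇f| > ε`; the magnitude is two-sided since a
confidently negative slope is equally usable), else proportional,
`g ← g + λ(E_target − E_k)/E_target`. Decaying Gaussian exploration
`σ_k = σ₀e^{−k/τ}` is added, and proposals are clamped to the bounds rather
than resampled so the iteration count stays deterministic for a fixed seed.

Numeric defaults (all config-exposed; the loop's formulas fix none of
them): α = 0.5, Δc = 0.34 (Newton engages after two gradient updates),
c_min = 0.5, ε = 1 Pa/unit, λ = 30 grayscale units, σ₀ = 5, τ = 3,
n = 3, k_max = 20, ε_tol = 0.03 (within the <5 % convergence band, matching
the 3–5 % accuracy the loop is expected to deliver), minimum admissible
pair spacing 0.5 grayscale units (smaller spacings amplify measurement
noise in the quotient).

Two deliberate mechanics beyond the update equations:

* *First iterations.* With fewer than two distinct-g evaluations no
  gradient exists; proportional control is used and confidence stays 0.
* *Bound-stall guard.* A noise-corrupted gradient can fling a Newton step
  onto a bound; once there, every new evaluation pair has Δg = 0, so the
  corrupted estimate could never be refreshed and a wrong-signed gradient
  would re-clamp to the same bound forever. A Newton step that would
  re-clamp onto the bound the loop already occupies therefore falls back to
  proportional control, which steps back into the interior. This closes the
  only deadlock the closed-loop simulations exposed.

Internally g is continuous; it is rounded to an integer only when emitted
to an 8-bit projection mask.

## Nodal grayscale fields (`grayfield`)

Each control node carries a position, an intensity `G_i ∈ [0, 255]` and a
decay constant `d_p > 0`. The default weight kernel is Gaussian,
`w_i(x) = exp(−‖x−p_i‖²/d_p,i)` — smooth everywhere including at the node,
which the plain-exponential alternative (`exp(−d/d_p)`, provided behind the
same interface) is not. The field is the multiplicative composition
`G(x) = G₀·∏(G_i/G₀)^{w_i}` over background G₀ (default 30, the minimum
grayscale that still prints resolvable features), clamped to 255 at
composition time because the raw product is unbounded for overlapping
bright nodes. Increasing any `G_i` never decreases the field anywhere;
with all `G_i = G₀` the decay constants have no influence at all.

**Units.** Node coordinates and `d_p` are expressed in *field units*; the
nine-node layout (eight nodes 25 % in from the corners, one at the centre)
spans its bounding box over 16 field units in the sweep harness. On that
scale the d_p = 30–50 sweep range traverses the transition from
quadrant-local influence (near-linear mean-field growth with G) to global
overlap (sigmoidal growth with an inflection), and the field is smooth
relative to a 16³ coarse grid.

**Two-stage evaluation.** Large fields are composed on a coarse grid and
upsampled by tri-cubic spline interpolation (endpoint-aligned grids, so
equal shapes reproduce direct evaluation exactly). Two details are load
bearing: interpolation runs on the *unclamped log-field* — the raw
composition is C∞ while the 255-ceiling introduces kinks a cubic stencil
overshoots — with the clamp applied afterwards (clamping is 1-Lipschitz, so
the error bound transfers); and the coarse grid is padded by 3 cells so the
fine domain is interior to the spline, eliminating edge-condition error.
The verified contract is ≤2 grayscale units maximum deviation from direct
evaluation at 4× upsampling over the d_p sweep range (measured ≈0.2).

Graded projection volumes are the voxel-wise product `V(x) = G(x)·I(x)`
with the binary geometry; quantization rounds ties-to-even to 8-bit slices.

## Layer-wise reconstruction QC (`lsrecon`)

The light sheet images `D_LS` = 500 µm below the projection plane to avoid
meniscus scatter, so recorded frame k shows the layer projected
`lag = D_LS/D_LH` layers earlier (10 at the 50 µm default pitch). The ratio
must divide exactly in a well-configured system; a remainder is rounded to
the nearest layer with a warning. Frames without a lagged ground-truth
counterpart are excluded from the mean and counted, not zero-filled.

*Frame synthesis* renders the lagged truth mask with depth-dependent
foreground attenuation, sheet-thickness blur, multiplicative speckle, a
smooth background gradient and additive sensor noise — enough structure to
exercise segmentation and scoring; it does not model real scattering
physics or refractive-index contrast.

*Segmentation* is a declared interface (frame in, binary mask out) so a
learned model can be plugged in without touching anything else. The
classical baseline: large-σ Gaussian background subtraction, an Otsu seed
refined by isodata iteration to the midpoint between class means (raw Otsu
can land inside the background cluster when the foreground is small), a
class-separation guard (foreground rejected when the class gap is below
2.5× the summed class spreads — an unstructured Gaussian frame produces a
gap of about 1.3×) so background-only frames yield empty masks, then
opening/closing *by reconstruction* and small-component removal.
Reconstruction-based morphology kills specks and pinholes while leaving
surviving object boundaries pixel-exact, which is why noiseless synthetic
frames segment exactly.

*Scoring.* Translation-only registration (phase cross-correlation peak,
integer pixels, shift capped; drift is the dominant misalignment between
projector and camera frames) followed by SSIM with an 11×11 Gaussian window
(σ = 1.5), standard stability constants, unit data range on binary-as-float
masks, clipped into [0, 1]. δ_struct is the arithmetic mean over scored
layers; identical masks score exactly 1. Although per-layer scores are
similarities (higher is better), the quantity is conventionally discussed
as a reconstruction "error"; this package reports it as a similarity.

## Problem sizes and runtime

The test-suite and acceptance script run entirely on synthetic data sized
for a single CPU: 20-seed batches for the recovery and convergence
statistics (60 replicates in the acceptance script for a stable median),
64³ voxel volumes for field-interpolation contracts, 64×64×24 frame stacks
for reconstruction. The full suite completes in a few seconds; the
acceptance script in about two.

## Known limitations

* The grayscale→modulus link and the light-sheet artefact model are
  constructed test harnesses; agreement there validates the algorithms,
  not material behaviour.
* Confidence in the seek loop never decreases, so a response with an abrupt
  regime change inside a run relies on the EMA and the stall guard rather
  than on confidence decay.
* Contact detection assumes a quiet pre-contact segment at the head of the
  trace; traces that begin in contact need an explicit `noise_sd`.
* The registration model is translation-only; rotation or scale drift
  between projector and camera is not corrected.
* Reading `d_p` in fine-voxel units on large grids makes the nine-node
  field too sharp for 4× coarse evaluation; use direct evaluation or a
  finer coarse grid in that regime.
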