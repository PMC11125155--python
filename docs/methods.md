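# Methods

`pdfshell` determines the structure of two-component (core–shell) spheroidal
surfactant micelles directly from a SAXS-derived pair-distance distribution
function P(r), without iterative curve fitting. This note records the model,
the numerical choices, and the limits of what the synthetic tests demonstrate.

## Model

A micelle is a uniform hydrophobic core — a spheroid of revolution with
equatorial half-size R_eq and polar half-size εR_eq (prolate ε > 1, oblate
ε < 1) — inside a uniform hydrated shell of thickness R_sh whose outer surface
is the spheroid with all semi-axes offset by R_sh. The core carries electron
contrast Δρ_E = ρ_core − ρ_buffer (negative for alkyl interiors) and the shell
Δρ_P = ρ_shell − ρ_buffer (positive for hydrated head groups). Volumes:
V_E = (4/3)π ε R_eq³, V_M = (4/3)π (R_eq+R_sh)² (εR_eq+R_sh).

Six structural unknowns describe the particle: D_M (overall size), R_sh, ε,
N_agg, Δρ_E, Δρ_P. Two come from the *graphical stage*, the remaining four
from an overdetermined *analytical stage*.

## Graphical stage

P(r) = r²γ(r), with γ the orientation-averaged autocorrelation of the excess
electron density. For core–shell profiles the first derivative dP/dr shows a
dominant maximum flanked by two minima. Operating rules:

* R_sh = (r_min_right − r_min_left)/4, or (r_peak − r_min_left)/2 for strongly
  asymmetric peaks (automatic switch above 25 % gap asymmetry). The doubled
  spacing (2R_sh, not R_sh) reflects the fluctuating thickness of the
  hydrophilic brush; an `ideal_spacing` flag exposes the rigid-interface
  halved divisors for box-autocorrelation arithmetic.
* D_max is read where |P| falls below 0.5 % of its maximum and *stays* below
  (skipping tail ripples), linearly interpolated between grid points.
  Because elongated particles approach zero with a high-order tangency, the
  plain crossing systematically undershoots; an optional power-law tail fit
  A(D−r)^m (window 0.2–4 % of the maximum, Poisson-type weights, m ∈
  [1.2, 8]) removes most of the bias and falls back to the crossing if it
  does not converge.
* Derivative smoothing is a Savitzky–Golay filter (default window 5 % of
  D_max, order 3). Extrema are accepted above a noise-adaptive prominence
  threshold (12× the high-frequency residual of the derivative, clipped to
  [0.5 %, 25 %] of its range): smooth indirect-transform output may carry
  genuinely shallow flanking minima, while finite-pair histograms need their
  wiggles suppressed. Local minima beyond the right flank are reported as
  `extra_minima` — the signature of an additional internal interface, e.g.
  drug loading.

Calibration caveat: on *sharp-interface* synthetic profiles the derivative
spacing overestimates R_sh by several Å when R_sh/D_max ≲ 0.12 (the spacing
is then dominated by micelle-scale structure, not the shell). All
experimental systems the method targets sit at R_sh/D_max ≈ 0.09–0.13 with
strongly smeared interfaces, where the doubled-spacing rule holds; the
pipeline additionally re-optimises R_sh (below) so the graphical value only
seeds a search window.

## Measured moments

R_PDF^n = ∫P(r)rⁿdr / (2ⁿ⁻¹∫P(r)dr) for n = 1, 2, 4, 6; r_g = √R_PDF²
(real-space radius of gyration); on absolute scale I(0) = 4π∫P dr (cm⁻¹).
Quadrature is the trapezoid rule on the native grid — bit-reproducible and
accurate to <0.1 % for the dense smooth profiles in scope. Moments integrate
to the estimated D_max plus a small pad so that pure-noise tail samples do
not enter the r⁶-weighted integral. The Shannon-channel count D_max·s_max/π
bounds the number of recoverable parameters (≈5–10 for typical curves, which
is why a six-parameter model is the practical ceiling).

## Model-side moments

The measured R_PDF^n equals the contrast-weighted pair moment
⟨|x₁−x₂|ⁿ⟩_w/2ⁿ⁻¹ of the particle. For the two-component spheroid these are
evaluated as:

* n = 2, 4, 6 — exact multinomial expansion of |x₁−x₂|ⁿ into products of
  single-body monomial moments of uniform ellipsoids (closed form, valid for
  general triaxial semi-axes).
* n = 1 — overlap-volume (correlation-function) representation
  ∫d³s |s| C(s). The same-shape terms (outer×outer, core×core) reduce to a
  closed form via an affine map to the unit ball; the outer×core cross term
  has no elementary closed form for displaced non-similar ellipsoids and is
  evaluated by nested Gauss–Legendre quadrature of circle–circle lens areas
  (48 points per dimension by default, relative error a few 1e-5; 32 points
  inside grid scans, still ~1e-4 — both far below measurement error).

A brute-force Monte-Carlo oracle (uniform pairs in the outer spheroid,
signed contrast weights, ratio estimator with a propagated standard error)
is the ground truth these expressions are tested against; it stays on plain
pseudo-random sampling precisely so that it is independent of the generator.

## Analytical stage

At fixed geometry (R_sh, D_max, branch, ε) the moments depend on the
contrasts only through η = Δρ_E/Δρ_P − 1, so the n = 2 equation is a
quadratic in η. The n = 1, 4, 6 equations become relative residuals whose
weighted RMS is the Figure of Merit; between the two quadratic roots the
smaller residual norm wins. n = 2 anchors the ratio because it is the most
noise-robust moment; the weight vector is configurable.

The FOM is scanned over ε ∈ [0.4, 2.5] (step 0.005), oblate mapping
(R_eq = D_max/2 − R_sh) below 1 and prolate (R_pol = D_max/2 − R_sh) above.
Near a zero the FOM is V-shaped, so minima are localised by a parabola
fitted to FOM²; the best minimum of each branch enters the relative
probability P[ε_P,O] = 1 − FOM[ε_P,O]/(FOM[ε_P] + FOM[ε_O]). Ties between
equal-FOM minima prefer the less eccentric shape.

Absolute scale: I(0) = K S²/N_agg with S = Δρ_P V_M + (Δρ_E−Δρ_P) V_E the
total excess electrons of one micelle and K = (c_mon−cmc) N_A r_e²/MW_mon.
The default closure is the electron balance S = N_agg (N_e − V_mon ρ_s),
giving N_agg = I(0)/(K ΔN_e²) and then both contrasts; a `fixed_nagg`
closure instead imposes the initial estimate. The initial N_agg (average of
the I(0)/I_mon route and the Tanford packing estimate
(4π/3)(1.5+1.265 n_c)³/(27.4+26.9 n_c)) is reported for reference and used
only by the `fixed_nagg` closure. Relative-scale input downgrades the output
to (ε, contrast ratio) with an explicit limitation note.

### Shell-size refinement

Because the graphical R_sh is biased on sharp-interface profiles, the
pipeline re-optimises R_sh against the moment system inside an asymmetric
window around the graphical value (default −12/+2 Å, 0.25 Å steps): a cheap
n = 4, 6 pre-scan ranks (R_sh, ε) combinations, parabola-interpolated full
FOM depths compare them, and the ~40 best shapes get a dense fine scan.
With R_sh free the system (ratio equation + three residuals) remains
overdetermined by one equation, which keeps solutions isolated. D_max is
*not* refined by default: freeing it as well makes the system exactly
determined and admits exact mirror solutions (typically a prolate impostor
for an oblate truth) that no figure of merit can rank; `refine_dmax=True`
exists for exploration.

## Synthetic generator

`synthesize_pdf` histograms contrast-weighted pair distances of points drawn
uniformly in the outer spheroid and normalises so that 4π∫P dr equals the
model I(0). Points come from a scrambled Sobol sequence (seeded, chunked in
2²¹ blocks, totals rounded up to a power of two): the low-discrepancy pairs
reduce the moment error at 2²³ pairs to a few 1e-5, over an order of
magnitude better than pseudo-random sampling — important because the shape
refinement discriminates FOM differences of ~1e-4. Optional Gaussian
convolution of width σ_interface emulates diffuse interfaces/shell
fluctuations (grid padded by 5σ); optional additive Gaussian noise is a
stated fraction of max|P|. `evaluate_pdf` provides the deterministic ideal
curve from the overlap-volume route (exact for spheres to machine
precision) for noise-free tests.

Default conditions used by the test suite: grid step 0.25 Å, 2²³ pairs,
micelles with D_max ≈ 100–140 Å, R_sh ≈ 12–20 Å, Δρ_E ∈ [−0.04, −0.02],
Δρ_P ∈ [0.03, 0.05] n_e/Å³, N_agg ≈ 60–160 — the regime of the polysorbate/
phosphocholine/tocopherol-PEG systems the method targets.

What the generator does *not* emulate: indirect-transform regularisation
artifacts, incoherent background mis-subtraction, inter-micelle structure
factors, and polydispersity. Passing tests therefore demonstrate the
internal consistency and invertibility of the method under its own model
assumptions, not robustness to every feature of real data.

## Verified behaviour and known limitations

* Closed-form moments agree with the Monte-Carlo oracle within 3 standard
  errors across random two-contrast models on both branches; sphere limits
  (mean pair distance 36R/35, R_g² = 3R²/5) hold to four digits.
* With the true sizes supplied, the ε scan recovers ε to ±0.05, contrasts to
  ±10 % and N_agg to ±5 % across random models on both branches.
* End to end (graphical stage included) the same bands hold on noise-free
  profiles in the study regime above. Near-spherical particles
  (|ε−1| ≲ 0.12) produce two competing branch minima of comparable FOM —
  a real ambiguity of the problem, reported through the candidate
  probabilities rather than hidden.
* With 1 % noise and a 3 Å interface smearing, ε stays within ±0.1 and the
  true branch keeps majority probability in ≥8/10 trials. Strong smearing
  (σ comparable to R_sh) inflates all apparent sizes by ~σ and biases the
  even moments by ~σ²-terms; recovering sharp-interface parameters from such
  profiles requires deconvolution (or a σ-aware moment model), which is out
  of scope — for such data the reported sizes must be read as
  smearing-broadened, D ≈ D_sharp + O(σ).
* The degenerate configuration Δρ_P V_M + (Δρ_E−Δρ_P) V_E → 0 (contrast
  cancellation) leaves the moments undefined and raises a dedicated error.

## Units and constants

Distances in Å, electron densities in n_e/Å³, concentrations in mg/mL,
intensities in cm⁻¹. N_A = 6.02214076e23/mol, r_e = 2.8179403e-13 cm. The
default buffer is water at 10 electrons per 29.9 Å³ (0.3344 n_e/Å³);
rounding it to 0.334 shifts the per-monomer forward intensity of PS20 by
about 2 % — the tabulated value requires the 10/29.9 convention.
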