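# Methods

## Physical model

The package treats a condensate as a droplet whose interface carries a
quadratic (Helfrich) free energy with bending rigidity κ and interfacial
tension σ, without spontaneous curvature or saddle-splay terms.  Expanding
the radius field around a sphere of radius R in real orthonormal spherical
harmonics, r(θ, φ) = R[1 + Σ u_lm Y_lm], each coefficient is an
independent quadratic degree of freedom.  Equipartition fixes

    Var(u_lm) = kB·T / { κ (l+2)(l−1) [ l(l+1) + σ̄ ] },   σ̄ = σR²/κ,

with l = 0 (volume) and l = 1 (translation) excluded.  The imaged
equatorial cross-section mixes all degrees l ≥ q into contour mode q with
the geometric weight N_lq² P_lq(0)², where N_lq² = (2l+1)/(4π)·(l−q)!/(l+q)!
and P_lq is the associated Legendre polynomial; odd l+q terms vanish
identically.  The resulting projected spectrum (the expression in the
README) is what the fitter inverts.

Mode amplitudes follow the one-sided 1/N DFT convention

    υ_q = (1/N) Σ_k [(D(φ_k) − R̄)/R̄] e^{−i q φ_k},

chosen because under it the projection identity is exact: the analytic
spectrum equals the ensemble power of equipartition-sampled 3D shapes
sectioned on the equator.  This identity is the package's central oracle
and is enforced by a Monte-Carlo test (10⁵ shapes, 3 standard errors per
mode).

The dimensionless fit (κ in kB·T, σ̄) converts to physical units via
κ_J = κ·kB·T and σ = σ̄·κ_J/R², with R the time-averaged contour radius
and T defaulting to 310 K (live mammalian cells; configurable).

## Base-shape correction

Condensates have irregular, non-spherical mean shapes, so each mode is
split into a static and a fluctuating part, |C_q|² = |⟨υ_q⟩|² and
|F_q|² = ⟨|υ_q|²⟩ − |⟨υ_q⟩|²; only |F_q|² enters the fit, and |C_2|² is
reported as a circularity (elongation) measure.  The complex time average
is taken in the detector frame without rotational registration: a granule
that physically rotates between frames converts static shape into apparent
fluctuation.  The rotating-rigid-body simulator exists precisely to bound
this failure mode (see below).

## Fitting

The fit error is E = RMS over q = 2..15 of [log10 |F_q|² − log10 model],
so each decade-spanning mode counts equally; a uniform factor-10 offset
gives exactly E = 1.  The two-parameter fit minimizes E on a 60×60
log-spaced grid (κ ∈ [10⁻², 10⁴] kB·T, σ̄ ∈ [10⁻⁴, 10⁶]) followed by
Nelder–Mead refinement in (log10 κ, log10 σ̄); the procedure is
deterministic.  Since κ enters only as a prefactor, the one-parameter
variants (tension-only: the analytic κ→0 limit; bending-only: σ̄ = 0) have
a closed-form optimum — the mean log offset — so their errors are the
population SD of the log residuals, which is exactly the minimum any
optimizer would reach.  q = 1 is computed but never fitted (it mixes with
centring error); modes with non-positive |F_q|² are dropped and at least 5
surviving modes are required.  A fit is flagged degenerate when the
tension/bending crossover √σ̄ lies beyond q = 15: above the crossover the
spectrum carries no bending information, which is the rationale for the
Δ-error filter below.

Population filters, applied sequentially with per-stage counts:
(1) outline pass rate ≥ 0.60 — the fraction of *video* frames with a
validated closed contour (the track-length denominator would flatter
late-appearing granules); (2) Δerror = E_tension_only − E_full ≥ 0.03;
(3) E_full ≤ 0.5.  All thresholds are configuration fields.  Survivors are
summarized by geometric means and exp(mean ± SD) bands of log σ and log κ
(the "67%" band of a log-normal population).

## Image analysis

* **Detection** — multi-scale difference-of-Gaussians (geometric scale
  ladder, ratio 1.6, covering granule radii 3–30 px), local maxima above a
  threshold of 0.12× the frame intensity range.  Rendered and imaged
  granules respond at ≈0.25× the range and pure pixel noise below ≈0.06×,
  so the default separates the two with a factor-2 margin each way.
  Sub-pixel centres by quadratic refinement of the band-pass response.
* **Extent** — flood fill at 0.5× the maximum image intensity (global
  reference by default; a per-granule local window is available because
  cytoplasmic brightness varies between cells); bodies under 100 px² are
  rejected as too small to analyze.
* **Gradient** — the five-point fourth-order stencil
  (I_{i−2} − 8I_{i−1} + 8I_{i+1} − I_{i+2})/12 per axis, exact through
  quartic intensity fields; a border of width 2 is flagged invalid.
* **Boundary** — 400 rays from the mask centroid; edge strength
  g = −∇I·r̂ (the outward intensity *drop*, which peaks at the edge of a
  bright body) sampled every 0.25 px over a radial window of
  [0.3, 2.0]× the seed scale; discrete maximum refined by a parabola
  through its neighbours.  Rays whose peak sits on the window boundary or
  below the noise floor are invalid.
* **Validation** — a contour fails when any ray is invalid or adjacent
  radii jump by more than 0.2× the mean radius (merging granules, wetting
  overhangs); rejection is per frame and feeds the pass-rate filter.
* **Tracking** — greedy globally-nearest linking of detections within one
  scale estimate per frame, 5-missed-frame memory; assignment order is by
  distance, making the result independent of detection list order.

Two numerical choices depart from the naive implementation, both measured
on rendered discs with known geometry:

* **Pre-smoothing (default σ = 1.5 px).**  At pixel signal-to-noise ~5 the
  stencil gradient of unsmoothed noise rivals the edge response, and
  spurious maxima inside the wide search window invalidate most frames.  A
  small Gaussian prefilter before the stencil (the stencil operator itself
  stays pure) is the knee of the validity/attenuation trade-off: 100% of
  frames validate, per-ray RMS error 0.34 px, and a q = 3 ripple is
  attenuated by only ≈12%.  The accompanying uniform inward radius bias
  (~σ²/R) cancels in every fluctuation mode.
* **Cubic ray sampling.**  Bilinear interpolation of the gradient locks
  the parabola-refined edge onto the pixel grid, leaving a static angular
  ripple of ≈0.135 px RMS (harmonics of mode 4) — above the 0.1 px
  sensitivity the method claims.  Cubic-spline sampling reduces it below
  0.01 px.

With these defaults the extractor recovers a static 0.05 px q = 3 ripple
above 3× the control noise floor from 200 frames at SNR 5 (the
`scripts/acceptance.py` measurement).

## Synthetic data: what it emulates, what it does not

`synthetic_data` renders bright quasi-circular granules (default R = 0.8 μm
at 0.065 μm/px ⇒ ≈12 px) on a 20% background with Gaussian PSF (1.3 px)
and Gaussian noise at SNR (foreground − background)/noise-SD = 5, matching
fast spinning-disk acquisitions of 1000 frames at 10 ms.  Frames are
temporally i.i.d.: only time-averaged powers are fitted, so temporal
correlation is irrelevant to the estimator (an AR(1)/Ornstein–Uhlenbeck
mode exists for autocorrelation tests).  The fixed-cell mimic renders one
quenched shape with fresh noise per frame.  The rotating rigid body draws
a quenched pink-noise shape (per-(l,m) amplitude uniform[0,1]/l with a
random phase split onto the cosine/sine harmonics, l = 2..15) and composes
random rotations (axis uniform on the hemisphere, angle ~ N(0, 2^β),
β = 0 by default).

Off-equator imaging is modelled as the constant-z section a plane missing
the equator by angle t cuts: the small circle θ₀ = π/2 − t, with in-plane
radius R sinθ₀ [1 + u(θ₀, φ)/sin²θ₀] to first order.  (A great circle
tilted *through the centre* of an isotropic ensemble would be statistically
identical to the equator and test nothing.)  At ≤20° the fitted σ and κ
move by ≲15%, small against the width of observed population bands.

Not emulated: shot-noise statistics and camera gain registers, non-Gaussian
PSFs, photobleaching, cytoplasmic texture, granule motion in z, and
inter-frame shape correlation.  Passing synthetic tests therefore
demonstrates correctness of the measurement chain under the stated optics,
not robustness to every property of real cells.

## Known limitations

* **Imaging noise floor.**  Detector noise adds white per-mode power
  (≈2×(σ_ray/R)²·(2/N)) that is *not* removed by the |F_q|² correction;
  at SNR 5 and R ≈ 12 px it rivals the thermal power of high-q modes,
  biasing image-level fits toward higher κ and lower σ̄ (measured:
  κ ≈ 3.5 recovered for a κ = 2 truth).  This is a bias, not variance —
  more frames do not remove it.  Contour-level recovery under the same
  study conditions is percent-level (median errors ≈3% over 50 replicates
  of 1000 frames).
* **Truncation tail.**  The projection weights tend to 1/π² at large l, so
  the highest fitted mode retains a slowly decaying tail: extending
  l_max = 75 → 150 moves q = 15 by ~3×10⁻³ relative at σ̄ ≤ 50 and ~1% at
  σ̄ = 10³.  The default non-convergence flag therefore triggers at 1%
  (reached around σ̄ ≳ 10⁴), where the truncation would visibly distort a
  fit; below that it is negligible against measurement noise.
* **Rigid-body discrimination is relative, not absolute.**  Rotating
  quenched bodies fit the thermal model about an order of magnitude worse
  than matched equilibrium simulations (median E ≈ 0.12 vs ≈ 0.015), but
  large random rotations orientation-average the quenched spectrum into a
  smooth, tension-like shape, so the absolute error rarely crosses the 0.5
  population-filter threshold.  Distinguishing slow rotators from live
  fluctuations in practice should use the autocorrelation of υ_2 alongside
  the fit error.
* **Granule rotation** between frames mixes C_q into F_q (no rotational
  registration is attempted); drifting phase of υ_2 is the symptom.
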