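# flickerspec

High-throughput flicker spectroscopy of biomolecular condensates: estimate
the **interfacial tension** σ and **bending rigidity** κ of droplet-like
condensates (stress granules, nucleoli, P-bodies, ...) in live cells from
the thermal fluctuations of their imaged boundaries.

## Who this is for

Labs imaging fluorescently labelled condensates with fast time-lapse
microscopy (≈1000 frames per field of view at ~10 ms exposure) who want
per-granule mechanical parameters and population-level statistics, rather
than estimates from a handful of coalescence events.  The package also
ships a complete synthetic-data subsystem (equipartition-sampled droplets,
rotating rigid bodies, microscope-like renderings), so every stage can be
validated without experimental data.

## The model

A quasi-spherical interface governed by the Helfrich free energy — bending
energy (κ/2)H² plus tension σ per unit area, no spontaneous curvature or
saddle-splay — has independent harmonic shape modes whose equipartition
variances are

    ⟨|u_lm|²⟩ = kB·T / { κ (l+2)(l−1) [ l(l+1) + σ̄ ] },     σ̄ = σR²/κ.

A microscope sees only the equatorial contour.  Writing the contour as
D(φ) and its relative radial profile as Fourier modes υ_q, the predicted
time-averaged spectrum is the projected sum

    ⟨|υ_q|²⟩ = (kB·T/κ) Σ_{l=q}^{l_max}  N_lq² P_lq(0)²
               / { (l+2)(l−1) [ l(l+1) + σ̄ ] },      l_max = 75.

Condensates are not perfectly spherical, so each measured mode is split
into a static part |C_q|² = |⟨υ_q⟩|² (base shape; |C_2|² doubles as a
circularity measure) and a fluctuating part |F_q|² = ⟨|υ_q|²⟩ − |⟨υ_q⟩|²;
only |F_q|² is thermal and only it is fitted, over q = 2..15.  The fit
error is the RMS of decimal-log residuals; granule populations are
filtered (outline pass rate ≥ 60%, bending must improve the fit by ≥ 0.03,
error ≤ 0.5) and summarized by geometric means with ±1 SD log-normal bands.

The measurement chain from raw images: difference-of-Gaussians granule
detection → frame-to-frame tracking → flood-fill extent estimate → 400-ray
sub-pixel boundary extraction at the maximum of the outward directional
intensity drop, using a fourth-order gradient stencil with parabolic
refinement (sensitive to ripples below 0.1 px) → per-frame contour
validation → mode statistics → spectrum fits.

## Worked example

Simulate a droplet with known parameters (κ = 2 kB·T, σ̄ = 50, R = 0.8 μm,
T = 310 K), analyze it at the contour level, then end-to-end through
rendered images:

```python
import numpy as np
from flickerspec import (ModelParams, OpticsModel, simulate_droplet_video,
                         sample_contour_ensemble, aggregate_modes, fit_spectrum)
from flickerspec.mode_analysis import ModeAmplitudes
from flickerspec.pipeline import PipelineConfig, analyze_stack

truth = ModelParams(kappa=2.0, sigma_bar=50.0, radius=0.8)

# 1000 statistically independent equatorial contours, decomposed and fitted
ups = sample_contour_ensemble(truth, 1000, l_sim=75, rng_seed=1)
series = [ModeAmplitudes(i, ups[i], truth.radius / 0.065) for i in range(1000)]
fit = fit_spectrum(aggregate_modes(series, pixel_size_um=0.065))
print(fit.kappa, fit.sigma_bar, fit.sigma_physical)

# the same droplet rendered as a microscope video (SNR 5) and re-analyzed
optics = OpticsModel(psf_sigma=1.3, snr=5.0, pixel_size=0.065)
video = simulate_droplet_video(truth, optics, n_frames=120, rng_seed=11, l_sim=40)
result = analyze_stack(video.frames, PipelineConfig())
print(result.granules[["kappa_kbt", "sigma_uN_per_m", "pass_rate"]])
```

This prints

```
contour-level fit: kappa = 2.01 kBT, sigma_bar = 48.8, sigma = 0.657 uN/m, fit error = 0.012
truth:             kappa = 2.00 kBT, sigma_bar = 50.0, sigma = 0.669 uN/m
image-level fit:   kappa = 3.50 kBT, sigma = 0.454 uN/m, pass_rate = 0.94
```

Contour-level recovery is percent-level.  The image-level fit carries the
detector noise floor of SNR-5 imaging (white per-mode power that inflates
high-q modes and biases κ upward), which is why real analyses rely on the
population filters and large granule counts; see `docs/methods.md`.

## Command line

```sh
flickerspec simulate-droplet --kappa 2 --sigma-bar 50 --n-frames 1000 --out droplet.tiff
flickerspec analyze config.yaml          # full pipeline from a YAML config
flickerspec simulate-rigid --beta 0      # rotating rigid-body control series
flickerspec zplane-study --max-tilt 20   # off-equator imaging robustness
flickerspec report granules.csv          # geometric means and 67% bands
```

`analyze` writes `contours.csv`, `mode_statistics.csv`, `granules.csv`,
`population_summary.csv` and a `run_report.json` with the configuration
hash, seed, versions and the per-stage filter ledger.

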