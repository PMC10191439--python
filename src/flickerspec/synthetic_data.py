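"""Ground-truth simulators: fluctuating droplets, rigid rotators, renderings.

Every stage of the analysis pipeline is testable without experimental data
through three generators:

* Equilibrium droplets.  3D shapes r(theta, phi) = R [1 + sum u_lm Y_lm] with
  real orthonormal spherical harmonics, each independent coefficient drawn
  with the equipartition variance
  kB T / { kappa (l+2)(l-1) [ l(l+1) + sigma_bar ] } (kappa in energy units).
  The equatorial cross-section of such shapes has exactly the projected
  spectrum computed by :mod:`flickerspec.helfrich_spectrum`, which makes the
  sampler the package's central closure oracle.
* Rigid rotators.  A single quenched rough shape with pink-noise harmonic
  amplitudes (magnitude ~ 1/l, random phases, l = 2..15) undergoing a series
  of random rotations; its cross-section series mimics a non-fluctuating,
  rotating mature granule and must *fail* the equilibrium spectrum fit.
* Microscope renderings.  Contours rasterized as bright discs on a non-zero
  background, blurred with a Gaussian PSF and degraded with Gaussian noise
  to a target signal-to-noise ratio (~5 for the spinning-disk acquisitions
  emulated here), written as ordinary image frames.

Frames are temporally i.i.d. by default: only time-averaged mode powers are
fitted, so temporal correlations are irrelevant to the estimator.  An
optional Ornstein-Uhlenbeck mode gives correlated series for
autocorrelation tests.  All generators are reproducible from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from .boundary_extraction import Contour, ImageFrame
from .helfrich_spectrum import ModelParams
from .mode_analysis import decompose_profiles

__all__ = [
    "HarmonicShape",
    "OpticsModel",
    "RigidConfig",
    "SimulatedVideo",
    "sample_equilibrium_modes",
    "equatorial_contour",
    "sample_contour_ensemble",
    "render_frame",
    "simulate_droplet_video",
    "simulate_rigid_rotation",
    "zplane_robustness",
]

#: Default pixel pitch, micrometres per pixel (100x oil objective with 1.5x
#: magnification on a 13-um camera pixel).
DEFAULT_PIXEL_SIZE_UM = 0.065


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class HarmonicShape:
    """Real spherical-harmonic amplitude set u_lm, l = 2..l_sim, |m| <= l.

    ``amplitudes[i]`` belongs to degree ``l_index[i]`` and order
    ``m_index[i]``; negative m labels the sine partner of the |m| harmonic.
    l = 0 (volume) and l = 1 (translation) are absent by construction.
    ``base_radius`` is in micrometres.
    """

    l_index: np.ndarray
    m_index: np.ndarray
    amplitudes: np.ndarray
    base_radius: float

    @property
    def l_sim(self) -> int:
        return int(self.l_index.max())


def _harmonic_index(l_min: int, l_max: int) -> tuple[np.ndarray, np.ndarray]:
    ls, ms = [], []
    for l in range(l_min, l_max + 1):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def mode_variance(params: ModelParams, l: np.ndarray) -> np.ndarray:
    """Equipartition variance of one real coefficient of degree l (kappa in kB*T)."""
    l = np.asarray(l, dtype=float)
    return 1.0 / (
        params.kappa * (l + 2.0) * (l - 1.0) * (l * (l + 1.0) + params.sigma_bar)
    )


def sample_equilibrium_modes(
    params: ModelParams, l_sim: int, rng_seed=0
) -> HarmonicShape:
    """Draw one thermally equilibrated droplet shape.

    Each real coefficient is an independent zero-mean Gaussian with the
    equipartition variance; doubling kappa halves every variance.
    """
    if l_sim < 15:
        raise ValueError(f"l_sim must be >= 15, got {l_sim}")
    if params.sigma_bar < 0:
        raise ValueError("sigma_bar must be >= 0")
    rng = _as_rng(rng_seed)
    l_idx, m_idx = _harmonic_index(2, l_sim)
    sd = np.sqrt(mode_variance(params, l_idx))
    amp = rng.standard_normal(l_idx.size) * sd
    return HarmonicShape(
        l_index=l_idx, m_index=m_idx, amplitudes=amp, base_radius=params.radius
    )


def _real_harmonics(
    l_idx: np.ndarray, m_idx: np.ndarray, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Matrix of real orthonormal spherical harmonics, shape (n_coeff, n_points).

    Built from the complex harmonics: Y_{l,0} = Re Y_l^0,
    Y_{l,m>0} = sqrt(2) (-1)^m Re Y_l^m, Y_{l,-m} = sqrt(2) (-1)^m Im Y_l^m.
    """
    out = np.empty((l_idx.size, theta.size))
    cache: dict[tuple[int, int], np.ndarray] = {}
    for i, (l, m) in enumerate(zip(l_idx, m_idx)):
        key = (int(l), abs(int(m)))
        if key not in cache:
            cache[key] = sph_harm_y(key[0], key[1], theta, phi)
        y = cache[key]
        if m == 0:
            out[i] = y.real
        elif m > 0:
            out[i] = np.sqrt(2.0) * (-1.0) ** m * y.real
        else:
            out[i] = np.sqrt(2.0) * (-1.0) ** (-m) * y.imag
    return out


@lru_cache(maxsize=16)
def _equator_basis(l_sim: int, tilt_mdeg: int, n_points: int) -> np.ndarray:
    """Harmonic basis on the circle of constant polar angle pi/2 - tilt.

    An imaging plane that misses the granule equator by ``tilt`` degrees
    cuts the sphere along the small circle theta0 = pi/2 - tilt; at tilt 0
    this is the equator.
    """
    l_idx, m_idx = _harmonic_index(2, l_sim)
    theta0 = np.pi / 2.0 - np.deg2rad(tilt_mdeg / 1000.0)
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    basis = _real_harmonics(l_idx, m_idx, np.full(n_points, theta0), phi)
    basis.setflags(write=False)
    return basis


def equatorial_contour(
    shape: HarmonicShape, tilt_deg: float = 0.0, n_points: int = 400
) -> Contour:
    """Cross-section of the shape seen by an imaging plane near the equator.

    At ``tilt_deg`` = 0 the section is the equator and the in-plane radius
    is r = R [1 + u(pi/2, phi)].  A plane missing the equator by ``tilt``
    degrees cuts the small circle theta0 = pi/2 - tilt; to first order in
    the deformation its in-plane radius is

        rho(phi) = R sin(theta0) [1 + u(theta0, phi) / sin^2(theta0)],

    so the apparent mean radius shrinks as cos(tilt) while deformations are
    slightly amplified.  ``radii`` are in the units of ``base_radius``
    (micrometres); zero amplitudes give a perfect circle.
    """
    if not abs(tilt_deg) < 90:
        raise ValueError("tilt_deg must satisfy |tilt| < 90")
    basis = _equator_basis(shape.l_sim, int(round(tilt_deg * 1000)), n_points)
    u = shape.amplitudes @ basis
    s = np.cos(np.deg2rad(tilt_deg))  # sin(theta0)
    radii = shape.base_radius * s * (1.0 + u / s**2)
    angles = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return Contour(
        center=(0.0, 0.0),
        angles=angles,
        radii=radii,
        ray_valid=np.ones(n_points, dtype=bool),
        valid=True,
    )


def sample_contour_ensemble(
    params: ModelParams,
    n_shapes: int,
    l_sim: int,
    rng_seed=0,
    tilt_deg: float = 0.0,
    n_points: int = 400,
    chunk: int = 2000,
) -> np.ndarray:
    """Mode amplitudes v_q of many independent equilibrium cross-sections.

    Vectorized sampler for Monte-Carlo closure studies: draws coefficients
    in chunks, projects onto the (tilted) great circle and Fourier-decomposes
    the relative profiles.  Returns a complex array (n_shapes, q_max) with
    column j holding v_{j+1}.  Identical seed gives identical output.
    """
    rng = _as_rng(rng_seed)
    l_idx, _ = _harmonic_index(2, l_sim)
    sd = np.sqrt(mode_variance(params, l_idx))
    basis = _equator_basis(l_sim, int(round(tilt_deg * 1000)), n_points)
    s2 = np.cos(np.deg2rad(tilt_deg)) ** 2  # sin^2(theta0)
    out = np.empty((n_shapes, params.q_max), dtype=complex)
    done = 0
    while done < n_shapes:
        m = min(chunk, n_shapes - done)
        coeffs = rng.standard_normal((m, l_idx.size)) * sd
        rho = (coeffs @ basis) / s2  # relative radial profile (D - Rbar)/Rbar
        out[done : done + m] = decompose_profiles(rho, params.q_max)
        done += m
    return out


@dataclass(frozen=True)
class OpticsModel:
    """Microscope-like rendering settings."""

    psf_sigma: float = 1.3  # px
    snr: float = 5.0  # (foreground - background) / noise SD
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # um / px
    background_level: float = 0.2  # background as fraction of foreground
    bit_depth: int | None = None  # quantize intensities when set

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


def render_frame(
    contour: Contour,
    optics: OpticsModel,
    rng_seed=0,
    frame_shape: tuple[int, int] | None = None,
    frame_index: int = 0,
    noise: bool = True,
) -> ImageFrame:
    """Rasterize a contour as a fluorescent body and degrade it optically.

    The filled region (foreground intensity 1.0 on ``background_level``) is
    rasterized with a 1-px anti-aliased edge, convolved with the Gaussian
    PSF, and Gaussian noise of SD (1 - background)/snr is added.  Contour
    radii are interpreted in micrometres and converted with
    ``optics.pixel_size``.  Contours that do not fit the frame are
    rejected.
    """
    if not contour.valid:
        raise ValueError("cannot render an invalid contour")
    radii_px = np.asarray(contour.radii) / optics.pixel_size
    r_max = float(radii_px.max())
    margin = int(np.ceil(4 * optics.psf_sigma + 6))
    if frame_shape is None:
        half = int(np.ceil(r_max)) + margin
        frame_shape = (2 * half + 1, 2 * half + 1)
    h, w = frame_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if r_max + 3 > min(cy, cx, h - 1 - cy, w - 1 - cx):
        raise ValueError(
            f"contour radius {r_max:.1f} px does not fit frame {frame_shape}"
        )

    rows, cols = np.indices(frame_shape, dtype=float)
    dr, dc = rows - cy, cols - cx
    r_pix = np.hypot(dr, dc)
    phi_pix = np.mod(np.arctan2(dr, dc), 2.0 * np.pi)
    angles = contour.angles
    d_interp = np.interp(
        phi_pix.ravel(),
        np.concatenate([angles, [2.0 * np.pi]]),
        np.concatenate([radii_px, [radii_px[0]]]),
    ).reshape(frame_shape)
    coverage = np.clip(d_interp - r_pix + 0.5, 0.0, 1.0)

    bg = optics.background_level
    img = bg + (1.0 - bg) * coverage
    if optics.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, optics.psf_sigma)
    if noise:
        rng = _as_rng(rng_seed)
        img = img + rng.normal(0.0, (1.0 - bg) / optics.snr, size=frame_shape)
    img = np.clip(img, 0.0, None)
    if optics.bit_depth is not None:
        levels = 2**optics.bit_depth - 1
        img = np.round(img * 0.5 * levels) / (0.5 * levels)
    return ImageFrame(
        pixels=img, pixel_size=optics.pixel_size, frame_index=frame_index
    )


@dataclass(frozen=True)
class SimulatedVideo:
    """Rendered frames with their ground-truth contours and parameters."""

    frames: np.ndarray  # (n_frames, H, W)
    contours: list[Contour]  # ground truth, radii in um
    truth: dict


def simulate_droplet_video(
    params: ModelParams,
    optics: OpticsModel,
    n_frames: int,
    rng_seed=0,
    l_sim: int | None = None,
    fixed_shape: bool = False,
    frame_shape: tuple[int, int] | None = None,
) -> SimulatedVideo:
    """Render a time-lapse of one fluctuating (or quenched) droplet.

    Shapes are i.i.d. equipartition draws per frame; with
    ``fixed_shape=True`` a single quenched shape is rendered with fresh
    noise each frame — the fixed-cell mimic, whose corrected spectrum
    contains only detector noise.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _as_rng(rng_seed)
    l_sim = l_sim or params.l_max
    if frame_shape is None:
        half = int(np.ceil(1.4 * params.radius / optics.pixel_size)) + int(
            np.ceil(4 * optics.psf_sigma + 6)
        )
        frame_shape = (2 * half + 1, 2 * half + 1)
    shape = sample_equilibrium_modes(params, l_sim, rng)
    frames = []
    contours = []
    for i in range(n_frames):
        if i > 0 and not fixed_shape:
            shape = sample_equilibrium_modes(params, l_sim, rng)
        contour = equatorial_contour(shape)
        contour.frame_index = i
        frame = render_frame(
            contour, optics, rng, frame_shape=frame_shape, frame_index=i
        )
        frames.append(frame.pixels)
        contours.append(contour)
    truth = {
        "kappa": params.kappa,
        "sigma_bar": params.sigma_bar,
        "radius_um": params.radius,
        "temperature": params.temperature,
        "l_sim": l_sim,
        "fixed_shape": fixed_shape,
        "seed": rng_seed if not isinstance(rng_seed, np.random.Generator) else None,
    }
    return SimulatedVideo(frames=np.stack(frames), contours=contours, truth=truth)


@dataclass(frozen=True)
class RigidConfig:
    """Quenched rough body undergoing random rotations.

    The rotation-angle SD is 2**beta radians; amplitudes follow a pink
    (1/l) spectrum over l = 2..l_max with random phases.
    """

    beta: float = 0.0
    n_rotations: int = 100
    l_min: int = 2
    l_max: int = 15
    seed: int = 0
    n_points: int = 400
    radius: float = 1.0  # simulation unit

    def __post_init__(self) -> None:
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")


def simulate_rigid_rotation(config: RigidConfig) -> list[Contour]:
    """Contour series of a rotating rigid body with quenched pink-noise shape.

    One random shape u(theta, phi) = sum U_lm/l-scaled harmonics with random
    phases is generated, then rotated ``n_rotations`` times: each step
    composes a rotation about an axis uniform on the unit hemisphere by an
    angle ~ Normal(0, 2**beta); the equatorial cross-section is recorded
    after every rotation.  As beta -> -inf all contours coincide and the
    corrected fluctuation power vanishes.
    """
    rng = np.random.default_rng(config.seed)
    l_idx, m_idx = _harmonic_index(config.l_min, config.l_max)
    coeffs = np.zeros(l_idx.size)
    # one magnitude + phase per (l, |m|) pair, split onto the cos/sin partners
    for l in range(config.l_min, config.l_max + 1):
        for m in range(0, l + 1):
            mag = rng.uniform(0.0, 1.0) / l
            psi = rng.uniform(0.0, 2.0 * np.pi)
            coeffs[(l_idx == l) & (m_idx == m)] = mag * np.cos(psi)
            if m > 0:
                coeffs[(l_idx == l) & (m_idx == -m)] = mag * np.sin(psi)

    t = np.linspace(0.0, 2.0 * np.pi, config.n_points, endpoint=False)
    equator = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    angles = t
    rot = Rotation.identity()
    contours: list[Contour] = []
    for step in range(config.n_rotations):
        z = rng.uniform(0.0, 1.0)
        az = rng.uniform(0.0, 2.0 * np.pi)
        axis = np.array(
            [np.sqrt(1 - z**2) * np.cos(az), np.sqrt(1 - z**2) * np.sin(az), z]
        )
        angle = rng.normal(0.0, 2.0**config.beta)
        rot = Rotation.from_rotvec(axis * angle) * rot
        pts = rot.inv().apply(equator)  # body-frame directions of the lab equator
        theta = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        u = coeffs @ _real_harmonics(l_idx, m_idx, theta, phi)
        contours.append(
            Contour(
                center=(0.0, 0.0),
                angles=angles,
                radii=config.radius * (1.0 + u),
                ray_valid=np.ones(config.n_points, dtype=bool),
                valid=True,
                frame_index=step,
            )
        )
    return contours


def zplane_robustness(
    params: ModelParams,
    tilt_grid,
    n_frames: int,
    rng_seed=0,
    l_sim: int | None = None,
):
    """Fitted (sigma, kappa) of the same droplet analyzed at different z planes.

    For each tilt the *same* shape sequence (same seed) is sectioned along a
    plane tilted from the equator, analyzed and fitted; the table reports
    the relative deviation from the tilt-0 fit.  Apparent mean radius
    shrinks with |tilt| because an off-equator plane cuts a smaller circle.
    """
    import pandas as pd

    from .mode_analysis import ModeAmplitudes, aggregate_modes
    from .spectrum_fitting import fit_spectrum

    tilt_grid = list(tilt_grid)
    if any(abs(t) > 30 for t in tilt_grid):
        raise ValueError("tilts must be within +/-30 degrees")
    l_sim = l_sim or params.l_max
    rows = []
    baseline = None
    for tilt in [0.0] + [t for t in tilt_grid if t != 0.0]:
        ups = sample_contour_ensemble(
            params, n_frames, l_sim, rng_seed=rng_seed, tilt_deg=tilt
        )
        # apparent section radius in um, shrinking off-equator
        radius_um = params.radius * float(np.cos(np.deg2rad(tilt)))
        series = [
            ModeAmplitudes(frame_index=i, upsilon=ups[i], mean_radius=radius_um)
            for i in range(ups.shape[0])
        ]
        stats = aggregate_modes(series, pixel_size_um=1.0)
        fit = fit_spectrum(
            stats, temperature=params.temperature, l_max=params.l_max, q_max=params.q_max
        )
        if baseline is None:
            baseline = fit
        rows.append(
            {
                "tilt_deg": tilt,
                "kappa_kbt": fit.kappa,
                "sigma_bar": fit.sigma_bar,
                "sigma_uN_per_m": fit.sigma_physical,
                "error_full": fit.error_full,
                "rel_dev_kappa": fit.kappa / baseline.kappa - 1.0,
                "rel_dev_sigma": (
                    fit.sigma_physical / baseline.sigma_physical - 1.0
                    if baseline.sigma_physical
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values("tilt_deg", key=np.abs, ignore_index=True)
    return df
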