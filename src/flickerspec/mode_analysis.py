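"""Fourier decomposition of contour time series and base-shape correction.

Each valid contour D(phi) is reduced to complex mode amplitudes

    v_q = (1/N) sum_k [(D(phi_k) - Rbar)/Rbar] exp(-i q phi_k),

the one-sided DFT of the relative radial profile, so a ripple
D = R (1 + 2 eps cos q phi) has |v_q| = eps.  Granules rarely have a perfectly
spherical base shape; following the fluctuating-plus-constant split
v_q(t) = F_q cos(w_q t + d_q) + C_q, the thermal part of each mode is
isolated from its static part by

    |F_q|^2 = <|v_q|^2> - |<v_q>|^2,        |C_q|^2 = |<v_q>|^2.

|F_q|^2 replaces <|v_q|^2> as the fluctuation measure fed to the spectrum
fit, and |C_2|^2 serves as a circularity (elongation) measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _acf

from .boundary_extraction import Contour

__all__ = [
    "ModeAmplitudes",
    "ModeStatistics",
    "Autocorrelation",
    "decompose_profiles",
    "decompose_contour",
    "aggregate_modes",
    "mode_autocorrelation",
]

DEFAULT_Q_MAX = 15

#: Minimum number of valid frames required before time statistics are formed.
MIN_FRAMES = 30


@dataclass(frozen=True)
class ModeAmplitudes:
    """Complex contour mode amplitudes of one frame, q = 1..q_max.

    ``upsilon[i]`` holds v_{i+1}; q = 0 (the mean radius) is excluded by
    construction and q = 1 mixes with centre error, so it is stored but
    never fitted.
    """

    frame_index: int
    upsilon: np.ndarray
    mean_radius: float

    @property
    def q(self) -> np.ndarray:
        return np.arange(1, len(self.upsilon) + 1)


def decompose_profiles(rho: np.ndarray, q_max: int = DEFAULT_Q_MAX) -> np.ndarray:
    """One-sided DFT amplitudes v_1..v_q_max of relative radial profiles.

    ``rho`` has shape (n_profiles, n_angles) and holds (D - Rbar)/Rbar
    sampled on evenly spaced angles; returns shape (n_profiles, q_max).
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    n = rho.shape[1]
    if q_max >= n // 2:
        raise ValueError(f"q_max={q_max} beyond Nyquist for {n} samples")
    return np.fft.rfft(rho, axis=1)[:, 1 : q_max + 1] / n


def decompose_contour(contour: Contour, q_max: int = DEFAULT_Q_MAX) -> ModeAmplitudes:
    """Fourier-decompose one valid contour into mode amplitudes.

    Raises ``ValueError`` on contours with invalid rays: missing samples
    would alias into every mode.
    """
    if not contour.valid or not bool(np.all(contour.ray_valid)):
        raise ValueError("cannot decompose an invalid contour")
    radii = np.asarray(contour.radii, dtype=float)
    rbar = radii.mean()
    if not rbar > 0:
        raise ValueError("contour mean radius must be positive")
    upsilon = decompose_profiles(radii[None, :] / rbar - 1.0, q_max)[0]
    return ModeAmplitudes(
        frame_index=contour.frame_index, upsilon=upsilon, mean_radius=rbar
    )


@dataclass(frozen=True)
class ModeStatistics:
    """Time statistics of contour modes for one granule.

    All powers are dimensionless (relative radial amplitude squared).
    ``mean_power`` is <|v_q|^2>, ``static_power`` = C2 = |<v_q>|^2 and
    ``F2`` = mean_power - static_power is the base-shape-corrected
    fluctuation power.  Arrays are indexed q = 1..q_max.
    """

    n_frames: int
    q: np.ndarray
    mean_power: np.ndarray
    static_power: np.ndarray
    F2: np.ndarray
    C2: np.ndarray
    circularity: float
    mean_radius_px: float
    mean_radius_um: float | None = None

    def power_at(self, q: int, corrected: bool = True) -> float:
        i = int(q) - 1
        return float(self.F2[i] if corrected else self.mean_power[i])

    def to_frame(self, granule_id: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "q": self.q,
                "mean_power": self.mean_power,
                "F2": self.F2,
                "C2": self.C2,
            }
        )
        if granule_id is not None:
            df.insert(0, "granule_id", granule_id)
        return df


def aggregate_modes(
    series: Sequence[ModeAmplitudes],
    min_frames: int = MIN_FRAMES,
    pixel_size_um: float | None = None,
) -> ModeStatistics:
    """Combine per-frame amplitudes into base-shape-corrected time statistics.

    The complex time average <v_q> is taken in the detector frame, without
    rotational registration; see the package methods notes for the
    implications when granules rotate between frames.  Invariant to frame
    order (only first and second moments are used).
    """
    if len(series) < min_frames:
        raise ValueError(
            f"need at least {min_frames} valid frames, got {len(series)}"
        )
    ups = np.stack([m.upsilon for m in series])
    if not np.all(np.isfinite(ups)):
        raise ValueError("non-finite mode amplitudes")
    mean_power = np.mean(np.abs(ups) ** 2, axis=0)
    static_power = np.abs(ups.mean(axis=0)) ** 2
    f2 = mean_power - static_power
    radius_px = float(np.mean([m.mean_radius for m in series]))
    q = np.arange(1, ups.shape[1] + 1)
    return ModeStatistics(
        n_frames=len(series),
        q=q,
        mean_power=mean_power,
        static_power=static_power,
        F2=f2,
        C2=static_power,
        circularity=float(static_power[1]),  # q = 2
        mean_radius_px=radius_px,
        mean_radius_um=None if pixel_size_um is None else radius_px * pixel_size_um,
    )


@dataclass(frozen=True)
class Autocorrelation:
    """Normalized autocorrelation of one mode's real part vs lag."""

    q: int
    lags: np.ndarray
    values: np.ndarray
    defined: bool


def mode_autocorrelation(
    series: Sequence[ModeAmplitudes], q: int, n_lags: int | None = None
) -> Autocorrelation:
    """Autocorrelation of Re(v_q(t) - <v_q>) across frames.

    Live interfaces decorrelate over a finite relaxation time, whereas
    frame-to-frame detector noise is white; the lag-1 value separates the
    two.  A constant series has no defined autocorrelation and is flagged.
    """
    if len(series) < 100:
        raise ValueError(f"need >= 100 frames, got {len(series)}")
    x = np.array([m.upsilon[q - 1].real for m in series], dtype=float)
    x = x - x.mean()
    if n_lags is None:
        n_lags = min(len(x) // 4, 100)
    if np.allclose(x, 0.0):
        return Autocorrelation(
            q=q,
            lags=np.arange(n_lags + 1),
            values=np.full(n_lags + 1, np.nan),
            defined=False,
        )
    values = _acf(x, nlags=n_lags, fft=True)
    return Autocorrelation(
        q=q, lags=np.arange(n_lags + 1), values=values, defined=True
    )
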