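"""Fit measured fluctuation spectra to the Helfrich model and filter granules.

The corrected mode powers |F_q|^2 (q = 2..15) are compared with the
theoretical spectrum through the fit error

    E = sqrt( (1/N_q) * sum_q [ log10 |F_q|^2 - log10 model_q ]^2 ),

the RMS of decimal-log residuals, so every mode of a spectrum spanning
orders of magnitude carries equal weight.  Three model variants are fitted:
the full two-parameter (kappa, sigma_bar) spectrum by a coarse log-grid
search refined with Nelder-Mead, and the tension-only / bending-only
one-parameter limits, whose single multiplicative parameter has a
closed-form optimum under E (the mean log offset), making their errors the
population SD of the log residuals.

Granule populations are then filtered exactly as a high-throughput run
requires, with per-stage counts: (1) closed outline in at least 60% of
frames; (2) bending rigidity must matter, i.e. the error increase when it
is removed, delta = E_tension_only - E_full, is at least 0.03 (granules
whose spectral crossover sqrt(sigma_bar) lies beyond q_max carry no bending
information and are excluded here); (3) E_full at most 0.5 (large irregular
granules fit nothing).  Survivors are summarized by geometric means with
+/-1 SD log-normal bands (the "67%" band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .helfrich_spectrum import (
    DEFAULT_L_MAX,
    DEFAULT_Q_MAX,
    DEFAULT_TEMPERATURE_K,
    ModelParams,
    TheoreticalSpectrum,
    convert_units,
    model_spectrum,
    projection_table,
)
from .mode_analysis import ModeStatistics

__all__ = [
    "HelfrichFit",
    "PopulationSummary",
    "FilterConfig",
    "fit_error",
    "fit_spectrum",
    "apply_filters",
    "population_stats",
]

#: Optimizer bounds in log10, bracketing the observed parameter ranges by
#: well over two decades on each side.
LOG10_KAPPA_BOUNDS = (-2.0, 4.0)
LOG10_SIGMA_BAR_BOUNDS = (-4.0, 6.0)
GRID_SIZE = 60

#: Minimum number of modes with positive corrected power for a fit.
MIN_FIT_MODES = 5


@dataclass(frozen=True)
class HelfrichFit:
    """Per-granule fit of the projected Helfrich spectrum."""

    kappa: float  # kB*T units
    sigma_bar: float  # dimensionless
    sigma_physical: float  # uN/m
    error_full: float
    error_tension_only: float
    error_bending_only: float
    delta_error_bending: float  # error_tension_only - error_full
    radius: float  # um (NaN when unknown)
    converged: bool
    degenerate: bool  # crossover sqrt(sigma_bar) beyond the fitted q range
    n_modes: int
    temperature: float

    def to_dict(self) -> dict:
        return {
            "kappa_kbt": self.kappa,
            "sigma_bar": self.sigma_bar,
            "sigma_uN_per_m": self.sigma_physical,
            "error_full": self.error_full,
            "error_tension_only": self.error_tension_only,
            "error_bending_only": self.error_bending_only,
            "delta_error_bending": self.delta_error_bending,
            "radius_um": self.radius,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_modes": self.n_modes,
        }


def fit_error(measured, model) -> float:
    """RMS of log10 residuals between measured and model mode powers.

    Symmetric in its arguments; a uniform factor-10 offset gives exactly
    1.0.  Non-positive powers signal a failed extraction and are rejected.
    """
    f2 = measured.F2 if isinstance(measured, ModeStatistics) else np.asarray(measured)
    m = model.power if isinstance(model, TheoreticalSpectrum) else np.asarray(model)
    f2 = np.asarray(f2, dtype=float)
    m = np.asarray(m, dtype=float)
    if f2.shape != m.shape:
        raise ValueError(f"shape mismatch: {f2.shape} vs {m.shape}")
    if np.any(f2 <= 0) or np.any(m <= 0):
        raise ValueError("fit_error requires strictly positive mode powers")
    r = np.log10(f2) - np.log10(m)
    return float(np.sqrt(np.mean(r**2)))


def _mode_sums(q: np.ndarray, l_max: int, sigma_bars: np.ndarray) -> np.ndarray:
    """f[j, i] = sum_l w_lq / {(l+2)(l-1)[l(l+1)+sigma_bar_j]} at q = q[i]."""
    table = projection_table(int(q.max()), l_max)
    l = np.arange(2, l_max + 1, dtype=float)
    w = table.weights[q][:, 2:]  # (n_q, n_l)
    denom = (l + 2) * (l - 1) * (
        l * (l + 1) + np.asarray(sigma_bars, dtype=float)[:, None]
    )  # (n_sb, n_l)
    return np.einsum("ql,sl->sq", w, 1.0 / denom)


def fit_spectrum(
    measured: ModeStatistics,
    temperature: float = DEFAULT_TEMPERATURE_K,
    l_max: int = DEFAULT_L_MAX,
    q_max: int = DEFAULT_Q_MAX,
    corrected: bool = True,
) -> HelfrichFit:
    """Fit (kappa, sigma_bar) to a granule's corrected fluctuation spectrum.

    Modes q = 2..q_max with positive power enter the fit (q = 1 mixes with
    centre error and is never fitted); at least ``MIN_FIT_MODES`` must
    survive.  A 60 x 60 log-spaced grid over kappa in [1e-2, 1e4] kB*T and
    sigma_bar in [1e-4, 1e6] seeds a Nelder-Mead refinement in
    (log10 kappa, log10 sigma_bar).  Deterministic given data and settings.
    ``corrected=False`` fits the uncorrected mean power <|v_q|^2> instead
    of |F_q|^2 (used to demonstrate the base-shape bias).
    """
    power_all = measured.F2 if corrected else measured.mean_power
    q_all = measured.q
    sel = (q_all >= 2) & (q_all <= q_max) & (power_all > 0)
    q = q_all[sel]
    f2 = power_all[sel]
    if q.size < MIN_FIT_MODES:
        raise ValueError(
            f"need >= {MIN_FIT_MODES} fitted modes with positive power, got {q.size}"
        )
    log_f2 = np.log10(f2)

    # --- coarse grid: kappa enters only as a prefactor, so evaluate the
    # sigma_bar-dependent sums once per grid column
    lk = np.linspace(*LOG10_KAPPA_BOUNDS, GRID_SIZE)
    ls = np.linspace(*LOG10_SIGMA_BAR_BOUNDS, GRID_SIZE)
    f = _mode_sums(q, l_max, 10.0**ls)  # (n_sb, n_q)
    log_f = np.log10(f)
    # E^2[i, j] over kappa i, sigma_bar j
    resid = log_f2[None, None, :] - (log_f[None, :, :] - lk[:, None, None])
    err2 = np.mean(resid**2, axis=2)
    i0, j0 = np.unravel_index(np.argmin(err2), err2.shape)

    def objective(x: np.ndarray) -> float:
        lk_, ls_ = x
        model = _mode_sums(q, l_max, np.array([10.0**ls_]))[0]
        r = log_f2 - (np.log10(model) - lk_)
        return float(np.mean(r**2))

    res = optimize.minimize(
        objective,
        x0=np.array([lk[i0], ls[j0]]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    lk_fit, ls_fit = res.x
    error_full = float(np.sqrt(res.fun))
    eps = 1e-3
    on_bound = (
        lk_fit <= LOG10_KAPPA_BOUNDS[0] + eps
        or lk_fit >= LOG10_KAPPA_BOUNDS[1] - eps
        or ls_fit <= LOG10_SIGMA_BAR_BOUNDS[0] + eps
        or ls_fit >= LOG10_SIGMA_BAR_BOUNDS[1] - eps
    )
    kappa = 10.0**lk_fit
    sigma_bar = 10.0**ls_fit

    # --- one-parameter variants: closed-form optimum of the log offset
    table = projection_table(q_max, l_max)
    l = np.arange(2, l_max + 1, dtype=float)
    w = table.weights[q][:, 2:]
    s_tension = (w / ((l + 2) * (l - 1))).sum(axis=1)
    s_bending = (w / ((l + 2) * (l - 1) * l * (l + 1))).sum(axis=1)
    error_tension = float(np.std(log_f2 - np.log10(s_tension)))
    error_bending = float(np.std(log_f2 - np.log10(s_bending)))

    radius_um = measured.mean_radius_um
    if radius_um is not None and radius_um > 0:
        sigma_si, _ = convert_units(kappa, sigma_bar, temperature, radius_um * 1e-6)
        sigma_un = sigma_si * 1e6
    else:
        radius_um = float("nan")
        sigma_un = float("nan")

    return HelfrichFit(
        kappa=float(kappa),
        sigma_bar=float(sigma_bar),
        sigma_physical=float(sigma_un),
        error_full=error_full,
        error_tension_only=error_tension,
        error_bending_only=error_bending,
        delta_error_bending=error_tension - error_full,
        radius=float(radius_um),
        converged=bool(res.success and not on_bound),
        degenerate=bool(np.sqrt(sigma_bar) > q_max),
        n_modes=int(q.size),
        temperature=float(temperature),
    )


@dataclass(frozen=True)
class FilterConfig:
    """Population filter thresholds (defaults as used throughout)."""

    min_pass_rate: float = 0.60
    min_delta_error: float = 0.03
    max_error: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_pass_rate <= 1):
            raise ValueError("min_pass_rate must be in (0, 1]")
        if self.min_delta_error < 0 or self.max_error <= 0:
            raise ValueError("filter thresholds must be positive")


def apply_filters(
    results: pd.DataFrame, thresholds: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sequential population filters with per-stage counts.

    ``results`` needs columns ``pass_rate``, ``delta_error_bending`` and
    ``error_full``.  Stage 1 removes granules lacking a closed outline in
    at least ``min_pass_rate`` of the frames; stage 2 removes granules
    whose fit is insensitive to bending rigidity
    (delta_error_bending < ``min_delta_error``); stage 3 removes poor fits
    (error_full > ``max_error``).  Returns the surviving rows (annotated
    with ``filter_stage_reached`` = 0) plus a count ledger; removed rows
    are not returned but their counts per stage are.
    """
    thresholds = thresholds or FilterConfig()
    df = results.copy()
    stage = filter_stages(df, thresholds)
    df["filter_stage_reached"] = stage
    kept = df[stage == 0].reset_index(drop=True)
    counts = {
        "n_input": int(len(df)),
        "removed_outline": int((stage == 1).sum()),
        "removed_bending": int((stage == 2).sum()),
        "removed_error": int((stage == 3).sum()),
        "n_final": int(len(kept)),
    }
    return kept, counts


def filter_stages(results: pd.DataFrame, thresholds: FilterConfig) -> np.ndarray:
    """Stage (1, 2, 3) at which each granule is removed; 0 = survives all."""
    stage = np.zeros(len(results), dtype=int)
    fail1 = results["pass_rate"].to_numpy() < thresholds.min_pass_rate
    fail2 = (~fail1) & (
        results["delta_error_bending"].to_numpy() < thresholds.min_delta_error
    )
    fail3 = (
        (~fail1)
        & (~fail2)
        & (results["error_full"].to_numpy() > thresholds.max_error)
    )
    stage[fail1], stage[fail2], stage[fail3] = 1, 2, 3
    return stage


@dataclass(frozen=True)
class PopulationSummary:
    """Geometric means with +/-1 SD log-normal bands (the 67% bands)."""

    n_granules: int
    geometric_mean_sigma: float  # uN/m
    sigma_band_lo: float
    sigma_band_hi: float
    geometric_mean_kappa: float  # kB*T
    kappa_band_lo: float
    kappa_band_hi: float

    def to_frame(self, treatment: str = "") -> pd.DataFrame:
        """Two-row summary table (interfacial tension, bending rigidity)."""
        return pd.DataFrame(
            {
                "treatment": [treatment, treatment],
                "quantity": ["interfacial_tension_uN_per_m", "bending_rigidity_kBT"],
                "geometric_mean": [
                    self.geometric_mean_sigma,
                    self.geometric_mean_kappa,
                ],
                "band_lo": [self.sigma_band_lo, self.kappa_band_lo],
                "band_hi": [self.sigma_band_hi, self.kappa_band_hi],
                "n_granules": [self.n_granules, self.n_granules],
            }
        )


def _geo_stats(values: np.ndarray) -> tuple[float, float, float]:
    logs = np.log(values)
    mu = logs.mean()
    sd = logs.std()  # population SD; degenerate (zero-width) band for n = 1
    return float(np.exp(mu)), float(np.exp(mu - sd)), float(np.exp(mu + sd))


def population_stats(fits: pd.DataFrame) -> PopulationSummary:
    """Geometric mean and +/-1 SD band of sigma and kappa over a population.

    ``fits`` needs positive ``sigma_uN_per_m`` and ``kappa_kbt`` columns.
    """
    if len(fits) < 1:
        raise ValueError("population_stats needs at least one granule")
    sigma = fits["sigma_uN_per_m"].to_numpy(dtype=float)
    kappa = fits["kappa_kbt"].to_numpy(dtype=float)
    if np.any(sigma <= 0) or np.any(kappa <= 0) or not np.all(
        np.isfinite(sigma) & np.isfinite(kappa)
    ):
        raise ValueError("fitted values must be positive and finite")
    gm_s, lo_s, hi_s = _geo_stats(sigma)
    gm_k, lo_k, hi_k = _geo_stats(kappa)
    return PopulationSummary(
        n_granules=len(fits),
        geometric_mean_sigma=gm_s,
        sigma_band_lo=lo_s,
        sigma_band_hi=hi_s,
        geometric_mean_kappa=gm_k,
        kappa_band_lo=lo_k,
        kappa_band_hi=hi_k,
    )
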