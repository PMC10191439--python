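"""Shared fixtures: synthetic contours, rendered discs, optics defaults."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from flickerspec import Contour, OpticsModel

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

PIXEL_SIZE_UM = 0.065


def make_contour(radii_px: np.ndarray, n: int = 400) -> Contour:
    """Ground-truth contour with radii given in pixels (stored in um)."""
    radii_px = np.broadcast_to(np.asarray(radii_px, dtype=float), (n,))
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Contour(
        center=(0.0, 0.0),
        angles=angles,
        radii=radii_px * PIXEL_SIZE_UM,
        ray_valid=np.ones(n, dtype=bool),
        valid=True,
    )


def frame_center(frame) -> tuple[float, float]:
    h, w = frame.pixels.shape
    return ((h - 1) / 2.0, (w - 1) / 2.0)


@pytest.fixture(scope="session")
def paper_optics() -> OpticsModel:
    """Rendering conditions emulating the acquisitions: PSF 1.3 px, SNR 5."""
    return OpticsModel(psf_sigma=1.3, snr=5.0, pixel_size=PIXEL_SIZE_UM)


@pytest.fixture()
def circle_contour() -> Contour:
    return make_contour(np.full(400, 12.0))


@pytest.fixture()
def angles400() -> np.ndarray:
    return np.linspace(0.0, 2.0 * np.pi, 400, endpoint=False)
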