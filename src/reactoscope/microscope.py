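"""Simulated microscope backend.

Renders camera images of the ground-truth population per channel and
exposure, delivers DMD light doses with Gaussian bleed-through, and exposes
the handle contract (`snap`, `set_exposure`, `dmd_stimulate`) that the
acquisition loop expects from hardware.

Camera model: expected pixel value inside a cell is

    background_level + intensity_gain * exposure_ms * signal(cell, channel)

with optional Poisson shot noise (mean = expected intensity) and additive
Gaussian read noise. Cells are filled ellipses; brightfield renders dark
interiors on a bright background with an edge gradient so that threshold
segmentation is well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .cells import CellTruth

CHANNELS = ("brightfield", "GFP", "RFP", "CFP")

# which molecular state each fluorescence channel reads out
_CHANNEL_SIGNAL = {
    "GFP": lambda c: c.protein_count,   # light-driven expression reporter
    "RFP": lambda c: c.dye_level,       # decaying membrane dye
    "CFP": lambda c: c.reporter_level,  # recombination reporter
}


@dataclass(frozen=True)
class VirtualSampleParams:
    """Optics + sample rendering parameters."""

    image_shape: tuple = (256, 256)
    pixel_size: float = 0.1  # um/px
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    dye_decay_rate: float = math.log(2) / 180.0  # 1/min
    bleed_psf_sigma: float = 2.0  # px
    intensity_gain: float = 0.01  # intensity units per (molecule * ms)

    def __post_init__(self) -> None:
        if min(self.image_shape) < 64:
            raise ValueError("image_shape must be at least 64x64")
        for name in ("read_noise_sd", "dye_decay_rate", "bleed_psf_sigma",
                     "intensity_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StimulationMask:
    """Boolean DMD pattern applied for ``duration_ms`` at relative intensity."""

    pixels: np.ndarray
    duration_ms: float = 1000.0
    intensity: float = 1.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


def cell_footprint(cell: CellTruth, shape: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices (rows, cols) of the cell's ground-truth ellipse."""
    return draw_ellipse(cell.centroid[0], cell.centroid[1],
                        cell.semi_axes[0], cell.semi_axes[1],
                        shape=shape, rotation=cell.orientation)


def ground_truth_labels(population: list[CellTruth], shape: tuple) -> np.ndarray:
    """Label image from ground-truth ellipses (label = cell id + 1)."""
    lab = np.zeros(shape, dtype=np.int32)
    for cell in population:
        rr, cc = cell_footprint(cell, shape)
        lab[rr, cc] = cell.id + 1
    return lab


def snap_image(
    population: list[CellTruth],
    channel: str,
    exposure_ms: float,
    params: VirtualSampleParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one camera frame (float image; intensity units)."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be > 0")
    shape = params.image_shape
    expected = np.full(shape, float(params.background_level))
    if channel == "brightfield":
        # dark interiors, brighter near the rim: radial gradient per cell
        for cell in population:
            rr, cc = cell_footprint(cell, shape)
            if len(rr) == 0:
                continue
            dr = rr - cell.centroid[0]
            dc = cc - cell.centroid[1]
            r_norm = np.sqrt((dr / max(cell.semi_axes[0], 1e-9)) ** 2
                             + (dc / max(cell.semi_axes[1], 1e-9)) ** 2)
            # 0.35x background at center rising to 0.7x at the rim, keeping a
            # sharp step at the cell boundary for threshold segmentation
            expected[rr, cc] = params.background_level * (0.35 + 0.35 * np.clip(r_norm, 0, 1))
    else:
        signal_of = _CHANNEL_SIGNAL[channel]
        gain = params.intensity_gain * exposure_ms
        for cell in population:
            rr, cc = cell_footprint(cell, shape)
            expected[rr, cc] = params.background_level + gain * signal_of(cell)
    if params.shot_noise:
        img = rng.poisson(expected).astype(float)
    else:
        img = expected.copy()
    if params.read_noise_sd > 0:
        img += rng.normal(0.0, params.read_noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def dmd_stimulate(
    population: list[CellTruth],
    mask: StimulationMask,
    params: VirtualSampleParams,
) -> dict[int, float]:
    """Deliver a DMD stimulation; returns per-cell light dose.

    The effective illumination field is the mask blurred with a Gaussian of
    ``bleed_psf_sigma`` px (DMD bleed-through). A cell's dose is
    ``duration_ms * intensity * mean(field over its ground-truth footprint)``.
    """
    pix = np.asarray(mask.pixels)
    if pix.shape != tuple(params.image_shape):
        raise ValueError("mask shape does not match the camera image")
    field = pix.astype(float)
    if params.bleed_psf_sigma > 0:
        field = ndimage.gaussian_filter(field, params.bleed_psf_sigma)
    doses: dict[int, float] = {}
    for cell in population:
        rr, cc = cell_footprint(cell, params.image_shape)
        cover = float(field[rr, cc].mean()) if len(rr) else 0.0
        doses[cell.id] = mask.duration_ms * mask.intensity * cover
    return doses


class VirtualMicroscope:
    """Hardware handle over a simulated sample.

    Tracks per-channel exposure (with clamping to ``[e_min, e_max]``), renders
    frames from the current population state, and records delivered light
    doses into each cell's light history.
    """

    def __init__(
        self,
        population: list[CellTruth],
        params: VirtualSampleParams,
        rng: np.random.Generator,
        e_min: float = 1.0,
        e_max: float = 1000.0,
        log=None,
    ):
        self.population = population
        self.params = params
        self.rng = rng
        self.e_min = float(e_min)
        self.e_max = float(e_max)
        self.exposures = {ch: 100.0 for ch in CHANNELS}
        self.clock_min = 0.0
        self.log = log

    def set_exposure(self, channel: str, exposure_ms: float) -> float:
        """Set channel exposure; out-of-range requests are clamped + warned."""
        if channel not in self.exposures:
            raise ValueError(f"unknown channel {channel!r}")
        clamped = min(max(exposure_ms, self.e_min), self.e_max)
        if clamped != exposure_ms and self.log is not None:
            self.log.warning("microscope", "exposure request clamped",
                             channel=channel, requested=exposure_ms, used=clamped)
        self.exposures[channel] = clamped
        if self.log is not None:
            self.log.info("microscope", "exposure set", channel=channel,
                          exposure_ms=clamped)
        return clamped

    def snap(self, channel: str, exposure_ms: float | None = None) -> np.ndarray:
        expo = self.exposures[channel] if exposure_ms is None else exposure_ms
        return snap_image(self.population, channel, expo, self.params, self.rng)

    def stimulate(self, mask: StimulationMask) -> dict[int, float]:
        doses = dmd_stimulate(self.population, mask, self.params)
        for cell in self.population:
            d = doses.get(cell.id, 0.0)
            if d > 0:
                cell.light_history.append((self.clock_min, d))
        if self.log is not None:
            self.log.info("microscope", "dmd stimulation delivered",
                          n_pixels=int(np.asarray(mask.pixels).sum()),
                          duration_ms=mask.duration_ms,
                          total_dose=float(sum(doses.values())))
        return doses
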