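"""Fluorescent sediment profile imaging (f-SPI) particle-reworking metrics.

A sediment aquarium is photographed through its transparent walls under UV
light so that fluorescent tracer particles (luminophores) resting on and
below the sediment surface stand out against the sediment matrix.  This
module turns such an image into four summary statistics of faunal particle
reworking:

``L_med``, ``L_mean``, ``L_max``
    median / mean / maximum mixed depth (cm) of tracer pixels below the
    *local* sediment-water interface.  The median tracks routine surficial
    activity, the maximum tracks rare deep transport events, and the mean
    sits between the two.
``SBR``
    surface boundary roughness: the vertical relief (max - min elevation,
    cm) of the detected sediment-water interface.

Depths are measured per column from the locally detected interface rather
than from a global plane, so a rough surface does not bias the shallow
statistics.  Metrics are computed over tracer *pixels* (area weighting);
individual particle identity is not recoverable from a photograph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

__all__ = [
    "ProfileImage",
    "TracerMask",
    "InterfaceProfile",
    "ReworkingMetrics",
    "ColorRule",
    "DegradedImageError",
    "detect_tracers",
    "detect_interface",
    "reworking_metrics",
    "analyze_profile_image",
]

#: default physical pixel size of the imaging setup, cm (56 um per pixel)
DEFAULT_PIXEL_SIZE_CM = 56e-4


class DegradedImageError(ValueError):
    """Raised when the sediment-water interface cannot be traced reliably."""


@dataclass
class ProfileImage:
    """One composite profile image of an aquarium (RGB, rows increase downward)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_size_cm: float = DEFAULT_PIXEL_SIZE_CM
    aquarium_id: str = ""
    face_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ProfileImage.pixels must be an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("ProfileImage must have at least 2 rows and 2 columns")
        if not self.pixel_size_cm > 0:
            raise ValueError("pixel_size_cm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class TracerMask:
    """Boolean mask of tracer pixels, aligned with a :class:`ProfileImage`."""

    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_tracer_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class InterfaceProfile:
    """Per-column row index of the sediment-water interface."""

    elevation: np.ndarray  # (W,) float row index, NaN where invalid
    valid: np.ndarray  # (W,) bool

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.elevation.shape != self.valid.shape:
            raise ValueError("elevation and valid must have the same length")


@dataclass
class ReworkingMetrics:
    """The four f-SPI summary statistics for one aquarium.

    All lengths in cm.  When no tracer pixels were found the three L metrics
    are NaN (an explicit missing-value record) and ``n_tracer_px`` is 0.
    """

    L_med_cm: float
    L_mean_cm: float
    L_max_cm: float
    SBR_cm: float
    n_tracer_px: int
    aquarium_id: str = ""

    def as_dict(self) -> dict:
        return {
            "aquarium_id": self.aquarium_id,
            "L_med_cm": self.L_med_cm,
            "L_mean_cm": self.L_mean_cm,
            "L_max_cm": self.L_max_cm,
            "SBR_cm": self.SBR_cm,
            "n_tracer_px": self.n_tracer_px,
        }


@dataclass
class ColorRule:
    """HSV window that defines "tracer-colored" pixels.

    Defaults target the saturated magenta rendering of pink luminophores:
    hue within ``hue_tol`` of ``hue_center`` (circular distance, hue in
    [0, 1)), saturation above ``sat_min`` and value above ``val_min``.
    """

    hue_center: float = 5.0 / 6.0  # magenta
    hue_tol: float = 0.10
    sat_min: float = 0.40
    val_min: float = 0.25

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        hsv = rgb2hsv(pixels)
        dh = np.abs(hsv[..., 0] - self.hue_center)
        dh = np.minimum(dh, 1.0 - dh)  # hue is circular
        return (dh <= self.hue_tol) & (hsv[..., 1] >= self.sat_min) & (hsv[..., 2] >= self.val_min)


def detect_tracers(
    image: ProfileImage,
    color_rule: ColorRule | None = None,
    remove_isolated: bool = True,
) -> TracerMask:
    """Segment tracer pixels by color.

    Pixels matching ``color_rule`` are kept; isolated single pixels with no
    true 8-neighbour are then removed as noise (sensor salt-and-pepper noise
    is single-pixel, real tracer particles span at least two pixels at the
    imaging resolution).  An empty mask is legal and simply yields
    ``n_tracer_px = 0``.
    """
    rule = color_rule or ColorRule()
    mask = rule.apply(image.pixels)
    if remove_isolated and mask.any():
        neighbours = ndimage.convolve(
            mask.astype(np.uint8), np.ones((3, 3), dtype=np.uint8), mode="constant"
        )
        # neighbours counts the pixel itself; ==1 means no 8-neighbour
        mask &= neighbours > 1
    return TracerMask(mask=mask)


def _luminance(pixels: np.ndarray) -> np.ndarray:
    p = pixels.astype(float)
    return 0.2125 * p[..., 0] + 0.7154 * p[..., 1] + 0.0721 * p[..., 2]


def detect_interface(
    image: ProfileImage,
    luminance_threshold: float | None = None,
    median_window: int = 11,
) -> InterfaceProfile:
    """Trace the sediment-water interface.

    For each column the interface is the first row (top-down) whose
    luminance exceeds ``luminance_threshold`` (Otsu's split of the image
    luminance when None — the water column is much darker than the sediment
    matrix).  The per-column elevations are median-filtered across columns
    (window ``median_window``) to suppress single-column artefacts.  Columns
    with no supra-threshold pixel are flagged invalid; if more than half the
    columns are invalid a :class:`DegradedImageError` is raised.
    """
    lum = _luminance(image.pixels)
    if luminance_threshold is None:
        luminance_threshold = float(threshold_otsu(lum))
    above = lum > luminance_threshold
    valid = above.any(axis=0)
    if valid.sum() < 0.5 * above.shape[1]:
        raise DegradedImageError(
            f"interface not detectable in {int((~valid).sum())} of {above.shape[1]} columns"
        )
    first = np.argmax(above, axis=0).astype(float)
    first[~valid] = np.nan
    if (~valid).any():
        cols = np.arange(above.shape[1])
        first[~valid] = np.interp(cols[~valid], cols[valid], first[valid])
    if median_window > 1:
        filtered = ndimage.median_filter(first, size=median_window, mode="nearest")
    else:
        filtered = first
    return InterfaceProfile(elevation=filtered, valid=valid)


def tracer_depths_cm(
    mask: TracerMask, interface: InterfaceProfile, pixel_size_cm: float
) -> np.ndarray:
    """Depth (cm) below the local interface of every tracer pixel.

    Pixels above the local interface (tracer resting on the surface of a
    rough bed) are clamped to depth 0.
    """
    rows, cols = np.nonzero(mask.mask)
    depths_px = rows - interface.elevation[cols]
    return np.maximum(depths_px, 0.0) * pixel_size_cm


def reworking_metrics(
    mask: TracerMask,
    interface: InterfaceProfile,
    pixel_size_cm: float,
    aquarium_id: str = "",
) -> ReworkingMetrics:
    """Compute L_med, L_mean, L_max and SBR from a tracer mask and interface.

    SBR is computed from the valid, median-filtered interface elevations.
    With an empty mask the depth statistics are undefined: a record with
    NaN L metrics is returned and a warning is emitted.
    """
    if mask.mask.shape[1] != interface.elevation.shape[0]:
        raise ValueError("mask and interface are not aligned to the same image")
    if not pixel_size_cm > 0:
        raise ValueError("pixel_size_cm must be positive")
    elev = interface.elevation[interface.valid]
    sbr = float((np.nanmax(elev) - np.nanmin(elev)) * pixel_size_cm) if elev.size else 0.0
    if mask.n_tracer_px == 0:
        warnings.warn(
            f"no tracer pixels detected{' in ' + aquarium_id if aquarium_id else ''}; "
            "L metrics are undefined",
            stacklevel=2,
        )
        return ReworkingMetrics(np.nan, np.nan, np.nan, sbr, 0, aquarium_id)
    depths = tracer_depths_cm(mask, interface, pixel_size_cm)
    return ReworkingMetrics(
        L_med_cm=float(np.median(depths)),
        L_mean_cm=float(np.mean(depths)),
        L_max_cm=float(np.max(depths)),
        SBR_cm=sbr,
        n_tracer_px=mask.n_tracer_px,
        aquarium_id=aquarium_id,
    )


def analyze_profile_image(
    image: ProfileImage,
    color_rule: ColorRule | None = None,
    luminance_threshold: float | None = None,
    median_window: int = 11,
) -> ReworkingMetrics:
    """Full f-SPI chain: tracers -> interface -> metrics for one image."""
    mask = detect_tracers(image, color_rule)
    interface = detect_interface(image, luminance_threshold, median_window)
    return reworking_metrics(mask, interface, image.pixel_size_cm, image.aquarium_id)
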