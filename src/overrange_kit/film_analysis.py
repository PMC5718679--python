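"""Exposed-length measurement from a (synthetic) CR film strip.

A computed-radiography strip laid along the scan axis records the full
longitudinal exposure pattern.  Fiducial markers of known centre-to-centre
separation give a length-to-pixel calibration; the exposed band's extent
at 10% of the maximum column-profile intensity, converted through that
calibration, is the absolute benchmark for the total exposed length.
The column profile is the mean over the strip's transverse axis
(integrating across the strip width), the simplest reproducible choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    AmbiguousPeakError,
    BandDetectionError,
    CalibrationError,
    NoSignalError,
)
from .edge_analysis import detect_edges
from .simulator import DosimeterTrace

__all__ = [
    "FilmMeasurement",
    "calibrate",
    "exposed_band_length",
    "measure_films",
    "reconcile",
]


@dataclass(frozen=True)
class FilmMeasurement:
    """Exposed-band length from one or more CR strip images."""

    band_pixels: float
    mm_per_pixel: float
    exposed_length: float  # mm = band_pixels * mm_per_pixel
    n_images: int = 1
    pixel_sd: float = 0.0


def calibrate(
    marker_pixel_positions: tuple[float, float], known_separation: float
) -> float:
    """Length-to-pixel calibration from a fiducial-marker pair, mm/px."""
    a, b = marker_pixel_positions
    d = abs(b - a)
    if d == 0:
        raise CalibrationError("fiducial markers are coincident")
    if known_separation <= 0:
        raise CalibrationError("known_separation must be positive")
    return known_separation / d


def _load(image: np.ndarray | str | Path) -> np.ndarray:
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        return np.asarray(iio.imread(image), dtype=float)
    return np.asarray(image, dtype=float)


def exposed_band_length(
    image: np.ndarray | str | Path,
    mm_per_pixel: float,
    threshold_fraction: float = 0.10,
) -> FilmMeasurement:
    """Measure the exposed band on a grayscale strip image.

    The band must run along axis 1 (columns = longitudinal direction).
    Its extent is the distance between the interpolated threshold
    crossings of the column profile, so the measurement is invariant to
    global intensity scaling.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    img = _load(image)
    if img.ndim == 3:  # collapse any colour axis
        img = img.mean(axis=-1)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    profile = img.mean(axis=0)
    pseudo = DosimeterTrace(
        readings=np.clip(profile, 0.0, None),
        sample_period=1.0,
        t0=0.0,
        label="film_profile",
    )
    try:
        edges = detect_edges(pseudo, threshold_fraction)
    except NoSignalError as exc:
        raise BandDetectionError("no exposed band found on the image") from exc
    except AmbiguousPeakError as exc:
        raise BandDetectionError(
            f"multiple exposed bands found: {exc.runs}"
        ) from exc
    band_px = edges.t_trail - edges.t_lead
    return FilmMeasurement(
        band_pixels=band_px,
        mm_per_pixel=mm_per_pixel,
        exposed_length=band_px * mm_per_pixel,
        n_images=1,
        pixel_sd=0.0,
    )


def measure_films(
    images: Sequence[np.ndarray | str | Path],
    mm_per_pixel: float,
    threshold_fraction: float = 0.10,
) -> FilmMeasurement:
    """Average the band length over repeated strip images (mean +/- sd)."""
    if not images:
        raise ValueError("images must be non-empty")
    px = np.array(
        [
            exposed_band_length(im, mm_per_pixel, threshold_fraction).band_pixels
            for im in images
        ]
    )
    mean_px = float(px.mean())
    return FilmMeasurement(
        band_pixels=mean_px,
        mm_per_pixel=mm_per_pixel,
        exposed_length=mean_px * mm_per_pixel,
        n_images=len(px),
        pixel_sd=float(px.std(ddof=1)) if len(px) > 1 else 0.0,
    )


def reconcile(
    exposed_length: float, console_length: float, collimation: float
) -> dict:
    """Compare film-measured exposure with the console displacement length.

    Returns the excess of the film measurement over the console value and
    that excess expressed in units of half a collimation width — the
    quantity that shows whether the console under-reports the exposure by
    one half beam width (ratio near 1).
    """
    if exposed_length <= 0 or console_length <= 0 or collimation <= 0:
        raise ValueError("all lengths must be positive")
    excess = exposed_length - console_length
    return {
        "excess": excess,
        "excess_in_collimation_halves": excess / (collimation / 2.0),
    }
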