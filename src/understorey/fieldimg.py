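"""Ground two-band (RED 660 nm / NIR 850 nm) and thermal image processing.

Implements the sample-point chain: calibrate camera digital numbers
against a ground target of known reflectance, compute per-pixel NDVI,
cut a region of interest (the 50 x 50 cm ruler square for NDVI images, a
fixed 150 x 150 cell extent for thermal matrices), and summarise it to
the statistics carried into the plot-level analyses.  Samples whose
calibration produced non-sensible NDVI are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TwoBandImage",
    "CalibrationTarget",
    "ThermalMatrix",
    "ROISummary",
    "SampleDecision",
    "calibrate",
    "calibrate_affine",
    "compute_ndvi",
    "delineate_roi",
    "summarize_roi",
    "validate_ndvi_sample",
    "read_thermal_csv",
    "read_two_band_png",
]


@dataclass
class TwoBandImage:
    """Congruent RED (660 nm) and NIR (850 nm) pixel grids."""

    red: np.ndarray
    nir: np.ndarray
    calibrated: bool = False
    units: str = "digital_number"

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        if self.red.shape != self.nir.shape:
            raise ValueError("RED and NIR bands must be congruent")


@dataclass
class CalibrationTarget:
    """Known reflectance and observed digital number per band, from the
    ground-target image acquired at the start of each survey."""

    known_reflectance: dict  # {"red": float, "nir": float}
    observed_dn: dict        # {"red": float, "nir": float}

    @classmethod
    def from_image(cls, image: TwoBandImage, known_reflectance: dict,
                   bounds=None) -> "CalibrationTarget":
        red, nir = image.red, image.nir
        if bounds is not None:
            red = delineate_roi(red, bounds)
            nir = delineate_roi(nir, bounds)
        return cls(
            known_reflectance=dict(known_reflectance),
            observed_dn={"red": float(np.nanmean(red)), "nir": float(np.nanmean(nir))},
        )


@dataclass
class ThermalMatrix:
    """A radiometric surface-temperature snapshot (deg C) read from CSV."""

    values: np.ndarray
    source: str = ""
    acquisition_time: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -20.0 or finite.max() > 70.0):
            warnings.warn(
                "thermal values outside the plausible (-20, 70) degC range",
                stacklevel=2,
            )


@dataclass
class ROISummary:
    mean: float
    median: float
    min: float
    max: float
    sd: float
    n_pixels: int


@dataclass
class SampleDecision:
    accepted: bool
    reason: str | None = None


def calibrate(image: TwoBandImage, target: CalibrationTarget) -> TwoBandImage:
    """Single-target multiplicative calibration (gain through the origin).

    Per band, gain = known_reflectance / observed_DN; survey digital
    numbers are multiplied by the gain to give reflectance.
    """
    if image.calibrated:
        raise ValueError("image is already calibrated")
    gains = {}
    for b in ("red", "nir"):
        dn = target.observed_dn[b]
        if not np.isfinite(dn) or dn <= 0:
            raise ValueError(
                f"calibration error: non-positive target DN for {b} band"
            )
        gains[b] = target.known_reflectance[b] / dn
    return TwoBandImage(
        red=image.red * gains["red"],
        nir=image.nir * gains["nir"],
        calibrated=True,
        units="reflectance",
    )


def calibrate_affine(image: TwoBandImage, dark: CalibrationTarget,
                     light: CalibrationTarget) -> TwoBandImage:
    """Two-target affine calibration: reflectance = gain * DN + offset,
    solved per band from a dark and a light reference patch."""
    if image.calibrated:
        raise ValueError("image is already calibrated")
    out = {}
    for b in ("red", "nir"):
        d0, d1 = dark.observed_dn[b], light.observed_dn[b]
        r0, r1 = dark.known_reflectance[b], light.known_reflectance[b]
        if d1 == d0:
            raise ValueError(f"calibration error: identical target DNs for {b}")
        gain = (r1 - r0) / (d1 - d0)
        offset = r0 - gain * d0
        out[b] = gain * getattr(image, b) + offset
    return TwoBandImage(red=out["red"], nir=out["nir"], calibrated=True,
                        units="reflectance")


def compute_ndvi(image: TwoBandImage, allow_uncalibrated: bool = False) -> np.ndarray:
    """Per-pixel NDVI = (NIR - RED) / (NIR + RED); NaN where the sum is 0."""
    if not image.calibrated and not allow_uncalibrated:
        raise ValueError("input must be calibrated (or pass allow_uncalibrated=True)")
    denom = image.nir + image.red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (image.nir - image.red) / denom, np.nan)
    return ndvi


def delineate_roi(values, bounds, thermal: bool = False) -> np.ndarray:
    """Cut the rectangular region of interest ``(row0, col0, row1, col1)``
    (inclusive corners) out of an image.

    Thermal regions must be exactly 150 x 150 cells, matching the fixed
    extent used for every thermal snapshot.
    """
    if isinstance(values, ThermalMatrix):
        values = values.values
        thermal = True
    values = np.asarray(values)
    r0, c0, r1, c1 = bounds
    if r0 < 0 or c0 < 0 or r1 >= values.shape[0] or c1 >= values.shape[1] or r1 < r0 or c1 < c0:
        raise ValueError(f"bounds {bounds} outside image of shape {values.shape}")
    h, w = r1 - r0 + 1, c1 - c0 + 1
    if thermal and (h, w) != (150, 150):
        raise ValueError(f"thermal ROI must be 150 x 150 cells, got {h} x {w}")
    return values[r0:r1 + 1, c0:c1 + 1]


def summarize_roi(values) -> ROISummary:
    """Summary statistics over the finite values of a region of interest.

    sd is the sample standard deviation (n - 1 denominator).
    """
    values = np.asarray(values, dtype=float).ravel()
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("region of interest contains no defined values")
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return ROISummary(
        mean=float(finite.mean()),
        median=float(np.median(finite)),
        min=float(finite.min()),
        max=float(finite.max()),
        sd=sd,
        n_pixels=int(finite.size),
    )


def validate_ndvi_sample(summary: ROISummary, values=None,
                         max_out_of_range: float = 0.05) -> SampleDecision:
    """Flag non-sensible NDVI samples produced by failed calibrations.

    Excludes when the ROI mean falls outside [-1, 1], or (when the pixel
    values are supplied) when more than ``max_out_of_range`` of the
    defined pixels do.
    """
    if not -1.0 <= summary.mean <= 1.0:
        return SampleDecision(False, f"mean NDVI {summary.mean:.3f} outside [-1, 1]")
    if values is not None:
        v = np.asarray(values, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size:
            frac = float(np.mean((v < -1.0) | (v > 1.0)))
            if frac > max_out_of_range:
                return SampleDecision(
                    False,
                    f"{100 * frac:.1f}% of pixels outside [-1, 1] "
                    f"(limit {100 * max_out_of_range:g}%)",
                )
    return SampleDecision(True)


def read_thermal_csv(path, delimiter: str = ",") -> ThermalMatrix:
    """Read a thermal snapshot stored as a headerless CSV grid of deg C."""
    values = pd.read_csv(path, header=None, delimiter=delimiter).to_numpy(dtype=float)
    return ThermalMatrix(values=values, source=str(path))


def read_two_band_png(path, red_band: int = 0, nir_band: int = 2) -> TwoBandImage:
    """Read a camera image whose channel 1 is RED and channel 3 is NIR."""
    from PIL import Image

    arr = np.asarray(Image.open(path), dtype=float)
    if arr.ndim != 3 or arr.shape[2] <= max(red_band, nir_band):
        raise ValueError(f"{path}: expected a 3-band image")
    return TwoBandImage(red=arr[:, :, red_band], nir=arr[:, :, nir_band])
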