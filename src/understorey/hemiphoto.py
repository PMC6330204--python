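"""Canopy structure from hemispherical photographs.

Processing chain: extract the blue band (maximum leaf/sky contrast),
threshold it with the global Ridler & Calvard (isodata) method, classify
pixels into vegetation and sky, restrict the field of view to zenith
angles of 0-60 degrees to avoid mixed pixels, and invert ring-wise gap
fractions into effective plant area index under the homogeneous-canopy
gap model P(theta) = exp(-G * L / cos(theta)) with a spherical leaf-angle
distribution (G = 0.5).  Foliage clumping is corrected with the
Lang-Xiang logarithmic gap averaging over azimuth cells, giving a
clumping index Omega <= 1 and LAI = LAI_effective / Omega.  Fractional
vegetation cover (FCover, %) is the share of vegetation pixels within
the 0-60 degree zone.

LAI here is a plant area index (PAI): stems, trunks and branches are not
masked out, as masking them would discard leaves hidden behind woody
material and bias LAI low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HemisphericalImage",
    "FisheyeBand",
    "BinaryCanopyMask",
    "GapFractionProfile",
    "CanopyStructure",
    "extract_blue_band",
    "ridler_calvard_threshold",
    "binarize",
    "gap_fraction_profile",
    "fcover",
    "invert_lai",
    "hinge_lai",
    "plot_canopy_structure",
    "VEGETATION",
    "SKY",
    "OUTSIDE",
]

# pixel classes of a BinaryCanopyMask
VEGETATION = 0
SKY = 1
OUTSIDE = 2

DEFAULT_G = 0.5  # spherical leaf-angle distribution
DEFAULT_MAX_ZENITH = 60.0  # degrees; field-of-view restriction


def _zenith_azimuth(shape, center, radius, lens, max_zenith_deg):
    """Per-pixel (zenith, azimuth) in degrees; NaN zenith outside footprint."""
    rows, cols = np.indices(shape[:2])
    dy = rows - center[0]
    dx = cols - center[1]
    r = np.hypot(dy, dx)
    frac = r / radius
    if lens == "equidistant":
        zen = max_zenith_deg * frac
    elif lens == "equisolid":
        s = np.sin(np.deg2rad(max_zenith_deg) / 2.0)
        zen = 2.0 * np.rad2deg(np.arcsin(np.clip(frac * s, 0.0, 1.0)))
    else:
        raise ValueError(f"unknown lens projection {lens!r}")
    zen = np.where(frac <= 1.0, zen, np.nan)
    azi = np.rad2deg(np.arctan2(dy, dx)) % 360.0
    return zen, azi


@dataclass
class HemisphericalImage:
    """An upward-looking fisheye photograph with its optical geometry.

    ``pixels`` is an (H, W, 3) array; ``optical_center`` is (row, col) in
    pixel coordinates; ``footprint_radius`` is the radius in pixels of the
    circular image footprint, which maps to ``max_zenith_deg`` under the
    given lens projection law.
    """

    pixels: np.ndarray
    optical_center: tuple[float, float]
    footprint_radius: float
    lens: str = "equidistant"
    max_zenith_deg: float = 90.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.footprint_radius <= 0:
            raise ValueError("footprint_radius must be positive")

    def zenith_azimuth(self):
        return _zenith_azimuth(
            self.pixels.shape, self.optical_center, self.footprint_radius,
            self.lens, self.max_zenith_deg,
        )


@dataclass
class FisheyeBand:
    """A single-channel image carrying the source fisheye geometry."""

    values: np.ndarray
    optical_center: tuple[float, float]
    footprint_radius: float
    lens: str = "equidistant"
    max_zenith_deg: float = 90.0

    def zenith_azimuth(self):
        return _zenith_azimuth(
            self.values.shape, self.optical_center, self.footprint_radius,
            self.lens, self.max_zenith_deg,
        )

    @property
    def footprint_mask(self):
        zen, _ = self.zenith_azimuth()
        return np.isfinite(zen)


@dataclass
class BinaryCanopyMask:
    """Per-pixel class in {VEGETATION, SKY, OUTSIDE} plus geometry."""

    classes: np.ndarray
    optical_center: tuple[float, float]
    footprint_radius: float
    lens: str = "equidistant"
    max_zenith_deg: float = 90.0
    threshold_used: float = np.nan

    def zenith_azimuth(self):
        return _zenith_azimuth(
            self.classes.shape, self.optical_center, self.footprint_radius,
            self.lens, self.max_zenith_deg,
        )


@dataclass
class GapFractionProfile:
    """Ring-wise gap fractions over (0, 60] degrees zenith.

    ``gap_fraction[i]`` is the sky share of ring ``rings[i]``;
    ``cell_gap_fraction[i, j]`` the sky share of azimuth cell j of that
    ring.  Cells that are fully vegetated (P = 0) are floored at
    1 / cell pixel count so that logarithms stay finite (the standard
    saturation guard of gap-fraction practice); raw counts are kept.
    """

    rings: list[tuple[float, float]]
    gap_fraction: np.ndarray            # (n_rings,)
    ring_counts: np.ndarray             # (n_rings,) in-footprint pixels
    ring_sky: np.ndarray                # (n_rings,) sky pixels
    cell_gap_fraction: np.ndarray       # (n_rings, n_cells)
    cell_counts: np.ndarray             # (n_rings, n_cells)
    cell_sky: np.ndarray                # (n_rings, n_cells)

    @property
    def ring_midpoints_deg(self):
        return np.array([(lo + hi) / 2.0 for lo, hi in self.rings])


@dataclass
class CanopyStructure:
    """Plot- or image-level canopy summary.

    fcover in percent over the 0-60 degree zone; lai_effective and lai in
    m2 m-2; clumping_index in (0, 1] with lai = lai_effective / clumping_index.
    """

    fcover: float
    lai_effective: float
    clumping_index: float
    lai: float
    n_images: int = 1
    fcover_per_image: list = field(default_factory=list)


def extract_blue_band(image: HemisphericalImage, band_index: int = 2) -> FisheyeBand:
    """Pull one channel (default the blue band) out of a fisheye image.

    The blue band maximises leaf/sky contrast: leaf absorption is near
    maximal and sky scattering highest there.
    """
    if image.pixels.ndim != 3 or image.pixels.shape[2] < 2:
        raise ValueError("expected a multi-channel image")
    if not 0 <= band_index < image.pixels.shape[2]:
        raise ValueError(f"band_index {band_index} out of range")
    return FisheyeBand(
        values=np.asarray(image.pixels[:, :, band_index], dtype=float),
        optical_center=image.optical_center,
        footprint_radius=image.footprint_radius,
        lens=image.lens,
        max_zenith_deg=image.max_zenith_deg,
    )


def ridler_calvard_threshold(
    band, footprint_mask=None, tol: float = 0.01, max_iter: int = 100
) -> float:
    """Global isodata (Ridler & Calvard) brightness threshold.

    Iterates T_{k+1} = (mean of values <= T_k + mean of values > T_k) / 2
    from the global mean until |T_{k+1} - T_k| < tol.  Raises on a
    constant image, for which no two-class threshold exists.
    """
    if isinstance(band, FisheyeBand):
        values = band.values
        if footprint_mask is None:
            footprint_mask = band.footprint_mask
    else:
        values = np.asarray(band, dtype=float)
    if footprint_mask is not None:
        values = values[np.asarray(footprint_mask, dtype=bool)]
    values = values[np.isfinite(values)].ravel()
    if values.size == 0:
        raise ValueError("no pixels to threshold")
    if np.min(values) == np.max(values):
        raise ValueError("constant image: no threshold exists")
    t = float(values.mean())
    for _ in range(max_iter):
        low = values[values <= t]
        high = values[values > t]
        if low.size == 0 or high.size == 0:
            # unreachable for t strictly inside (min, max); guard anyway
            raise ValueError("degenerate image: threshold iteration failed")
        t_new = (low.mean() + high.mean()) / 2.0
        if abs(t_new - t) < tol:
            return float(t_new)
        t = float(t_new)
    return float(t)


def binarize(band: FisheyeBand, threshold: float) -> BinaryCanopyMask:
    """Classify pixels: value > threshold -> SKY, <= threshold -> VEGETATION.

    Pixels outside the circular footprint are OUTSIDE.
    """
    inside = band.footprint_mask
    classes = np.full(band.values.shape, OUTSIDE, dtype=np.uint8)
    classes[inside & (band.values > threshold)] = SKY
    classes[inside & (band.values <= threshold)] = VEGETATION
    return BinaryCanopyMask(
        classes=classes,
        optical_center=band.optical_center,
        footprint_radius=band.footprint_radius,
        lens=band.lens,
        max_zenith_deg=band.max_zenith_deg,
        threshold_used=float(threshold),
    )


def _ring_cell_counts(mask: BinaryCanopyMask, ring_width_deg, n_azimuth_cells,
                      max_zenith_deg):
    zen, azi = mask.zenith_azimuth()
    edges = np.arange(0.0, max_zenith_deg + 1e-9, ring_width_deg)
    if edges[-1] < max_zenith_deg:
        edges = np.append(edges, max_zenith_deg)
    n_rings = len(edges) - 1
    n_cells = int(n_azimuth_cells)
    valid = (mask.classes != OUTSIDE) & np.isfinite(zen) & (zen <= max_zenith_deg)
    ring_idx = np.clip(np.searchsorted(edges, zen[valid], side="right") - 1, 0, n_rings - 1)
    cell_idx = np.clip((azi[valid] / 360.0 * n_cells).astype(int), 0, n_cells - 1)
    sky = (mask.classes[valid] == SKY).astype(np.int64)
    counts = np.zeros((n_rings, n_cells), dtype=np.int64)
    sky_counts = np.zeros((n_rings, n_cells), dtype=np.int64)
    np.add.at(counts, (ring_idx, cell_idx), 1)
    np.add.at(sky_counts, (ring_idx, cell_idx), sky)
    rings = [(float(edges[i]), float(edges[i + 1])) for i in range(n_rings)]
    return rings, counts, sky_counts


def _profile_from_counts(rings, counts, sky_counts) -> GapFractionProfile:
    ring_counts = counts.sum(axis=1)
    ring_sky = sky_counts.sum(axis=1)
    for (lo, hi), n in zip(rings, ring_counts):
        if n == 0:
            raise ValueError(f"empty zenith ring ({lo:g}, {hi:g}] deg: no pixels")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ring = ring_sky / ring_counts
        p_cell = np.where(counts > 0, sky_counts / np.maximum(counts, 1), np.nan)
    # saturation guard: fully vegetated -> 1/(pixel count) so logs stay finite
    p_ring = np.where(ring_sky == 0, 1.0 / ring_counts, p_ring)
    sat = (sky_counts == 0) & (counts > 0)
    p_cell = np.where(sat, 1.0 / np.maximum(counts, 1), p_cell)
    return GapFractionProfile(
        rings=rings,
        gap_fraction=p_ring.astype(float),
        ring_counts=ring_counts,
        ring_sky=ring_sky,
        cell_gap_fraction=p_cell.astype(float),
        cell_counts=counts,
        cell_sky=sky_counts,
    )


def gap_fraction_profile(
    mask: BinaryCanopyMask,
    ring_width_deg: float = 5.0,
    n_azimuth_cells: int = 8,
    max_zenith_deg: float = DEFAULT_MAX_ZENITH,
) -> GapFractionProfile:
    """Ring-wise (and azimuth-cell-wise) gap fractions within 0-60 degrees."""
    rings, counts, sky_counts = _ring_cell_counts(
        mask, ring_width_deg, n_azimuth_cells, max_zenith_deg
    )
    return _profile_from_counts(rings, counts, sky_counts)


def fcover(mask: BinaryCanopyMask, max_zenith_deg: float = DEFAULT_MAX_ZENITH) -> float:
    """Fractional vegetation cover (%) over the zenith <= max_zenith zone."""
    zen, _ = mask.zenith_azimuth()
    zone = (mask.classes != OUTSIDE) & np.isfinite(zen) & (zen <= max_zenith_deg)
    n = int(zone.sum())
    if n == 0:
        raise ValueError("no pixels inside the evaluation zone")
    veg = int((mask.classes[zone] == VEGETATION).sum())
    return 100.0 * veg / n


def invert_lai(profile: GapFractionProfile, g: float = DEFAULT_G) -> CanopyStructure:
    """Invert a gap-fraction profile into effective and clumping-corrected LAI.

    Effective LAI: under P(theta) = exp(-G L / cos theta) every ring gives
    -ln(P) cos(theta) = G L, so the ring-pixel-count-weighted mean k of
    -ln(P_ring) cos(theta_mid) estimates G L and LAI_eff = k / G (= 2 k for
    the spherical distribution).  Clumping: per ring,
    Omega_r = ln(mean-over-cells P) / mean-over-cells(ln P)  (Lang-Xiang),
    combined across rings by pixel-count weights; LAI = LAI_eff / Omega.
    """
    theta = np.deg2rad(profile.ring_midpoints_deg)
    p = np.clip(profile.gap_fraction, None, 1.0)
    w = profile.ring_counts.astype(float)
    if np.any(w <= 0):
        raise ValueError("every ring must contain pixels")
    k = float(np.sum(w * (-np.log(p) * np.cos(theta))) / np.sum(w))
    lai_eff = k / g

    # Lang-Xiang clumping from azimuth cells
    omegas = []
    omega_w = []
    for i in range(len(profile.rings)):
        cells = profile.cell_gap_fraction[i]
        cc = profile.cell_counts[i].astype(float)
        have = cc > 0
        if have.sum() < 2:
            continue
        pc = np.clip(cells[have], None, 1.0)
        wc = cc[have]
        p_bar = float(np.sum(wc * pc) / np.sum(wc))
        mean_ln = float(np.sum(wc * np.log(pc)) / np.sum(wc))
        if p_bar >= 1.0 or mean_ln == 0.0:
            continue  # fully open ring carries no clumping information
        omegas.append(np.log(p_bar) / mean_ln)
        omega_w.append(w[i])
    if omegas:
        omega = float(np.average(omegas, weights=omega_w))
    else:
        omega = 1.0
    if not 0.0 < omega <= 1.0:
        warnings.warn(
            f"clumping index {omega:.3f} outside (0, 1]; clipped to 1",
            stacklevel=2,
        )
        omega = 1.0
    lai = lai_eff / omega
    return CanopyStructure(
        fcover=float(np.nan),
        lai_effective=lai_eff,
        clumping_index=omega,
        lai=lai,
        n_images=1,
    )


def hinge_lai(profile: GapFractionProfile, g: float = DEFAULT_G) -> float:
    """Single-ring hinge-angle (57.5 deg) LAI estimate, as a cross-check.

    Near 57.5 degrees the projection function is close to 0.5 for any
    leaf-angle distribution, so one ring suffices:
    L = -ln(P) cos(theta) / G.
    """
    mids = profile.ring_midpoints_deg
    i = int(np.argmin(np.abs(mids - 57.5)))
    p = min(profile.gap_fraction[i], 1.0)
    return float(-np.log(p) * np.cos(np.deg2rad(mids[i])) / g)


def plot_canopy_structure(
    images: Sequence,
    ring_width_deg: float = 5.0,
    n_azimuth_cells: int = 8,
    max_zenith_deg: float = DEFAULT_MAX_ZENITH,
    g: float = DEFAULT_G,
    band_index: int = 2,
) -> CanopyStructure:
    """Plot-level canopy structure from all fisheye images of a plot.

    Ring-wise sky/vegetation pixel counts are pooled across images before
    the logarithm is taken (gap-fraction averaging precedes the log
    transform), then inverted once.  FCover is computed per image and
    reported as the plot mean.  Accepts HemisphericalImage or
    BinaryCanopyMask inputs.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    total_counts = None
    total_sky = None
    rings_ref = None
    fcovers = []
    for img in images:
        if isinstance(img, HemisphericalImage):
            band = extract_blue_band(img, band_index=band_index)
            t = ridler_calvard_threshold(band)
            mask = binarize(band, t)
        elif isinstance(img, BinaryCanopyMask):
            mask = img
        else:
            raise TypeError(f"cannot process {type(img).__name__}")
        rings, counts, sky = _ring_cell_counts(
            mask, ring_width_deg, n_azimuth_cells, max_zenith_deg
        )
        if rings_ref is None:
            rings_ref, total_counts, total_sky = rings, counts, sky
        else:
            if rings != rings_ref or counts.shape != total_counts.shape:
                raise ValueError("images use differing ring schemes")
            total_counts = total_counts + counts
            total_sky = total_sky + sky
        fcovers.append(fcover(mask, max_zenith_deg))
    profile = _profile_from_counts(rings_ref, total_counts, total_sky)
    structure = invert_lai(profile, g=g)
    structure.fcover = float(np.mean(fcovers))
    structure.fcover_per_image = [float(f) for f in fcovers]
    structure.n_images = len(images)
    return structure
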