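"""Synthetic inputs for every stage of the field-to-map pipeline.

The generators emulate the study conditions: 20 m x 20 m plots along
transects of paired habitats, ~12 fisheye sample points and 5 ground
NDVI/thermal sample points per plot, a homogeneous (or optionally
clumped) canopy of known leaf area, linear plot-level relationships with
field-calibrated coefficients, and a Landsat-like reflectance scene
driven by a smooth true-LAI field.  Every generator is a pure function
of its seed.

The default plot-level coefficients are the field-calibrated values of
the coastal-forest study system this package was built around: the
interaction model Thermal_ground ~ FCover * T_air with coefficients
(2.074357, 0.155010, 0.887836, -0.007211), its LAI counterpart
(3.2155, 3.0012, 0.8054, -0.1424), the marginal linear relations
Thermal_ground = 27.4 - 1.19 LAI and 27.6 - 0.06 FCover, and
NDVI_down = 0.57 - 0.09 LAI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .fieldimg import ThermalMatrix, TwoBandImage
from .hemiphoto import HemisphericalImage, _zenith_azimuth
from .satfeatures import RasterStack

__all__ = [
    "CanopySceneParams",
    "PlotSimParams",
    "PlotTruth",
    "LandsatSimParams",
    "gen_hemiphoto",
    "gen_ground_scene",
    "gen_plot_dataset",
    "gen_sample_points",
    "gen_landsat_scene",
    "HABITATS",
    "GROUND_TARGET_REFLECTANCE",
    "GROUND_GAINS",
]

HABITATS = ("grassland", "bush", "edge", "forest", "woodland", "plantation")

#: study sampling design: thermal dataset habitat composition (34 plots)
DEFAULT_HABITAT_MIX = {
    "grassland": 6 / 34, "bush": 1 / 34, "edge": 11 / 34,
    "forest": 12 / 34, "woodland": 0.0, "plantation": 4 / 34,
}

#: known reflectance of the calibration ground target, per band
GROUND_TARGET_REFLECTANCE = {"red": 0.87, "nir": 0.87}
#: true sensor gains (reflectance per digital number) of the simulated camera
GROUND_GAINS = {"red": 0.004, "nir": 0.005}


# ---------------------------------------------------------------------------
# hemispherical canopy scenes


@dataclass
class CanopySceneParams:
    """A homogeneous canopy stand of known leaf area photographed through
    a fisheye lens.  The gap probability at zenith theta is
    P(theta) = exp(-G * LAI / cos theta)."""

    true_lai: float
    projection_coefficient: float = 0.5
    image_size: int = 512
    lens: str = "equidistant"
    seed: int = 0
    clumped: bool = False
    disc_radius_frac: float = 0.012  # foliage-disc radius / image size (clumped mode)

    def __post_init__(self):
        if not np.isfinite(self.true_lai) or self.true_lai < 0:
            raise ValueError("true_lai must be finite and >= 0")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


def _paint(shape, sky_mask, inside, rng):
    """Render a uint8 RGB image: bright blue sky, dark vegetation."""
    h, w = shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    blue = np.where(sky_mask, 225.0, 30.0) + rng.normal(0.0, 6.0, (h, w))
    red = np.where(sky_mask, 170.0, 45.0) + rng.normal(0.0, 6.0, (h, w))
    green = np.where(sky_mask, 190.0, 70.0) + rng.normal(0.0, 6.0, (h, w))
    for c, chan in enumerate((red, green, blue)):
        img[:, :, c] = np.clip(np.where(inside, chan, 0.0), 0, 255).astype(np.uint8)
    return img


def gen_hemiphoto(params: CanopySceneParams) -> HemisphericalImage:
    """Simulate an upward fisheye photograph of a homogeneous canopy.

    Per-pixel sky/vegetation states are independent Bernoulli draws with
    ring-wise success probability exp(-G L / cos theta); in clumped mode
    foliage is instead laid down as opaque discs from a Boolean model
    whose disc intensity reproduces the same expected gap fraction while
    dispersing foliage non-randomly (clumping index < 1).
    """
    s = params.image_size
    center = ((s - 1) / 2.0, (s - 1) / 2.0)
    radius = (s - 1) / 2.0
    zen, _ = _zenith_azimuth((s, s), center, radius, params.lens, 90.0)
    inside = np.isfinite(zen)
    rng = np.random.default_rng(params.seed)
    g, lai = params.projection_coefficient, params.true_lai
    with np.errstate(divide="ignore", over="ignore"):
        cosz = np.cos(np.deg2rad(np.where(inside, zen, 0.0)))
        p_sky = np.exp(-np.divide(g * lai, np.maximum(cosz, 1e-9)))
    if not params.clumped or lai == 0:
        sky = rng.random((s, s)) < p_sky
    else:
        # Boolean disc model: gap probability exp(-mu * A) at intensity mu,
        # disc area A; choose mu(theta) A = g L / cos(theta)
        rd = max(2.0, params.disc_radius_frac * s)
        disc_area = np.pi * rd ** 2
        veg = np.zeros((s, s), dtype=bool)
        lam = g * lai / np.maximum(cosz, 1e-9) / disc_area  # discs per pixel
        lam = np.where(inside, lam, 0.0)
        n_discs = rng.poisson(lam.sum())
        if n_discs > 0:
            # sample centres proportional to local intensity
            flat = lam.ravel()
            idx = rng.choice(flat.size, size=n_discs, p=flat / flat.sum())
            rows, cols = np.unravel_index(idx, (s, s))
            yy, xx = np.mgrid[-int(rd) - 1:int(rd) + 2, -int(rd) - 1:int(rd) + 2]
            stamp = (yy ** 2 + xx ** 2) <= rd ** 2
            for r0, c0 in zip(rows, cols):
                rlo, rhi = r0 - int(rd) - 1, r0 + int(rd) + 2
                clo, chi = c0 - int(rd) - 1, c0 + int(rd) + 2
                sr = slice(max(rlo, 0), min(rhi, s))
                sc = slice(max(clo, 0), min(chi, s))
                veg[sr, sc] |= stamp[sr.start - rlo:sr.stop - rlo,
                                     sc.start - clo:sc.stop - clo]
        sky = ~veg
    img = _paint((s, s), sky, inside, rng)
    return HemisphericalImage(
        pixels=img, optical_center=center, footprint_radius=radius,
        lens=params.lens, max_zenith_deg=90.0,
    )


# ---------------------------------------------------------------------------
# ground two-band + thermal scenes


def gen_ground_scene(ndvi_true: float, temp_mean: float, temp_sd: float,
                     size: int = 200, seed: int = 0,
                     ndvi_noise_sd: float = 0.02):
    """Simulate one sample point: an uncalibrated two-band camera image,
    the calibration-target image, and a thermal matrix.

    The scene's reflectances are constructed so that a correctly
    calibrated NDVI recovers ``ndvi_true`` in expectation; the target
    image encodes the known target reflectance through the true sensor
    gains.  The thermal matrix is Gaussian with the stated mean/sd.
    """
    if not -1.0 <= ndvi_true <= 1.0:
        raise ValueError("ndvi_true must lie in [-1, 1]")
    if temp_sd < 0:
        raise ValueError("temp_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ndvi = ndvi_true + (rng.normal(0.0, ndvi_noise_sd, (size, size))
                        if ndvi_noise_sd > 0 else 0.0)
    ndvi = np.clip(ndvi, -0.999, 0.999)
    total = 0.6  # NIR + RED reflectance of the ground surface
    nir_refl = total * (1.0 + ndvi) / 2.0
    red_refl = total * (1.0 - ndvi) / 2.0
    survey = TwoBandImage(
        red=red_refl / GROUND_GAINS["red"],
        nir=nir_refl / GROUND_GAINS["nir"],
        calibrated=False,
    )
    target = TwoBandImage(
        red=np.full((32, 32), GROUND_TARGET_REFLECTANCE["red"] / GROUND_GAINS["red"]),
        nir=np.full((32, 32), GROUND_TARGET_REFLECTANCE["nir"] / GROUND_GAINS["nir"]),
        calibrated=False,
    )
    thermal = ThermalMatrix(
        values=temp_mean + (rng.normal(0.0, temp_sd, (size, size))
                            if temp_sd > 0 else np.zeros((size, size))),
        source="synthetic",
    )
    return survey, target, thermal


# ---------------------------------------------------------------------------
# plot-level datasets


@dataclass
class PlotTruth:
    """Generative coefficients for the plot-level relationships."""

    thermal_model: str = "fcover_x_tair"  # lai | fcover | fcover_x_tair | lai_x_tair
    thermal_lai: tuple = (27.4, -1.19)
    thermal_fcover: tuple = (27.6, -0.06)
    interaction_fcover: tuple = (2.074357, 0.155010, 0.887836, -0.007211)
    interaction_lai: tuple = (3.2155, 3.0012, 0.8054, -0.1424)
    ndvi_down_lai: tuple = (0.57, -0.09)


@dataclass
class PlotSimParams:
    """Design of a simulated plot campaign."""

    n_plots: int = 34
    habitat_mix: dict = field(default_factory=lambda: dict(DEFAULT_HABITAT_MIX))
    coefficients: PlotTruth = field(default_factory=PlotTruth)
    noise_sd_thermal: float = 1.5
    noise_sd_ndvi: float = 0.08
    t_air_range: tuple = (21.0, 29.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 4:
            raise ValueError("need at least 4 plots for model fitting")
        if self.noise_sd_thermal < 0 or self.noise_sd_ndvi < 0:
            raise ValueError("noise sd must be >= 0")
        total = sum(self.habitat_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"habitat proportions sum to {total}, not 1")
        unknown = set(self.habitat_mix) - set(HABITATS)
        if unknown:
            raise ValueError(f"unknown habitats {sorted(unknown)}")


#: LAI range sampled per habitat (m2 m-2)
_LAI_RANGE = {
    "grassland": (0.0, 0.0), "bush": (0.3, 1.5), "edge": (0.5, 3.0),
    "forest": (2.0, 6.0), "woodland": (0.5, 2.5), "plantation": (1.5, 4.0),
}


def _thermal_truth(truth: PlotTruth, lai, fcover, t_air):
    m = truth.thermal_model
    if m == "lai":
        a, b = truth.thermal_lai
        return a + b * lai
    if m == "fcover":
        a, b = truth.thermal_fcover
        return a + b * fcover
    if m == "fcover_x_tair":
        b0, bs, bt, bi = truth.interaction_fcover
        return b0 + bs * fcover + bt * t_air + bi * fcover * t_air
    if m == "lai_x_tair":
        b0, bs, bt, bi = truth.interaction_lai
        return b0 + bs * lai + bt * t_air + bi * lai * t_air
    raise ValueError(f"unknown thermal_model {m!r}")


def gen_plot_dataset(params: PlotSimParams) -> pd.DataFrame:
    """Simulate the plot table: habitat, T_air, canopy structure, ground
    greenness and ground temperature satisfying the stated linear or
    interaction structure plus Gaussian noise.

    Grassland rows carry no canopy measurements (NaN); the treeless
    defaults rule fills them downstream.  The generative formula uses the
    structural zeros for those plots.
    """
    rng = np.random.default_rng(params.seed)
    truth = params.coefficients
    habitats = [h for h in HABITATS if params.habitat_mix.get(h, 0) > 0]
    probs = np.array([params.habitat_mix[h] for h in habitats], dtype=float)
    probs /= probs.sum()
    # deterministic counts closest to the stated proportions, remainder random
    counts = np.floor(probs * params.n_plots).astype(int)
    while counts.sum() < params.n_plots:
        counts[rng.integers(len(habitats))] += 1
    hab_col = np.repeat(habitats, counts)
    rng.shuffle(hab_col)

    n = params.n_plots
    lo, hi = params.t_air_range
    t_air = rng.uniform(lo, hi, n)
    lai = np.array([rng.uniform(*_LAI_RANGE[h]) for h in hab_col])
    fcover = np.clip(
        100.0 * (1.0 - np.exp(-0.65 * lai))
        + np.where(lai > 0, rng.normal(0.0, 3.0, n), 0.0),
        0.0, 100.0,
    )
    ndvi_up = np.where(
        lai > 0,
        np.clip(0.8 * (1.0 - np.exp(-0.6 * lai)) - 0.1
                + rng.normal(0.0, 0.05, n), -1.0, 1.0),
        -1.0,
    )
    a_nd, b_nd = truth.ndvi_down_lai
    ndvi_down = a_nd + b_nd * lai + (
        rng.normal(0.0, params.noise_sd_ndvi, n) if params.noise_sd_ndvi > 0 else 0.0
    )
    thermal = _thermal_truth(truth, lai, fcover, t_air) + (
        rng.normal(0.0, params.noise_sd_thermal, n)
        if params.noise_sd_thermal > 0 else 0.0
    )
    df = pd.DataFrame({
        "plot_id": [f"P{i + 1:03d}" for i in range(n)],
        "transect_id": [f"T{i // 3 + 1:02d}" for i in range(n)],
        "habitat": hab_col,
        "t_air": t_air,
        "lai": lai,
        "fcover": fcover,
        "ndvi_up": ndvi_up,
        "ndvi_down": ndvi_down,
        "thermal_ground": thermal,
    })
    grass = df["habitat"] == "grassland"
    df.loc[grass, ["lai", "fcover", "ndvi_up"]] = np.nan
    return df


def gen_sample_points(plot_row, n_points: int = 5, sd_ndvi: float = 0.05,
                      sd_thermal: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Per-point sample summaries around a plot's true values, emulating
    the five ground sample points of the 5 m x 5 m subplot."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_points):
        rows.append({
            "plot_id": plot_row["plot_id"], "point_id": f"S{k + 1}",
            "metric": "NDVI_down",
            "mean": plot_row["ndvi_down"] + rng.normal(0, sd_ndvi),
            "excluded": False,
        })
        rows.append({
            "plot_id": plot_row["plot_id"], "point_id": f"S{k + 1}",
            "metric": "Thermal_ground",
            "mean": plot_row["thermal_ground"] + rng.normal(0, sd_thermal),
            "excluded": False,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Landsat-like scenes


@dataclass
class LandsatSimParams:
    """A reflectance scene driven by a smooth true-LAI field.

    The forward model maps LAI to RED/NIR/SWIR1 reflectance through
    saturating exponentials plus Gaussian noise; the QA band scatters
    clear, water and other codes at the stated proportions.
    """

    grid_size: int = 120
    lai_range: tuple = (0.0, 6.0)
    smoothness: float = 8.0          # Gaussian-filter sigma in pixels
    noise_sd: float = 0.01
    qa_proportions: dict = field(default_factory=lambda: {
        322: 0.8, 834: 0.05, 324: 0.08, 968: 0.07})
    qa_patch_sigma: float = 4.0   # spatial scale of cloud/water patches (px)
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        total = sum(self.qa_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"QA proportions sum to {total}, not 1")


def _forward_reflectance(lai):
    red = 0.28 * np.exp(-0.45 * lai) + 0.04
    nir = 0.18 + 0.32 * (1.0 - np.exp(-0.5 * lai))
    swir = 0.30 * np.exp(-0.35 * lai) + 0.05
    return red, nir, swir


def gen_landsat_scene(params: LandsatSimParams):
    """Simulate a (RasterStack, true-LAI raster) pair.

    The LAI field is a smoothed Gaussian random field rescaled to the
    stated range; reflectances are a deterministic monotone function of
    LAI plus optional noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    s = params.grid_size
    fieldz = gaussian_filter(rng.normal(size=(s, s)), params.smoothness)
    lo, hi = params.lai_range
    zmin, zmax = fieldz.min(), fieldz.max()
    lai = lo + (fieldz - zmin) / max(zmax - zmin, 1e-12) * (hi - lo)
    red, nir, swir = _forward_reflectance(lai)
    bands = {}
    for name, b in (("RED", red), ("NIR", nir), ("SWIR1", swir)):
        if params.noise_sd > 0:
            b = b + rng.normal(0.0, params.noise_sd, (s, s))
        bands[name] = np.clip(b, 0.0, 1.0)
    # QA codes in spatially contiguous patches (clouds and water are
    # blobs, not salt-and-pepper): rank a smooth noise field and assign
    # codes to rank bands matching the stated proportions exactly
    codes = np.array(list(params.qa_proportions), dtype=np.int64)
    probs = np.array(list(params.qa_proportions.values()), dtype=float)
    probs = probs / probs.sum()
    patch = gaussian_filter(rng.normal(size=(s, s)), params.qa_patch_sigma)
    order = np.argsort(patch, axis=None, kind="stable")
    qa = np.empty(s * s, dtype=np.int64)
    counts = np.floor(probs * s * s).astype(int)
    counts[np.argmax(counts)] += s * s - counts.sum()
    start = 0
    for code, cnt in zip(codes, counts):
        qa[order[start:start + cnt]] = code
        start += cnt
    bands["QA"] = qa.reshape(s, s)
    stack = RasterStack(bands=bands, transform=(0.0, 30.0, 0.0, 0.0, 0.0, -30.0))
    return stack, lai


def write_manifest(path, params) -> None:
    """Record all truth parameters and the seed of a simulation run."""
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, default=str)
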