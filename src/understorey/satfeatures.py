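"""Landsat-side predictor layers for canopy-structure upscaling.

Starting from a co-registered surface-reflectance stack (RED, NIR, SWIR1
plus an integer pixel-QA band), this module masks every pixel whose QA
code does not signal clear conditions (water and any other code are set
undefined), computes three vegetation indices (NDVI, MSAVI2, EVI2),
grey-level co-occurrence texture layers (MEAN and DISSIMILARITY, 64 grey
levels, 90-degree shift, 3 x 3 window) for the three reflectance bands,
and focal mean/sd layers of NDVI.  The derived layers are sampled at
plot positions into the feature table consumed by the Random-Forest
models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RasterStack",
    "QARule",
    "TextureParams",
    "apply_qa_mask",
    "vegetation_indices",
    "glcm_textures",
    "focal_stats",
    "build_feature_stack",
    "sample_at",
]

IDENTITY_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)  # x0, dx, rx, y0, ry, dy


@dataclass
class RasterStack:
    """Named congruent band grids with an affine geotransform.

    Reflectance/index bands are float arrays with NaN marking undefined
    pixels; the QA band is integer-valued.
    """

    bands: dict
    transform: tuple = IDENTITY_TRANSFORM
    crs: str | None = None

    def __post_init__(self):
        shapes = {name: np.asarray(b).shape for name, b in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"bands are not congruent: {shapes}")
        self.bands = {name: np.asarray(b) for name, b in self.bands.items()}

    def band(self, name: str) -> np.ndarray:
        if name not in self.bands:
            raise KeyError(f"missing band {name!r}")
        return self.bands[name]

    @property
    def shape(self):
        return next(iter(self.bands.values())).shape

    def copy(self) -> "RasterStack":
        return RasterStack(
            bands={k: v.copy() for k, v in self.bands.items()},
            transform=self.transform,
            crs=self.crs,
        )

    def to_tif(self, path):
        """Write as a multi-page TIFF; band names and the geotransform go
        into a JSON description tag."""
        import tifffile

        names = list(self.bands)
        data = np.stack([self.bands[n].astype(np.float64) for n in names])
        meta = {"bands": names, "transform": list(self.transform),
                "crs": self.crs}
        tifffile.imwrite(path, data, photometric="minisblack",
                         description=json.dumps(meta))

    @classmethod
    def from_tif(cls, path) -> "RasterStack":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        bands = {}
        for i, name in enumerate(meta["bands"]):
            arr = data[i]
            if name == "QA":
                arr = np.where(np.isfinite(arr), arr, -1).astype(np.int64)
            bands[name] = arr
        return cls(bands=bands, transform=tuple(meta["transform"]),
                   crs=meta.get("crs"))


@dataclass
class QARule:
    """Pixel-QA code sets of the Landsat 8 surface-reflectance product.

    Only clear-condition codes are retained; water codes and every other
    code (cloud, haze, shadow, fill) are masked out.
    """

    clear_codes: frozenset = frozenset({322, 386, 834, 898, 1346})
    water_codes: frozenset = frozenset({324, 388, 836, 900, 1348})

    def __post_init__(self):
        self.clear_codes = frozenset(self.clear_codes)
        self.water_codes = frozenset(self.water_codes)
        if self.clear_codes & self.water_codes:
            raise ValueError("clear and water code sets must be disjoint")


@dataclass
class TextureParams:
    """Grey-level co-occurrence setup: 64 equal-width levels over the
    band's finite range, vertical (90-degree) neighbour offset with
    symmetric accumulation, 3 x 3 moving window."""

    levels: int = 64
    window: int = 3
    metrics: tuple = ("MEAN", "DISSIMILARITY")

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


def apply_qa_mask(stack: RasterStack, rule: QARule | None = None) -> RasterStack:
    """Set every band undefined where the QA code is not a clear code."""
    rule = rule or QARule()
    if "QA" not in stack.bands:
        raise ValueError("stack has no QA band")
    qa = stack.band("QA")
    keep = np.isin(qa, list(rule.clear_codes))
    out = stack.copy()
    for name, band in out.bands.items():
        if name == "QA":
            continue
        band = band.astype(float)
        band[~keep] = np.nan
        out.bands[name] = band
    return out


def vegetation_indices(red: np.ndarray, nir: np.ndarray) -> dict:
    """NDVI, MSAVI2 and EVI2 from RED and NIR reflectance.

    NDVI   = (N - R) / (N + R)
    MSAVI2 = (2N + 1 - sqrt((2N + 1)^2 - 8 (N - R))) / 2
    EVI2   = 2.5 (N - R) / (N + 2.4 R + 1)

    Undefined (NaN) inputs propagate.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if red.shape != nir.shape:
        raise ValueError("RED and NIR must be congruent")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = nir + red
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
        disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - red)
        msavi2 = (2.0 * nir + 1.0 - np.sqrt(np.clip(disc, 0.0, None))) / 2.0
        msavi2 = np.where(disc >= 0, msavi2, np.nan)
        evi2 = 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)
    return {"NDVI": ndvi, "MSAVI2": msavi2, "EVI2": evi2}


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization over the whole band's finite range
    (global bins, so textures compare across the scene).  Returns float
    level indices with NaN preserved."""
    band = np.asarray(band, dtype=float)
    finite = band[np.isfinite(band)]
    if finite.size == 0:
        raise ValueError("band has no finite values")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        warnings.warn("constant band: all pixels fall in one grey level",
                      stacklevel=2)
        q = np.where(np.isfinite(band), 0.0, np.nan)
        return q
    q = np.floor((band - lo) / (hi - lo) * levels)
    q = np.clip(q, 0, levels - 1)
    return np.where(np.isfinite(band), q, np.nan)


def glcm_textures(band: np.ndarray, params: TextureParams | None = None) -> dict:
    """Per-pixel GLCM MEAN and DISSIMILARITY textures.

    For each output pixel a symmetric co-occurrence matrix is accumulated
    over the vertical-neighbour pixel pairs inside the window centred
    there, then normalised to probabilities p(i, j):
    MEAN = sum i p(i, j), DISSIMILARITY = sum |i - j| p(i, j).  Windows
    touching the image edge or containing an undefined pixel are
    undefined.
    """
    params = params or TextureParams()
    q = quantize(band, params.levels)
    h, w = q.shape
    half = params.window // 2
    mean_out = np.full((h, w), np.nan)
    diss_out = np.full((h, w), np.nan)
    if h < params.window or w < params.window:
        return {"MEAN": mean_out, "DISSIMILARITY": diss_out}
    # vertical pairs: pair p[i, j] joins pixels (i, j) and (i+1, j)
    top = q[:-1, :]
    bot = q[1:, :]
    pair_sum = top + bot          # NaN if either member undefined
    pair_absdiff = np.abs(top - bot)
    # window of pairs fully inside a (window x window) pixel window:
    # pair rows r-half .. r+half-1, cols c-half .. c+half
    from numpy.lib.stride_tricks import sliding_window_view

    win_sum = sliding_window_view(pair_sum, (params.window - 1, params.window))
    win_diff = sliding_window_view(pair_absdiff, (params.window - 1, params.window))
    n_pairs = (params.window - 1) * params.window
    # symmetric GLCM: MEAN = sum(i+j)/ (2 n), DISSIMILARITY = mean |i-j|
    m = win_sum.sum(axis=(2, 3)) / (2.0 * n_pairs)
    d = win_diff.sum(axis=(2, 3)) / n_pairs
    mean_out[half:h - half, half:w - half] = m
    diss_out[half:h - half, half:w - half] = d
    return {"MEAN": mean_out, "DISSIMILARITY": diss_out}


def focal_stats(raster: np.ndarray, window_pixels: int = 9,
                stats: tuple = ("mean", "sd")) -> dict:
    """Sliding-window mean and sample sd centred per pixel.

    Undefined cells (and cells beyond the image edge) are excluded from
    the window sample; a window with fewer than 2 defined cells has an
    undefined sd, with none an undefined mean.
    """
    if window_pixels < 3:
        raise ValueError("window must be at least 3 pixels")
    raster = np.asarray(raster, dtype=float)
    half = window_pixels // 2
    padded = np.pad(raster, half, mode="constant", constant_values=np.nan)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(padded, (window_pixels, window_pixels))
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        counts = np.isfinite(win).sum(axis=(2, 3))
        if "mean" in stats:
            m = np.nanmean(win, axis=(2, 3))
            out["mean"] = np.where(counts >= 1, m, np.nan)
        if "sd" in stats:
            s = np.nanstd(win, axis=(2, 3), ddof=1)
            out["sd"] = np.where(counts >= 2, s, np.nan)
    return out


#: layer naming used in the feature table (matching the field shorthand:
#: band M = GLCM mean, band D = GLCM dissimilarity, NDVIMFocal / NDVISD =
#: focal mean / sd of NDVI)
TEXTURE_NAME = {"RED": ("REDM", "REDD"), "NIR": ("NIRM", "NIRD"),
                "SWIR1": ("SWIRM", "SWIRD")}


def build_feature_stack(stack: RasterStack,
                        texture: TextureParams | None = None,
                        focal_window: int = 9,
                        qa_rule: QARule | None = None) -> RasterStack:
    """Derive the full predictor stack from a masked reflectance stack.

    Applies the QA mask when a QA band is present, then adds the three
    vegetation indices, GLCM MEAN/DISSIMILARITY for RED, NIR and SWIR1,
    and focal mean/sd of NDVI.
    """
    if "QA" in stack.bands:
        stack = apply_qa_mask(stack, qa_rule)
    out = stack.copy()
    idx = vegetation_indices(stack.band("RED"), stack.band("NIR"))
    out.bands.update(idx)
    for bname, (mname, dname) in TEXTURE_NAME.items():
        if bname not in stack.bands:
            continue
        tex = glcm_textures(stack.band(bname), texture)
        out.bands[mname] = tex["MEAN"]
        out.bands[dname] = tex["DISSIMILARITY"]
    foc = focal_stats(idx["NDVI"], focal_window)
    out.bands["NDVIMFocal"] = foc["mean"]
    out.bands["NDVISD"] = foc["sd"]
    return out


def sample_at(stack: RasterStack, rows, cols,
              layers: list | None = None) -> pd.DataFrame:
    """Sample stack layers at pixel positions into a feature table."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    h, w = stack.shape
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise ValueError("sample positions outside the raster")
    layers = layers or [n for n in stack.bands if n != "QA"]
    data = {name: stack.band(name)[rows, cols] for name in layers}
    return pd.DataFrame(data)
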