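"""Low-level image statistics and procedural stimulus generation.

Four scalar parameters summarise an image's low-level content, computed on
the 8-bit scale:

* luminance       — mean grayscale pixel value;
* RMS contrast    — standard deviation of grayscale pixel values;
* gradient        — sum over pixels of the gradient magnitude
                    sqrt(dx^2 + dy^2) of the grayscale image;
* saturation      — mean over pixels of (max(R,G,B) - min(R,G,B)) / max(R,G,B),
                    in [0, 1]; not applicable to grayscale input.

Grayscale conversion is the ITU-R 601 luma: 0.299 R + 0.587 G + 0.114 B.
Native grayscale images are measured on their raw pixel values and the
saturation entry is left out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from ._rng import rng_for

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_gray_values(image: np.ndarray) -> np.ndarray:
    """Grayscale plane (float, 0–255 scale) of an RGB or grayscale raster."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ GRAY_WEIGHTS
    raise ValueError(f"expected HxW or HxWx3 raster, got shape {img.shape}")


@dataclass
class ImageParams:
    luminance: float
    rms_contrast: float
    gradient: float
    saturation: float | None  # None for native grayscale input

    def as_dict(self) -> dict:
        return {
            "luminance": self.luminance,
            "rms_contrast": self.rms_contrast,
            "gradient": self.gradient,
            "saturation": self.saturation,
        }


def image_params(image: np.ndarray) -> ImageParams:
    """Measure luminance, RMS contrast, gradient and saturation of one image."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    gray = to_gray_values(img)
    gy, gx = np.gradient(gray)
    grad = float(np.sum(np.sqrt(gx**2 + gy**2)))
    if img.ndim == 2:
        sat = None
    else:
        mx = img.max(axis=2)
        mn = img.min(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(mx > 0, (mx - mn) / mx, 0.0)
        sat = float(s.mean())
    return ImageParams(float(gray.mean()), float(gray.std()), grad, sat)


def params_table(images: dict) -> pd.DataFrame:
    """Measure a set of images; rows indexed by exemplar id."""
    rows = {k: image_params(v).as_dict() for k, v in images.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def _face_pattern(size: int, rng) -> np.ndarray:
    """Smooth zero-mean unit-SD field with a face-like central blob."""
    noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 10)
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = (size - 1) / 2, (size - 1) / 2
    blob = np.exp(-(((yy - cy) / (0.38 * size)) ** 2 + ((xx - cx) / (0.30 * size)) ** 2))
    eyes = np.exp(-(((yy - 0.38 * size) / (0.05 * size)) ** 2)) * (
        np.exp(-(((xx - 0.35 * size) / (0.05 * size)) ** 2))
        + np.exp(-(((xx - 0.65 * size) / (0.05 * size)) ** 2))
    )
    p = 1.2 * noise / max(noise.std(), 1e-12) + 1.5 * blob - 1.2 * eyes
    p -= p.mean()
    sd = p.std()
    p = np.clip(p / sd if sd > 0 else p, -2.2, 2.2)  # tame tails so moderate
    p -= p.mean()  # contrasts stay inside the 8-bit range
    return p / p.std()


def generate_face_images(
    n: int, params: pd.DataFrame | None = None, seed: int = 0, size: int = 64
) -> tuple[dict, pd.DataFrame]:
    """Generate procedural face-like RGB stimuli with controlled statistics.

    Parameters
    ----------
    params : DataFrame, optional
        One row per image with columns ``luminance``, ``rms_contrast``,
        ``saturation`` (targets on the 8-bit / unit scales) and optionally
        ``hue`` in [0, 1).  Defaults to plausible portrait statistics drawn
        per image.
    seed : int
        All pattern noise, hues and defaults derive from this.

    Returns
    -------
    images : dict
        exemplar id -> uint8 array (size, size, 3).
    table : DataFrame
        Target and re-measured parameters per image.

    Raises
    ------
    ValueError
        If a target combination is unreachable within the 8-bit range
        (for example contrast above 127.5 at mid luminance).
    """
    rng = rng_for(seed, "face_images")
    if params is None:
        params = pd.DataFrame(
            {
                "luminance": rng.uniform(110, 150, n),
                "rms_contrast": rng.uniform(20, 35, n),
                "saturation": rng.uniform(0.15, 0.45, n),
            }
        )
    if len(params) != n:
        raise ValueError("params must have one row per image")

    images, rows = {}, []
    for idx in range(n):
        row = params.iloc[idx]
        lum, con, sat = float(row["luminance"]), float(row["rms_contrast"]), float(row["saturation"])
        hue = float(row["hue"]) if "hue" in params.columns else float(rng.uniform(0.02, 0.10))
        if not 0 <= sat <= 1:
            raise ValueError(f"saturation target {sat} outside [0, 1]")
        # With constant hue and saturation, RGB is linear in the HSV value
        # plane: gray = c * V, so luminance/contrast targets map exactly onto
        # the mean/SD of V.
        unit_rgb = hsv_to_rgb([hue, sat, 1.0])
        c = float(unit_rgb @ GRAY_WEIGHTS)
        pattern = _face_pattern(size, rng) if con > 0 else np.zeros((size, size))
        value = (lum + con * pattern) / c
        if value.min() < -1e-9 or value.max() > 255 + 1e-9:
            raise ValueError(
                f"image {idx}: luminance {lum} with contrast {con} at saturation "
                f"{sat} is unreachable within the 8-bit range"
            )
        rgb = np.clip(value, 0, 255)[:, :, None] * unit_rgb[None, None, :]
        img = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
        eid = f"face_{idx + 1:02d}"
        images[eid] = img
        meas = image_params(img)
        rows.append(
            {
                "exemplar_id": eid,
                "target_luminance": lum,
                "target_rms_contrast": con,
                "target_saturation": sat,
                **{f"measured_{k}": v for k, v in meas.as_dict().items()},
            }
        )
    return images, pd.DataFrame(rows).set_index("exemplar_id")
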