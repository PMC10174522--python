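"""Image normalization, the l2 image-difference score, and the GI index."""

from __future__ import annotations

import numpy as np

from .errors import DataError, MetricError, ShapeError
from .raster import PixelImage

__all__ = ["normalize_image", "l2_image_difference", "gi_index"]


def _values(img):
    return np.asarray(getattr(img, "values", img), dtype=float)


def normalize_image(img):
    """Min-max rescale to [0, 1] over the full raster.

    Constant images (undefined min-max) map to all zeros.  Returns the same
    container type as the input (PixelImage in, PixelImage out).
    """
    v = _values(img)
    if not np.all(np.isfinite(v)):
        raise DataError("image contains non-finite values")
    lo, hi = v.min(), v.max()
    out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    if isinstance(img, PixelImage):
        return img.copy_with(out)
    return out


def l2_image_difference(recon, truth, squared: bool = False) -> float:
    """Pixelwise l2 norm of the difference between two (normalized) rasters.

    ``squared=True`` returns the raw sum of squared differences instead of
    its square root; orderings and relative comparisons are unaffected by
    the monotone transform.
    """
    a, b = _values(recon), _values(truth)
    if a.shape != b.shape:
        raise ShapeError("images differ in shape")
    ss = float(np.sum((a - b) ** 2))
    return ss if squared else float(np.sqrt(ss))


def gi_index(tidal, lung_mask) -> float:
    """Global inhomogeneity index of a tidal image over a fixed lung region.

    Sum of absolute deviations from the lung-region median divided by the
    lung-region sum.  Scale-invariant; zero for a homogeneous lung.
    """
    v = _values(tidal)
    mask = np.asarray(lung_mask, dtype=bool)
    if v.shape != mask.shape:
        raise ShapeError("image and lung mask differ in shape")
    if not mask.any():
        raise MetricError("lung region is empty")
    lung = v[mask]
    denom = lung.sum()
    if denom == 0:
        raise MetricError("lung-region sum is zero")
    return float(np.abs(lung - np.median(lung)).sum() / denom)
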