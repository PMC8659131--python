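"""Masks and morphometric/photometric features for event images.

The analysis consumes per-event "default masks" (pixels distinguishable
from background in one channel) and a compact set of features computed
over them: size (area, diameter, axis lengths), shape (aspect ratio,
circularity, elongation), signal strength (background-subtracted
intensity, mean/median/std pixel, raw max pixel), focus quality
(gradient RMS) and texture (homogeneity, contrast).

Feature names follow the ``<Feature>_<Channel>`` convention with the
channel aliases BF (brightfield, Ch01) and SSC (darkfield, Ch06).
Features that are undefined on an empty mask are NaN; downstream stages
treat NaN as "missing" and never raise on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology
from skimage.feature import peak_local_max
from skimage.measure import perimeter as _perimeter

from .events import EventImageSet

#: Channels whose default mask carries the object morphology.
_DARK_OBJECT_CHANNELS = {"Ch01"}  # brightfield: absorbing cells on bright background


@dataclass
class Mask:
    """Boolean pixel region tied to one channel image."""

    pixels: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())

    @property
    def empty(self) -> bool:
        return not self.pixels.any()


def _border_stats(img: np.ndarray) -> tuple[float, float]:
    border = np.concatenate([img[0, :], img[-1, :], img[1:-1, 0], img[1:-1, -1]])
    return float(border.mean()), float(border.std())


def default_mask(image: np.ndarray, channel: str) -> Mask:
    """Pixels detected as different from the background of one channel.

    Thresholding combines Otsu's method with a border-pixel background
    estimate (mean +/- 3 sigma of the 1-px image frame): the stricter of
    the two is applied, which keeps Otsu from splitting pure-noise images
    in half. For brightfield the object is darker than background, so the
    logic inverts. The largest connected component is retained together
    with any component at least 25% of its area, and a morphological
    closing of radius 1 smooths the result. An all-background image gives
    an empty mask (not an error).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("default_mask requires a non-empty 2-D image")
    mu, sd = _border_stats(img)
    dark = channel in _DARK_OBJECT_CHANNELS
    try:
        otsu = float(filters.threshold_otsu(img))
    except ValueError:  # constant image
        otsu = mu
    if dark:
        thr = min(otsu, mu - 3.0 * sd)
        fg = img < thr
    else:
        thr = max(otsu, mu + 3.0 * sd)
        fg = img > thr

    if not fg.any():
        return Mask(np.zeros_like(fg), channel)

    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = sizes.max()
    keep = np.flatnonzero(sizes >= 0.25 * largest) + 1
    fg = np.isin(labels, keep)
    fg = morphology.closing(fg, morphology.disk(1))
    return Mask(fg, channel)


def combine_masks(a: Mask, b: Mask | None, op: str) -> Mask:
    """Boolean combination of two masks (``and``, ``or``, ``xor``, ``not``).

    ``not`` is unary and ignores ``b``.
    """
    if op == "not":
        return Mask(~a.pixels, a.channel)
    if b is None:
        raise ValueError(f"binary op {op!r} requires two masks")
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("masks must share one shape")
    ops = {"and": np.logical_and, "or": np.logical_or, "xor": np.logical_xor}
    if op not in ops:
        raise ValueError(f"unknown mask op {op!r}")
    return Mask(ops[op](a.pixels, b.pixels), a.channel)


def area(mask: Mask, pixel_scale_um: float) -> float:
    """Mask area in square micrometres (pixel count x scale^2)."""
    if pixel_scale_um <= 0:
        raise ValueError("pixel_scale_um must be > 0")
    return mask.count * pixel_scale_um**2


def _central_moments(mask: Mask) -> tuple[float, float] | None:
    """Eigenvalues (major, minor) of the pixel-coordinate covariance."""
    coords = np.argwhere(mask.pixels)
    if len(coords) == 0:
        return None
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(coords)
    lam = np.linalg.eigvalsh(cov)
    return float(lam[1]), float(lam[0])


def aspect_ratio(mask: Mask) -> float:
    """Minor axis / major axis of the mask, in (0, 1].

    Axis lengths come from the second central moments of the mask pixel
    coordinates. Masks of two pixels or fewer return 1.0 by convention;
    an empty mask is missing (NaN).
    """
    if mask.empty:
        return float("nan")
    if mask.count <= 2:
        return 1.0
    lam_major, lam_minor = _central_moments(mask)
    if lam_major <= 0:
        return 1.0
    return float(np.sqrt(max(lam_minor, 0.0) / lam_major))


def gradient_rms(image: np.ndarray, mask: Mask) -> float:
    """Contrast metric: RMS gradient magnitude over the mask, normalized
    by the mean in-mask intensity. Low values flag out-of-focus events."""
    if mask.empty:
        return float("nan")
    img = np.asarray(image, dtype=float)
    gr, gc = np.gradient(img)
    mag2 = gr**2 + gc**2
    mean_int = img[mask.pixels].mean()
    if mean_int == 0:
        return float("nan")
    return float(np.sqrt(mag2[mask.pixels].mean()) / mean_int)


def raw_max_pixel(image: np.ndarray, mask: Mask | None = None) -> float:
    """Maximum background-uncorrected intensity within the mask.

    Falls back to the whole image when the mask is empty or absent, so the
    staining-positivity filter remains defined for unstained events.
    """
    img = np.asarray(image, dtype=float)
    if mask is None or mask.empty:
        return float(img.max())
    return float(img[mask.pixels].max())


def intensity_features(image: np.ndarray, mask: Mask) -> dict[str, float]:
    """Signal-strength features over a mask.

    ``Intensity`` is the background-subtracted sum (background = median of
    off-mask pixels); the pixel statistics are raw values.
    """
    nan = float("nan")
    if mask.empty:
        return {"Intensity": nan, "MeanPixel": nan, "MedianPixel": nan, "StdPixel": nan}
    img = np.asarray(image, dtype=float)
    inside = img[mask.pixels]
    outside = img[~mask.pixels]
    background = float(np.median(outside)) if outside.size else 0.0
    return {
        "Intensity": float(inside.sum() - background * inside.size),
        "MeanPixel": float(inside.mean()),
        "MedianPixel": float(np.median(inside)),
        "StdPixel": float(inside.std()),
    }


def shape_features(mask: Mask, pixel_scale_um: float) -> dict[str, float]:
    """Size/shape features: axis lengths, equivalent diameter, perimeter,
    circularity, elongation (1 - aspect ratio) and solidity (area over
    convex-hull area — clumps and chains of cells score below a single
    convex cell). Lengths are in micrometres."""
    nan = float("nan")
    if mask.empty:
        return {
            "MajorAxis": nan,
            "MinorAxis": nan,
            "Diameter": nan,
            "Perimeter": nan,
            "Circularity": nan,
            "Elongation": nan,
            "Solidity": nan,
        }
    n = mask.count
    lam = _central_moments(mask)
    # full axis lengths under the ellipse convention (4 sqrt(lambda))
    major = 4.0 * np.sqrt(max(lam[0], 1.0 / 12.0))
    minor = 4.0 * np.sqrt(max(lam[1], 1.0 / 12.0))
    diameter = 2.0 * np.sqrt(n / np.pi)
    per = float(_perimeter(mask.pixels, neighborhood=4))
    circ = 4.0 * np.pi * n / per**2 if per > 0 else 1.0
    hull = int(morphology.convex_hull_image(mask.pixels).sum())
    ar = aspect_ratio(mask)
    return {
        "MajorAxis": float(major * pixel_scale_um),
        "MinorAxis": float(minor * pixel_scale_um),
        "Diameter": float(diameter * pixel_scale_um),
        "Perimeter": float(per * pixel_scale_um),
        "Circularity": float(min(circ, 1.0)),
        "Elongation": float(1.0 - ar),
        "Solidity": float(n / hull) if hull else nan,
    }


def texture_features(image: np.ndarray, mask: Mask) -> dict[str, float]:
    """Texture features over a mask.

    ``Homogeneity`` is ``1 / (1 + CV^2)`` with CV the in-mask coefficient
    of variation (1.0 for a constant region, decreasing with speckle);
    ``Contrast`` is the in-mask interquartile range over the median.
    """
    nan = float("nan")
    if mask.empty:
        return {"Homogeneity": nan, "Contrast": nan}
    vals = np.asarray(image, dtype=float)[mask.pixels]
    mean = vals.mean()
    med = float(np.median(vals))
    homog = 1.0 / (1.0 + vals.var() / mean**2) if mean != 0 else nan
    iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
    contrast = iqr / med if med != 0 else nan
    return {"Homogeneity": float(homog), "Contrast": contrast}


def threshold_mask(image: np.ndarray, mask: Mask, percentile: float) -> Mask:
    """Function mask: in-mask pixels above the q-th in-mask percentile."""
    if mask.empty:
        return Mask(np.zeros_like(mask.pixels), mask.channel)
    img = np.asarray(image, dtype=float)
    thr = np.percentile(img[mask.pixels], percentile)
    return Mask(mask.pixels & (img > thr), mask.channel)


def spot_peaks(
    image: np.ndarray,
    mask: Mask,
    threshold_abs: float,
    min_distance: int = 2,
) -> np.ndarray:
    """(row, col) positions of local maxima above a threshold inside a mask."""
    if mask.empty:
        return np.empty((0, 2), dtype=float)
    labels = mask.pixels.astype(int)
    return np.asarray(
        peak_local_max(
            np.asarray(image, dtype=float),
            min_distance=min_distance,
            threshold_abs=threshold_abs,
            labels=labels,
            exclude_border=False,
        ),
        dtype=float,
    ).reshape(-1, 2)


def spot_count(
    image: np.ndarray,
    mask: Mask,
    threshold_abs: float,
    min_distance: int = 2,
) -> int:
    """Count local intensity maxima above an absolute threshold inside a mask."""
    return int(len(spot_peaks(image, mask, threshold_abs, min_distance)))


# ---------------------------------------------------------------------------
# per-event feature vector and table


def extract_features(event: EventImageSet) -> dict[str, float]:
    """Compute the full feature vector of one event.

    Size/shape features are computed on the BF and SSC default masks,
    signal-strength features for the fluorescence channels (Ch02, Ch05)
    over the BF default mask (the cell footprint), focus quality on BF and
    texture on SSC. Missing values propagate as NaN.
    """
    scale = event.pixel_scale_um
    bf = event["Ch01"]
    ssc = event["Ch06"]
    bf_mask = default_mask(bf, "Ch01")
    ssc_mask = default_mask(ssc, "Ch06")

    feats: dict[str, float] = {}
    for mask, img, alias in ((bf_mask, bf, "BF"), (ssc_mask, ssc, "SSC")):
        feats[f"Area_{alias}"] = area(mask, scale)
        feats[f"AspectRatio_{alias}"] = aspect_ratio(mask)
        for name, val in shape_features(mask, scale).items():
            feats[f"{name}_{alias}"] = val
    feats["GradientRMS_BF"] = gradient_rms(bf, bf_mask)
    for name, val in texture_features(ssc, ssc_mask).items():
        feats[f"{name}_SSC"] = val

    for ch in ("Ch02", "Ch05"):
        img = event[ch]
        ch_mask = default_mask(img, ch)
        feats[f"RawMaxPixel_{ch}"] = raw_max_pixel(img, ch_mask)
        for name, val in intensity_features(img, bf_mask).items():
            feats[f"{name}_{ch}"] = val
    return feats


def extract_feature_table(events: list[EventImageSet]) -> pd.DataFrame:
    """Feature table for a sample: one row per event, indexed by event id.

    All events share the feature name set (rectangularity); the pixel
    scale is recorded in ``DataFrame.attrs['pixel_scale_um']``.
    """
    rows = {ev.event_id: extract_features(ev) for ev in events}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "event_id"
    if events:
        table.attrs["pixel_scale_um"] = events[0].pixel_scale_um
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV (event_id column + one column per feature).

    Accepts externally produced tables with the same header contract, so
    real exported IFC feature data can be fed into the downstream stages.
    """
    table = pd.read_csv(path, index_col="event_id")
    table.index = table.index.astype(str)
    return table
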