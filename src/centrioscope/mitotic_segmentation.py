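"""Identification of mitotic figures among interphase cells.

A mitotic figure is characterised by simultaneously bright condensed
chromatin (DNA channel) and a bright spindle (tubulin channel).  The
detector works on 2D maximum-intensity projections: both projections are
Gaussian-smoothed and multiplied element-wise into a correlation image
CM, which is bright only where both signals coincide.  CM is segmented
either by Otsu's method (when the Otsu mask is well separated from
background, S/N > 2.5) or by a robust intensity criterion
(mean + 6·sd).  Surviving objects are dilated by 2.2 µm, filtered by a
convex-hull circularity criterion (< 0.2) and a minimum area (400 µm²),
and dilated once more so each final region also covers centrioles near
the spindle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import convex_hull_image, disk

from .image_model import ImageStack, PixelGeometry, um_to_px


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested on a constant image."""


@dataclass(frozen=True)
class MitoticParams:
    """Tunable constants of the mitotic-figure detector (defaults in µm / %)."""

    sigma_um: float = 1.15      # Gaussian smoothing sigma
    snr_min: float = 2.5        # Otsu-vs-robust branch gate
    k_sd: float = 6.0           # robust threshold = mean + k_sd * sd
    dilate_um: float = 2.2      # circular dilation radius (applied twice)
    circ_max: float = 0.2       # convex-hull circularity ceiling
    min_area_um2: float = 400.0 # minimum object area after first dilation


@dataclass
class CorrelationImage:
    """Element-wise product of the smoothed DNA and tubulin projections."""

    cm: np.ndarray
    mean: float
    sd: float


@dataclass
class MitoticRegion:
    """A 2D region believed to contain one mitotic cell.

    ``area_um2`` and ``circ`` are the values measured at filter time (after
    the first dilation); ``mask`` includes the second, spindle-vicinity
    dilation.  ``touches_border`` flags regions clipped by the field edge.
    """

    mask: np.ndarray
    area_um2: float
    circ: float
    snr_used: float | None
    threshold_branch: str
    touches_border: bool = False

    def bbox(self) -> tuple[int, int, int, int]:
        ys, xs = np.nonzero(self.mask)
        return int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1


def project_max(stack: ImageStack, role: str) -> np.ndarray:
    """Maximum-intensity projection of one channel along z (MaxB / MaxR)."""
    return np.asarray(stack.channel(role), dtype=np.float64).max(axis=0)


def smooth(
    img: np.ndarray, geometry: PixelGeometry, sigma_um: float = 1.15
) -> np.ndarray:
    """Gaussian smoothing with a physically specified sigma (reflected border)."""
    if sigma_um <= 0:
        raise ValueError("sigma must be strictly positive")
    sigma_px = sigma_um / geometry.um_per_px
    return ndimage.gaussian_filter(
        np.asarray(img, dtype=np.float64), sigma=sigma_px, mode="reflect"
    )


def correlation_image(maxB: np.ndarray, maxR: np.ndarray) -> CorrelationImage:
    """Per-element product of the two projections, with its grand mean/sd."""
    maxB = np.asarray(maxB, dtype=np.float64)
    maxR = np.asarray(maxR, dtype=np.float64)
    if maxB.shape != maxR.shape:
        raise ValueError(f"shape mismatch: {maxB.shape} vs {maxR.shape}")
    cm = maxB * maxR
    return CorrelationImage(cm=cm, mean=float(cm.mean()), sd=float(cm.std()))


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of the image's value range.

    Pixels strictly above the returned value form the object class.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0 or img.min() == img.max():
        raise DegenerateHistogramError("degenerate histogram: constant image")
    return float(threshold_otsu(img, nbins=256))


def snr(cm: CorrelationImage, object_mask: np.ndarray) -> float:
    """Signal-to-noise ratio: mean CM over object pixels / mean over the rest."""
    object_mask = np.asarray(object_mask, dtype=bool)
    n_obj = int(object_mask.sum())
    if n_obj == 0 or n_obj == object_mask.size:
        raise ValueError("object mask must contain object and background pixels")
    s = float(cm.cm[object_mask].mean())
    n = float(cm.cm[~object_mask].mean())
    if n == 0:
        return np.inf
    return s / n


def robust_threshold(cm: CorrelationImage, k_sd: float = 6.0) -> np.ndarray:
    """Mask of pixels with CM > mean + k_sd·sd (may be empty)."""
    if not np.isfinite(cm.sd):
        raise ValueError("CM standard deviation must be finite")
    return cm.cm > cm.mean + k_sd * cm.sd


def circularity(object_mask: np.ndarray) -> float:
    """Convex-hull circularity Circ = (H_area − O_area) / H_area in [0, 1).

    H_area counts the pixels of the filled convex hull of the object's
    pixel set.  Compact convex objects score near 0, edgy / concave
    objects near 1.  Degenerate (collinear) objects are defined as 0.
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    o_area = int(object_mask.sum())
    if o_area < 3:
        raise ValueError("object must contain at least 3 pixels")
    ys, xs = np.nonzero(object_mask)
    if np.all(ys == ys[0]) or np.all(xs == xs[0]):
        return 0.0
    # crop to bbox: hull filling is local to the object
    sub = object_mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    hull = convex_hull_image(sub, offset_coordinates=False)
    h_area = int(hull.sum())
    if h_area < o_area:  # conservative guard against rasterisation slack
        h_area = o_area
    return (h_area - o_area) / h_area


def _dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=disk(radius_px))


def find_mitotic_regions(
    stack: ImageStack, params: MitoticParams = MitoticParams()
) -> list[MitoticRegion]:
    """Run the full mitotic-figure chain on one field of view.

    Returns one :class:`MitoticRegion` per surviving connected component
    (possibly empty).  The Otsu-vs-robust branch decision is global: one
    S/N value for the whole Otsu mask selects the thresholding mode for
    the field.
    """
    geometry = stack.geometry
    maxB = smooth(project_max(stack, "dna"), geometry, params.sigma_um)
    maxR = smooth(project_max(stack, "tubulin"), geometry, params.sigma_um)
    cm = correlation_image(maxB, maxR)

    branch = "otsu"
    snr_used: float | None = None
    try:
        t = otsu_threshold(cm.cm)
        mask = cm.cm > t
    except DegenerateHistogramError:
        mask = np.zeros(cm.cm.shape, dtype=bool)
    if mask.any() and not mask.all():
        snr_used = snr(cm, mask)
        if snr_used <= params.snr_min:
            branch = "robust"
            mask = robust_threshold(cm, params.k_sd)
    elif not mask.any():
        branch = "robust"
        mask = robust_threshold(cm, params.k_sd)

    radius_px = um_to_px(params.dilate_um, geometry)
    dilated = _dilate(mask, radius_px)
    labels, n = label(dilated, connectivity=2, return_num=True)

    survivors: list[tuple[np.ndarray, float, float]] = []
    for i in range(1, n + 1):
        obj = labels == i
        if int(obj.sum()) < 3:
            continue
        circ = circularity(obj)
        if circ >= params.circ_max:
            continue
        area_um2 = float(obj.sum()) * geometry.um2_per_px
        if area_um2 < params.min_area_um2:
            continue
        survivors.append((obj, area_um2, circ))
    if not survivors:
        return []

    union = np.zeros(cm.cm.shape, dtype=bool)
    for obj, _, _ in survivors:
        union |= obj
    final = _dilate(union, radius_px)
    final_labels, n_final = label(final, connectivity=2, return_num=True)

    regions: list[MitoticRegion] = []
    for i in range(1, n_final + 1):
        comp = final_labels == i
        # survivors merged into this component determine its provenance stats
        areas = [a for obj, a, _ in survivors if (obj & comp).any()]
        circs = [c for obj, _, c in survivors if (obj & comp).any()]
        border = bool(
            comp[0, :].any() or comp[-1, :].any()
            or comp[:, 0].any() or comp[:, -1].any()
        )
        regions.append(
            MitoticRegion(
                mask=comp,
                area_um2=float(sum(areas)),
                circ=float(min(circs)),
                snr_used=snr_used,
                threshold_branch=branch,
                touches_border=border,
            )
        )
    return regions
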