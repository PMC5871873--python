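"""Pole-wise PCM and microtubule-regrowth intensity quantification.

Centrosomes are detected as 3D objects above a Yen threshold computed on
the maximum-intensity projection; each object's *integrated density* is
the sum of its voxel intensities, corrected by a local background term —
the mean of the average-intensity z-projection over the object's xy
footprint times the object's voxel count — and clamped at zero.
Spindle-pole asymmetry is expressed as the ratio of corrected densities,
with the numerator pole chosen either as the pole carrying the overly
long centriole(s) or, in control mode, as the pole with the higher
centrin density.  For microtubule-regrowth assays, the mean of the
minimum-intensity projection is subtracted from every plane before
sum-projection and per-pole integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_yen

from .image_model import ImageStack, um_to_px
from .mitotic_segmentation import DegenerateHistogramError

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PoleMeasurement:
    """Background-corrected integrated density of one centrosome/pole."""

    integrated_density_raw: float
    background_density: float
    integrated_density: float     # max(0, raw − background)
    n_voxels: int
    centrin_density: float = 0.0
    centroid_xy: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class AsymmetryRatio:
    numerator_pole: str           # {"long_centriole", "high_centrin"}
    ratio: float


def yen_threshold(img: np.ndarray) -> float:
    """Yen's maximum-correlation threshold over a 256-bin histogram.

    Used as a *minimum* threshold for 3D object detection, mirroring
    ImageJ-style centrosome quantification.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0 or img.min() == img.max():
        raise DegenerateHistogramError("degenerate histogram: constant image")
    return float(threshold_yen(img, nbins=256))


def pole_integrated_density(
    stack: ImageStack,
    role: str,
    threshold: float,
    centrin_role: str = "centrin",
    background: str = "footprint",
    min_voxels: int = 8,
) -> list[PoleMeasurement]:
    """Detect 3D objects above a threshold and measure corrected densities.

    Objects are 26-connected voxel sets above ``threshold`` seeded from
    the maximum-projection mask.  The local background per object is the
    mean of the average-intensity z-projection over the object's xy
    footprint (or the whole projection with ``background="global"``)
    multiplied by the object's voxel count.  Returned largest-first.
    """
    chan = np.asarray(stack.channel(role), dtype=np.float64)
    nz = chan.shape[0]
    proj_mask = chan.max(axis=0) > threshold
    mask3d = (chan > threshold) & proj_mask[None, :, :]
    labels, n = ndimage.label(mask3d, structure=_STRUCT_26)
    if n == 0:
        return []
    avg_proj = chan.mean(axis=0)
    centrin = (
        np.asarray(stack.channel(centrin_role), dtype=np.float64)
        if centrin_role in stack.channels
        else None
    )
    out: list[PoleMeasurement] = []
    for i in range(1, n + 1):
        obj = labels == i
        n_vox = int(obj.sum())
        if n_vox < min_voxels:
            continue
        raw = float(chan[obj].sum())
        footprint = obj.any(axis=0)
        if background == "footprint":
            bg_per_vox = float(avg_proj[footprint].mean())
        elif background == "global":
            bg_per_vox = float(avg_proj.mean())
        else:
            raise ValueError(f"unknown background mode {background!r}")
        bg = bg_per_vox * n_vox
        zs, ys, xs = np.nonzero(obj)
        centrin_raw = float(centrin[obj].sum()) if centrin is not None else 0.0
        out.append(
            PoleMeasurement(
                integrated_density_raw=raw,
                background_density=bg,
                integrated_density=max(0.0, raw - bg),
                n_voxels=n_vox,
                centrin_density=centrin_raw,
                centroid_xy=(float(ys.mean()), float(xs.mean())),
            )
        )
    out.sort(key=lambda m: -m.n_voxels)
    return out


def pole_ratio(
    poleA: PoleMeasurement,
    poleB: PoleMeasurement,
    mode: str = "high_centrin",
    long_pole: str = "A",
) -> AsymmetryRatio:
    """Asymmetry ratio of two spindle poles' corrected densities.

    ``mode="long_centriole"``: the numerator is the pole flagged (via
    ``long_pole``) as containing the overly long centriole(s).
    ``mode="high_centrin"`` (control): the numerator is the pole with the
    higher centrin density, so the ratio is ≥ 1 by construction.
    """
    if poleA.integrated_density <= 0 or poleB.integrated_density <= 0:
        raise ValueError("both corrected densities must be positive")
    if mode == "long_centriole":
        num, den = (poleA, poleB) if long_pole == "A" else (poleB, poleA)
    elif mode == "high_centrin":
        if poleA.centrin_density >= poleB.centrin_density:
            num, den = poleA, poleB
        else:
            num, den = poleB, poleA
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AsymmetryRatio(
        numerator_pole=mode, ratio=num.integrated_density / den.integrated_density
    )


def _find_pole_foci(
    stack: ImageStack, n_foci: int = 2, min_separation_um: float = 5.0
) -> list[tuple[int, int]]:
    """The two brightest, well-separated centrin foci on the max projection.

    The separation floor must exceed the within-pole centriole scatter so
    the two foci land on different spindle poles, not two centrioles of
    the same pole.
    """
    proj = np.asarray(stack.channel("centrin"), dtype=np.float64).max(axis=0)
    sm = ndimage.gaussian_filter(proj, sigma=2.0)
    min_sep = um_to_px(min_separation_um, stack.geometry)
    foci: list[tuple[int, int]] = []
    work = sm.copy()
    yy, xx = np.mgrid[: sm.shape[0], : sm.shape[1]]
    for _ in range(n_foci):
        y, x = np.unravel_index(np.argmax(work), work.shape)
        if work[y, x] <= 0:
            break
        foci.append((int(y), int(x)))
        work[(yy - y) ** 2 + (xx - x) ** 2 <= min_sep ** 2] = -np.inf
    return foci


def mt_regrowth_density(
    stack: ImageStack,
    pole_rois: list[tuple[int, int]] | None = None,
    roi_radius_um: float = 2.2,
) -> tuple[float, float]:
    """Per-pole corrected α-tubulin densities for a regrowth assay.

    The mean of the minimum-intensity z-projection (the background/noise
    floor) is subtracted from every plane (clamped at 0), the stack is
    sum-projected, and the result is integrated over a disk of
    ``roi_radius_um`` around each spindle pole (auto-placed at the two
    brightest centrin foci when not supplied).
    """
    tub = np.asarray(stack.channel("tubulin"), dtype=np.float64)
    if pole_rois is None:
        pole_rois = _find_pole_foci(stack)
    if len(pole_rois) < 2:
        raise ValueError("fewer than 2 centrin foci / pole ROIs")
    bg = float(tub.min(axis=0).mean())
    corrected = np.clip(tub - bg, 0.0, None)
    sum_proj = corrected.sum(axis=0)
    r = um_to_px(roi_radius_um, stack.geometry)
    yy, xx = np.mgrid[: sum_proj.shape[0], : sum_proj.shape[1]]
    densities = []
    for (y, x) in pole_rois[:2]:
        # recentre on the local tubulin centre of mass: the centrin foci
        # seed the search, but the measured object is the aster itself
        for _ in range(2):
            win = (yy - y) ** 2 + (xx - x) ** 2 <= (1.5 * r) ** 2
            w = sum_proj * win
            tot = w.sum()
            if tot <= 0:
                break
            y = int(round((w * yy).sum() / tot))
            x = int(round((w * xx).sum() / tot))
        roi = (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2
        densities.append(float(sum_proj[roi].sum()))
    if densities[0] == 0 and densities[1] == 0:
        raise ValueError("no signal at either pole ROI")
    return densities[0], densities[1]


def centrin_pcm_correlation(
    pairs: list[tuple[float, float]]
) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties, two-tailed p) of
    per-centrosome centrin vs PCM integrated densities."""
    if len(pairs) < 5:
        raise ValueError("need at least 5 centrosomes")
    x, y = zip(*pairs)
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise ValueError("constant input vector")
    from scipy import stats

    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
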