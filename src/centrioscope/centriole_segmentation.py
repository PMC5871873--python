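"""Detection, colocalisation, splitting and 3D length measurement of centrioles.

Within each mitotic region the centrin (and optionally CP110) projection
is upsampled ×8 (bicubic), Otsu-thresholded, and filtered by area
(0.1–1 µm² at original scale) and — in dual-marker mode — by Manders
overlap with the CP110 channel, which suppresses centriolar-satellite
false positives.  Each surviving 2D candidate is grown into a 3D voxel
set (per-plane bicubic upsampling in xy, same Otsu threshold), and then
recursively split: principal-component analysis on the
anisotropy-corrected voxel cloud gives the long axis, the maximum-
intensity profile along that axis is scanned for intensity valleys
(Sobel derivative responses), and the object is cut by planes normal to
the long axis until no valley remains.  Terminal objects are single
centrioles; their length is the extent of the voxel projections on the
long axis plus one upsampled-pixel end cap.

Voxel coordinates are kept in the *upsampled field frame*: ``(z, yu, xu)``
with ``yu = 8·y`` so that candidates from different ROIs can be compared
and de-duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .image_model import ImageStack, PixelGeometry
from .mitotic_segmentation import (
    DegenerateHistogramError,
    MitoticRegion,
    otsu_threshold,
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class CentrioleParams:
    """Tunable constants of the centriole detector."""

    upsample_factor: int = 8
    area_min_um2: float = 0.1
    area_max_um2: float = 1.0
    manders_min: float = 0.5       # colocalisation cut (dual-marker mode)
    sobel_prominence: float = 0.25  # |dp/dt| floor, fraction of max response
    valley_depth: float = 0.20      # profile dip floor, fraction of profile max
    max_depth: int = 10             # recursion safety rail
    length_mode: str = "fwhm"       # {fwhm, extent, eigen_scaled}
    # acquisition PSF, used for moment-based deblurring of the principal
    # frame (set both to 0 to disable)
    psf_sigma_xy_nm: float = 100.0
    psf_sigma_z_nm: float = 300.0

    @property
    def psf_sigma_nm(self) -> tuple[float, float] | None:
        if self.psf_sigma_xy_nm <= 0 and self.psf_sigma_z_nm <= 0:
            return None
        return (self.psf_sigma_z_nm, self.psf_sigma_xy_nm)


@dataclass
class CandidateObject2D:
    """A 2D centriole candidate from the upsampled centrin projection."""

    roi_offset: tuple[int, int]          # (y0, x0) of ROI bbox in field px
    pixels: np.ndarray                   # (N, 2) int (yu, xu), upsampled ROI frame
    threshold: float                     # the centrin Otsu value of this ROI
    area_um2: float                      # at original (pre-upsampling) scale
    manders: float | None = None


@dataclass
class CentrioleObject:
    """A connected 3D voxel set classified as a single centriole."""

    voxels: np.ndarray                   # (N, 3) int (z, yu, xu), upsampled field frame
    intensities: np.ndarray
    eigvals: np.ndarray                  # (3,) nm², descending
    eigvecs: np.ndarray                  # columns = principal axes, (z, y, x) nm frame
    length_nm: float
    parent_cell: str = ""


def extract_roi(
    stack: ImageStack, region: MitoticRegion, role: str
) -> tuple[np.ndarray, tuple[int, int]]:
    """Max-projection of a channel over the region's bounding box.

    Pixels outside the region mask are zeroed; the returned offset is the
    bbox origin ``(y0, x0)`` in field coordinates.
    """
    if not region.mask.any():
        raise ValueError("region mask is empty")
    y0, y1, x0, x1 = region.bbox()
    proj = np.asarray(stack.channel(role), dtype=np.float64).max(axis=0)
    roi = proj[y0:y1, x0:x1] * region.mask[y0:y1, x0:x1]
    return roi, (y0, x0)


def upsample(roi: np.ndarray, factor: int = 8) -> np.ndarray:
    """Bicubic upsampling by an integer factor; negative ringing clipped at 0."""
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    if factor == 1:
        return np.asarray(roi, dtype=np.float64).copy()
    out = ndimage.zoom(
        np.asarray(roi, dtype=np.float64),
        factor,
        order=3,
        grid_mode=True,
        mode="nearest",  # edge replication: no boundary ringing or drift
    )
    return np.clip(out, 0.0, None)


def manders_overlap(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Manders' overlap coefficient R = Σab / √(Σa²·Σb²) over mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    av = np.asarray(a, dtype=np.float64)[mask]
    bv = np.asarray(b, dtype=np.float64)[mask]
    denom = np.sqrt((av ** 2).sum() * (bv ** 2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def _upsampled_valid(valid_mask: np.ndarray, factor: int) -> np.ndarray:
    """Region-validity mask at upsampled scale, eroded by one original pixel
    so the bicubic rolloff ring at the mask edge stays out of histograms."""
    up = np.repeat(np.repeat(valid_mask, factor, axis=0), factor, axis=1)
    return ndimage.binary_erosion(up, structure=np.ones((2 * factor + 1,) * 2, bool))


def detect_candidates_2d(
    roi_centrin: np.ndarray,
    roi_cp110: np.ndarray | None,
    geometry: PixelGeometry,
    params: CentrioleParams = CentrioleParams(),
    roi_offset: tuple[int, int] = (0, 0),
    valid_mask: np.ndarray | None = None,
) -> list[CandidateObject2D]:
    """Otsu-segment centriole candidates on the ×8 upsampled centrin ROI.

    The Otsu histogram is restricted to in-region pixels (``valid_mask``,
    original scale) — the zero padding outside the mitotic region mask is
    an artefact of the ROI frame, not image content.  In dual-marker mode
    a candidate is kept only when its Manders overlap with the CP110
    image reaches ``manders_min`` *and* the CP110 Otsu mask intersects
    it; this is what rejects centrin-only satellite decoys.
    """
    f = params.upsample_factor
    roi_centrin = np.asarray(roi_centrin, dtype=np.float64)
    if roi_centrin.size == 0 or roi_centrin.min() == roi_centrin.max():
        return []
    up_c = upsample(roi_centrin, f)
    if valid_mask is not None:
        valid_up = _upsampled_valid(np.asarray(valid_mask, bool), f)
        if not valid_up.any():
            return []
    else:
        valid_up = up_c > 0 if (up_c == 0).any() else np.ones(up_c.shape, bool)
    try:
        t = otsu_threshold(up_c[valid_up])
    except DegenerateHistogramError:
        return []
    mask = up_c > t

    up_p = None
    cp_mask = None
    if roi_cp110 is not None:
        up_p = upsample(np.asarray(roi_cp110, dtype=np.float64), f)
        try:
            cp_mask = up_p > otsu_threshold(up_p[valid_up])
        except DegenerateHistogramError:
            cp_mask = np.zeros_like(mask)

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    candidates: list[CandidateObject2D] = []
    for i in range(1, n + 1):
        obj = labels == i
        n_up = int(obj.sum())
        area_um2 = n_up / (f * f) * geometry.um2_per_px
        if not params.area_min_um2 <= area_um2 <= params.area_max_um2:
            continue
        manders = None
        if up_p is not None:
            manders = manders_overlap(up_c, up_p, obj)
            if manders < params.manders_min or not (cp_mask & obj).any():
                continue
        ys, xs = np.nonzero(obj)
        candidates.append(
            CandidateObject2D(
                roi_offset=roi_offset,
                pixels=np.column_stack([ys, xs]).astype(np.int64),
                threshold=float(t),
                area_um2=float(area_um2),
                manders=manders,
            )
        )
    return candidates


def grow_3d(
    stack: ImageStack,
    candidate: CandidateObject2D,
    factor: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow a 2D candidate into a 3D voxel set at the stored Otsu threshold.

    Each z-plane of the centrin channel, restricted to the candidate's xy
    bounding box, is bicubically upsampled ×factor in-plane (z is never
    upsampled); voxels above the candidate's threshold whose xy position
    falls within the candidate footprint dilated by one upsampled pixel
    are kept, and the 26-connected component with the largest overlap
    with the footprint is returned.

    Returns ``(voxels, intensities)`` with voxels as ``(N, 3)`` integer
    ``(z, yu, xu)`` coordinates in the upsampled field frame; empty when
    nothing exceeds the threshold.
    """
    comps = grow_3d_components(stack, candidate, factor)
    if not comps:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)
    return comps[0]


def grow_3d_components(
    stack: ImageStack,
    candidate: CandidateObject2D,
    factor: int = 8,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All 3D components of a candidate's growth that lie under its footprint.

    A single 2D candidate can cover several structures that are distinct
    in z (their projections merge, their voxel sets do not); each such
    26-connected component substantially overlapping the candidate
    footprint is returned, largest overlap first.  :func:`grow_3d`
    returns only the first.
    """
    chan = stack.channel("centrin")
    nz, ny, nx = chan.shape
    oy, ox = candidate.roi_offset
    pix_field = candidate.pixels + np.array([oy * factor, ox * factor])
    y0 = max(int(pix_field[:, 0].min() // factor) - 1, 0)
    y1 = min(int(pix_field[:, 0].max() // factor) + 2, ny)
    x0 = max(int(pix_field[:, 1].min() // factor) - 1, 0)
    x1 = min(int(pix_field[:, 1].max() // factor) + 2, nx)
    h, w = (y1 - y0) * factor, (x1 - x0) * factor
    footprint = np.zeros((h, w), dtype=bool)
    fy = pix_field[:, 0] - y0 * factor
    fx = pix_field[:, 1] - x0 * factor
    ok = (fy >= 0) & (fy < h) & (fx >= 0) & (fx < w)
    footprint[fy[ok], fx[ok]] = True
    allowed = ndimage.binary_dilation(footprint, structure=np.ones((3, 3), bool))
    mask3d = np.zeros((nz, h, w), dtype=bool)
    planes = np.zeros((nz, h, w), dtype=np.float32)
    for z in range(nz):
        up = upsample(chan[z, y0:y1, x0:x1], factor)
        planes[z] = up
        mask3d[z] = (up > candidate.threshold) & allowed
    labels, n = ndimage.label(mask3d, structure=_STRUCT_26)
    if n == 0:
        return []
    return _overlapping_components(labels, n, footprint, planes, y0, x0, factor)


def _overlapping_components(
    labels: np.ndarray,
    n: int,
    footprint: np.ndarray,
    planes: np.ndarray,
    y0: int,
    x0: int,
    factor: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Components whose xy projection overlaps ≥25% of itself with the
    candidate footprint (in upsampled field coordinates, best first)."""
    picked: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        comp_xy = (labels == i).any(axis=0)
        overlap = int((comp_xy & footprint).sum())
        if overlap > 0 and overlap >= 0.25 * int(comp_xy.sum()):
            picked.append((overlap, i))
    picked.sort(reverse=True)
    out = []
    for _, i in picked:
        zs, ys, xs = np.nonzero(labels == i)
        intens = planes[zs, ys, xs].astype(np.float64)
        voxels = np.column_stack(
            [zs, ys + y0 * factor, xs + x0 * factor]
        ).astype(np.int64)
        out.append((voxels, intens))
    return out


def voxels_to_nm(
    voxels: np.ndarray, geometry: PixelGeometry, factor: int = 8
) -> np.ndarray:
    """Scale upsampled (z, yu, xu) voxel indices to nm (z, y, x) coordinates."""
    scale = np.array(
        [geometry.nm_per_voxel_z, geometry.nm_per_px / factor, geometry.nm_per_px / factor]
    )
    return np.asarray(voxels, dtype=np.float64) * scale


def principal_axes(
    voxels: np.ndarray,
    geometry: PixelGeometry,
    factor: int = 8,
    psf_sigma_nm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted PCA of the anisotropy-corrected voxel cloud.

    Voxel indices are scaled to nm before the decomposition so that the
    axial (z) anisotropy of the acquisition is honoured.  Returns
    eigenvalues (nm², descending, clipped at 0) and the orthonormal
    eigenvector matrix (columns, in the (z, y, x) nm frame).  Exactly
    collinear clouds get λ2 = λ3 = 0 with an arbitrary frame completion.

    ``psf_sigma_nm = (sigma_z, sigma_xy)`` applies moment-based
    deblurring: the point-spread function is axis-aligned and adds its
    own covariance ``diag(σz², σxy², σxy²)`` to any structure's, so
    subtracting it before the eigendecomposition recovers the
    structure's principal frame.  Without it the ~3× wider axial blur
    makes any sub-µm in-plane rod look z-elongated.
    """
    voxels = np.asarray(voxels)
    if len(voxels) < 2:
        raise ValueError("need at least 2 voxels for principal axes")
    coords = voxels_to_nm(voxels, geometry, factor)
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    if psf_sigma_nm is not None:
        sz, sxy = psf_sigma_nm
        cov = cov - np.diag([sz ** 2, sxy ** 2, sxy ** 2])
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    if np.linalg.det(vecs) < 0:  # keep a right-handed frame
        vecs[:, 2] = -vecs[:, 2]
    return vals, vecs


def _axis_bin_nm(e1: np.ndarray, geometry: PixelGeometry, factor: int) -> float:
    """Profile bin width: one upsampled pixel, widened to the voxel
    lattice's projection on e1 so steep axes don't comb into empty bins."""
    cap = geometry.nm_per_px / factor
    return float(max(cap, abs(e1[0]) * geometry.nm_per_voxel_z))


def _axis_profile(
    coords_nm: np.ndarray, intensities: np.ndarray, e1: np.ndarray, bin_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integrated-intensity ("mass") profile along e1.

    Each bin (one upsampled pixel wide) accumulates the intensities of
    the voxels projecting into it: the cross-section mass of the object
    along its long axis.  For a PSF-blurred rod this is a plateau with
    error-function ends whose half-maximum crossings sit at the true rod
    tips; a pair of touching rods shows a genuine valley.  Summing over
    the full cross-section averages shot noise away, unlike a per-bin
    maximum which is itself an extreme-value statistic.
    """
    t = coords_nm @ e1
    t0 = t.min()
    u = (t - t0) / bin_nm
    nbins = int(np.floor(u.max())) + 1
    profile = np.zeros(nbins)
    # triangular (linear) binning: each voxel's intensity is shared between
    # its two nearest bins, which suppresses voxel-lattice aliasing that
    # hard binning would turn into periodic fake valleys
    f = u - 0.5
    i0 = np.clip(np.floor(f).astype(int), 0, nbins - 1)
    i1 = np.clip(i0 + 1, 0, nbins - 1)
    w1 = np.clip(f - np.floor(f), 0.0, 1.0)
    np.add.at(profile, i0, intensities * (1.0 - w1))
    np.add.at(profile, i1, intensities * w1)
    # a steep axis can still leave empty bins between planes; bridge them
    # so lattice gaps cannot masquerade as intensity valleys
    empty = profile == 0
    if empty.any() and not empty.all():
        xs = np.arange(nbins)
        profile[empty] = np.interp(xs[empty], xs[~empty], profile[~empty])
    if nbins >= 3:  # light [1,2,1]/4 smoothing against discretisation ripple
        profile = np.convolve(profile, [0.25, 0.5, 0.25], mode="same")
        profile[0] = profile[1]
        profile[-1] = profile[-2]
    centers = t0 + (np.arange(nbins) + 0.5) * bin_nm
    return centers, profile


def _ridge_profile(
    coords_nm: np.ndarray, intensities: np.ndarray, e1: np.ndarray, bin_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Max-intensity (centreline) profile along e1.

    The per-bin maximum tracks the structure's centreline intensity,
    whose half-maximum crossings sit at the true tips of a PSF-blurred
    rod — the right profile for length measurement, whereas the mass
    profile (cross-section integral) narrows before the tip.
    """
    t = coords_nm @ e1
    t0 = t.min()
    idx = np.floor((t - t0) / bin_nm).astype(int)
    nbins = idx.max() + 1
    profile = np.zeros(nbins)
    np.maximum.at(profile, idx, intensities)
    empty = profile == 0
    if empty.any() and not empty.all():
        xs = np.arange(nbins)
        profile[empty] = np.interp(xs[empty], xs[~empty], profile[~empty])
    if nbins >= 3:
        profile = np.convolve(profile, [0.25, 0.5, 0.25], mode="same")
        profile[0] = profile[1]
        profile[-1] = profile[-2]
    centers = t0 + (np.arange(nbins) + 0.5) * bin_nm
    return centers, profile


def axis_profile_inflections(
    voxels: np.ndarray,
    intensities: np.ndarray,
    e1: np.ndarray,
    geometry: PixelGeometry,
    factor: int = 8,
    params: CentrioleParams = CentrioleParams(),
) -> list[float]:
    """Positions (nm, along e1) where the axial intensity profile dips.

    The profile's Sobel derivative [-1, 0, +1] flags steep flanks; a cut
    position is emitted at each genuine intensity valley — an interior
    local minimum whose depth below its flanking maxima is at least
    ``valley_depth`` of the profile maximum and whose neighbourhood
    carries a Sobel response of at least ``sobel_prominence`` of the
    maximum interior response.  A clean single rod (monotone flanks, flat
    top) therefore yields no cut; a dumbbell of two touching rods yields
    one cut inside the valley.
    """
    bin_nm = _axis_bin_nm(e1, geometry, factor)
    coords = voxels_to_nm(voxels, geometry, factor)
    centers, profile = _axis_profile(coords, intensities, e1, bin_nm)
    n = len(profile)
    if n < 5:
        return []
    sobel = np.zeros(n)
    sobel[1:-1] = profile[2:] - profile[:-2]
    interior = slice(1, n - 1)
    max_resp = np.abs(sobel[interior]).max()
    if max_resp == 0:
        return []
    pmax = profile.max()
    if pmax <= 0:
        return []

    # no cut within 100 nm of either end: no centriole is that short, and
    # edge ramps would otherwise shed meaningless slivers
    margin = max(2, int(round(100.0 / bin_nm)))
    cuts: list[tuple[float, float]] = []  # (depth, position)
    for i in range(margin, n - margin):
        if not (profile[i] <= profile[i - 1] and profile[i] <= profile[i + 1]):
            continue
        left_max = profile[: i].max()
        right_max = profile[i + 1 :].max()
        depth = min(left_max, right_max) - profile[i]
        if depth < params.valley_depth * pmax:
            continue
        lo, hi = max(i - 2, 1), min(i + 3, n - 1)
        if np.abs(sobel[lo:hi]).max() < params.sobel_prominence * max_resp:
            continue
        cuts.append((depth, centers[i]))

    # one cut per valley: greedy deepest-first with a minimum spacing (no
    # centriole is shorter than ~150 nm, so closer cuts cannot both be real)
    cuts.sort(key=lambda c: -c[0])
    min_sep = 150.0
    kept: list[float] = []
    for _, pos in cuts:
        if all(abs(pos - k) >= min_sep for k in kept):
            kept.append(pos)
    return sorted(kept)


def split_object(
    voxels: np.ndarray,
    intensities: np.ndarray,
    e1: np.ndarray,
    cut_positions: list[float],
    geometry: PixelGeometry,
    factor: int = 8,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition a voxel set by planes normal to e1 at the cut positions.

    Voxels exactly on a cut plane join the lower-t segment.  Each segment
    is re-checked for 26-connectivity and split into its components; the
    returned sets are pairwise disjoint and their union is the input.
    """
    voxels = np.asarray(voxels)
    intensities = np.asarray(intensities)
    if not cut_positions:
        return [(voxels, intensities)]
    t = voxels_to_nm(voxels, geometry, factor) @ e1
    cuts = np.sort(np.asarray(cut_positions, dtype=np.float64))
    seg = np.searchsorted(cuts, t, side="left")
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for s in range(len(cuts) + 1):
        sel = seg == s
        if not sel.any():
            continue
        out.extend(_connected_pieces(voxels[sel], intensities[sel]))
    return _absorb_fragments(out)


def _absorb_fragments(
    pieces: list[tuple[np.ndarray, np.ndarray]], min_vox: int = 30
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Merge sub-detection fragments back into an adjacent sibling.

    The connectivity recheck after a planar cut can shed slivers far
    smaller than any real centriole; a sliver that touches (26-adjacency)
    a larger sibling is rejoined to it, so no voxel is lost and no
    spurious object is created.  Slivers with no adjacent host are kept.
    """
    big = [i for i, (v, _) in enumerate(pieces) if len(v) >= min_vox]
    if not big or len(big) == len(pieces):
        return pieces
    merged: dict[int, list[int]] = {i: [i] for i in big}
    orphans: list[int] = []
    for i, (v, _) in enumerate(pieces):
        if i in merged:
            continue
        best, best_d2 = None, np.inf
        for j in big:
            w = pieces[j][0]
            d2 = np.min(
                ((v[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
            )
            if d2 < best_d2:
                best, best_d2 = j, d2
        if best is not None and best_d2 <= 3:  # 26-adjacent
            merged[best].append(i)
        else:
            orphans.append(i)
    out = []
    for j in big:
        vs = np.concatenate([pieces[k][0] for k in merged[j]])
        ws = np.concatenate([pieces[k][1] for k in merged[j]])
        out.append((vs, ws))
    out.extend(pieces[k] for k in orphans)
    return out


def _connected_pieces(
    voxels: np.ndarray, intensities: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a voxel subset into its 26-connected components."""
    if len(voxels) == 0:
        return []
    mins = voxels.min(axis=0)
    local = voxels - mins
    shape = tuple(local.max(axis=0) + 1)
    grid = np.zeros(shape, dtype=bool)
    grid[tuple(local.T)] = True
    labels, n = ndimage.label(grid, structure=_STRUCT_26)
    if n == 1:
        return [(voxels, intensities)]
    lab = labels[tuple(local.T)]
    return [(voxels[lab == i], intensities[lab == i]) for i in range(1, n + 1)]


def centriole_length(
    voxels: np.ndarray,
    geometry: PixelGeometry,
    factor: int = 8,
    eigvecs: np.ndarray | None = None,
    mode: str = "fwhm",
    intensities: np.ndarray | None = None,
) -> float:
    """3D length in nm of one centriole voxel set.

    Default ``fwhm`` mode measures the distance between the half-maximum
    crossings of the axial (e1) intensity profile: for a structure
    blurred by a Gaussian PSF the half-maximum point of an edge sits at
    the true edge, so this estimate is unbiased where the raw voxel
    extent inherits the threshold-dependent PSF spill.  ``extent`` mode
    is the spread of the voxel projections on the first principal axis
    plus one upsampled-pixel end cap (exact for ideal binary rods);
    ``eigen_scaled`` scales the leading PCA eigenvalue as 2·√(3·λ1),
    which equals the extent for a uniform rod.
    """
    voxels = np.asarray(voxels)
    cap = geometry.nm_per_px / factor
    if len(voxels) == 1:
        return cap
    if eigvecs is not None and mode != "eigen_scaled":
        vecs = eigvecs
    else:
        vals, vecs = principal_axes(voxels, geometry, factor)
        if eigvecs is not None:
            vecs = eigvecs
    if mode == "eigen_scaled":
        return float(2.0 * np.sqrt(3.0 * vals[0]))
    t = voxels_to_nm(voxels, geometry, factor) @ vecs[:, 0]
    if mode == "fwhm":
        if intensities is None or len(t) < 5:
            return float(t.max() - t.min() + cap)
        bin_nm = _axis_bin_nm(vecs[:, 0], geometry, factor)
        coords = voxels_to_nm(voxels, geometry, factor)
        centers, profile = _ridge_profile(
            coords, intensities, e1=vecs[:, 0], bin_nm=bin_nm
        )
        half = profile.max() / 2.0
        above = np.nonzero(profile >= half)[0]
        if len(above) == 0:
            return float(t.max() - t.min() + cap)
        i0, i1 = above[0], above[-1]
        left = centers[i0] - bin_nm / 2.0
        if i0 > 0:  # linear interpolation of the crossing
            frac = (half - profile[i0 - 1]) / (profile[i0] - profile[i0 - 1])
            left = centers[i0 - 1] + frac * bin_nm
        right = centers[i1] + bin_nm / 2.0
        if i1 < len(profile) - 1:
            frac = (half - profile[i1 + 1]) / (profile[i1] - profile[i1 + 1])
            right = centers[i1 + 1] - frac * bin_nm
        return float(max(right - left, cap))
    if mode != "extent":
        raise ValueError(f"unknown length mode {mode!r}")
    return float(t.max() - t.min() + cap)


def segment_centrioles(
    stack: ImageStack,
    region: MitoticRegion,
    params: CentrioleParams = CentrioleParams(),
    mode: str = "secondary",
    cell_id: str = "",
) -> list[CentrioleObject]:
    """Full per-cell chain: candidates → 3D growth → recursive splitting.

    ``mode`` is ``"primary"`` (centrin only) or ``"secondary"``
    (centrin + CP110 colocalisation).  Cells with no detected centriole
    return an empty list (count 0), which is a valid outcome.
    """
    f = params.upsample_factor
    geometry = stack.geometry
    roi_c, offset = extract_roi(stack, region, "centrin")
    roi_p = None
    if mode == "secondary" and "cp110" in stack.channels:
        roi_p, _ = extract_roi(stack, region, "cp110")
    y0, y1, x0, x1 = region.bbox()
    candidates = detect_candidates_2d(
        roi_c, roi_p, geometry, params, offset,
        valid_mask=region.mask[y0:y1, x0:x1],
    )

    # candidates whose 3D growth touches merge into one connected complex, so
    # an object reached from several 2D candidates is processed exactly once
    complexes: list[dict[tuple[int, int, int], float]] = []
    for cand in candidates:
        for voxels, intens in grow_3d_components(stack, cand, f):
            merged = {tuple(v): float(i) for v, i in zip(voxels, intens)}
            rest = []
            for c in complexes:
                if merged.keys() & c.keys():
                    merged = {**c, **merged}
                else:
                    rest.append(c)
            complexes = rest + [merged]
    grown: list[tuple[np.ndarray, np.ndarray]] = []
    for c in complexes:
        voxels = np.array(list(c.keys()), dtype=np.int64)
        intens = np.array(list(c.values()))
        grown.append((voxels, intens))

    objects: list[CentrioleObject] = []
    min_extent_nm = 2 * geometry.nm_per_px / f

    def process(voxels: np.ndarray, intens: np.ndarray, depth: int) -> None:
        if len(voxels) < 3 or depth >= params.max_depth:
            objects.append(_finalize(voxels, intens))
            return
        vals, vecs = principal_axes(voxels, geometry, f, params.psf_sigma_nm)
        t = voxels_to_nm(voxels, geometry, f) @ vecs[:, 0]
        if t.max() - t.min() < min_extent_nm:
            objects.append(_finalize(voxels, intens))
            return
        cuts = axis_profile_inflections(voxels, intens, vecs[:, 0], geometry, f, params)
        cuts = [c for c in cuts if t.min() < c < t.max()]
        if not cuts:
            objects.append(_finalize(voxels, intens))
            return
        for v, w in split_object(voxels, intens, vecs[:, 0], cuts, geometry, f):
            process(v, w, depth + 1)

    def _finalize(voxels: np.ndarray, intens: np.ndarray) -> CentrioleObject:
        if len(voxels) >= 2:
            vals, vecs = principal_axes(voxels, geometry, f, params.psf_sigma_nm)
        else:
            vals = np.zeros(3)
            vecs = np.eye(3)
        length = centriole_length(
            voxels, geometry, f,
            eigvecs=vecs if len(voxels) >= 2 else None,
            mode=params.length_mode, intensities=intens,
        )
        return CentrioleObject(
            voxels=voxels,
            intensities=intens,
            eigvals=vals,
            eigvecs=vecs,
            length_nm=length,
            parent_cell=cell_id,
        )

    for voxels, intens in grown:
        process(voxels, intens, 0)
    return objects
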