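"""Synthetic multi-channel z-stacks with known centriole ground truth.

The generator emulates the acquisition geometry of a spinning-disk
confocal screen: 86.7 nm lateral pixels, 200 nm plane spacing, 10–14 µm
z-range.  A field holds one (or more) rounded mitotic cell — condensed
chromatin rosette plus a bright bipolar spindle — among dimmer
interphase nuclei.  Centrioles are rendered as line ("capsule") kernels
of the specified length and 3D orientation, convolved with an
anisotropic Gaussian PSF (σxy 100 nm, σz 300 nm), with optional
centrin-only satellite decoys; Poisson photon noise and Gaussian read
noise complete the image.  Rendered total centrin signal per centriole
is proportional to its length, and a fixed seed reproduces the stack
bit-for-bit.

``simulate_population`` is the fast path: it samples per-cell centriole
counts and lengths from the same distributions without rendering,
optionally coupling over-elongation to amplification with a specified
odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_model import CellRecord, ImageStack


@dataclass(frozen=True)
class Centriole:
    centre_nm: tuple[float, float, float]   # (z, y, x) in nm, field frame
    orientation: tuple[float, float, float]  # unit vector (z, y, x)
    length_nm: float
    has_cp110: bool = True
    is_satellite_decoy: bool = False


@dataclass(frozen=True)
class CellTruth:
    cell_id: str
    is_mitotic: bool
    centre_nm: tuple[float, float, float]
    centrioles: tuple[Centriole, ...] = ()


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellTruth, ...]
    seed: int

    def mitotic_cells(self) -> list[CellTruth]:
        return [c for c in self.cells if c.is_mitotic]


@dataclass(frozen=True)
class SimulationProfile:
    """Study conditions of a simulated screen.

    Geometry defaults follow the emulated acquisition (86.7 nm pixels,
    200 nm plane spacing, 50 planes = 10 µm); phenotype defaults follow
    the screened populations: amplified cells mostly carry 5–8
    centrioles, normal centrin-measured length is ~425 nm, overly long
    centrioles run from ~550 nm up to a couple of µm.
    """

    # acquisition geometry
    voxel_xy_nm: float = 86.7
    voxel_z_nm: float = 200.0
    z_planes: int = 50
    field_px: int = 512

    # field composition
    mitotic_per_field: int = 1
    interphase_per_field: int = 8

    # phenotype
    p_amplified: float = 0.0
    count_distribution_given_amplified: tuple[tuple[int, float], ...] = (
        (5, 0.30), (6, 0.25), (7, 0.20), (8, 0.15),
        (9, 0.04), (10, 0.03), (11, 0.02), (12, 0.01),
    )
    p_overlong: float = 0.0            # per-centriole base rate (non-amplified cell)
    overlong_odds_ratio: float = 1.0   # odds multiplier in amplified cells
    normal_length_nm: tuple[float, float] = (425.0, 40.0)   # mean, sd (clipped 250–500)
    overlong_length_lognorm: tuple[float, float] = (math.log(800.0), 0.35)
    fixed_length_nm: float | None = None   # overrides length sampling when set
    fixed_count: int | None = None         # overrides count sampling when set
    long_length_nm: float | None = None    # exactly one centriole of this length
    satellite_rate: float = 0.0            # expected centrin-only decoys per mitotic cell

    # mitotic cell geometry (µm)
    rosette_radius_um: float = 10.0
    cell_radius_um: float = 12.5
    pole_distance_um: float = 15.0
    pole_scatter_um: float = 1.2        # centriole scatter radius around a pole
    min_gap_px: float = 3.0             # minimum capsule-to-capsule gap
    max_tilt_deg: float = 30.0          # centriole tilt out of the xy plane
    # resolvable-configuration floor for pole-mates: a pair is only placed
    # when laterally or axially separable at the acquisition's resolution
    # (no intensity-based method can count sub-PSF-separated objects)
    min_lateral_sep_nm: float = 420.0
    min_axial_sep_nm: float = 650.0

    # rendering amplitudes (photons)
    dna_amp: float = 60.0
    dna_interphase_amp: float = 18.0
    tubulin_spindle_amp: float = 50.0
    tubulin_cytoplasm_amp: float = 35.0
    tubulin_interphase_amp: float = 4.0
    centrin_density_per_nm: float = 25.0
    cp110_density_per_nm: float = 20.0
    # satellite decoys: centrin-positive granule clusters big enough to pass
    # the candidate area filter (the behaviour that inflates single-marker
    # counts), distinguished only by their missing second marker
    satellite_density_per_nm: float = 22.0
    satellite_length_nm: float = 400.0
    psf_sigma_xy_nm: float = 100.0
    psf_sigma_z_nm: float = 300.0
    dna_structure_sigma_um: float = 0.55
    tubulin_structure_sigma_um: float = 0.45
    background_offset: float = 5.0
    read_noise_sd: float = 2.0
    textured_chromatin: bool = False    # large chromosome clusters (dim preset)

    # pole-wise intensity asymmetries
    tubulin_pole_ratio: float = 1.0     # pole 0 vs pole 1 aster signal
    pcm_pole_amplitudes: tuple[float, float] | None = None
    render_cp110: bool = True

    @property
    def field_um(self) -> float:
        return self.field_px * self.voxel_xy_nm / 1000.0

    @property
    def z_range_um(self) -> float:
        return self.z_planes * self.voxel_z_nm / 1000.0

    def __post_init__(self) -> None:
        for p in (self.p_amplified, self.p_overlong):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 10.0 <= self.z_range_um <= 14.0:
            # acquisition emulation: stacks span 10–14 µm by design
            if self.z_planes * self.voxel_z_nm / 1000.0 > 14.0 + 1e-9:
                raise ValueError("z-range exceeds the 10–14 µm acquisition band")
            raise ValueError("z-range below the 10–14 µm acquisition band")

    @classmethod
    def dim(cls, **overrides) -> "SimulationProfile":
        """Low-contrast preset: haze and bright interphase drive the Otsu
        mask's S/N below 2.5, so detection must fall back to the robust
        (mean + 6·sd) branch.  A mean+6·sd mask can only exist when the
        bright object occupies a small fraction of the field, so this
        preset uses a wide field; chromatin is rendered as large
        chromosome clusters whose correlation-image texture peaks survive
        the 1.15 µm smoothing and seed the robust mask, which the 2.2 µm
        dilation then fuses into one region."""
        base = dict(
            field_px=1280,
            dna_amp=26.0,
            dna_interphase_amp=12.0,
            tubulin_spindle_amp=30.0,
            tubulin_cytoplasm_amp=20.0,
            tubulin_interphase_amp=8.0,
            background_offset=45.0,
            interphase_per_field=4,
            rosette_radius_um=11.5,
            cell_radius_um=14.0,
            pole_distance_um=17.0,
            textured_chromatin=True,
            render_cp110=False,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def regrowth(cls, pole_ratio: float = 1.0, **overrides) -> "SimulationProfile":
        """Microtubule-regrowth assay preset: cold treatment depolymerises
        cytoplasmic microtubules, so after brief regrowth the tubulin
        signal is concentrated in the two centrosomal asters (optionally
        asymmetric by ``pole_ratio``) over a faint remnant background."""
        base = dict(
            field_px=352,
            interphase_per_field=0,
            tubulin_cytoplasm_amp=0.5,
            tubulin_spindle_amp=40.0,
            tubulin_interphase_amp=1.0,
            tubulin_pole_ratio=pole_ratio,
            background_offset=1.0,
            fixed_count=4,
        )
        base.update(overrides)
        return cls(**base)


# ----------------------------------------------------------------------------
# population fast path


def _sample_count(profile: SimulationProfile, rng: np.random.Generator) -> tuple[int, bool]:
    if profile.fixed_count is not None:
        n = profile.fixed_count
        return n, n > 4
    if rng.random() < profile.p_amplified:
        counts, probs = zip(*profile.count_distribution_given_amplified)
        probs = np.asarray(probs, dtype=np.float64)
        return int(rng.choice(counts, p=probs / probs.sum())), True
    return 4, False


def _sample_lengths(
    n: int, amplified: bool, profile: SimulationProfile, rng: np.random.Generator
) -> list[float]:
    if profile.fixed_length_nm is not None:
        return [float(profile.fixed_length_nm)] * n
    if profile.long_length_nm is not None:
        mu, sd = profile.normal_length_nm
        rest = np.clip(rng.normal(mu, sd, n - 1), 250.0, 500.0)
        return [float(profile.long_length_nm)] + [float(v) for v in rest]
    q = profile.p_overlong
    if amplified and profile.overlong_odds_ratio != 1.0 and 0 < q < 1:
        odds = profile.overlong_odds_ratio * q / (1 - q)
        q = odds / (1 + odds)
    mu, sd = profile.normal_length_nm
    lmu, lsd = profile.overlong_length_lognorm
    over = rng.random(n) < q
    normals = np.clip(rng.normal(mu, sd, n), 250.0, 500.0)
    longs = np.clip(rng.lognormal(lmu, lsd, n), 550.0, 2500.0)
    return [float(v) for v in np.where(over, longs, normals)]


def simulate_population(
    profile: SimulationProfile, n_cells: int, seed: int
) -> list[CellRecord]:
    """Sample per-cell centriole counts and lengths without rendering."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_cells):
        n, amplified = _sample_count(profile, rng)
        lengths = _sample_lengths(n, amplified, profile, rng)
        records.append(CellRecord(cell_id=f"sim_{i:05d}", lengths_nm=lengths))
    return records


# ----------------------------------------------------------------------------
# rendering


def _splat(grid: np.ndarray, pts: np.ndarray, amps: np.ndarray) -> None:
    """Trilinear deposition of point masses into a (z, y, x) grid."""
    nz, ny, nx = grid.shape
    base = np.floor(pts).astype(int)
    frac = pts - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                z = base[:, 0] + dz
                y = base[:, 1] + dy
                x = base[:, 2] + dx
                ok = (z >= 0) & (z < nz) & (y >= 0) & (y < ny) & (x >= 0) & (x < nx)
                np.add.at(grid, (z[ok], y[ok], x[ok]), amps[ok] * w[ok])


class _Renderer:
    def __init__(self, profile: SimulationProfile):
        self.p = profile
        self.shape = (profile.z_planes, profile.field_px, profile.field_px)
        self.sxy = profile.voxel_xy_nm      # nm per pixel
        self.sz = profile.voxel_z_nm

    def grid(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=np.float32)

    def nm_to_vox(self, pts_nm: np.ndarray) -> np.ndarray:
        return pts_nm / np.array([self.sz, self.sxy, self.sxy])

    def blur(self, grid: np.ndarray, sigma_xy_nm: float, sigma_z_nm: float) -> np.ndarray:
        return ndimage.gaussian_filter(
            grid, sigma=(sigma_z_nm / self.sz, sigma_xy_nm / self.sxy, sigma_xy_nm / self.sxy),
            mode="constant",
        )

    def ball_points(
        self, rng: np.random.Generator, n: int, centre_nm: np.ndarray,
        radius_nm: float, z_thickness_nm: float,
    ) -> np.ndarray:
        """Uniform points in a flattened ball (cell bodies, nuclei)."""
        pts = []
        while len(pts) < n:
            c = rng.uniform(-1, 1, size=(n, 3))
            keep = (c ** 2).sum(axis=1) <= 1.0
            pts.extend(c[keep])
        pts = np.asarray(pts[:n]) * np.array([z_thickness_nm / 2, radius_nm, radius_nm])
        return pts + centre_nm

    def fill_cylinder(
        self, grid: np.ndarray, rng: np.random.Generator, centre_nm: np.ndarray,
        radius_nm: float, z_thickness_nm: float, brightness: float, n: int = 4000,
    ) -> None:
        """Uniform-brightness disc (constant z-thickness to the rim), the
        shape of a condensed metaphase chromosome plate/rosette."""
        phi = rng.uniform(0, 2 * np.pi, n)
        rad = radius_nm * np.sqrt(rng.uniform(0, 1, n))
        z = rng.uniform(-z_thickness_nm / 2, z_thickness_nm / 2, n)
        pts = np.column_stack([z, rad * np.sin(phi), rad * np.cos(phi)]) + centre_nm
        vol_vox = np.pi * (radius_nm / self.sxy) ** 2 * (z_thickness_nm / self.sz)
        _splat(grid, self.nm_to_vox(pts), np.full(n, brightness * vol_vox / n))

    def fill_ball(
        self, grid: np.ndarray, rng: np.random.Generator, centre_nm: np.ndarray,
        radius_nm: float, z_thickness_nm: float, brightness: float, n: int = 4000,
    ) -> None:
        """Deposit photons so the flattened ball averages ``brightness``
        photons per voxel (total photons = brightness × ball volume)."""
        vol_vox = (
            (4.0 / 3.0) * np.pi
            * (radius_nm / self.sxy) ** 2
            * (z_thickness_nm / 2.0 / self.sz)
        )
        pts = self.ball_points(rng, n, centre_nm, radius_nm, z_thickness_nm)
        _splat(grid, self.nm_to_vox(pts), np.full(n, brightness * vol_vox / n))


def _segment_points(
    centre_nm: np.ndarray, direction: np.ndarray, length_nm: float, step_nm: float = 30.0
) -> np.ndarray:
    n = max(int(length_nm / step_nm) + 1, 2)
    t = np.linspace(-length_nm / 2, length_nm / 2, n)
    return centre_nm[None, :] + t[:, None] * direction[None, :]


def _seg_seg_distance(p1, d1, l1, p2, d2, l2) -> float:
    """Minimum distance between two finite 3D segments (sampled)."""
    a = _segment_points(p1, d1, l1, step_nm=25.0)
    b = _segment_points(p2, d2, l2, step_nm=25.0)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def _random_orientation(rng: np.random.Generator, max_tilt_deg: float) -> np.ndarray:
    phi = rng.uniform(0, 2 * np.pi)
    tilt = np.deg2rad(rng.uniform(-max_tilt_deg, max_tilt_deg))
    return np.array([np.sin(tilt), np.cos(tilt) * np.sin(phi), np.cos(tilt) * np.cos(phi)])


def _place_centrioles(
    rng: np.random.Generator,
    profile: SimulationProfile,
    poles_nm: np.ndarray,
    lengths: list[float],
) -> list[Centriole]:
    """Scatter centrioles around the two spindle poles with a minimum
    capsule-to-capsule gap of ``min_gap_px`` pixels."""
    min_gap_nm = profile.min_gap_px * profile.voxel_xy_nm
    base_scatter_nm = profile.pole_scatter_um * 1000.0
    # alternate poles; any overly long centrioles all go to pole 0 so that
    # asymmetric-spindle fields have a well-defined "long" pole
    order = np.argsort([-v for v in lengths])
    placed: list[Centriole] = []
    assignments: list[int] = []
    for rank, idx in enumerate(order):
        assignments.append((idx, 0 if (lengths[idx] > 500 or rank % 2 == 0) else 1))
    assignments.sort()
    # constant packing density: the scatter radius grows with the cube root
    # of the per-pole count, as a rosette of extra centrioles does
    per_pole = [sum(1 for _, p in assignments if p == q) for q in (0, 1)]
    for idx, pole_idx in assignments:
        length = lengths[idx]
        scatter_nm = base_scatter_nm * max(1.0, per_pole[pole_idx] / 2.0) ** (1.0 / 3.0)
        for attempt in range(300):
            offset = rng.uniform(-1, 1, 3)
            if (offset ** 2).sum() > 1:
                continue
            offset = offset * scatter_nm
            offset[0] = np.clip(offset[0], -800.0, 800.0)  # stay well inside the stack
            centre = poles_nm[pole_idx] + offset
            direction = _random_orientation(rng, profile.max_tilt_deg)
            ok = True
            for other in placed:
                d = _seg_seg_distance(
                    centre, direction, length,
                    np.array(other.centre_nm), np.array(other.orientation), other.length_nm,
                )
                if d < min_gap_nm:
                    ok = False
                    break
                lateral = float(np.hypot(
                    centre[1] - other.centre_nm[1], centre[2] - other.centre_nm[2]
                ))
                axial = abs(centre[0] - other.centre_nm[0])
                if lateral < profile.min_lateral_sep_nm and axial < profile.min_axial_sep_nm:
                    ok = False
                    break
            if ok:
                placed.append(
                    Centriole(
                        centre_nm=tuple(centre),
                        orientation=tuple(direction),
                        length_nm=length,
                        has_cp110=True,
                    )
                )
                break
        else:
            raise RuntimeError("could not place centriole without overlap")
    return placed


def _place_satellites(
    rng: np.random.Generator, profile: SimulationProfile, poles_nm: np.ndarray
) -> list[Centriole]:
    n = rng.poisson(profile.satellite_rate)
    sats = []
    for _ in range(n):
        pole = poles_nm[rng.integers(0, 2)]
        r = rng.uniform(1500.0, 3000.0)
        phi = rng.uniform(0, 2 * np.pi)
        dz = rng.uniform(-600.0, 600.0)
        centre = pole + np.array([dz, r * np.sin(phi), r * np.cos(phi)])
        sats.append(
            Centriole(
                centre_nm=tuple(centre),
                orientation=tuple(_random_orientation(rng, profile.max_tilt_deg)),
                length_nm=profile.satellite_length_nm,
                has_cp110=False,
                is_satellite_decoy=True,
            )
        )
    return sats


def simulate_stack(
    profile: SimulationProfile, seed: int
) -> tuple[ImageStack, GroundTruth]:
    """Render one field of view and return it with its ground truth."""
    rng = np.random.default_rng(seed)
    r = _Renderer(profile)
    nz, ny, nx = r.shape
    field_nm = nx * profile.voxel_xy_nm
    z_mid_nm = nz * profile.voxel_z_nm / 2

    dna = r.grid()
    tub = r.grid()
    cen = r.grid()
    cp110 = r.grid() if profile.render_cp110 else None
    pcm = r.grid() if profile.pcm_pole_amplitudes is not None else None

    cells: list[CellTruth] = []
    margin_nm = profile.cell_radius_um * 1000.0 + 2000.0
    if profile.mitotic_per_field * (2 * margin_nm) > 2 * field_nm:
        raise ValueError("geometry overflow: mitotic cells do not fit the field")

    # --- mitotic cells -----------------------------------------------------
    mitotic_centres = []
    for m in range(profile.mitotic_per_field):
        for attempt in range(200):
            cy, cx = rng.uniform(margin_nm, field_nm - margin_nm, 2)
            if all(np.hypot(cy - oy, cx - ox) > 2.2 * margin_nm for oy, ox in mitotic_centres):
                break
        else:
            raise ValueError("geometry overflow: mitotic cells do not fit the field")
        mitotic_centres.append((cy, cx))
        centre = np.array([z_mid_nm, cy, cx])
        axis_phi = rng.uniform(0, 2 * np.pi)
        half = profile.pole_distance_um * 500.0
        axis = np.array([0.0, np.sin(axis_phi), np.cos(axis_phi)])
        poles = np.stack([centre + half * axis, centre - half * axis])

        n, amplified = _sample_count(profile, rng)
        lengths = _sample_lengths(n, amplified, profile, rng)
        centrioles = _place_centrioles(rng, profile, poles, lengths)
        centrioles += _place_satellites(rng, profile, poles)

        _render_mitotic(r, rng, dna, tub, centre, axis, poles, profile)
        for c in centrioles:
            pts = _segment_points(np.array(c.centre_nm), np.array(c.orientation), c.length_nm)
            step = c.length_nm / (len(pts) - 1)
            dens = (
                profile.satellite_density_per_nm
                if c.is_satellite_decoy
                else profile.centrin_density_per_nm
            )
            amps = np.full(len(pts), dens * step)
            _splat(cen, r.nm_to_vox(pts), amps)
            if cp110 is not None and c.has_cp110:
                amps_p = np.full(len(pts), profile.cp110_density_per_nm * step)
                _splat(cp110, r.nm_to_vox(pts), amps_p)
        if pcm is not None:
            for pole, amp in zip(poles, profile.pcm_pole_amplitudes):
                _splat(pcm, r.nm_to_vox(pole[None, :]), np.array([amp]))
        cells.append(
            CellTruth(
                cell_id=f"fov{seed}_m{m}",
                is_mitotic=True,
                centre_nm=tuple(centre),
                centrioles=tuple(centrioles),
            )
        )

    # --- interphase background --------------------------------------------
    nuc_r_nm = 4200.0
    for i in range(profile.interphase_per_field):
        for attempt in range(100):
            cy, cx = rng.uniform(nuc_r_nm, field_nm - nuc_r_nm, 2)
            if all(
                np.hypot(cy - oy, cx - ox) > margin_nm + nuc_r_nm
                for oy, ox in mitotic_centres
            ):
                break
        else:
            continue
        centre = np.array([z_mid_nm + rng.uniform(-1000, 1000), cy, cx])
        r.fill_ball(dna, rng, centre, nuc_r_nm, 5000.0, profile.dna_interphase_amp, n=1500)
        r.fill_ball(
            tub, rng, centre, nuc_r_nm + 2000.0, 6000.0,
            profile.tubulin_interphase_amp, n=1200,
        )
        cells.append(
            CellTruth(cell_id=f"fov{seed}_i{i}", is_mitotic=False, centre_nm=tuple(centre))
        )

    # --- PSF blur + noise ---------------------------------------------------
    p = profile
    dna = r.blur(dna, p.dna_structure_sigma_um * 1000.0, p.dna_structure_sigma_um * 1200.0)
    tub = r.blur(tub, p.tubulin_structure_sigma_um * 1000.0, p.tubulin_structure_sigma_um * 1200.0)
    cen = r.blur(cen, p.psf_sigma_xy_nm, p.psf_sigma_z_nm)
    channels = {"dna": dna, "tubulin": tub, "centrin": cen}
    if cp110 is not None:
        channels["cp110"] = r.blur(cp110, p.psf_sigma_xy_nm, p.psf_sigma_z_nm)
    if pcm is not None:
        channels["pcm"] = r.blur(pcm, 500.0, 700.0)

    for role, grid in channels.items():
        # Poisson(signal) + Poisson(offset) = Poisson(signal + offset); sampling
        # the uniform offset with a scalar rate and the signal only on its
        # support (tails < 0.01 photon dropped) is exact and much faster
        out = rng.normal(0.0, p.read_noise_sd, size=grid.shape)
        out += rng.poisson(p.background_offset, size=grid.shape)
        support = grid > 1e-2
        sig = grid[support].astype(np.float64)
        out[support] += rng.poisson(sig)
        np.clip(out, 0.0, None, out=out)
        channels[role] = out.astype(np.float32)

    stack = ImageStack(
        channels=channels,
        voxel_size_xy_nm=p.voxel_xy_nm,
        voxel_size_z_nm=p.voxel_z_nm,
        source_id=f"synthetic_seed{seed}",
    )
    return stack, GroundTruth(cells=tuple(cells), seed=seed)


def _render_mitotic(
    r: _Renderer,
    rng: np.random.Generator,
    dna: np.ndarray,
    tub: np.ndarray,
    centre: np.ndarray,
    axis: np.ndarray,
    poles: np.ndarray,
    profile: SimulationProfile,
) -> None:
    """Condensed chromatin plus a bipolar spindle inside a rounded cell."""
    p = profile
    rosette_nm = p.rosette_radius_um * 1000.0
    cell_nm = p.cell_radius_um * 1000.0

    if p.textured_chromatin:
        # two rings of large chromosome clusters + a central one: texture at
        # a length scale that survives the pipeline's 1.15 µm smoothing and
        # covers the whole figure, so the robust-threshold speckles fuse
        # into one region after the 2.2 µm dilation
        rings = [(0.88 * rosette_nm, 12), (0.45 * rosette_nm, 6), (0.0, 1)]
        for ring_r, n_clusters in rings:
            for k in range(n_clusters):
                phi = 2 * np.pi * k / n_clusters + rng.uniform(-0.15, 0.15)
                c = centre + np.array([0.0, ring_r * np.sin(phi), ring_r * np.cos(phi)])
                r.fill_ball(dna, rng, c, 1100.0, 2800.0, p.dna_amp * 8.0, n=600)
    else:
        r.fill_cylinder(dna, rng, centre, rosette_nm, 3000.0, p.dna_amp, n=4000)

    # cytoplasmic tubulin throughout the rounded cell
    r.fill_ball(tub, rng, centre, cell_nm, 6000.0, p.tubulin_cytoplasm_amp, n=5000)
    # spindle fibres pole→equator, plus asters (optionally asymmetric)
    amps = [
        p.tubulin_spindle_amp * p.tubulin_pole_ratio,
        p.tubulin_spindle_amp,
    ]
    perp = np.array([0.0, axis[2], -axis[1]])
    sigma_lat_nm, sigma_z_nm = 1500.0, 800.0
    # effective fibre-bundle volume: Gaussian cross-section 2π·σlat·σz (in
    # voxels) times the pole→equator length in pixels
    cross_vox = 2.0 * np.pi * (sigma_lat_nm / r.sxy) * (sigma_z_nm / r.sz)
    half_len_px = p.pole_distance_um * 500.0 / r.sxy
    vol_vox = cross_vox * half_len_px
    n_fib = 1500
    for pole, amp in zip(poles, amps):
        lat = rng.normal(0, sigma_lat_nm, n_fib)
        zoff = rng.normal(0, sigma_z_nm, n_fib)
        eq = centre[None, :] + lat[:, None] * perp[None, :]
        eq[:, 0] += zoff
        t = rng.random(n_fib)[:, None]
        pts = pole[None, :] + t * (eq - pole[None, :])
        _splat(tub, r.nm_to_vox(pts), np.full(n_fib, amp * vol_vox / n_fib))
        r.fill_ball(tub, rng, pole, 1500.0, 2000.0, amp * 2.5, n=1500)
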