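"""Core data types, physical-unit handling, and stack / result-table I/O.

Everything downstream works in physical units (nm for lengths, µm² for
areas); this module is the only place where pixels are converted to and
from micrometres.  Stacks are stored as ``(z, y, x)`` arrays of
non-negative floats regardless of on-disk bit depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ROLES = ("dna", "tubulin", "centrin", "cp110", "pcm")

#: roles that must be present in every stack
REQUIRED_ROLES = ("dna", "centrin")


class StackFormatError(ValueError):
    """Raised when an on-disk stack cannot be interpreted."""


@dataclass(frozen=True)
class PixelGeometry:
    """Lateral pixel size and axial plane spacing of an acquisition.

    Parameters
    ----------
    um_per_px :
        Lateral (x = y) pixel size in micrometres.  The default spinning-disk
        configuration emulated throughout this package uses 86.7 nm.
    nm_per_voxel_z :
        Distance between consecutive z-planes in nanometres (default 200).
    """

    um_per_px: float = 0.0867
    nm_per_voxel_z: float = 200.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or self.nm_per_voxel_z <= 0:
            raise ValueError("pixel geometry must be strictly positive")

    @property
    def um2_per_px(self) -> float:
        """Area of one pixel in µm²."""
        return self.um_per_px ** 2

    @property
    def nm_per_px(self) -> float:
        return self.um_per_px * 1000.0


def um_to_px(value_um: float, geometry: PixelGeometry) -> int:
    """Convert a physical length to a pixel count, rounding half-up.

    Kernel radii derived from micrometre constants (e.g. the 2.2 µm
    dilation radius, the 1.15 µm smoothing sigma) use this conversion;
    any strictly positive length maps to at least one pixel so that
    small-pixel images never produce empty kernels.
    """
    if value_um < 0:
        raise ValueError("length must be non-negative")
    if value_um == 0:
        return 0
    px = math.floor(value_um / geometry.um_per_px + 0.5)
    return max(px, 1)


@dataclass
class ImageStack:
    """One multi-channel field of view.

    ``channels`` maps a role (dna, tubulin, centrin, cp110, pcm) to a 3D
    ``(z, y, x)`` grid of non-negative intensities.  All grids share one
    shape; dna and centrin are always present (cp110 only in dual-marker
    mode).
    """

    channels: dict[str, np.ndarray]
    voxel_size_xy_nm: float
    voxel_size_z_nm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.voxel_size_xy_nm <= 0 or self.voxel_size_z_nm <= 0:
            raise ValueError("voxel sizes must be strictly positive")
        for role in REQUIRED_ROLES:
            if role not in self.channels:
                raise ValueError(f"required channel role {role!r} missing")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel grids differ in shape: {shapes}")
        shape = next(iter(shapes))
        if len(shape) != 3:
            raise ValueError("channel grids must be 3D (z, y, x)")
        if shape[0] < 2:
            raise StackFormatError("fewer than 2 z-planes along axis z")
        for role, grid in self.channels.items():
            if np.any(grid < 0):
                raise ValueError(f"negative intensities in channel {role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def geometry(self) -> PixelGeometry:
        return PixelGeometry(
            um_per_px=self.voxel_size_xy_nm / 1000.0,
            nm_per_voxel_z=self.voxel_size_z_nm,
        )

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"channel role {role!r} not present in stack")
        return self.channels[role]


@dataclass
class CellRecord:
    """Per-mitotic-cell result: centriole count, lengths and defect flags.

    ``amplified`` and ``n_overlong`` are derived from the length list and
    kept consistent by construction: a cell is amplified iff it carries
    more than four centrioles, and a centriole is overly long iff it
    measures strictly more than 500 nm.
    """

    cell_id: str
    lengths_nm: list[float] = field(default_factory=list)
    curation_status: str = "auto"
    #: stable per-centriole tags ("c0", "c1", …) assigned at detection time;
    #: curation refers to these, so replaying decisions is idempotent
    centriole_ids: list[str] | None = None

    OVERLONG_NM = 500.0
    AMPLIFIED_ABOVE = 4

    def __post_init__(self) -> None:
        if self.curation_status not in ("auto", "accepted", "rejected"):
            raise ValueError(f"bad curation status {self.curation_status!r}")
        self.lengths_nm = [float(v) for v in self.lengths_nm]
        if any(not math.isfinite(v) or v < 0 for v in self.lengths_nm):
            raise ValueError("lengths must be finite and non-negative")
        if self.centriole_ids is None:
            self.centriole_ids = [f"c{i}" for i in range(len(self.lengths_nm))]
        elif len(self.centriole_ids) != len(self.lengths_nm):
            raise ValueError("centriole_ids and lengths_nm differ in length")

    @property
    def n_centrioles(self) -> int:
        return len(self.lengths_nm)

    @property
    def amplified(self) -> bool:
        return self.n_centrioles > self.AMPLIFIED_ABOVE

    @property
    def n_overlong(self) -> int:
        return sum(1 for v in self.lengths_nm if v > self.OVERLONG_NM)


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int],
    geometry: PixelGeometry,
    source_id: str | None = None,
) -> ImageStack:
    """Read a multi-channel TIFF / OME-TIFF into an :class:`ImageStack`.

    ``channel_map`` assigns channel roles to 0-based channel indices.
    Explicit ``geometry`` always wins over any file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes.upper()
    arr = _as_czyx(arr, axes)
    n_channels = arr.shape[0]
    channels: dict[str, np.ndarray] = {}
    for role, idx in channel_map.items():
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r}")
        if not 0 <= idx < n_channels:
            raise IndexError(
                f"channel index {idx} for role {role!r} out of range "
                f"(stack has {n_channels} channels)"
            )
        channels[role] = np.asarray(arr[idx], dtype=np.float32)
    if arr.shape[1] < 2:
        raise StackFormatError("fewer than 2 z-planes along axis z")
    return ImageStack(
        channels=channels,
        voxel_size_xy_nm=geometry.nm_per_px,
        voxel_size_z_nm=geometry.nm_per_voxel_z,
        source_id=source_id if source_id is not None else path.stem,
    )


def _as_czyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Rearrange a tifffile array to (C, Z, Y, X), inserting missing axes."""
    axes = axes.replace("S", "C")  # treat sample axis as channel
    if set(axes) - set("CZYX"):
        # drop singleton time/other axes
        keep = [i for i, a in enumerate(axes) if a in "CZYX" or arr.shape[i] > 1]
        if any(axes[i] not in "CZYX" for i in keep):
            raise StackFormatError(f"unsupported axes {axes!r}")
        arr = arr.reshape([arr.shape[i] for i in keep])
        axes = "".join(axes[i] for i in keep)
    if "Y" not in axes or "X" not in axes:
        raise StackFormatError(f"no spatial axes in {axes!r}")
    if "Z" not in axes:
        raise StackFormatError("fewer than 2 z-planes along axis z")
    if "C" not in axes:
        arr = arr[None]
        axes = "C" + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(arr, order)


def write_stack(stack: ImageStack, path: str | Path) -> list[str]:
    """Write a stack as an OME-TIFF with axes CZYX; returns the role order."""
    roles = [r for r in CHANNEL_ROLES if r in stack.channels]
    data = np.stack([stack.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": roles},
            "PhysicalSizeX": stack.voxel_size_xy_nm / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.voxel_size_xy_nm / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.voxel_size_z_nm / 1000.0,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return roles


_RECORD_COLUMNS = [
    "cell_id",
    "n_centrioles",
    "lengths_nm",
    "amplified",
    "n_overlong",
    "curation_status",
]


def write_cell_records(records: Sequence[CellRecord], path: str | Path) -> None:
    """Write per-cell results to CSV (lengths as semicolon-joined nm values)."""
    if not records:
        raise ValueError("no records to write")
    rows = [
        {
            "cell_id": r.cell_id,
            "n_centrioles": r.n_centrioles,
            "lengths_nm": ";".join(f"{v:.3f}" for v in r.lengths_nm),
            "amplified": r.amplified,
            "n_overlong": r.n_overlong,
            "curation_status": r.curation_status,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)


def read_cell_records(path: str | Path) -> list[CellRecord]:
    """Read back a table written by :func:`write_cell_records`."""
    df = pd.read_csv(path, dtype={"lengths_nm": str}, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        raw = row["lengths_nm"]
        lengths = [float(v) for v in raw.split(";")] if raw else []
        records.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                lengths_nm=lengths,
                curation_status=str(row["curation_status"]),
            )
        )
    return records
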