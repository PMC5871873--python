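"""Screen orchestration: fields → mitotic regions → centrioles → records.

``run_screen`` chains the full analysis over a list of fields and emits
a per-cell record table, a per-line summary, a JSON manifest (all
parameters plus per-stage counts: the reproducibility contract is that
manifest + inputs fully determine outputs) and, optionally, a gallery of
annotated per-cell PNGs for visual curation.  Curation itself is
file-based: a reviewer records accept/reject decisions per region or per
centriole in a table, and ``apply_curation`` replays those decisions
onto the auto-generated records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .centriole_segmentation import CentrioleParams, segment_centrioles
from .image_model import CellRecord, ImageStack, write_cell_records
from .mitotic_segmentation import MitoticParams, find_mitotic_regions
from .population_stats import LineSummary, summarize_line

logger = logging.getLogger("centrioscope")


@dataclass(frozen=True)
class CurationEntry:
    object_id: str            # region: cell id; centriole: "<cell id>:c<i>"
    stage: str                # {"region", "centriole"}
    decision: str             # {"accept", "reject"}
    note: str = ""


@dataclass
class CurationFile:
    entries: list[CurationEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for stage in ("region", "centriole"):
            ids = [e.object_id for e in self.entries if e.stage == stage]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate object ids in stage {stage!r}")
        for e in self.entries:
            if e.stage not in ("region", "centriole"):
                raise ValueError(f"unknown stage {e.stage!r}")
            if e.decision not in ("accept", "reject"):
                raise ValueError(f"unknown decision {e.decision!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurationFile":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(
            entries=[
                CurationEntry(
                    object_id=str(r["object_id"]),
                    stage=str(r["stage"]),
                    decision=str(r["decision"]),
                    note=str(r.get("note", "")),
                )
                for _, r in df.iterrows()
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([dataclasses.asdict(e) for e in self.entries]).to_csv(
            path, index=False
        )


def apply_curation(
    records: Sequence[CellRecord], curation: CurationFile
) -> list[CellRecord]:
    """Replay accept/reject decisions onto auto-generated cell records.

    Rejected regions drop their cells; a rejected centriole ``<cell>:c<i>``
    (0-based index into the cell's auto length list) is removed and the
    cell's count and defect flags recompute automatically.  The operation
    is idempotent: decisions whose target was already removed by this
    same curation file are no-ops (a region-reject of an absent cell is
    indistinguishable from one already applied, and is tolerated); other
    ids that never belonged to the record set raise, listing the ids.
    """
    by_cell = {r.cell_id: r for r in records}
    rejected_regions = {
        e.object_id for e in curation.entries
        if e.stage == "region" and e.decision == "reject"
    }
    unknown = []
    drop_centrioles: dict[str, set[int]] = {}
    for e in curation.entries:
        if e.stage == "region":
            if e.object_id not in by_cell and e.object_id not in rejected_regions:
                unknown.append(e.object_id)
        else:
            cell_id, _, tag = e.object_id.rpartition(":")
            if not cell_id or not tag.startswith("c") or not tag[1:].isdigit():
                unknown.append(e.object_id)
                continue
            if cell_id not in by_cell and cell_id not in rejected_regions:
                unknown.append(e.object_id)
                continue
            if e.decision == "reject":
                drop_centrioles.setdefault(cell_id, set()).add(int(tag[1:]))
    if unknown:
        raise KeyError(f"unknown curation object ids: {sorted(unknown)}")

    out: list[CellRecord] = []
    for r in records:
        if r.cell_id in rejected_regions:
            continue
        drops = {f"c{i}" for i in drop_centrioles.get(r.cell_id, set())}
        keep = [i for i, cid in enumerate(r.centriole_ids) if cid not in drops]
        status = "accepted" if (drops or _curated(curation, r.cell_id)) else r.curation_status
        out.append(
            CellRecord(
                cell_id=r.cell_id,
                lengths_nm=[r.lengths_nm[i] for i in keep],
                curation_status=status,
                centriole_ids=[r.centriole_ids[i] for i in keep],
            )
        )
    return out


def _curated(curation: CurationFile, cell_id: str) -> bool:
    return any(
        e.object_id == cell_id or e.object_id.startswith(cell_id + ":")
        for e in curation.entries
    )


@dataclass
class ScreenResult:
    records: list[CellRecord]
    summary: LineSummary
    manifest: dict


def run_screen(
    fields: Iterable[tuple[str, ImageStack]],
    mode: str = "secondary",
    mitotic_params: MitoticParams = MitoticParams(),
    centriole_params: CentrioleParams = CentrioleParams(),
    line_id: str = "line",
    out_dir: str | Path | None = None,
    gallery: bool = False,
) -> ScreenResult:
    """Run the full screen over a set of fields.

    ``mode`` is ``"primary"`` (centrin only) or ``"secondary"``
    (centrin + CP110, the default and authoritative configuration).  A
    field that fails to process is logged and skipped; it aborts that
    field, not the run.
    """
    if mode not in ("primary", "secondary"):
        raise ValueError(f"unknown screen mode {mode!r}")
    records: list[CellRecord] = []
    n_fields = n_failed = n_regions = 0
    gallery_items = []
    for source_id, stack in fields:
        n_fields += 1
        try:
            regions = find_mitotic_regions(stack, mitotic_params)
            for k, region in enumerate(regions):
                cell_id = f"{source_id}_cell{k}"
                objs = segment_centrioles(
                    stack, region, centriole_params, mode=mode, cell_id=cell_id
                )
                records.append(
                    CellRecord(
                        cell_id=cell_id,
                        lengths_nm=[o.length_nm for o in objs],
                    )
                )
                if gallery:
                    gallery_items.append((cell_id, stack, region, objs))
            n_regions += len(regions)
        except Exception:
            n_failed += 1
            logger.warning("field %s failed; skipping", source_id, exc_info=True)
    if not records:
        records = []
        summary = LineSummary(
            line_id=line_id, n_cells=0, pct_amplified=0.0, pct_overlong=0.0,
            mean_length_nm=float("nan"), vmr=0.0, n_centrioles_measured=0,
        )
    else:
        summary = summarize_line(records, line_id=line_id)
    manifest = {
        "software": "centrioscope",
        "version": __version__,
        "mode": mode,
        "line_id": line_id,
        "mitotic_params": dataclasses.asdict(mitotic_params),
        "centriole_params": dataclasses.asdict(centriole_params),
        "counts": {
            "fields": n_fields,
            "fields_failed": n_failed,
            "mitotic_regions": n_regions,
            "cells": len(records),
            "centrioles": sum(r.n_centrioles for r in records),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if records:
            write_cell_records(records, out_dir / "cells.csv")
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(
            out_dir / "line_summary.csv", index=False
        )
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if gallery:
            gal = out_dir / "gallery"
            gal.mkdir(exist_ok=True)
            for cell_id, stack, region, objs in gallery_items:
                _save_gallery_png(gal / f"{cell_id}.png", stack, region, objs)
    return ScreenResult(records=records, summary=summary, manifest=manifest)


def _save_gallery_png(path: Path, stack: ImageStack, region, objs) -> None:
    """Annotated per-cell image: region outline + centriole boxes/lengths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    f = 8  # upsampled-frame factor used by the detector
    proj = np.asarray(stack.channel("centrin")).max(axis=0)
    y0, y1, x0, x1 = region.bbox()
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(proj[y0:y1, x0:x1], cmap="gray")
    ax.contour(region.mask[y0:y1, x0:x1], levels=[0.5], colors="cyan", linewidths=0.8)
    for o in objs:
        v = o.voxels / f  # back to original pixel scale
        ys, xs = v[:, 1] - y0, v[:, 2] - x0
        ax.plot(
            [xs.min(), xs.max(), xs.max(), xs.min(), xs.min()],
            [ys.min(), ys.min(), ys.max(), ys.max(), ys.min()],
            color="yellow", linewidth=0.8,
        )
        ax.text(
            xs.min(), ys.min() - 1, f"{o.length_nm:.0f} nm",
            color="yellow", fontsize=6,
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
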