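"""Shared fixtures: rendered synthetic fields are expensive, so batches
are session-scoped and reused across tests."""

from dataclasses import replace

import numpy as np
import pytest

from centrioscope import (
    CentrioleParams,
    SimulationProfile,
    find_mitotic_regions,
    segment_centrioles,
    simulate_stack,
)
from centrioscope.centriole_segmentation import (
    detect_candidates_2d,
    extract_roi,
    grow_3d_components,
)

#: compact per-cell field: one mitotic cell, a couple of interphase
#: neighbours, default contrast and acquisition geometry
CELL_PROFILE = SimulationProfile(field_px=352, interphase_per_field=2)


@pytest.fixture(scope="session")
def single_cell():
    """One rendered mitotic cell with 4 centrioles plus its region."""
    profile = replace(CELL_PROFILE, fixed_count=4)
    stack, truth = simulate_stack(profile, seed=11)
    regions = find_mitotic_regions(stack)
    assert len(regions) == 1
    return stack, truth, regions[0]


@pytest.fixture(scope="session")
def cell_batch():
    """50 rendered mitotic cells with 2-8 centrioles (seeded), with their
    grown voxel complexes and terminal centriole objects.

    Returned entries: (true_count, true_lengths, grown_union, objects).
    ``grown_union`` is the union of grown candidate voxels (the
    conservation reference).
    """
    rng = np.random.default_rng(2024)
    params = CentrioleParams()
    entries = []
    for i in range(50):
        k = int(rng.integers(2, 9))
        profile = replace(CELL_PROFILE, fixed_count=k)
        stack, truth = simulate_stack(profile, seed=3000 + i)
        regions = find_mitotic_regions(stack)
        if not regions:
            continue
        region = regions[0]
        roi_c, off = extract_roi(stack, region, "centrin")
        roi_p, _ = extract_roi(stack, region, "cp110")
        y0, y1, x0, x1 = region.bbox()
        cands = detect_candidates_2d(
            roi_c, roi_p, stack.geometry, params, off,
            valid_mask=region.mask[y0:y1, x0:x1],
        )
        grown_union = set()
        for cand in cands:
            for vox, _ in grow_3d_components(stack, cand, params.upsample_factor):
                grown_union.update(map(tuple, vox))
        objs = segment_centrioles(stack, region, params, mode="secondary")
        truths = [c.length_nm for c in truth.mitotic_cells()[0].centrioles]
        entries.append((k, truths, grown_union, objs))
    assert len(entries) >= 45  # the detector found a region in ~every field
    return entries
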