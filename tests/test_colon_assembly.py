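"""Morphology, mask combination, block cleanup, row stripping, SLDR, and
the assembled per-slice pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

import colonseg as cs
from colonseg.colon_assembly import (
    PipelineConfig,
    and_with_initial,
    binarize_opened,
    block_grid,
    combine,
    concatenate_pve,
    morphological_open,
    remove_small_segments,
    remove_tiny_holes,
    run_pipeline,
    sldr,
    strip_border_rows,
)

masks_32 = hnp.arrays(bool, (32, 32))


def test_opening_removes_isolated_pixel():
    mask = np.zeros((16, 16), bool)
    mask[8, 8] = True
    assert not morphological_open(mask, 2).any()


def test_opening_keeps_large_region_except_corner_rounding():
    mask = np.zeros((32, 32), bool)
    mask[5:25, 5:25] = True
    out = morphological_open(mask, 2)
    # a large convex region survives; only the sharp corners are rounded
    # off by the disk element (3 px per corner)
    assert out[7:23, 7:23].all()
    assert (mask & ~out).sum() == 12
    disk_mask = np.zeros((32, 32), bool)
    rr, cc = np.ogrid[:32, :32]
    disk_mask[(rr - 16) ** 2 + (cc - 16) ** 2 <= 100] = True
    assert np.array_equal(morphological_open(disk_mask, 2), disk_mask)


@given(masks_32)
@settings(max_examples=30)
def test_opening_idempotent_and_antiextensive(mask):
    opened = morphological_open(mask, 2)
    assert not (opened & ~mask).any()
    assert np.array_equal(morphological_open(opened, 2), opened)


def test_binarize_opened_empty_support_gives_empty():
    sl = np.full((16, 16), 30000, dtype=np.uint16)
    assert not binarize_opened(np.zeros((16, 16), bool), sl).any()


def test_binarize_opened_recovers_opened_air(small_phantom):
    _, volume, gt = small_phantom
    i = 2  # no lungs on this slice
    sl = volume.data[i]
    res = cs.otsu_threshold(sl)
    IS = cs.extract_air(sl, res)
    interior = cs.remove_external_air(IS)
    I_mo = morphological_open(interior, 2)
    D1 = binarize_opened(I_mo, sl)
    opened_IS = morphological_open(IS, 2)
    dice = 2 * (D1 & opened_IS).sum() / (D1.sum() + opened_IS.sum())
    assert dice >= 0.95
    assert (D1 & gt.colon_mask[i]).sum() / gt.colon_mask[i].sum() >= 0.95
    assert np.array_equal(D1, binarize_opened(I_mo, sl))


def test_combine_identity_disjoint_and_oracle():
    rng = np.random.default_rng(0)
    d1 = rng.random((16, 16)) > 0.5
    assert np.array_equal(combine(np.ones((16, 16), bool), d1), d1)
    d0 = ~d1
    assert not combine(d0, d1).any()
    a, b = rng.random((16, 16)) > 0.5, rng.random((16, 16)) > 0.5
    expected = np.array([[a[i, j] and b[i, j] for j in range(16)] for i in range(16)])
    assert np.array_equal(combine(a, b), expected)
    with pytest.raises(ValueError):
        combine(a, np.zeros((8, 8), bool))


def test_block_partition_geometry():
    nr, nc, per_block = block_grid((512, 512), 8)
    assert (nr, nc, per_block) == (64, 64, 64)
    assert nr * nc == 4096


def test_small_block_cleared_large_block_kept():
    mask = np.zeros((16, 16), bool)
    mask[0:3, 0:3] = True   # 9 px in block (0, 0)
    mask[8:16, 8:16] = True  # 64 px in block (1, 1)
    out = remove_tiny_holes(mask, 8, 10)
    assert not out[0:8, 0:8].any()
    assert out[8:16, 8:16].all()


def test_strictness_of_the_area_test():
    mask = np.zeros((8, 8), bool)
    mask[:2, :5] = True  # exactly 10 px
    assert remove_tiny_holes(mask, 8, 10, strict=True).sum() == 10
    assert remove_tiny_holes(mask, 8, 10, strict=False).sum() == 0


@given(masks_32)
@settings(max_examples=30)
def test_block_cleanup_antiextensive(mask):
    out = remove_tiny_holes(mask, 8, 10)
    assert not (out & ~mask).any()


def test_blocks_clip_at_edges():
    mask = np.ones((20, 20), bool)
    out = remove_tiny_holes(mask, 8, 10)
    # the 4x4 corner block holds 16 px >= 10 and survives
    assert out.all()
    mask2 = np.zeros((20, 20), bool)
    mask2[16:19, 16:19] = True  # 9 px in the clipped corner block
    assert not remove_tiny_holes(mask2, 8, 10).any()


def test_block_larger_than_mask_rejected():
    with pytest.raises(ValueError):
        remove_tiny_holes(np.zeros((4, 4), bool), 8, 10)


def test_remove_small_segments_by_component_area():
    mask = np.zeros((64, 64), bool)
    mask[2:4, 2:4] = True       # 4 px fragment
    mask[10:20, 10:30] = True   # 200 px segment spanning many blocks
    out = remove_small_segments(mask, 35)
    assert not out[2:4, 2:4].any()
    assert out[10:20, 10:30].all()


def test_strip_border_rows_spans():
    mask = np.ones((512, 512), bool)
    out = strip_border_rows(mask)
    kept = np.flatnonzero(out.any(axis=1))
    assert kept[0] == 40 and kept[-1] == 398  # rows 41..399, 1-based
    assert out[199, 49]  # an interior pixel survives
    assert not strip_border_rows(np.zeros((512, 512), bool)).any()


def test_and_with_initial_matches_conjunction():
    rng = np.random.default_rng(1)
    a, b = rng.random((16, 16)) > 0.5, rng.random((16, 16)) > 0.5
    assert np.array_equal(and_with_initial(a, b), a & b)


def test_sldr_keeps_persistent_segments():
    rng = np.random.default_rng(2)
    cur = rng.random((32, 32)) > 0.7
    out, decisions = sldr(cur, cur)
    assert np.array_equal(out, cur)
    assert all(not d.removed and d.xor_fraction == 0.0 for d in decisions)


def test_sldr_removes_segment_without_predecessor_overlap():
    prev = np.zeros((32, 32), bool)
    prev[4:10, 4:10] = True
    cur = np.zeros((32, 32), bool)
    cur[4:10, 4:10] = True     # colon: persists
    cur[20:26, 20:26] = True   # bowel: new
    out, decisions = sldr(prev, cur)
    assert out[4:10, 4:10].all()
    assert not out[20:26, 20:26].any()
    fractions = {d.segment_label: d.xor_fraction for d in decisions}
    assert 1.0 in fractions.values()
    removed = [d for d in decisions if d.removed]
    assert len(removed) == 1 and removed[0].xor_fraction == 1.0


def test_sldr_first_slice_passes_through():
    cur = np.random.default_rng(3).random((16, 16)) > 0.5
    out, decisions = sldr(None, cur)
    assert np.array_equal(out, cur)
    assert decisions == []


def test_sldr_threshold_validated():
    with pytest.raises(ValueError):
        sldr(np.zeros((4, 4), bool), np.zeros((4, 4), bool), overlap_threshold=1.5)


def test_concatenate_fills_holes_and_merges_adjacent_fluid():
    colon = np.zeros((32, 32), bool)
    colon[5:15, 5:15] = True
    colon[9:11, 9:11] = False  # hole
    out = concatenate_pve(colon, np.zeros_like(colon))
    assert out[9:11, 9:11].all()
    fluid = np.zeros_like(colon)
    fluid[15:20, 5:15] = True  # directly below the air region
    merged = concatenate_pve(colon, fluid)
    from scipy import ndimage

    _, n = ndimage.label(merged, structure=np.ones((3, 3)))
    assert n == 1
    assert np.array_equal(concatenate_pve(merged, np.zeros_like(colon)), merged)


def test_single_slice_volume_skips_sldr(truth_net):
    net, _ = truth_net
    spec = cs.PhantomSpec(n_slices=1, seed=17)
    volume, _ = cs.generate_phantom(spec)
    states, finals = run_pipeline(volume, net)
    assert len(finals) == 1
    assert states[0].sldr_decisions == []
    assert np.array_equal(finals[0], concatenate_pve(
        remove_small_segments(states[0].OutF1, 35), states[0].fluid))


def test_pipeline_is_deterministic(truth_net):
    net, _ = truth_net
    spec = cs.PhantomSpec(n_slices=3, slice_shape=(128, 128), lung_slice_range=(0, 1), seed=4)
    volume, _ = cs.generate_phantom(spec)
    _, f1 = run_pipeline(volume, net)
    _, f2 = run_pipeline(volume, net)
    assert all(np.array_equal(a, b) for a, b in zip(f1, f2))


def test_pipeline_state_relations(pipeline_run):
    _, _, states, finals = pipeline_run
    for s, final in zip(states, finals):
        assert np.array_equal(s.OutF, s.D0 & s.D1)
        assert not (s.OutF1 & ~s.OI).any()
        assert np.array_equal(s.final, final)


def test_empty_volume_rejected(truth_net):
    net, _ = truth_net
    with pytest.raises(ValueError):
        run_pipeline(cs.CTVolume(np.zeros((0, 8, 8), dtype=np.uint16)), net)
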