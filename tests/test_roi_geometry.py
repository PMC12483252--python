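"""ROI derivation checked against brute-force per-pixel definitions."""

import numpy as np
import pytest

from prognomil import roi_geometry as roi
from prognomil.roi_geometry import (
    ConfigurationError,
    ROIMask,
    SegmentationMask,
    TileRecord,
    border_region,
    disk_radius_px,
    extract_tile_grid,
    invasive_front,
    multiscale_tiles,
    select_class_mask,
    tissue_sections,
)
from prognomil.synthetic_data import (
    SYNTH_CLASS_MAP,
    random_tissue_mask,
    synth_tissue_mask,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent per-pixel definitions)


def brute_within(mask: np.ndarray, r: int) -> np.ndarray:
    """True where a true pixel of ``mask`` lies within Euclidean distance r."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    pts = np.argwhere(mask)
    for y in range(h):
        for x in range(w):
            if pts.size and (((pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2) <= r * r).any():
                out[y, x] = True
    return out


def brute_border(seg: SegmentationMask, distance_um: float) -> np.ndarray:
    uro = seg.class_mask("urothelium")
    lp = seg.class_mask("lamina propria")
    r = round(distance_um / seg.pixel_size_um)
    return brute_within(uro, r) & brute_within(lp, r) & (uro | lp)


def brute_front(seg: SegmentationMask, border: np.ndarray,
                distance_um: float) -> np.ndarray:
    muscle = seg.class_mask("muscle")
    r = round(distance_um / seg.pixel_size_um)
    sections = tissue_sections(seg)
    good = np.zeros_like(border)
    for lab in np.unique(sections[muscle]):
        if lab > 0:
            good |= sections == lab
    return border & good & brute_within(muscle, r)


def make_seg(labels) -> SegmentationMask:
    return SegmentationMask(np.asarray(labels, dtype=np.uint8),
                            dict(SYNTH_CLASS_MAP), pixel_size_um=8.0)


# ---------------------------------------------------------------------------
# class selection


def test_select_class_mask_cases():
    empty = make_seg(np.zeros((4, 4)))
    assert not select_class_mask(empty, {"urothelium"}).mask.any()

    solid = make_seg(np.ones((4, 4)))
    assert select_class_mask(solid, {"urothelium"}).mask.all()

    halves = np.ones((4, 4))
    halves[:, 2:] = 2
    both = select_class_mask(make_seg(halves), {"urothelium", "lamina propria"})
    assert both.mask.all()
    assert both.roi_name == "UROLP"


def test_select_class_mask_rejects_unknown_class():
    with pytest.raises(ConfigurationError):
        select_class_mask(make_seg(np.zeros((2, 2))), {"cartilage"})


@pytest.mark.parametrize(
    "distance,pixel,expected",
    [(800, 8.0, 100), (800, 0.25, 3200), (800, 3.0, 267)],
)
def test_disk_radius_px(distance, pixel, expected):
    assert disk_radius_px(distance, pixel) == expected


def test_disk_radius_px_rejects_nonpositive():
    with pytest.raises(ValueError):
        disk_radius_px(0, 1.0)
    with pytest.raises(ValueError):
        disk_radius_px(800, -1.0)


# ---------------------------------------------------------------------------
# border


def test_border_band_on_halfplane_interface():
    # rows 0-9 urothelium, rows 10-19 lamina propria, r = 3 -> rows 7-12
    labels = np.ones((20, 20))
    labels[10:] = 2
    seg = make_seg(labels)
    band = border_region(seg, distance_um=3 * seg.pixel_size_um)
    expected = np.zeros((20, 20), dtype=bool)
    expected[7:13] = True
    np.testing.assert_array_equal(band.mask, expected)
    np.testing.assert_array_equal(band.mask, brute_border(seg, 24.0))


def test_border_empty_when_classes_far_apart():
    labels = np.zeros((40, 40))
    labels[0:4, 0:4] = 1
    labels[36:40, 36:40] = 2
    band = border_region(make_seg(labels), distance_um=2 * 8.0)
    assert not band.mask.any()


def test_border_zero_distance_is_empty():
    labels = np.ones((8, 8))
    labels[4:] = 2
    assert not border_region(make_seg(labels), distance_um=0).mask.any()


# ---------------------------------------------------------------------------
# sections


def test_tissue_sections_counts_components():
    assert tissue_sections(make_seg(np.zeros((6, 6)))).max() == 0

    two = np.zeros((10, 10))
    two[0:3, 0:3] = 1
    two[7:10, 7:10] = 2
    labs = tissue_sections(make_seg(two))
    assert set(np.unique(labs)) == {0, 1, 2}


def test_tissue_sections_diagonal_touch_is_one_component():
    diag = np.zeros((6, 6))
    diag[0:3, 0:3] = 1
    diag[3:6, 3:6] = 3  # touches only at the corner pixel
    labs = tissue_sections(make_seg(diag))
    assert labs.max() == 1


# ---------------------------------------------------------------------------
# front


def test_front_empty_without_muscle():
    labels = np.ones((12, 12))
    labels[6:] = 2
    seg = make_seg(labels)
    border = border_region(seg, 16.0)
    assert border.mask.any()
    assert not invasive_front(seg, border, 16.0).mask.any()


def test_front_equals_border_when_muscle_adjacent():
    seg = synth_tissue_mask("ribbon", 24, pixel_size_um=8.0)
    # dilation radius spans the whole raster -> both conditions hold everywhere
    border = border_region(seg, distance_um=30 * 8.0)
    front = invasive_front(seg, border, distance_um=30 * 8.0)
    np.testing.assert_array_equal(front.mask, border.mask)


def test_front_respects_section_membership():
    seg = synth_tissue_mask("two-sections", 48, pixel_size_um=8.0)
    border = border_region(seg, 4 * 8.0)
    front = invasive_front(seg, border, 10 * 8.0)
    np.testing.assert_array_equal(front.mask, brute_front(seg, border.mask, 10 * 8.0))
    # the muscle-free section (left half) contributes nothing
    assert not front.mask[:, :20].any()


@pytest.mark.parametrize("seed", range(12))
def test_border_and_front_match_bruteforce_on_random_masks(seed):
    rng = np.random.default_rng(seed)
    size = int(rng.integers(16, 48))
    seg = random_tissue_mask(size, pixel_size_um=8.0, rng=rng)
    distance = float(rng.integers(1, 5)) * 8.0
    border = border_region(seg, distance)
    np.testing.assert_array_equal(border.mask, brute_border(seg, distance))
    front = invasive_front(seg, border, distance)
    np.testing.assert_array_equal(front.mask, brute_front(seg, border.mask, distance))


def test_roi_nesting_and_monotonicity():
    rng = np.random.default_rng(99)
    seg = random_tissue_mask(48, pixel_size_um=8.0, rng=rng)
    uro_lp = select_class_mask(seg, {"urothelium", "lamina propria"}).mask
    prev_area = -1
    for distance in (8.0, 24.0, 48.0, 96.0):
        border = border_region(seg, distance)
        front = invasive_front(seg, border, distance)
        assert not (border.mask & ~uro_lp).any()  # BORDER within UROLP
        assert not (front.mask & ~border.mask).any()  # FRONT within BORDER
        area = int(border.mask.sum())
        assert area >= prev_area  # dilation is monotone in the radius
        prev_area = area


def test_roi_derivation_is_deterministic():
    rng = np.random.default_rng(5)
    seg = random_tissue_mask(32, pixel_size_um=8.0, rng=rng)
    a = border_region(seg, 24.0).mask
    b = border_region(seg, 24.0).mask
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# tile grids


def test_tile_grid_full_roi_counts():
    mask = ROIMask(np.ones((1024, 1024), dtype=bool), "UROLP", 1.0)
    tiles = extract_tile_grid(mask, magnification=40, size_px=256,
                              coverage_min=0.5)
    assert len(tiles) == 16
    # row-major deterministic order
    assert tiles[0].x == 0 and tiles[0].y == 0
    assert tiles[1].x == 256 and tiles[1].y == 0


def test_tile_grid_empty_roi():
    mask = ROIMask(np.zeros((512, 512), dtype=bool), "URO", 1.0)
    assert extract_tile_grid(mask, 40, 256) == []


def test_tile_grid_coverage_threshold_boundary():
    # ROI covers exactly the left half of each tile in the second column
    m = np.zeros((256, 512), dtype=bool)
    m[:, :384] = True
    mask = ROIMask(m, "URO", 1.0)
    half_in = extract_tile_grid(mask, 40, 256, coverage_min=0.5)
    assert len(half_in) == 2
    strict = extract_tile_grid(mask, 40, 256, coverage_min=0.51)
    assert len(strict) == 1

    # brute-force pixel-count verification
    for tile in half_in:
        sub = m[tile.y:tile.y + 256, tile.x:tile.x + 256]
        assert sub.mean() >= 0.5


def test_tile_grid_level0_coordinates_at_lower_magnification():
    # mask stored at level-0 resolution; a 256-px tile at 10x spans 1024 px
    mask = ROIMask(np.ones((2048, 2048), dtype=bool), "UROLP", 0.25)
    tiles = extract_tile_grid(mask, 10, 256, coverage_min=0.5)
    assert len(tiles) == 4
    assert {(t.x, t.y) for t in tiles} == {(0, 0), (1024, 0), (0, 1024), (1024, 1024)}


def test_tile_grid_rejects_bad_magnification():
    mask = ROIMask(np.ones((64, 64), dtype=bool), "URO", 1.0)
    with pytest.raises(ConfigurationError):
        extract_tile_grid(mask, 5, 256)


# ---------------------------------------------------------------------------
# multi-scale tiles


def test_multiscale_cocentering_and_fov_ratio():
    mask = ROIMask(np.ones((8192, 8192), dtype=bool), "URO", 0.25)
    anchor = TileRecord(4000, 4000, 40, 128, "URO")
    (triplet,) = multiscale_tiles(mask, [anchor])
    assert triplet.tile_40x.center == triplet.tile_10x.center == triplet.tile_2_5x.center
    assert triplet.tile_10x.level0_extent == 4 * triplet.tile_40x.level0_extent
    assert triplet.tile_2_5x.level0_extent == 16 * triplet.tile_40x.level0_extent


def test_multiscale_drops_corner_anchor():
    mask = ROIMask(np.ones((8192, 8192), dtype=bool), "URO", 0.25)
    corner = TileRecord(0, 0, 40, 128, "URO")
    assert multiscale_tiles(mask, [corner]) == []


# ---------------------------------------------------------------------------
# I/O round trips


def test_mask_and_manifest_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    seg = random_tissue_mask(32, pixel_size_um=8.0, rng=rng)
    from PIL import Image
    import yaml

    png = tmp_path / "mask.png"
    meta = tmp_path / "mask.yaml"
    Image.fromarray(seg.labels).save(png)
    meta.write_text(yaml.safe_dump(
        {"class_map": {int(k): v for k, v in seg.class_map.items()},
         "pixel_size_um": 8.0}
    ))
    loaded = roi.load_mask(png, meta)
    np.testing.assert_array_equal(loaded.labels, seg.labels)
    assert loaded.pixel_size_um == 8.0

    tiles = [TileRecord(0, 0, 10, 256, "URO"), TileRecord(1024, 0, 10, 256, "URO")]
    manifest = tmp_path / "tiles.csv"
    roi.write_tile_manifest(tiles, manifest, slide_id="s1")
    ids, back = roi.read_tile_manifest(manifest)
    assert ids == ["s1", "s1"]
    assert back == tiles
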