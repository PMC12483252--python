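"""Domain-knowledge region-of-interest derivation from tissue-segmentation masks.

Bladder whole-slide images are segmented upstream into six tissue classes
(urothelium, lamina propria, muscle, blood, damage, background).  This module
turns those class rasters into the ROIs the prognostic pipeline consumes:

* ``URO`` / ``LP`` / ``UROLP`` — plain class selections and their union;
* ``BORDER`` — the urothelium / lamina-propria interface band, obtained by
  dilating both class masks with a Euclidean disk whose radius corresponds to
  a physical depth (800 um by default, a clinically motivated interaction
  depth) and intersecting the dilations with the tissue itself;
* ``FRONT`` — the putative invasive front: the subset of BORDER lying in a
  tissue section that contains muscle, and within the same physical depth of
  that muscle.

It also emits deterministic row-major tile grids over any ROI, at the
magnification / tile-size conventions used throughout (256 px @ 10x,
512 px @ 20x, 128 px for the tri-scale setting), with coordinates reported in
the level-0 pixel frame of the slide.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import distance_transform_edt
from skimage.measure import label as cc_label

TISSUE_CLASSES = frozenset(
    {"urothelium", "lamina propria", "muscle", "blood", "damage", "background"}
)

#: nominal objective power -> downsample factor relative to level 0 (40x)
MAGNIFICATION_DOWNSAMPLE = {40: 1, 20: 2, 10: 4, 2.5: 16}

#: clinically motivated default interaction depth (um)
DEFAULT_DEPTH_UM = 800.0

ROI_NAMES = ("URO", "LP", "UROLP", "BORDER", "FRONT", "ANNO")


class ConfigurationError(ValueError):
    """Raised for invalid class names, magnifications, or tile conventions."""


@dataclass
class SegmentationMask:
    """Tissue-class label raster with physical pixel size.

    Parameters
    ----------
    labels
        2-D integer raster of class codes.
    class_map
        Mapping from raster code to class name; must cover every code present
        and only use the six canonical class names.
    pixel_size_um
        Physical edge length of one mask pixel, in micrometres.
    """

    labels: np.ndarray
    class_map: dict[int, str]
    pixel_size_um: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        unknown = set(self.class_map.values()) - TISSUE_CLASSES
        if unknown:
            raise ConfigurationError(f"unknown tissue classes in class_map: {unknown}")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"raster codes without class_map entry: {missing}")

    def class_mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.class_map.items() if n == name]
        return np.isin(self.labels, codes)


@dataclass
class ROIMask:
    """Boolean ROI raster tied to its source mask geometry."""

    mask: np.ndarray
    roi_name: str
    pixel_size_um: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.roi_name not in ROI_NAMES:
            raise ConfigurationError(f"unknown ROI name {self.roi_name!r}")


@dataclass(frozen=True)
class TileRecord:
    """Axis-aligned tile in level-0 coordinates (0-based, half-open extent)."""

    x: int
    y: int
    magnification: float
    size_px: int
    roi_name: str

    def __post_init__(self):
        if self.size_px not in (128, 256, 512):
            raise ConfigurationError(f"unsupported tile size {self.size_px}")

    @property
    def downsample(self) -> int:
        return MAGNIFICATION_DOWNSAMPLE[self.magnification]

    @property
    def level0_extent(self) -> int:
        """Edge length of the tile footprint in level-0 pixels."""
        return self.size_px * self.downsample

    @property
    def center(self) -> tuple[float, float]:
        half = self.level0_extent / 2.0
        return (self.x + half, self.y + half)


@dataclass(frozen=True)
class MultiScaleTile:
    """Co-centered 128-px tiles at 40x, 10x and 2.5x around one anchor point."""

    tile_40x: TileRecord
    tile_10x: TileRecord
    tile_2_5x: TileRecord

    def __post_init__(self):
        centers = {t.center for t in (self.tile_40x, self.tile_10x, self.tile_2_5x)}
        if len(centers) != 1:
            raise ValueError("multi-scale tiles must share a physical center")


# ---------------------------------------------------------------------------
# operations


def select_class_mask(mask: SegmentationMask, classes: set[str]) -> ROIMask:
    """Boolean ROI selecting all pixels whose class is in ``classes``.

    Requesting ``{urothelium}`` yields URO, ``{lamina propria}`` yields LP and
    their union yields UROLP; any other combination is reported as UROLP-style
    unions under the name of the closest canonical ROI or ``ANNO``.
    """
    unknown = set(classes) - TISSUE_CLASSES
    if unknown:
        raise ConfigurationError(f"unknown tissue classes requested: {unknown}")
    out = np.zeros(mask.labels.shape, dtype=bool)
    for name in classes:
        out |= mask.class_mask(name)
    if classes == {"urothelium"}:
        roi_name = "URO"
    elif classes == {"lamina propria"}:
        roi_name = "LP"
    elif classes == {"urothelium", "lamina propria"}:
        roi_name = "UROLP"
    else:
        roi_name = "ANNO"
    return ROIMask(out, roi_name, mask.pixel_size_um)


def disk_radius_px(distance_um: float, pixel_size_um: float) -> int:
    """Disk radius in pixels for a physical distance; round-half-even."""
    if distance_um <= 0 or pixel_size_um <= 0:
        raise ValueError("distance_um and pixel_size_um must be positive")
    return round(distance_um / pixel_size_um)


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Euclidean-disk dilation via the exact distance transform.

    A pixel is in the dilation iff some true pixel lies within Euclidean
    distance ``radius`` — identical to dilating with a disk structuring
    element, but with memory use independent of the radius.
    """
    if radius <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    return distance_transform_edt(~mask) <= radius


def border_region(mask: SegmentationMask,
                  distance_um: float = DEFAULT_DEPTH_UM) -> ROIMask:
    """Urothelium / lamina-propria interface band (the BORDER ROI).

    Both class masks are dilated with a Euclidean disk of radius
    ``round(distance_um / pixel_size_um)``; BORDER is the overlap of the two
    dilations restricted to tissue actually labeled urothelium or lamina
    propria, which guarantees ``BORDER ⊆ UROLP``.
    """
    uro = mask.class_mask("urothelium")
    lp = mask.class_mask("lamina propria")
    if distance_um == 0:
        # degenerate radius: classes are pixel-exclusive, so no overlap
        return ROIMask(np.zeros_like(uro), "BORDER", mask.pixel_size_um)
    r = disk_radius_px(distance_um, mask.pixel_size_um)
    band = _dilate(uro, r) & _dilate(lp, r) & (uro | lp)
    return ROIMask(band, "BORDER", mask.pixel_size_um)


def tissue_sections(mask: SegmentationMask) -> np.ndarray:
    """Label connected tissue sections (non-background union, 8-connectivity).

    Background pixels get label 0; each disjoint piece of tissue gets a
    positive integer label.
    """
    tissue = ~mask.class_mask("background")
    return cc_label(tissue, connectivity=2)


def invasive_front(mask: SegmentationMask, border: ROIMask,
                   distance_um: float = DEFAULT_DEPTH_UM) -> ROIMask:
    """Refine BORDER to the invasive front (the FRONT ROI).

    A BORDER pixel is kept iff (i) its tissue section contains muscle and
    (ii) it lies within ``distance_um`` of muscle (same disk radius as the
    border construction).  ``FRONT ⊆ BORDER`` by construction.
    """
    if border.mask.shape != mask.labels.shape:
        raise ValueError("border mask shape does not match segmentation mask")
    muscle = mask.class_mask("muscle")
    if not muscle.any():
        return ROIMask(np.zeros_like(border.mask), "FRONT", mask.pixel_size_um)
    sections = tissue_sections(mask)
    muscle_sections = np.unique(sections[muscle])
    muscle_sections = muscle_sections[muscle_sections > 0]
    in_muscle_section = np.isin(sections, muscle_sections)
    r = disk_radius_px(distance_um, mask.pixel_size_um)
    near_muscle = _dilate(muscle, r)
    front = border.mask & in_muscle_section & near_muscle
    return ROIMask(front, "FRONT", mask.pixel_size_um)


def extract_tile_grid(roi: ROIMask, magnification: float, size_px: int,
                      coverage_min: float = 0.5,
                      level0_pixel_size_um: float | None = None) -> list[TileRecord]:
    """Non-overlapping row-major tile grid over an ROI.

    Tiles are laid out on a regular grid anchored at the slide origin; a tile
    is kept when the fraction of its footprint covered by the ROI is at least
    ``coverage_min``.  Coordinates are reported in the level-0 frame using the
    40x=1 / 20x=2 / 10x=4 / 2.5x=16 downsample convention.

    ``level0_pixel_size_um`` defaults to the ROI raster resolution, i.e. the
    mask is assumed to be stored at level 0; pass the true level-0 pixel size
    when the mask is a downsampled overview.
    """
    if magnification not in MAGNIFICATION_DOWNSAMPLE:
        raise ConfigurationError(f"unsupported magnification {magnification}")
    if not 0.0 < coverage_min <= 1.0:
        raise ConfigurationError("coverage_min must be in (0, 1]")
    if size_px not in (128, 256, 512):
        raise ConfigurationError(f"unsupported tile size {size_px}")
    if level0_pixel_size_um is None:
        level0_pixel_size_um = roi.pixel_size_um
    downsample = MAGNIFICATION_DOWNSAMPLE[magnification]
    extent_l0 = size_px * downsample  # tile edge, level-0 px
    # tile edge in mask pixels
    scale = level0_pixel_size_um / roi.pixel_size_um
    edge_mask = int(round(extent_l0 * scale))
    if edge_mask < 1:
        raise ConfigurationError("tile smaller than one mask pixel")
    h, w = roi.mask.shape
    # integral image for O(1) box sums
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(roi.mask, axis=0), axis=1)
    records: list[TileRecord] = []
    min_count = coverage_min * edge_mask * edge_mask
    for row in range(0, h - edge_mask + 1, edge_mask):
        for col in range(0, w - edge_mask + 1, edge_mask):
            count = (
                integral[row + edge_mask, col + edge_mask]
                - integral[row, col + edge_mask]
                - integral[row + edge_mask, col]
                + integral[row, col]
            )
            if count >= min_count:
                x_l0 = int(round(col / scale))
                y_l0 = int(round(row / scale))
                records.append(
                    TileRecord(x_l0, y_l0, magnification, size_px, roi.roi_name)
                )
    return records


def multiscale_tiles(roi: ROIMask, anchors: list[TileRecord],
                     slide_dims: tuple[int, int] | None = None,
                     level0_pixel_size_um: float | None = None) -> list[MultiScaleTile]:
    """Build co-centered (40x, 10x, 2.5x) 128-px triplets from 40x anchors.

    The 10x and 2.5x tiles cover 4x and 16x the physical width of the 40x
    anchor around the same center.  Anchors whose 2.5x context would leave the
    slide are dropped.  ``slide_dims`` is (width, height) in level-0 pixels;
    by default it is derived from the ROI raster.
    """
    if level0_pixel_size_um is None:
        level0_pixel_size_um = roi.pixel_size_um
    if slide_dims is None:
        scale = roi.pixel_size_um / level0_pixel_size_um
        slide_dims = (
            int(round(roi.mask.shape[1] * scale)),
            int(round(roi.mask.shape[0] * scale)),
        )
    width, height = slide_dims
    out: list[MultiScaleTile] = []
    for anchor in anchors:
        if anchor.magnification != 40 or anchor.size_px != 128:
            raise ConfigurationError("anchors must be 128-px tiles at 40x")
        cx, cy = anchor.center
        triplet = []
        ok = True
        for mag in (40, 10, 2.5):
            half = 128 * MAGNIFICATION_DOWNSAMPLE[mag] / 2.0
            x, y = cx - half, cy - half
            if x < 0 or y < 0 or cx + half > width or cy + half > height:
                ok = False
                break
            triplet.append(TileRecord(int(x), int(y), mag, 128, anchor.roi_name))
        if ok:
            out.append(MultiScaleTile(*triplet))
    return out


# ---------------------------------------------------------------------------
# I/O


def load_mask(image_path: str | Path, meta_path: str | Path) -> SegmentationMask:
    """Read an indexed PNG/TIFF class raster plus its YAML sidecar.

    The sidecar must define ``class_map`` (code -> class name) and
    ``pixel_size_um``.
    """
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        labels = np.asarray(tifffile.imread(image_path))
    else:
        labels = np.asarray(Image.open(image_path))
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    class_map = {int(k): str(v) for k, v in meta["class_map"].items()}
    return SegmentationMask(labels, class_map, float(meta["pixel_size_um"]))


def save_roi_png(roi: ROIMask, path: str | Path) -> None:
    """Write an ROI as an 8-bit boolean PNG (255 = inside)."""
    Image.fromarray((roi.mask * 255).astype(np.uint8)).save(path)


def write_tile_manifest(records: list[TileRecord], path: str | Path,
                        slide_id: str) -> None:
    """Write the CSV tile manifest consumed by the embedding stage."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "x", "y", "magnification", "size_px", "roi_name"])
        for t in records:
            writer.writerow([slide_id, t.x, t.y, t.magnification, t.size_px, t.roi_name])


def read_tile_manifest(path: str | Path) -> tuple[list[str], list[TileRecord]]:
    slide_ids, records = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            slide_ids.append(row["slide_id"])
            records.append(
                TileRecord(
                    int(row["x"]), int(row["y"]), float(row["magnification"]),
                    int(row["size_px"]), row["roi_name"],
                )
            )
    return slide_ids, records
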