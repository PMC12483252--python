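"""Derive the urothelium / lamina-propria border band and invasive front
from a tissue-segmentation mask, then tile the border.

Builds a synthetic 256x256 mask (urothelium over lamina propria over
muscle, 8 um pixels), applies the 800-um morphological border rule and
prints the ROI areas and the tile grid size.
"""

from prognomil import roi_geometry as rg
from prognomil.synthetic_data import synth_tissue_mask

mask = synth_tissue_mask("ribbon", 256, pixel_size_um=8.0)

border = rg.border_region(mask, distance_um=800.0)
front = rg.invasive_front(mask, border, distance_um=800.0)
tiles = rg.extract_tile_grid(border, magnification=40, size_px=128,
                             coverage_min=0.5)

print(f"disk radius: {rg.disk_radius_px(800.0, mask.pixel_size_um)} px")
print(f"BORDER area: {int(border.mask.sum())} px "
      f"({border.mask.mean():.1%} of the raster)")
print(f"FRONT  area: {int(front.mask.sum())} px (subset of BORDER: "
      f"{bool((front.mask <= border.mask).all())})")
print(f"tiles at 40x/128px covering >=50% border: {len(tiles)}")
# The border band hugs the urothelium/lamina-propria interface; the front is
# the part of that band lying in a muscle-bearing section within 800 um of
# muscle -- the putative invasive front a pathologist would inspect first.
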