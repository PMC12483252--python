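"""Export an attention heatmap over tile footprints.

Paints per-tile attention scores into their level-0 footprints at a chosen
downsample and writes a grayscale+alpha PNG plus a JSON sidecar with the
georeferencing (downsample + origin).
"""

import tempfile
from pathlib import Path

import numpy as np

from prognomil.roi_geometry import TileRecord
from prognomil.training_eval import attention_heatmap, save_heatmap_png

tiles = [TileRecord(x, y, 10, 256, "UROLP")
         for y in range(0, 4096, 1024) for x in range(0, 4096, 1024)]
rng = np.random.default_rng(0)
attention = rng.dirichlet(np.ones(len(tiles)))

heat = attention_heatmap(tiles, attention, slide_dims=(4096, 4096),
                         downsample=64)
out = Path(tempfile.mkdtemp()) / "heatmap.png"
save_heatmap_png(heat, out, downsample=64)

print(f"{len(tiles)} tiles painted; raster {heat.shape}, "
      f"{(~heat.mask).mean():.0%} covered")
print(f"max-attention tile: index {int(np.argmax(attention))} "
      f"(normalized to 1.0 in the overlay)")
print(f"wrote {out} (+ {out.with_suffix('.json').name})")
# Scores are min-max normalized per slide; transparent pixels lie outside
# every tile footprint, so the overlay composites cleanly onto the WSI.
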