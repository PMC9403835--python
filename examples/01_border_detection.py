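"""Detect a cytoarchitectonic border in a synthetic serial-section stack.

Renders five serial cell-body-stained sections of a flat cortical ribbon
containing two areas that differ only in their layer-IV cell density
(0.2 vs 0.6), then runs the full chain: Otsu segmentation -> GLI map ->
Laplace traverses -> depth-normalized profiles -> 10-feature vectors ->
sliding-window Mahalanobis distance (block sizes 12-30, Bonferroni-
corrected Hotelling tests at family alpha 0.001) -> multi-scale and
multi-section acceptance.
"""

import numpy as np

import cytoborder as cb
from cytoborder.synthetic import AreaSpec, LaminarSpec, flat_ribbon

PIXEL_UM = 3.0
N_TRAVERSES = 90
WIDTH_UM, THICK_UM = 2400.0, 600.0
SPACING_UM = WIDTH_UM / N_TRAVERSES
BORDER_UM = 1230.0

fractions = (0.10, 0.08, 0.32, 0.15, 0.17, 0.18)
area_a = AreaSpec("A", LaminarSpec(fractions, (0.05, 0.35, 0.25, 0.20, 0.25, 0.20), 5, 1))
area_b = AreaSpec("B", LaminarSpec(fractions, (0.05, 0.35, 0.25, 0.60, 0.25, 0.20), 5, 1))

geom = flat_ribbon(WIDTH_UM, THICK_UM, pixel_size_um=PIXEL_UM, margin_um=30)
stack = cb.make_stack(geom, [area_a, area_b], [BORDER_UM], n_sections=5,
                      border_jitter_um=50.0, seed=7)

result = cb.detect_borders_in_stack(stack, field_size_px=8, grid_res_um=9.0,
                                    n_traverses=N_TRAVERSES)

print(f"true border: {BORDER_UM:.0f} um = profile index {BORDER_UM / SPACING_UM:.1f}")
for b in result.accepted:
    um = result.sections[0].profile_index_to_um(b.position)
    print(f"accepted border at profile index {b.position:.1f} ({um:.0f} um), "
          f"supported by {len(b.block_sizes)} block sizes in sections {b.section_ids}")
# The accepted position should sit within a few profile spacings of the
# true border; a single-area stack would print no accepted border at all.
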