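"""Shared fixtures: a simulation-scale flat ribbon with precomputed
traverses, and the two-area laminar contrast used by the recovery studies.

The study geometry is deliberately scaled down from full histology
(600 um deep ribbon at 3 um/px, 8 px GLI fields, 90 traverses): the
statistics operate on profile feature vectors and are agnostic to the
absolute raster size.
"""

import numpy as np
import pytest

import cytoborder as cb
from cytoborder.synthetic import AreaSpec, LaminarSpec, flat_ribbon

PIXEL_UM = 3.0
FIELD_PX = 8
WIDTH_UM = 2400.0
THICK_UM = 600.0
N_TRAVERSES = 90
SPACING_UM = WIDTH_UM / N_TRAVERSES  # ~26.7 um between profiles

LAYER_FRACTIONS = (0.10, 0.08, 0.32, 0.15, 0.17, 0.18)


def area_with_layer4(density4: float, name: str = "area") -> AreaSpec:
    dens = (0.05, 0.35, 0.25, density4, 0.25, 0.20)
    return AreaSpec(name, LaminarSpec(LAYER_FRACTIONS, dens,
                                      cell_radius_um=5.0, cell_radius_sd_um=1.0))


AREA_LOW = area_with_layer4(0.2, "low4")
AREA_HIGH = area_with_layer4(0.6, "high4")


@pytest.fixture(scope="session")
def flat_geom():
    return flat_ribbon(WIDTH_UM, THICK_UM, pixel_size_um=PIXEL_UM, margin_um=30)


@pytest.fixture(scope="session")
def flat_traverses(flat_geom):
    # serial sections share their contours, so the potential field and the
    # traverses are computed once per geometry
    _, trav = cb.compute_traverses(flat_geom, grid_res_um=9.0, n_traverses=N_TRAVERSES)
    return trav


def run_stack(geom, traverses, areas, borders_um, n_sections, jitter_um, seed,
              **kw):
    stack = cb.make_stack(geom, areas, borders_um, n_sections,
                          border_jitter_um=jitter_um, seed=seed)
    return cb.detect_borders_in_stack(stack, traverses=traverses,
                                      field_size_px=FIELD_PX, **kw)
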