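"""End-to-end section and stack analysis.

Chains the full workflow: stained image -> cell-body segmentation -> GLI
map -> potential field and traverses -> depth-normalized profiles ->
10-feature vectors -> sliding-window Mahalanobis distance at all block
sizes -> multi-scale consensus within a section -> multi-section
confirmation.  Serial sections of one stack share their ribbon geometry,
so the potential field and traverses are computed once per stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import borders as bd
from .geometry import solve_laplace, trace_traverses
from .gli import gli_map_from_image
from .profiles import extract_profile, feature_matrix
from .synthetic import SyntheticSection

__all__ = ["SectionResult", "StackResult", "compute_traverses", "process_section",
           "detect_borders_in_stack"]


@dataclass
class SectionResult:
    """Per-section analysis products."""

    features: np.ndarray
    distance_functions: dict            # block size -> DistanceFunction
    candidates_by_block_size: dict      # block size -> maxima positions
    consensus: list                     # ConsensusCandidate list
    traverses: list
    section_id: int = -1

    def profile_index_to_um(self, index) -> float:
        """Arc-length position (um) of a (possibly fractional) profile index."""
        s = np.array([t.seed_arclength_um for t in self.traverses])
        return float(np.interp(index, np.arange(len(s)), s))


@dataclass
class StackResult:
    """Stack-level borders plus the per-section products."""

    accepted: list                      # AcceptedBorder list
    sections: list                      # SectionResult list

    def accepted_positions(self) -> np.ndarray:
        return np.array([b.position for b in self.accepted])


def compute_traverses(geometry, grid_res_um: float, n_traverses: int,
                      tol: float = 1e-5, max_iter: int = 20000):
    """Potential field plus traverses for one ribbon geometry."""
    fieldobj = solve_laplace(geometry, None, grid_res_um, tol=tol, max_iter=max_iter)
    return fieldobj, trace_traverses(fieldobj, n_traverses=n_traverses)


def process_section(section: SyntheticSection | np.ndarray, *, traverses=None,
                    geometry=None, pixel_size_um: float | None = None,
                    field_size_px: int = 16, segmentation: str = "otsu",
                    threshold: float | None = None, grid_res_um: float | None = None,
                    n_traverses: int = 100, n_points: int = 101,
                    block_sizes=range(12, 31), alpha: float = bd.DEFAULT_ALPHA,
                    min_block_sizes: int = 3, position_tol: float = 4.0,
                    max_window: int = 2) -> SectionResult:
    """Run the border-detection chain on one section image."""
    if isinstance(section, SyntheticSection):
        image = section.image
        geometry = section.geometry if geometry is None else geometry
        sec_id = section.section_id
    else:
        image = np.asarray(section)
        sec_id = -1
    if geometry is None and traverses is None:
        raise ValueError("need ribbon geometry or precomputed traverses")
    px = geometry.pixel_size_um if (pixel_size_um is None and geometry is not None) \
        else (pixel_size_um or 1.02)

    if traverses is None:
        if grid_res_um is None:
            grid_res_um = 4.0 * px
        _, traverses = compute_traverses(geometry, grid_res_um, n_traverses)

    gli = gli_map_from_image(image, pixel_size_um=px, field_size_px=field_size_px,
                             method=segmentation, threshold=threshold)
    profiles = [extract_profile(gli, t, n_points=n_points) for t in traverses]
    feats = feature_matrix(profiles)

    dfuncs = {}
    cands = {}
    for b in block_sizes:
        dfun = bd.md_function(feats, b, alpha=alpha)
        dfuncs[b] = dfun
        cands[b] = bd.detect_maxima(dfun, window=max_window)
    consensus = bd.accept_borders(cands, min_block_sizes=min_block_sizes,
                                  position_tol=position_tol, section_id=sec_id)
    return SectionResult(features=feats, distance_functions=dfuncs,
                         candidates_by_block_size=cands, consensus=consensus,
                         traverses=traverses, section_id=sec_id)


def detect_borders_in_stack(stack, *, share_traverses: bool = True,
                            min_sections: int = 3, section_tol: float = 6.0,
                            **section_kw) -> StackResult:
    """Detect borders across a stack of serial sections.

    With ``share_traverses`` (the default, valid because serial sections of
    one synthetic stack share their contours) the potential field is solved
    once and reused for every section.
    """
    stack = list(stack)
    if not stack:
        raise ValueError("empty stack")
    if share_traverses and "traverses" not in section_kw:
        geometry = stack[0].geometry
        px = geometry.pixel_size_um
        grid_res = section_kw.get("grid_res_um") or 4.0 * px
        n_trav = section_kw.get("n_traverses", 100)
        _, traverses = compute_traverses(geometry, grid_res, n_trav)
        section_kw = dict(section_kw, traverses=traverses)
    results = [process_section(sec, **section_kw) for sec in stack]
    accepted = bd.confirm_across_sections([r.consensus for r in results],
                                          min_sections=min_sections,
                                          section_tol=section_tol)
    return StackResult(accepted=accepted, sections=results)
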