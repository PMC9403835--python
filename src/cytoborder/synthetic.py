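"""Synthetic histology generator.

Produces cell-body-stained section images with known ground truth so that
every downstream stage (GLI mapping, traverses, profiles, border detection,
atlas building, volumetry) can be exercised without real post-mortem
material.  A section is a folded or flat cortical ribbon between an outer
(layer I/II) and an inner (layer VI/white matter) contour; "cell bodies"
are dark anti-aliased disks whose local coverage follows a six-layer
laminar density profile that may change abruptly at areal borders.

Disk placement uses a Boolean (Poisson germ-grain) model: germ intensity is
solved analytically from the requested coverage fraction, ``rho = 1 -
exp(-lambda * pi * E[R^2])``, so the rendered foreground fraction of a
homogeneous band converges to the specified layer density by construction.
All generators are pure functions of their parameters and an integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LaminarSpec",
    "AreaSpec",
    "RibbonGeometry",
    "SyntheticSection",
    "SyntheticCohort",
    "make_laminar_profile",
    "render_section",
    "make_stack",
    "make_cohort",
    "flat_ribbon",
    "annulus_ribbon",
    "example_area_specs",
]

_MAX_DENSITY = 0.97  # Boolean-model intensity diverges as coverage -> 1


@dataclass(frozen=True)
class LaminarSpec:
    """Six-layer laminar structure of one cortical area.

    ``layer_fractions`` are the depth fractions occupied by layers I-VI
    (must sum to 1); ``layer_density`` is the target foreground coverage
    (volume fraction of cell bodies) inside each layer, each in [0, 1].
    ``cell_radius_um`` and ``cell_radius_sd_um`` parameterize the rendered
    soma radii.
    """

    layer_fractions: tuple = (0.10, 0.08, 0.32, 0.12, 0.20, 0.18)
    layer_density: tuple = (0.05, 0.35, 0.25, 0.35, 0.25, 0.20)
    cell_radius_um: float = 5.0
    cell_radius_sd_um: float = 1.0

    def __post_init__(self):
        fr = np.asarray(self.layer_fractions, float)
        de = np.asarray(self.layer_density, float)
        if fr.shape != (6,) or de.shape != (6,):
            raise ValueError("LaminarSpec needs six layer fractions and six densities")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"layer fractions must sum to 1, got {fr.sum()!r}")
        if np.any(fr <= 0):
            raise ValueError("layer fractions must be positive")
        if np.any((de < 0) | (de > 1)):
            raise ValueError("layer densities must lie in [0, 1]")
        if self.cell_radius_um <= 0:
            raise ValueError("cell radius must be positive")

    @property
    def boundaries(self) -> np.ndarray:
        """Normalized depth of the layer lower boundaries (cumulative fractions)."""
        return np.cumsum(np.asarray(self.layer_fractions, float))


@dataclass(frozen=True)
class AreaSpec:
    """A named cortical area with its laminar structure."""

    name: str
    laminar: LaminarSpec


@dataclass(frozen=True)
class RibbonGeometry:
    """Cortical ribbon between an outer and an inner contour.

    Contours are ordered polylines in micrometres, image convention
    (origin top-left, y down).  ``pixel_size_um`` sets the rendering scale.
    """

    outer_contour: np.ndarray
    inner_contour: np.ndarray
    pixel_size_um: float = 1.02

    def __post_init__(self):
        object.__setattr__(self, "outer_contour", np.asarray(self.outer_contour, float))
        object.__setattr__(self, "inner_contour", np.asarray(self.inner_contour, float))
        for c in (self.outer_contour, self.inner_contour):
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
                raise ValueError("contours must be (n>=2, 2) point arrays")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def outer_arclength_um(self) -> float:
        seg = np.diff(self.outer_contour, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def is_closed(self) -> bool:
        return bool(
            np.allclose(self.outer_contour[0], self.outer_contour[-1])
            and np.allclose(self.inner_contour[0], self.inner_contour[-1])
        )


@dataclass
class SyntheticSection:
    """A rendered section image plus its ground truth."""

    image: np.ndarray
    geometry: RibbonGeometry
    areas: tuple
    truth_borders_um: np.ndarray
    seed: int
    section_id: int = 0

    def truth_label(self, arclength_um) -> np.ndarray:
        """Area index owning a given arc-length position on the outer contour."""
        return np.searchsorted(self.truth_borders_um, np.asarray(arclength_um, float), side="right")


@dataclass
class SyntheticCohort:
    """Multi-subject label volumes in one common voxel space."""

    labels: np.ndarray  # (n_subjects, X, Y, Z) int
    sex: tuple  # 'M' / 'F' per subject
    fresh_volume_mm3: np.ndarray
    processed_volume_mm3: np.ndarray
    voxel_size_mm: tuple
    area_ids: tuple

    @property
    def n_subjects(self) -> int:
        return self.labels.shape[0]

    @property
    def shrinkage_factors(self) -> np.ndarray:
        return self.fresh_volume_mm3 / self.processed_volume_mm3


# ---------------------------------------------------------------------------
# geometry helpers

def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def ribbon_area_um2(geometry: RibbonGeometry) -> float:
    """Enclosed ribbon area (um^2) from the contour polygons."""
    if geometry.is_closed:
        return _shoelace(geometry.outer_contour[:-1]) - _shoelace(geometry.inner_contour[:-1])
    poly = np.vstack([geometry.outer_contour, geometry.inner_contour[::-1]])
    return _shoelace(poly)


def flat_ribbon(width_um: float, thickness_um: float, pixel_size_um: float = 1.02,
                margin_um: float = 0.0) -> RibbonGeometry:
    """Flat ribbon with parallel horizontal contours (outer on top)."""
    x0, x1 = margin_um, margin_um + width_um
    outer = [(x0, margin_um), (x1, margin_um)]
    inner = [(x0, margin_um + thickness_um), (x1, margin_um + thickness_um)]
    return RibbonGeometry(outer, inner, pixel_size_um)


def annulus_ribbon(r_outer: float, r_inner: float, center=(0.0, 0.0), n_points: int = 360,
                   pixel_size_um: float = 1.02, span_deg: float = 360.0) -> RibbonGeometry:
    """Circular-arc ribbon; outer contour at ``r_outer``, inner at ``r_inner``."""
    if not r_outer > r_inner > 0:
        raise ValueError("need r_outer > r_inner > 0")
    th = np.linspace(0, np.deg2rad(span_deg), n_points)
    cx, cy = center
    outer = np.c_[cx + r_outer * np.cos(th), cy + r_outer * np.sin(th)]
    inner = np.c_[cx + r_inner * np.cos(th), cy + r_inner * np.sin(th)]
    return RibbonGeometry(outer, inner, pixel_size_um)


# ---------------------------------------------------------------------------
# laminar profile

def make_laminar_profile(spec: LaminarSpec, n_points: int, smooth_sigma: float = 0.0) -> np.ndarray:
    """Piecewise-constant laminar density over normalized depth [0, 1].

    The value inside each layer band equals that layer's density; with
    ``smooth_sigma > 0`` (in depth-fraction units) the steps are blurred by
    a Gaussian to mimic gradual laminar transitions.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    t = np.linspace(0.0, 1.0, n_points)
    curve = laminar_density_at(spec, t)
    if smooth_sigma > 0:
        dt = 1.0 / (n_points - 1)
        curve = ndimage.gaussian_filter1d(curve, smooth_sigma / dt, mode="nearest")
    return curve


def laminar_density_at(spec: LaminarSpec, t) -> np.ndarray:
    """Layer density at normalized depth(s) ``t`` in [0, 1]."""
    t = np.asarray(t, float)
    idx = np.searchsorted(spec.boundaries, t, side="right")
    idx = np.clip(idx, 0, 5)
    return np.asarray(spec.layer_density, float)[idx]


# ---------------------------------------------------------------------------
# rendering

def _polyline_arclengths(points: np.ndarray) -> np.ndarray:
    seg = np.diff(points, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def _densify(points: np.ndarray, spacing: float) -> tuple:
    """Resample a polyline at ~``spacing`` while keeping cumulative arc length."""
    s = _polyline_arclengths(points)
    n = max(int(np.ceil(s[-1] / spacing)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    x = np.interp(si, s, points[:, 0])
    y = np.interp(si, s, points[:, 1])
    return np.c_[x, y], si


def _ribbon_mask(geometry: RibbonGeometry, shape, origin_um, px: float) -> np.ndarray:
    from skimage.draw import polygon

    def to_px(pts):
        return (pts - np.asarray(origin_um)) / px

    if geometry.is_closed:
        po = to_px(geometry.outer_contour)
        pi = to_px(geometry.inner_contour)
        rr, cc = polygon(po[:, 1], po[:, 0], shape)
        mask = np.zeros(shape, bool)
        mask[rr, cc] = True
        rr, cc = polygon(pi[:, 1], pi[:, 0], shape)
        hole = np.zeros(shape, bool)
        hole[rr, cc] = True
        return mask & ~hole
    poly = np.vstack([to_px(geometry.outer_contour), to_px(geometry.inner_contour[::-1])])
    rr, cc = polygon(poly[:, 1], poly[:, 0], shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _depth_and_owner(geometry: RibbonGeometry, shape, origin_um, px):
    """Per-pixel normalized depth and outer-contour foot-point arc length."""
    dense_o, s_o = _densify(geometry.outer_contour, px / 2)
    dense_i, _ = _densify(geometry.inner_contour, px / 2)

    def raster(pts):
        ij = np.round((pts - np.asarray(origin_um)) / px).astype(int)
        ij[:, 0] = np.clip(ij[:, 0], 0, shape[1] - 1)
        ij[:, 1] = np.clip(ij[:, 1], 0, shape[0] - 1)
        return ij

    out_px = raster(dense_o)
    in_px = raster(dense_i)

    grid_outer = np.ones(shape, bool)
    grid_outer[out_px[:, 1], out_px[:, 0]] = False
    # distance to outer, with nearest outer raster pixel for ownership
    d_out, (ny, nx) = ndimage.distance_transform_edt(grid_outer, return_indices=True)

    # arc length recorded on the outer raster (last write wins on collisions)
    arc_grid = np.zeros(shape)
    arc_grid[out_px[:, 1], out_px[:, 0]] = s_o
    owner_arc = arc_grid[ny, nx]

    grid_inner = np.ones(shape, bool)
    grid_inner[in_px[:, 1], in_px[:, 0]] = False
    d_in = ndimage.distance_transform_edt(grid_inner)

    with np.errstate(invalid="ignore", divide="ignore"):
        depth = d_out / (d_out + d_in)
    depth = np.nan_to_num(depth, nan=0.5)
    return depth, owner_arc


def render_section(geometry: RibbonGeometry, areas, border_arclengths_um=(), seed: int = 0,
                   *, background_intensity: float = 0.9, cell_intensity: float = 0.1,
                   noise_sigma: float = 0.02, margin_px: int = 4,
                   section_id: int = 0) -> SyntheticSection:
    """Render a cell-body-stained section of a multi-area cortical ribbon.

    The area owning a pixel is decided by the outer-contour foot point of
    that pixel: areas occupy consecutive arc-length intervals split at
    ``border_arclengths_um``.  Local disk coverage follows the owning
    area's laminar density at the pixel's normalized cortical depth.
    """
    areas = tuple(areas)
    if len(areas) == 0:
        raise ValueError("need at least one area")
    borders = np.asarray(border_arclengths_um, float)
    if len(borders) != len(areas) - 1:
        raise ValueError("need exactly len(areas)-1 border positions")
    total_arc = RibbonGeometry(geometry.outer_contour, geometry.inner_contour,
                               geometry.pixel_size_um).outer_arclength_um
    if len(borders) and (np.any(np.diff(borders) <= 0) or borders[0] <= 0 or borders[-1] >= total_arc):
        raise ValueError("border arc lengths must be strictly increasing inside (0, outer length)")

    px = geometry.pixel_size_um
    allpts = np.vstack([geometry.outer_contour, geometry.inner_contour])
    origin = allpts.min(axis=0) - margin_px * px
    extent = allpts.max(axis=0) - origin + margin_px * px
    shape = (int(np.ceil(extent[1] / px)), int(np.ceil(extent[0] / px)))  # (rows, cols)
    if min(shape) < 2:
        raise ValueError("ribbon has zero area at this pixel size")

    if ribbon_area_um2(geometry) < px**2:
        raise ValueError("zero-area ribbon (contours enclose less than one pixel)")
    mask = _ribbon_mask(geometry, shape, origin, px)
    if not mask.any():
        raise ValueError("ribbon encloses no pixels (zero-area ribbon)")
    depth, owner_arc = _depth_and_owner(geometry, shape, origin, px)

    # per-pixel target coverage
    area_of_pixel = np.searchsorted(borders, owner_arc, side="right")
    rho = np.zeros(shape)
    for ai, area in enumerate(areas):
        sel = mask & (area_of_pixel == ai)
        if sel.any():
            rho[sel] = laminar_density_at(area.laminar, depth[sel])
    rho = np.clip(rho, 0.0, _MAX_DENSITY)

    rng = np.random.default_rng(seed)
    r_mean_px = areas[0].laminar.cell_radius_um / px
    r_sd_px = areas[0].laminar.cell_radius_sd_um / px
    er2 = r_mean_px**2 + r_sd_px**2

    lam = -np.log1p(-rho) / (np.pi * er2)  # germs per px^2
    lam_max = float(lam[mask].max(initial=0.0))
    canvas = np.zeros(shape)
    if lam_max > 0:
        ys, xs = np.nonzero(mask)
        n_cand = rng.poisson(lam_max * len(ys))
        if n_cand > 0:
            pick = rng.integers(0, len(ys), n_cand)
            cy = ys[pick] + rng.random(n_cand) - 0.5
            cx = xs[pick] + rng.random(n_cand) - 0.5
            keep = rng.random(n_cand) < lam[ys[pick], xs[pick]] / lam_max
            cy, cx = cy[keep], cx[keep]
            radii = np.clip(rng.normal(r_mean_px, r_sd_px, len(cy)), 0.3 * r_mean_px, None)
            canvas = _stamp_disks(shape, cy, cx, radii)

    image = background_intensity - canvas * (background_intensity - cell_intensity)
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return SyntheticSection(image=image, geometry=geometry, areas=areas,
                            truth_borders_um=borders, seed=seed, section_id=section_id)


def _stamp_disks(shape, cy, cx, radii) -> np.ndarray:
    """Anti-aliased disk coverage in [0, 1] via a vectorized scatter-max."""
    canvas = np.zeros((shape[0] + 2, shape[1] + 2))  # 1-px guard ring
    if len(cy) == 0:
        return canvas[1:-1, 1:-1]
    P = int(np.ceil(2 * radii.max())) + 3
    off = np.arange(P) - P // 2
    oy, ox = np.meshgrid(off, off, indexing="ij")
    iy = np.round(cy).astype(int)
    ix = np.round(cx).astype(int)
    fy = (cy - iy)[:, None, None]
    fx = (cx - ix)[:, None, None]
    dist = np.sqrt((oy[None] - fy) ** 2 + (ox[None] - fx) ** 2)
    alpha = np.clip(radii[:, None, None] + 0.5 - dist, 0.0, 1.0)
    rows = np.clip(iy[:, None, None] + oy[None] + 1, 0, shape[0] + 1)
    cols = np.clip(ix[:, None, None] + ox[None] + 1, 0, shape[1] + 1)
    flat = rows * (shape[1] + 2) + cols
    np.maximum.at(canvas.ravel(), flat.ravel(), alpha.ravel())
    return canvas[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# stacks and cohorts

def make_stack(geometry: RibbonGeometry, areas, border_arclengths_um, n_sections: int,
               border_jitter_um: float = 0.0, seed: int = 0, **render_kw) -> list:
    """Serial sections sharing geometry, with near-constant border positions.

    Each section's true border positions are the base positions plus an
    independent uniform jitter within +/- ``border_jitter_um``.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    base = np.asarray(border_arclengths_um, float)
    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    section_seeds = ss.generate_state(n_sections)
    sections = []
    for i in range(n_sections):
        jitter = jitter_rng.uniform(-border_jitter_um, border_jitter_um, base.shape)
        sections.append(render_section(geometry, areas, base + jitter,
                                       seed=int(section_seeds[i] % (2**31)),
                                       section_id=i, **render_kw))
    return sections


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / max(r, 1e-6)) ** 2
    return acc <= 1.0


def make_cohort(n_subjects: int = 10, area_shape_variability: float = 1.0,
                sex_assignment: str = "alternate", seed: int = 0, *,
                shape=(40, 28, 28), voxel_size_mm=(1.0, 1.0, 1.0), n_areas: int = 4,
                shrinkage_range=(1.5, 2.5), fresh_volume_mean_mm3: float = 1_250_000.0,
                fresh_volume_sd_mm3: float = 120_000.0) -> SyntheticCohort:
    """Per-subject 3D label volumes in a common voxel grid plus metadata.

    Each area is an ellipsoidal blob perturbed around a template; blobs are
    painted in area-id order (later areas overwrite earlier on overlap), so
    labels are always from the declared id set.  Fresh/processed volume
    pairs carry shrinkage factors uniform in ``shrinkage_range``; the
    default cohort mirrors a 10-brain, 5 male / 5 female design.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    area_ids = tuple(range(1, n_areas + 1))

    # template: blob centers along the long axis of the grid
    span = shape[0] - 12
    centers0 = [(6 + span * (k + 0.5) / n_areas, shape[1] / 2, shape[2] / 2)
                for k in range(n_areas)]
    radii0 = [(0.45 * span / n_areas + 1.5, shape[1] / 4.5, shape[2] / 4.5)] * n_areas

    if sex_assignment == "alternate":
        sex = tuple("M" if i % 2 == 0 else "F" for i in range(n_subjects))
    elif sex_assignment in ("M", "F"):
        sex = tuple(sex_assignment) * n_subjects
    else:
        sex = tuple(sex_assignment)

    labels = np.zeros((n_subjects,) + tuple(shape), np.int16)
    v = area_shape_variability
    for s in range(n_subjects):
        for aid, c0, r0 in zip(area_ids, centers0, radii0):
            c = np.asarray(c0) + rng.normal(0.0, v, 3)
            r = np.asarray(r0) * np.exp(rng.normal(0.0, 0.05 * v, 3))
            labels[s][_ellipsoid_mask(shape, c, r)] = aid

    fresh = rng.normal(fresh_volume_mean_mm3, fresh_volume_sd_mm3, n_subjects)
    fresh = np.clip(fresh, 0.5 * fresh_volume_mean_mm3, None)
    factors = rng.uniform(*shrinkage_range, n_subjects)
    processed = fresh / factors

    return SyntheticCohort(labels=labels, sex=sex, fresh_volume_mm3=fresh,
                           processed_volume_mm3=processed,
                           voxel_size_mm=tuple(voxel_size_mm), area_ids=area_ids)


# ---------------------------------------------------------------------------
# ready-made area fixtures

def example_area_specs(cell_radius_um: float = 5.0, cell_radius_sd_um: float = 1.0) -> tuple:
    """Four areas loosely emulating qualitative laminar contrasts of the
    anterior DLPFC areas (dense vs. blurry layer IV, prominent layer VI,
    homogeneous columns); not claimed to be quantitatively faithful."""
    fr = (0.10, 0.08, 0.32, 0.12, 0.20, 0.18)

    def spec(dens):
        return LaminarSpec(fr, dens, cell_radius_um, cell_radius_sd_um)

    return (
        AreaSpec("SFS1", spec((0.05, 0.40, 0.28, 0.55, 0.25, 0.20))),  # dense layer IV
        AreaSpec("SFS2", spec((0.05, 0.30, 0.30, 0.20, 0.28, 0.35))),  # blurry IV, rich VI
        AreaSpec("MFG1", spec((0.05, 0.28, 0.22, 0.35, 0.30, 0.38))),  # big infragranular
        AreaSpec("MFG2", spec((0.05, 0.38, 0.30, 0.50, 0.22, 0.22))),  # homogeneous, dense IV
    )
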