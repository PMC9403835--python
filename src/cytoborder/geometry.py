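"""Cortical ribbon geometry: potential field and curvilinear traverses.

Profiles must be sampled perpendicular to the cortical layers.  Following
the electric-field-line model, a Laplace equation is solved on the ribbon
between the outer contour (Dirichlet value 0, layer I/II boundary) and the
inner contour (value 1, layer VI/white-matter boundary); the lateral open
ends of a mapped region get reflecting (zero-flux) boundaries.  Traverses
are streamlines of the normalized potential gradient, seeded at equal arc
length along the outer contour and integrated with a fixed-step midpoint
scheme until the potential reaches ~1.

All coordinates are micrometres, image convention (origin top-left, y
down); the potential grid has its own resolution ``grid_res_um``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import RibbonGeometry, _densify, _polyline_arclengths

__all__ = ["PotentialField", "Traverse", "solve_laplace", "trace_traverses"]


@dataclass
class PotentialField:
    """Discrete Laplace solution phi on the ribbon, 0 at outer, 1 at inner."""

    phi: np.ndarray
    mask: np.ndarray          # ribbon interior incl. contour cells
    origin_um: np.ndarray     # world coords (x, y) of grid cell (0, 0) centre
    grid_res_um: float
    residual: float
    converged: bool
    n_iter: int
    geometry: RibbonGeometry | None = None

    def world_to_grid(self, xy_um) -> np.ndarray:
        xy = np.asarray(xy_um, float)
        return (xy - self.origin_um) / self.grid_res_um  # (col, row) fractional

    def grid_to_world(self, colrow) -> np.ndarray:
        return np.asarray(colrow, float) * self.grid_res_um + self.origin_um


@dataclass
class Traverse:
    """Streamline from the outer to the inner contour."""

    points: np.ndarray        # (m, 2) um, outer -> inner
    index: int                # gap-free rank along the outer contour
    seed_arclength_um: float  # seed position on the outer contour
    ok: bool = True

    @property
    def length_um(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _raster_cells(points_um, origin, res, shape):
    ij = np.round((points_um - origin) / res).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, shape[1] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, shape[0] - 1)
    return ij[:, 1], ij[:, 0]  # rows, cols


def _contours_intersect(outer: np.ndarray, inner: np.ndarray) -> bool:
    try:
        from shapely.geometry import LineString

        return LineString(outer).intersects(LineString(inner))
    except Exception:  # pragma: no cover - shapely is installed in practice
        return False


def solve_laplace(outer, inner, grid_res_um: float, tol: float = 1e-5,
                  max_iter: int = 20000, omega: float = 1.9,
                  pixel_size_um: float = 1.02) -> PotentialField:
    """Solve the Laplace equation between the two contours by SOR.

    Dirichlet values 0/1 on the rasterized outer/inner contours, zero-flux
    on the remaining ribbon boundary.  Red-black successive over-relaxation
    runs until the largest update between sweeps drops below ``tol`` (or
    ``max_iter`` is reached, in which case ``converged`` is False).
    """
    geometry = outer if isinstance(outer, RibbonGeometry) else RibbonGeometry(
        outer, inner, pixel_size_um)
    if grid_res_um <= 0:
        raise ValueError("grid_res_um must be positive")
    if _contours_intersect(geometry.outer_contour, geometry.inner_contour):
        raise ValueError("outer and inner contours intersect")

    from .synthetic import _ribbon_mask

    res = grid_res_um
    allpts = np.vstack([geometry.outer_contour, geometry.inner_contour])
    origin = allpts.min(axis=0) - 2 * res
    extent = allpts.max(axis=0) - origin + 2 * res
    shape = (int(np.ceil(extent[1] / res)) + 1, int(np.ceil(extent[0] / res)) + 1)

    mask = _ribbon_mask(geometry, shape, origin, res)
    dense_o, _ = _densify(geometry.outer_contour, res / 2)
    dense_i, _ = _densify(geometry.inner_contour, res / 2)
    r_o, c_o = _raster_cells(dense_o, origin, res, shape)
    r_i, c_i = _raster_cells(dense_i, origin, res, shape)
    mask[r_o, c_o] = True
    mask[r_i, c_i] = True

    phi = np.zeros(shape)
    fixed = np.zeros(shape, bool)
    phi[r_i, c_i] = 1.0
    fixed[r_i, c_i] = True
    phi[r_o, c_o] = 0.0
    fixed[r_o, c_o] = True

    free = mask & ~fixed
    if not free.any():
        raise ValueError("contours enclose no ribbon interior at this resolution")

    # neighbour bookkeeping on the padded grid: Neumann (reflecting) walls are
    # realised by averaging over in-mask neighbours only
    pad = np.pad(mask, 1)
    phiP = np.pad(phi, 1)
    nb = [(0, 1), (2, 1), (1, 0), (1, 2)]  # up, down, left, right offsets
    nmask = [pad[dy:dy + shape[0], dx:dx + shape[1]] for dy, dx in nb]
    counts = np.sum(nmask, axis=0).astype(float)
    counts[counts == 0] = 1.0

    rows, cols = np.indices(shape)
    red = ((rows + cols) % 2 == 0)
    upd_sets = [free & red, free & ~red]

    residual = np.inf
    it = 0
    inner_view = phiP[1:-1, 1:-1]
    for it in range(1, max_iter + 1):
        residual = 0.0
        for sel in upd_sets:
            ssum = np.zeros(shape)
            for (dy, dx), m in zip(nb, nmask):
                ssum += phiP[dy:dy + shape[0], dx:dx + shape[1]] * m
            new = ssum / counts
            delta = omega * (new - inner_view)
            residual = max(residual, float(np.abs(delta[sel]).max(initial=0.0)))
            inner_view[sel] += delta[sel]
        if residual <= tol:
            break
    phi = inner_view.copy()
    phi[free] = np.clip(phi[free], 0.0, 1.0)
    phi[~mask] = 0.0

    return PotentialField(phi=phi, mask=mask, origin_um=np.asarray(origin, float),
                          grid_res_um=res, residual=residual,
                          converged=residual <= tol, n_iter=it, geometry=geometry)


def _fill_nearest(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace out-of-mask cells by their nearest in-mask value (for smooth
    interpolation near the ribbon boundary)."""
    if mask.all():
        return values
    _, (iy, ix) = ndimage.distance_transform_edt(~mask, return_indices=True)
    return values[iy, ix]


def _bilinear(grid: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    h, w = grid.shape
    r = np.clip(row, 0.0, h - 1.001)
    c = np.clip(col, 0.0, w - 1.001)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    return ((1 - fr) * (1 - fc) * grid[r0, c0] + (1 - fr) * fc * grid[r0, c0 + 1]
            + fr * (1 - fc) * grid[r0 + 1, c0] + fr * fc * grid[r0 + 1, c0 + 1])


def trace_traverses(fieldobj: PotentialField, n_traverses: int | None = None,
                    seed_spacing_um: float | None = None, eps: float = 1e-3,
                    step_um: float | None = None, max_steps: int | None = None) -> list:
    """Trace traverses from the outer contour down the potential gradient.

    Seeds sit at equal arc-length spacing on the outer contour (cell-centred,
    so end points are avoided); each streamline integrates the normalized
    gradient of phi with a fixed-step midpoint scheme (step = grid_res / 2)
    and terminates at phi >= 1 - ``eps``.  Streamlines whose gradient
    vanishes or that leave the ribbon before arriving are flagged, excluded
    and re-indexed gap-free; a warning reports the exclusions.
    """
    if fieldobj.geometry is None:
        raise ValueError("potential field carries no geometry")
    if not fieldobj.converged:
        warnings.warn("tracing on a non-converged potential field", stacklevel=2)

    outer = fieldobj.geometry.outer_contour
    s = _polyline_arclengths(outer)
    total = s[-1]
    if n_traverses is None and seed_spacing_um is None:
        raise ValueError("give n_traverses or seed_spacing_um")
    if n_traverses is None:
        n_traverses = max(int(np.floor(total / seed_spacing_um)), 1)
    seeds_s = (np.arange(n_traverses) + 0.5) * total / n_traverses
    seed_x = np.interp(seeds_s, s, outer[:, 0])
    seed_y = np.interp(seeds_s, s, outer[:, 1])

    res = fieldobj.grid_res_um
    step = res / 2 if step_um is None else step_um
    phi = _fill_nearest(fieldobj.phi, fieldobj.mask)
    gy, gx = np.gradient(phi, res)

    h, w = phi.shape
    diag = np.hypot(h, w) * res
    if max_steps is None:
        max_steps = int(np.ceil(3 * diag / step))

    pos = np.c_[seed_x, seed_y]
    paths = [[p.copy()] for p in pos]
    active = np.ones(n_traverses, bool)
    ok = np.zeros(n_traverses, bool)

    def grad_at(p):
        g = fieldobj.world_to_grid(p)
        col, row = g[:, 0], g[:, 1]
        return np.c_[_bilinear(gx, row, col), _bilinear(gy, row, col)]

    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        p = pos[idx]
        g1 = grad_at(p)
        n1 = np.hypot(g1[:, 0], g1[:, 1])
        dead = n1 < 1e-12
        g1n = g1 / np.where(n1[:, None] < 1e-12, 1.0, n1[:, None])
        pm = p + 0.5 * step * g1n
        g2 = grad_at(pm)
        n2 = np.hypot(g2[:, 0], g2[:, 1])
        dead |= n2 < 1e-12
        g2n = g2 / np.where(n2[:, None] < 1e-12, 1.0, n2[:, None])
        pnew = p + step * g2n

        gcoord = fieldobj.world_to_grid(pnew)
        out = ((gcoord[:, 0] < 0) | (gcoord[:, 0] > w - 1)
               | (gcoord[:, 1] < 0) | (gcoord[:, 1] > h - 1))
        phival = _bilinear(phi, gcoord[:, 1], gcoord[:, 0])
        arrived = phival >= 1.0 - eps

        for j, i in enumerate(idx):
            if dead[j] or out[j]:
                active[i] = False
                continue
            paths[i].append(pnew[j].copy())
            if arrived[j]:
                ok[i] = True
                active[i] = False
        pos[idx[~(dead | out)]] = pnew[~(dead | out)]

    n_fail = int(n_traverses - ok.sum())
    if n_fail:
        warnings.warn(f"{n_fail} traverse(s) failed to reach the inner contour "
                      "and were excluded", stacklevel=2)
    traverses = []
    rank = 0
    for i in range(n_traverses):
        if not ok[i]:
            continue
        traverses.append(Traverse(points=np.asarray(paths[i]), index=rank,
                                  seed_arclength_um=float(seeds_s[i]), ok=True))
        rank += 1
    return traverses
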