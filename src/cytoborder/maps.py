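"""Probabilistic atlas maps.

Per-area probability maps give, at every voxel of a common reference grid,
the fraction of subjects whose area covers that voxel; the maximum
probability map (MPM) is the winner-take-all parcellation derived from
them.  Centres of gravity are probability-weighted mean voxel-centre
coordinates.  Voxel convention: 0-based indices, world mm = (index + 0.5)
* voxel_size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbabilityMap",
    "MPMVolume",
    "CenterOfGravity",
    "probability_map",
    "maximum_probability_map",
    "center_of_gravity",
]


@dataclass
class ProbabilityMap:
    """Voxelwise subject-overlap fraction for one area."""

    area_id: int
    values: np.ndarray        # 3D fractions, multiples of 1/n_subjects
    n_subjects: int
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)


@dataclass
class MPMVolume:
    """Winner-take-all parcellation (0 = unassigned) with provenance."""

    voxels: np.ndarray            # 3D int labels
    winning_probability: np.ndarray
    area_ids: tuple
    n_tie_voxels: int
    n_ties_broken_by_id: int
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)


@dataclass
class CenterOfGravity:
    area_id: int
    x_mm: float
    y_mm: float
    z_mm: float

    @property
    def coords_mm(self):
        return np.array([self.x_mm, self.y_mm, self.z_mm])


def _as_label_stack(volumes) -> np.ndarray:
    if isinstance(volumes, np.ndarray) and volumes.ndim == 4:
        return volumes
    vols = [np.asarray(getattr(v, "voxels", v)) for v in volumes]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"label volumes have mismatching shapes: {sorted(shapes)}")
    return np.stack(vols)


def probability_map(volumes, area_id: int, voxel_size_mm=(1.0, 1.0, 1.0)) -> ProbabilityMap:
    """Fraction of subjects labelling each voxel with ``area_id``."""
    stack = _as_label_stack(volumes)
    n = stack.shape[0]
    values = (stack == area_id).sum(axis=0) / n
    return ProbabilityMap(area_id=int(area_id), values=values, n_subjects=n,
                          voxel_size_mm=tuple(voxel_size_mm))


def _neighborhood_mean(values: np.ndarray, idx: tuple) -> float:
    """Mean probability over the 26-neighbourhood of one voxel."""
    sl = tuple(slice(max(i - 1, 0), min(i + 2, s)) for i, s in zip(idx, values.shape))
    block = values[sl]
    total = block.sum() - values[idx]
    return float(total / 26.0)


def maximum_probability_map(pmaps, min_prob_threshold: float = 0.0) -> MPMVolume:
    """Assign each voxel to the area with the highest probability.

    Only probabilities strictly above ``min_prob_threshold`` compete;
    all-zero voxels stay unassigned (0).  Ties are broken first by the
    higher mean probability in the voxel's 26-neighbourhood, then by the
    lower area id; tie events are counted in the result.
    """
    pmaps = list(pmaps)
    if not pmaps:
        raise ValueError("no probability maps given")
    shapes = {p.values.shape for p in pmaps}
    if len(shapes) != 1:
        raise ValueError("probability maps are not aligned")
    area_ids = [p.area_id for p in pmaps]
    order = np.argsort(area_ids)  # ensures 'lower id' fallback is well-defined
    pmaps = [pmaps[i] for i in order]
    area_ids = [pmaps[i].area_id for i in range(len(pmaps))]

    probs = np.stack([p.values for p in pmaps])  # (A, X, Y, Z)
    eligible = probs > min_prob_threshold
    masked = np.where(eligible, probs, -1.0)
    best = masked.max(axis=0)
    assigned = best > -1.0

    labels = np.zeros(probs.shape[1:], np.int16)
    winning = np.zeros(probs.shape[1:])
    n_top = (np.abs(masked - best) < 1e-12).sum(axis=0)
    ties = assigned & (n_top > 1)
    clear = assigned & ~ties

    argbest = masked.argmax(axis=0)
    ids_arr = np.asarray(area_ids, np.int16)
    labels[clear] = ids_arr[argbest[clear]]
    winning[assigned] = best[assigned]

    n_by_id = 0
    tie_idx = np.argwhere(ties)
    for idx in map(tuple, tie_idx):
        contenders = [a for a in range(len(pmaps))
                      if eligible[a][idx] and abs(probs[a][idx] - best[idx]) < 1e-12]
        nmeans = [_neighborhood_mean(probs[a], idx) for a in contenders]
        top = max(nmeans)
        finalists = [a for a, m in zip(contenders, nmeans) if abs(m - top) < 1e-12]
        if len(finalists) > 1:
            n_by_id += 1
        labels[idx] = ids_arr[min(finalists)]  # pmaps sorted by id
    return MPMVolume(voxels=labels, winning_probability=winning,
                     area_ids=tuple(area_ids), n_tie_voxels=int(ties.sum()),
                     n_ties_broken_by_id=n_by_id,
                     voxel_size_mm=pmaps[0].voxel_size_mm)


def center_of_gravity(volume, voxel_size_mm=None, area_id: int | None = None) -> CenterOfGravity:
    """Probability- (or mask-) weighted mean voxel-centre position in mm."""
    if isinstance(volume, ProbabilityMap):
        weights = volume.values
        vs = volume.voxel_size_mm if voxel_size_mm is None else voxel_size_mm
        aid = volume.area_id if area_id is None else area_id
    else:
        arr = np.asarray(volume)
        weights = (arr == area_id).astype(float) if area_id is not None else arr.astype(float)
        vs = (1.0, 1.0, 1.0) if voxel_size_mm is None else voxel_size_mm
        aid = -1 if area_id is None else area_id
    tot = weights.sum()
    if tot <= 0:
        raise ValueError("empty support: centre of gravity undefined")
    idx = np.indices(weights.shape)
    cog = [(float((g * weights).sum() / tot) + 0.5) * s for g, s in zip(idx, vs)]
    return CenterOfGravity(area_id=int(aid), x_mm=cog[0], y_mm=cog[1], z_mm=cog[2])
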