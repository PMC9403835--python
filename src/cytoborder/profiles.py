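"""GLI profiles and their 10-feature shape parameterization.

A GLI profile is the sequence of GLI values sampled along one traverse,
rescaled to 0-100 % cortical depth (n_points equidistant samples, default
101).  Its shape is summarized by ten features: treating the profile y(x)
as a weight distribution over depth x, the mean amplitude, centre-of-
gravity depth, weighted standard deviation, skewness and kurtosis are
computed for the profile itself and for the absolute first derivative
(central differences, one-sided at the ends).  These feature vectors are
the unit of statistical comparison for border detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Traverse, _bilinear
from .gli import GLIMap

__all__ = [
    "GLIProfile",
    "ProfileBlock",
    "FEATURE_NAMES",
    "extract_profile",
    "profile_features",
    "feature_matrix",
    "build_blocks",
    "block_positions",
    "mean_profile",
]

FEATURE_NAMES = (
    "mean", "cog", "sd", "skew", "kurt",
    "d_mean", "d_cog", "d_sd", "d_skew", "d_kurt",
)

BLOCK_SIZE_MIN = 12
BLOCK_SIZE_MAX = 30


@dataclass
class GLIProfile:
    """Depth-normalized laminar GLI curve along one traverse."""

    values: np.ndarray        # (n_points,) fractions in [0, 1]
    depths: np.ndarray        # 0 .. 100 (% cortical depth)
    traverse_index: int = -1
    section_id: int = -1

    @property
    def n_points(self) -> int:
        return len(self.values)


@dataclass
class ProfileBlock:
    """A contiguous block of profiles pooled for one side of a comparison."""

    start: int                # first member profile index (inclusive)
    features: np.ndarray      # (b, 10) feature matrix

    @property
    def size(self) -> int:
        return self.features.shape[0]

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.size)


def extract_profile(gli: GLIMap, traverse: Traverse, n_points: int = 101) -> GLIProfile:
    """Sample the GLI map along a traverse at equal arc-length spacing.

    Bilinear interpolation on the GLI grid; the depth axis is rescaled to
    0-100 %.  Raises if the traverse leaves the GLI map's image footprint.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    pts = traverse.points
    seg = np.diff(pts, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if s[-1] <= 0:
        raise ValueError(f"traverse {traverse.index} has zero length")
    si = np.linspace(0.0, s[-1], n_points)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])

    h, w = gli.values.shape
    f_um = gli.field_size_um
    # image footprint covered by complete fields
    if (x.min() < -0.5 * f_um or y.min() < -0.5 * f_um
            or x.max() > (w + 0.5) * f_um or y.max() > (h + 0.5) * f_um):
        raise ValueError(f"traverse {traverse.index} exits the GLI map footprint")
    rc = gli.cell_coords_from_um(np.c_[x, y])
    vals = _bilinear(gli.values, rc[:, 0], rc[:, 1])
    return GLIProfile(values=vals, depths=np.linspace(0.0, 100.0, n_points),
                      traverse_index=traverse.index)


def _weighted_moments(x: np.ndarray, wgt: np.ndarray, mid: float):
    """(mean amplitude, cog, sd, skew, kurt) of weights over x.

    ``mid`` is the centre-of-gravity convention when all weights vanish
    (only reached by the derivative features of a constant profile).
    """
    n = len(wgt)
    amp = float(wgt.sum() / n)
    tot = float(wgt.sum())
    if tot <= 0:
        return amp, mid, 0.0, 0.0, 0.0
    c = float((x * wgt).sum() / tot)
    var = float((((x - c) ** 2) * wgt).sum() / tot)
    if var <= 0:
        return amp, c, 0.0, 0.0, 0.0
    s = float(np.sqrt(var))
    g1 = float((((x - c) ** 3) * wgt).sum() / (tot * s**3))
    g2 = float((((x - c) ** 4) * wgt).sum() / (tot * s**4))
    return amp, c, s, g1, g2


def profile_features(profile: GLIProfile | np.ndarray, depths: np.ndarray | None = None,
                     derivative: str = "absolute") -> np.ndarray:
    """Ten-feature shape vector of a GLI profile.

    The profile is treated as a frequency distribution over cortical depth;
    the same five moments are computed on the absolute first derivative
    (``derivative='signed'`` keeps the sign, exposed for comparison).
    """
    if isinstance(profile, GLIProfile):
        y = np.asarray(profile.values, float)
        x = np.asarray(profile.depths, float)
    else:
        y = np.asarray(profile, float)
        x = np.linspace(0.0, 100.0, len(y)) if depths is None else np.asarray(depths, float)
    if len(y) < 5:
        raise ValueError("profile needs at least 5 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("profile contains non-finite values")
    if np.any(y < 0):
        raise ValueError("GLI profile values must be non-negative")
    if y.sum() == 0:
        raise ValueError("all-zero profile: centre of gravity undefined")

    if derivative not in ("absolute", "signed"):
        raise ValueError("derivative must be 'absolute' or 'signed'")
    dy = np.gradient(y, x)
    if derivative == "absolute":
        dy = np.abs(dy)

    mid = 0.5 * (x[0] + x[-1])
    feats = _weighted_moments(x, y, mid) + _weighted_moments(x, dy, mid)
    return np.asarray(feats, float)


def feature_matrix(profiles, derivative: str = "absolute") -> np.ndarray:
    """(n_profiles, 10) feature matrix for an ordered profile sequence."""
    return np.vstack([profile_features(p, derivative=derivative) for p in profiles])


def block_positions(n_profiles: int, b: int) -> np.ndarray:
    """Valid sliding border positions k: blocks [k-b, k) and [k, k+b)."""
    if n_profiles < 2 * b:
        raise ValueError(f"need at least {2 * b} profiles for block size {b}, "
                         f"got {n_profiles}")
    return np.arange(b, n_profiles - b + 1)


def build_blocks(features: np.ndarray, b: int, strict_range: bool = True) -> list:
    """Adjacent block pairs for every valid border position.

    Returns a list of ``(k, ProfileBlock [k-b, k), ProfileBlock [k, k+b))``.
    In standard runs the block size must lie in [12, 30].
    """
    features = np.atleast_2d(np.asarray(features, float))
    if strict_range and not (BLOCK_SIZE_MIN <= b <= BLOCK_SIZE_MAX):
        raise ValueError(f"block size {b} outside the standard range "
                         f"[{BLOCK_SIZE_MIN}, {BLOCK_SIZE_MAX}]; "
                         "pass strict_range=False to override")
    out = []
    for k in block_positions(features.shape[0], b):
        out.append((int(k),
                    ProfileBlock(start=int(k - b), features=features[k - b:k]),
                    ProfileBlock(start=int(k), features=features[k:k + b])))
    return out


def mean_profile(profiles) -> GLIProfile:
    """Pointwise arithmetic mean of same-length profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("mean_profile of an empty profile set")
    n = profiles[0].n_points
    if any(p.n_points != n for p in profiles):
        raise ValueError("profiles have differing n_points")
    vals = np.mean([p.values for p in profiles], axis=0)
    return GLIProfile(values=vals, depths=profiles[0].depths.copy())
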