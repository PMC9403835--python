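"""Volumetry and group statistics.

Areal volumes are estimated from serial-section cross-sectional areas by
the Cavalieri method (sum of areas times section spacing, default 1.2 mm),
corrected for histological shrinkage by the ratio of fresh to processed
whole-brain volume, and normalized to individual whole-brain volume for
group comparison.  Group aggregates reproduce the per-sex / per-hemisphere
/ per-area summary surface of the printed volume table; hypothesis tests
use a split-plot (mixed repeated-measures) ANOVA with area and hemisphere
as within-subject factors and sex as the between-subject factor.

The per-brain volume table and the cohort metadata table are packaged as
CSV fixtures (``load_table4`` / ``load_table1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ShrinkageFactor",
    "VolumeAggregates",
    "shrinkage_factor",
    "cavalieri_volume",
    "normalize_volume",
    "aggregate_table",
    "mixed_anova",
    "compare_gli",
    "round_half_away",
    "load_table1",
    "load_table4",
]


@dataclass(frozen=True)
class ShrinkageFactor:
    """Fresh-to-processed whole-brain volume ratio of one brain."""

    fresh_volume_mm3: float
    processed_volume_mm3: float
    brain_id: str = ""

    @property
    def factor(self) -> float:
        return self.fresh_volume_mm3 / self.processed_volume_mm3

    def __float__(self) -> float:
        return self.factor


def shrinkage_factor(fresh_volume_mm3: float, processed_volume_mm3: float,
                     brain_id: str = "") -> ShrinkageFactor:
    """Shrinkage correction factor = fresh volume / processed volume."""
    if fresh_volume_mm3 <= 0 or processed_volume_mm3 <= 0:
        raise ValueError("volumes must be positive")
    return ShrinkageFactor(float(fresh_volume_mm3), float(processed_volume_mm3), brain_id)


def cavalieri_volume(cross_section_areas_mm2, section_spacing_mm=1.2,
                     shrinkage: float | ShrinkageFactor = 1.0) -> float:
    """Cavalieri volume estimate, shrinkage-corrected.

    ``volume = factor * sum_i(area_i * spacing_i)``; ``section_spacing_mm``
    is a scalar for equidistant sections or a per-section sequence of
    explicit distances (required when spacing is mixed).
    """
    areas = np.asarray(cross_section_areas_mm2, float)
    if areas.size < 1:
        raise ValueError("need at least one cross-sectional area")
    if np.any(areas < 0):
        raise ValueError("cross-sectional areas must be non-negative")
    spacing = np.asarray(section_spacing_mm, float)
    if spacing.ndim == 0:
        spacing = np.full(areas.shape, float(spacing))
    elif spacing.shape != areas.shape:
        raise ValueError("mixed spacing requires one explicit distance per section")
    if np.any(spacing <= 0):
        raise ValueError("section spacing must be positive")
    return float(float(shrinkage) * (areas * spacing).sum())


def normalize_volume(volume_mm3: float, whole_brain_volume_mm3: float) -> float:
    """Area volume as a fraction of the whole-brain volume."""
    if whole_brain_volume_mm3 <= 0:
        raise ValueError("whole-brain volume must be positive")
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    return float(volume_mm3 / whole_brain_volume_mm3)


def round_half_away(x):
    """Round half away from zero (the convention of the printed tables)."""
    x = np.asarray(x, float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


# ---------------------------------------------------------------------------
# aggregates

@dataclass
class VolumeAggregates:
    """Group summary of a per-brain volume table.

    All statistics are unrounded; apply :func:`round_half_away` for
    comparison with printed integers.  Standard deviations are sample SDs
    (n - 1).
    """

    by_cell: pd.DataFrame            # (sex, hemisphere, area) -> mean, sd, n
    bilateral_by_area: pd.DataFrame  # area -> mean, sd of per-brain left+right
    hemisphere_totals: pd.DataFrame  # (sex, hemisphere) -> mean, sd of per-brain sums
    hemisphere_totals_combined: pd.DataFrame  # hemisphere -> mean, sd (all brains)
    brain_totals: pd.DataFrame       # sex -> mean, sd of per-brain grand totals


def _check_complete(df: pd.DataFrame):
    hemis = sorted(df["hemisphere"].unique())
    areas = sorted(df["area"].unique())
    missing = []
    for brain, sub in df.groupby("brain"):
        have = set(zip(sub["hemisphere"], sub["area"]))
        for h in hemis:
            for a in areas:
                if (h, a) not in have:
                    missing.append((brain, h, a))
    if len(hemis) != 2:
        raise ValueError(f"expected records for 2 hemispheres, found {hemis}")
    if missing:
        raise ValueError(f"incomplete volume table; missing cells: {missing}")


def aggregate_table(records: pd.DataFrame, value: str = "volume_mm3") -> VolumeAggregates:
    """Group aggregates of a long per-brain volume table.

    ``records`` needs columns brain, sex, hemisphere, area and the value
    column.  Raises (naming the cells) if any brain misses a hemisphere x
    area combination.
    """
    df = records.copy()
    _check_complete(df)

    by_cell = (df.groupby(["sex", "hemisphere", "area"])[value]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count"))

    per_brain_area = df.pivot_table(index=["brain", "sex", "area"], columns="hemisphere",
                                    values=value, aggfunc="sum")
    bilateral = per_brain_area.sum(axis=1).rename("bilateral").reset_index()
    bilateral_by_area = (bilateral.groupby("area")["bilateral"]
                         .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count"))

    hemi_sums = (df.groupby(["brain", "sex", "hemisphere"])[value].sum()
                 .rename("total").reset_index())
    hemisphere_totals = (hemi_sums.groupby(["sex", "hemisphere"])["total"]
                         .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count"))
    hemisphere_totals_combined = (hemi_sums.groupby("hemisphere")["total"]
                                  .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count"))

    brain_sums = (df.groupby(["brain", "sex"])[value].sum().rename("total").reset_index())
    brain_totals = (brain_sums.groupby("sex")["total"]
                    .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count"))

    return VolumeAggregates(by_cell=by_cell, bilateral_by_area=bilateral_by_area,
                            hemisphere_totals=hemisphere_totals,
                            hemisphere_totals_combined=hemisphere_totals_combined,
                            brain_totals=brain_totals)


# ---------------------------------------------------------------------------
# split-plot ANOVA

def _balanced_array(df, dv, subject, within, between):
    """Rearrange a long table into (groups, subjects, w1[, w2]) cell means."""
    req = [subject, between, *within, dv]
    for col in req:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    counts = df.groupby([subject, *within], observed=True)[dv].count()
    if counts.min() != 1 or counts.max() != 1:
        raise ValueError("unbalanced design: need exactly one observation per "
                         "subject x within-cell")
    subj_sex = df.groupby(subject, observed=True)[between].agg(lambda s: s.iloc[0])
    groups = sorted(df[between].unique())
    per_group = [sorted(subj_sex[subj_sex == g].index) for g in groups]
    sizes = {len(p) for p in per_group}
    if len(sizes) != 1:
        raise ValueError("unbalanced design: unequal group sizes "
                         f"{[len(p) for p in per_group]}")
    levels = [sorted(df[w].unique()) for w in within]
    piv = df.set_index([subject, *within])[dv]
    shape = (len(groups), len(per_group[0]), *[len(l) for l in levels])
    arr = np.empty(shape)
    import itertools
    for gi, subs in enumerate(per_group):
        for si, s in enumerate(subs):
            for cell in itertools.product(*[range(len(l)) for l in levels]):
                key = (s, *[levels[d][cell[d]] for d in range(len(within))])
                try:
                    arr[(gi, si) + cell] = piv.loc[key]
                except KeyError:
                    raise ValueError(f"unbalanced design: missing cell {key}") from None
    return arr, groups, levels


def _anova_two_within(arr, names):
    """Split-plot SS decomposition, one between + two within factors."""
    G, n, A, H = arr.shape
    m = arr.mean()
    m_g = arr.mean((1, 2, 3))
    m_s = arr.mean((2, 3))
    m_a = arr.mean((0, 1, 3))
    m_ga = arr.mean((1, 3))
    m_h = arr.mean((0, 1, 2))
    m_gh = arr.mean((1, 2))
    m_ah = arr.mean((0, 1))
    m_gah = arr.mean(1)
    m_sa = arr.mean(3)
    m_sh = arr.mean(2)

    ss = {}
    ss["between"] = n * A * H * ((m_g - m) ** 2).sum()
    ss["subj"] = A * H * ((m_s - m_g[:, None]) ** 2).sum()
    ss["w1"] = G * n * H * ((m_a - m) ** 2).sum()
    ss["w1:between"] = n * H * ((m_ga - m_g[:, None] - m_a[None, :] + m) ** 2).sum()
    ss["w1:subj"] = H * ((m_sa - m_s[:, :, None] - m_ga[:, None, :]
                          + m_g[:, None, None]) ** 2).sum()
    ss["w2"] = G * n * A * ((m_h - m) ** 2).sum()
    ss["w2:between"] = n * A * ((m_gh - m_g[:, None] - m_h[None, :] + m) ** 2).sum()
    ss["w2:subj"] = A * ((m_sh - m_s[:, :, None] - m_gh[:, None, :]
                          + m_g[:, None, None]) ** 2).sum()
    ss["w1:w2"] = G * n * ((m_ah - m_a[:, None] - m_h[None, :] + m) ** 2).sum()
    ss["w1:w2:between"] = n * ((m_gah - m_ga[:, :, None] - m_gh[:, None, :]
                                - m_ah[None, :, :] + m_g[:, None, None]
                                + m_a[None, :, None] + m_h[None, None, :] - m) ** 2).sum()
    ss["total"] = ((arr - m) ** 2).sum()
    ss["w1:w2:subj"] = ss["total"] - sum(v for k, v in ss.items()
                                         if k not in ("total", "w1:w2:subj"))
    ss["w1:w2:subj"] = max(ss["w1:w2:subj"], 0.0)

    df = {
        "between": G - 1, "subj": G * (n - 1),
        "w1": A - 1, "w1:between": (A - 1) * (G - 1), "w1:subj": (A - 1) * G * (n - 1),
        "w2": H - 1, "w2:between": (H - 1) * (G - 1), "w2:subj": (H - 1) * G * (n - 1),
        "w1:w2": (A - 1) * (H - 1), "w1:w2:between": (A - 1) * (H - 1) * (G - 1),
        "w1:w2:subj": (A - 1) * (H - 1) * G * (n - 1),
    }
    tests = [
        ("between", "subj"), ("w1", "w1:subj"), ("w1:between", "w1:subj"),
        ("w2", "w2:subj"), ("w2:between", "w2:subj"),
        ("w1:w2", "w1:w2:subj"), ("w1:w2:between", "w1:w2:subj"),
    ]
    return ss, df, tests


def _anova_one_within(arr, names):
    G, n, A = arr.shape
    m = arr.mean()
    m_g = arr.mean((1, 2))
    m_s = arr.mean(2)
    m_a = arr.mean((0, 1))
    m_ga = arr.mean(1)

    ss = {}
    ss["between"] = n * A * ((m_g - m) ** 2).sum()
    ss["subj"] = A * ((m_s - m_g[:, None]) ** 2).sum()
    ss["w1"] = G * n * ((m_a - m) ** 2).sum()
    ss["w1:between"] = n * ((m_ga - m_g[:, None] - m_a[None, :] + m) ** 2).sum()
    ss["total"] = ((arr - m) ** 2).sum()
    ss["w1:subj"] = max(ss["total"] - ss["between"] - ss["subj"] - ss["w1"]
                        - ss["w1:between"], 0.0)
    df = {
        "between": G - 1, "subj": G * (n - 1),
        "w1": A - 1, "w1:between": (A - 1) * (G - 1), "w1:subj": (A - 1) * G * (n - 1),
    }
    tests = [("between", "subj"), ("w1", "w1:subj"), ("w1:between", "w1:subj")]
    return ss, df, tests


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (orthogonal to the unit vector)."""
    q, _ = np.linalg.qr(np.c_[np.ones(k), np.eye(k)[:, :-1]])
    return q[:, 1:].T


def _gg_epsilon(arr: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one within stratum.

    ``arr`` is (groups, subjects, cells); ``C`` the stratum's orthonormal
    contrast matrix over the flattened within cells.
    """
    q = C.shape[0]
    if q <= 1:
        return 1.0
    G, n, _ = arr.shape
    S = np.zeros((arr.shape[2], arr.shape[2]))
    for g in range(G):
        Y = arr[g] - arr[g].mean(axis=0)
        S += Y.T @ Y
    S /= G * (n - 1)
    E = C @ S @ C.T
    tr = np.trace(E)
    denom = q * np.trace(E @ E)
    if denom <= 0:
        return 1.0
    return float(min(max(tr**2 / denom, 1.0 / q), 1.0))


def mixed_anova(data: pd.DataFrame, dv: str, subject: str, within, between: str,
                sphericity_correction: str = "none") -> pd.DataFrame:
    """Split-plot (mixed repeated-measures) ANOVA for a balanced design.

    ``within`` may name one or two within-subject factors; ``between``
    names the grouping factor (subjects are nested in it).  Each effect is
    tested against its own effect-by-subject-within-group error stratum;
    partial eta^2 = SS_effect / (SS_effect + SS_error).  Raises for
    unbalanced designs.  The full SS decomposition (including error
    strata and the total) is attached as ``result.attrs['ss']``.

    ``sphericity_correction='greenhouse-geisser'`` scales each within
    stratum's degrees of freedom by its Greenhouse-Geisser epsilon before
    computing p-values (off by default).
    """
    from scipy import stats as sps

    if sphericity_correction not in ("none", "greenhouse-geisser"):
        raise ValueError("sphericity_correction must be 'none' or 'greenhouse-geisser'")
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("within must name one or two factors")
    arr, groups, levels = _balanced_array(data, dv, subject, within, between)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 subjects per group")
    if len(within) == 2:
        ss, dfs, tests = _anova_two_within(arr, within)
    else:
        ss, dfs, tests = _anova_one_within(arr, within)

    eps = {}
    if sphericity_correction == "greenhouse-geisser":
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        if len(within) == 1:
            eps["w1"] = _gg_epsilon(flat, _orthonormal_contrasts(arr.shape[2]))
        else:
            A, H = arr.shape[2], arr.shape[3]
            PA, PH = _orthonormal_contrasts(A), _orthonormal_contrasts(H)
            oneA, oneH = np.full((1, A), A**-0.5), np.full((1, H), H**-0.5)
            eps["w1"] = _gg_epsilon(flat, np.kron(PA, oneH))
            eps["w2"] = _gg_epsilon(flat, np.kron(oneA, PH))
            eps["w1:w2"] = _gg_epsilon(flat, np.kron(PA, PH))

    def label(key):
        parts = key.split(":")
        out = []
        for p in parts:
            if p == "between":
                out.append(between)
            elif p == "w1":
                out.append(within[0])
            elif p == "w2":
                out.append(within[1])
            else:
                out.append(p)
        return ":".join(out)

    rows = []
    eps_zero = 1e-12 * max(ss["total"], 1.0)  # degenerate strata from float noise
    for eff, err in tests:
        ms_e = ss[eff] / dfs[eff]
        ms_r = ss[err] / dfs[err]
        if ss[err] < eps_zero:
            F = 0.0 if ss[eff] < eps_zero else np.inf
        else:
            F = ms_e / ms_r
        if eff in ("w1", "w1:between"):
            stratum = "w1"
        elif eff in ("w2", "w2:between"):
            stratum = "w2"
        elif eff in ("w1:w2", "w1:w2:between"):
            stratum = "w1:w2"
        else:
            stratum = None
        e = eps.get(stratum, 1.0)
        p = float(sps.f.sf(F, e * dfs[eff], e * dfs[err])) if np.isfinite(F) else 0.0
        denom = ss[eff] + ss[err]
        rows.append({"effect": label(eff), "SS": ss[eff], "df1": dfs[eff],
                     "df2": dfs[err], "MS": ms_e, "F": F, "p_value": p,
                     "partial_eta_sq": ss[eff] / denom if denom > 0 else 0.0,
                     "gg_epsilon": e, "error_SS": ss[err]})
    out = pd.DataFrame(rows)
    out.attrs["ss"] = {label(k): v for k, v in ss.items()}
    out.attrs["df"] = {label(k): v for k, v in dfs.items()}
    return out


def compare_gli(records: pd.DataFrame, dv: str = "mean_gli", subject: str = "brain",
                within=("area", "hemisphere"), between: str = "sex") -> pd.DataFrame:
    """Split-plot ANOVA of mean areal GLI values (sex x hemisphere x area)."""
    if dv in records.columns and np.any((records[dv] < 0) | (records[dv] > 1)):
        raise ValueError("mean GLI values must lie in [0, 1]")
    return mixed_anova(records, dv=dv, subject=subject, within=list(within),
                       between=between)


# ---------------------------------------------------------------------------
# packaged fixtures

def load_table1() -> pd.DataFrame:
    """Cohort metadata: 10 brains, 5 male / 5 female, fresh brain weights."""
    with resources.files("cytoborder.data").joinpath("table1_brains.csv").open() as fh:
        return pd.read_csv(fh)


def load_table4() -> pd.DataFrame:
    """Per-brain shrinkage-corrected areal volumes (mm^3), long format."""
    with resources.files("cytoborder.data").joinpath("table4_volumes.csv").open() as fh:
        return pd.read_csv(fh)
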