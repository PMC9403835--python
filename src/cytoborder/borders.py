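"""Observer-independent border detection.

Cytoarchitectonic borders are detected as significant local maxima of the
Mahalanobis distance between the mean 10-feature vectors of two adjacent
blocks of 12-30 GLI profiles, slid along the cortical ribbon.  Each
distance is converted to Hotelling's T^2 and an F statistic; positions are
flagged at a Bonferroni-corrected family level of alpha = 0.001 (divided
by the number of tested positions per block size).  Candidate maxima are
accepted as borders only when they recur at the same position for at least
three block sizes and are reproducible in at least three adjacent serial
sections.

The pooled block covariance is shrunk toward its diagonal (smallest lambda
in {0, 1e-4, 1e-3, 1e-2} achieving condition number < 1e8) to keep small-
block comparisons well-posed; the applied lambda is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .profiles import block_positions

__all__ = [
    "BlockComparison",
    "DistanceFunction",
    "ConsensusCandidate",
    "AcceptedBorder",
    "mahalanobis_blocks",
    "hotelling_test",
    "md_function",
    "detect_maxima",
    "accept_borders",
    "confirm_across_sections",
]

SHRINKAGE_LADDER = (0.0, 1e-4, 1e-3, 1e-2)
MAX_CONDITION = 1e8
DEFAULT_ALPHA = 1e-3


@dataclass
class BlockComparison:
    """One sliding-window comparison of two adjacent profile blocks."""

    position: int
    block_size: int
    d2: float
    t2: float
    f: float
    df1: int
    df2: int
    p_value: float
    shrinkage: float = 0.0


@dataclass
class DistanceFunction:
    """Mahalanobis distance vs. profile index at one block size."""

    block_size: int
    positions: np.ndarray
    d2: np.ndarray
    t2: np.ndarray
    f: np.ndarray
    p_values: np.ndarray
    alpha: float
    alpha_corrected: float
    significant: np.ndarray
    shrinkage: np.ndarray

    def __len__(self):
        return len(self.positions)

    def comparison(self, k: int) -> BlockComparison:
        i = int(np.nonzero(self.positions == k)[0][0])
        b = self.block_size
        return BlockComparison(position=k, block_size=b, d2=float(self.d2[i]),
                               t2=float(self.t2[i]), f=float(self.f[i]), df1=10,
                               df2=2 * b - 11, p_value=float(self.p_values[i]),
                               shrinkage=float(self.shrinkage[i]))


@dataclass
class ConsensusCandidate:
    """A candidate border confirmed across block sizes within one section."""

    position: float
    block_sizes: tuple
    member_positions: tuple
    section_id: int = -1


@dataclass
class AcceptedBorder:
    """A border surviving multi-block-size and multi-section acceptance."""

    position: float
    section_ids: tuple
    block_sizes: tuple
    member_positions: tuple
    position_spread: float


# ---------------------------------------------------------------------------
# core statistics

def _shrink(C: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * C + lam * np.diag(np.diag(C))


def _condition(C: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(C)
    if ev[-1] <= 0 or ev[0] <= 0:
        return np.inf
    return float(ev[-1] / ev[0])


def mahalanobis_blocks(block_a: np.ndarray, block_b: np.ndarray,
                       return_shrinkage: bool = False):
    """Squared Mahalanobis distance between two blocks' mean feature vectors.

    ``D^2 = (m_A - m_B)^T C^-1 (m_A - m_B)`` with C the pooled sample
    covariance ``((n_A-1) S_A + (n_B-1) S_B) / (n_A + n_B - 2)``.
    """
    A = np.atleast_2d(np.asarray(getattr(block_a, "features", block_a), float))
    B = np.atleast_2d(np.asarray(getattr(block_b, "features", block_b), float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("each block needs at least 2 profiles")
    if nA != nB:
        raise ValueError("blocks must have equal size")
    delta = A.mean(axis=0) - B.mean(axis=0)
    SA = np.cov(A, rowvar=False, ddof=1)
    SB = np.cov(B, rowvar=False, ddof=1)
    C = ((nA - 1) * SA + (nB - 1) * SB) / (nA + nB - 2)
    for lam in SHRINKAGE_LADDER:
        Cs = _shrink(C, lam)
        if _condition(Cs) < MAX_CONDITION:
            d2 = float(delta @ np.linalg.solve(Cs, delta))
            d2 = max(d2, 0.0)
            return (d2, lam) if return_shrinkage else d2
    raise np.linalg.LinAlgError(
        "pooled covariance singular even after maximal shrinkage; "
        "increase block size or drop constant features")


def hotelling_test(d2: float, nA: int, nB: int, p: int = 10):
    """Hotelling's two-sample T^2 test from a squared Mahalanobis distance.

    Returns ``(T^2, F, df1, df2, p_value)`` with ``T^2 = nA nB / (nA + nB)
    * D^2`` and ``F = T^2 (nA + nB - p - 1) / ((nA + nB - 2) p)`` on
    ``(p, nA + nB - p - 1)`` degrees of freedom.
    """
    df2 = nA + nB - p - 1
    if df2 < 1:
        raise ValueError(f"df2 = nA+nB-p-1 = {df2} < 1: use a larger block size")
    if d2 < 0:
        raise ValueError("D^2 must be non-negative")
    t2 = nA * nB / (nA + nB) * d2
    f = t2 * df2 / ((nA + nB - 2) * p)
    p_value = float(stats.f.sf(f, p, df2))
    return float(t2), float(f), int(p), int(df2), p_value


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def md_function(features: np.ndarray, b: int, alpha: float = DEFAULT_ALPHA,
                standardize: bool = True, strict_range: bool = True) -> DistanceFunction:
    """Sliding-window Mahalanobis distance function at one block size.

    Features are z-scored across the section's profile set before distance
    computation (features have incommensurate units).  The Bonferroni
    correction divides ``alpha`` by the number of tested positions at this
    block size.
    """
    from .profiles import BLOCK_SIZE_MAX, BLOCK_SIZE_MIN

    X = np.atleast_2d(np.asarray(features, float))
    if strict_range and not (BLOCK_SIZE_MIN <= b <= BLOCK_SIZE_MAX):
        raise ValueError(f"block size {b} outside [{BLOCK_SIZE_MIN}, {BLOCK_SIZE_MAX}]")
    n, p = X.shape
    positions = block_positions(n, b)
    if standardize:
        X = _zscore_columns(X)

    # cumulative first and second moments for O(1) per-position block stats
    S1 = np.vstack([np.zeros(p), np.cumsum(X, axis=0)])
    xxt = np.einsum("ni,nj->nij", X, X)
    S2 = np.concatenate([np.zeros((1, p, p)), np.cumsum(xxt, axis=0)])

    P = len(positions)
    sumA = S1[positions] - S1[positions - b]
    sumB = S1[positions + b] - S1[positions]
    mA, mB = sumA / b, sumB / b
    SSA = (S2[positions] - S2[positions - b]
           - np.einsum("ki,kj->kij", sumA, sumA) / b)
    SSB = (S2[positions + b] - S2[positions]
           - np.einsum("ki,kj->kij", sumB, sumB) / b)
    C = (SSA + SSB) / (2 * b - 2)
    delta = mA - mB

    lam_used = np.zeros(P)
    d2 = np.full(P, np.nan)
    todo = np.arange(P)
    for lam in SHRINKAGE_LADDER:
        if len(todo) == 0:
            break
        Cs = _shrink_batch(C[todo], lam)
        ev = np.linalg.eigvalsh(Cs)
        good = (ev[:, 0] > 0) & (ev[:, -1] / np.where(ev[:, 0] > 0, ev[:, 0], 1.0)
                                 < MAX_CONDITION)
        if good.any():
            sel = todo[good]
            z = np.linalg.solve(Cs[good], delta[sel][..., None])[..., 0]
            d2[sel] = np.maximum(np.einsum("ki,ki->k", delta[sel], z), 0.0)
            lam_used[sel] = lam
        todo = todo[~good]
    if len(todo):
        raise np.linalg.LinAlgError(
            f"pooled covariance singular after maximal shrinkage at positions "
            f"{positions[todo][:5].tolist()}...")

    t2 = b * b / (2 * b) * d2
    df1, df2 = p, 2 * b - p - 1
    if df2 < 1:
        raise ValueError(f"df2 = {df2} < 1: use a larger block size")
    f = t2 * df2 / ((2 * b - 2) * df1)
    pvals = stats.f.sf(f, df1, df2)
    alpha_corr = alpha / P
    return DistanceFunction(block_size=b, positions=positions, d2=d2, t2=t2, f=f,
                            p_values=pvals, alpha=alpha, alpha_corrected=alpha_corr,
                            significant=pvals <= alpha_corr, shrinkage=lam_used)


def _shrink_batch(C: np.ndarray, lam: float) -> np.ndarray:
    diag = np.zeros_like(C)
    idx = np.arange(C.shape[1])
    diag[:, idx, idx] = C[:, idx, idx]
    return (1.0 - lam) * C + lam * diag


# ---------------------------------------------------------------------------
# maxima, multi-scale and multi-section acceptance

def detect_maxima(dist: DistanceFunction, window: int = 2,
                  require_significant: bool = True) -> list:
    """Positions that are strict local maxima of D^2 over +/- ``window``.

    A plateau of exactly equal values yields its leftmost index.  By
    default only positions significant after Bonferroni correction are
    returned.
    """
    d2 = dist.d2
    n = len(d2)
    out = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        left = d2[lo:i]
        right = d2[i + 1:hi]
        if len(left) and not np.all(d2[i] > left):
            continue
        if len(right) and not np.all(d2[i] >= right):
            continue
        # a flat stretch is not a maximum: require a strictly smaller
        # neighbour somewhere in the window
        neigh = np.concatenate([left, right])
        if len(neigh) == 0 or not np.any(neigh < d2[i]):
            continue
        if require_significant and not dist.significant[i]:
            continue
        out.append(int(dist.positions[i]))
    return out


def accept_borders(candidates_by_block_size: dict, min_block_sizes: int = 3,
                   position_tol: float = 4.0, section_id: int = -1) -> list:
    """Cluster candidate maxima across block sizes; keep multi-scale ones.

    Candidates from all block sizes are clustered by single linkage at
    ``position_tol`` profiles; clusters supported by at least
    ``min_block_sizes`` distinct block sizes yield a consensus border at
    the median member position.
    """
    pairs = sorted((pos, b) for b, cands in candidates_by_block_size.items()
                   for pos in cands)
    if not pairs:
        return []
    clusters = [[pairs[0]]]
    for pos, b in pairs[1:]:
        if pos - clusters[-1][-1][0] <= position_tol:
            clusters[-1].append((pos, b))
        else:
            clusters.append([(pos, b)])
    out = []
    for cl in clusters:
        sizes = sorted({b for _, b in cl})
        if len(sizes) >= min_block_sizes:
            poss = [p for p, _ in cl]
            out.append(ConsensusCandidate(position=float(np.median(poss)),
                                          block_sizes=tuple(sizes),
                                          member_positions=tuple(poss),
                                          section_id=section_id))
    return out


def confirm_across_sections(per_section_candidates: list, min_sections: int = 3,
                            section_tol: float = 6.0) -> list:
    """Match candidates across consecutive sections; keep reproducible ones.

    ``per_section_candidates`` lists, for each section in serial order, its
    ``ConsensusCandidate`` list.  Candidates are chained across *adjacent*
    sections when their positions differ by at most ``section_tol``; a gap
    breaks the chain.  Chains spanning at least ``min_sections`` sections
    are accepted at their median position.
    """
    chains = []  # each: dict(last_section, members=[(section, candidate)])
    for sec_idx, cands in enumerate(per_section_candidates):
        cands = sorted(cands, key=lambda c: c.position)
        open_chains = [ch for ch in chains if ch["last"] == sec_idx - 1]
        # one-to-one matching, closest pairs first, so a distant candidate
        # cannot steal a chain from a nearer one
        pairs = sorted((abs(ch["members"][-1][1].position - cand.position), ci, cj)
                       for ci, ch in enumerate(open_chains)
                       for cj, cand in enumerate(cands))
        taken_chain, taken_cand = set(), set()
        for d, ci, cj in pairs:
            if d > section_tol:
                break
            if ci in taken_chain or cj in taken_cand:
                continue
            ch = open_chains[ci]
            ch["members"].append((sec_idx, cands[cj]))
            ch["last"] = sec_idx
            taken_chain.add(ci)
            taken_cand.add(cj)
        for cj, cand in enumerate(cands):
            if cj not in taken_cand:
                chains.append({"last": sec_idx, "members": [(sec_idx, cand)]})
    accepted = []
    for ch in chains:
        if len(ch["members"]) < min_sections:
            continue
        poss = [c.position for _, c in ch["members"]]
        sizes = sorted({b for _, c in ch["members"] for b in c.block_sizes})
        members = tuple(p for _, c in ch["members"] for p in c.member_positions)
        secs = tuple(s for s, _ in ch["members"])
        accepted.append(AcceptedBorder(position=float(np.median(poss)),
                                       section_ids=secs, block_sizes=tuple(sizes),
                                       member_positions=members,
                                       position_spread=float(max(poss) - min(poss))))
    return accepted
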