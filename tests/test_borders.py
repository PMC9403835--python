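"""Border detection: Mahalanobis/Hotelling statistics, sliding-window
distance functions, maxima, multi-scale and multi-section acceptance."""

import numpy as np
import pytest

from cytoborder.borders import (ConsensusCandidate, accept_borders,
                                confirm_across_sections, detect_maxima,
                                hotelling_test, mahalanobis_blocks, md_function)


def _gauss_solve(C, d):
    """Explicit Gaussian elimination with partial pivoting (oracle)."""
    C = [row[:] for row in C.tolist()]
    d = list(d)
    n = len(d)
    for i in range(n):
        piv = max(range(i, n), key=lambda r: abs(C[r][i]))
        C[i], C[piv] = C[piv], C[i]
        d[i], d[piv] = d[piv], d[i]
        for r in range(i + 1, n):
            f = C[r][i] / C[i][i]
            for c in range(i, n):
                C[r][c] -= f * C[i][c]
            d[r] -= f * d[i]
    z = [0.0] * n
    for i in reversed(range(n)):
        z[i] = (d[i] - sum(C[i][c] * z[c] for c in range(i + 1, n))) / C[i][i]
    return np.asarray(z)


# ---------------------------------------------------------------------------
# Mahalanobis

def test_identical_blocks_give_zero_distance():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(15, 10))
    assert mahalanobis_blocks(A, A.copy()) == pytest.approx(0.0, abs=1e-10)


def test_unit_covariance_unit_shift_closed_form():
    """Three-feature toy with near-identity pooled covariance and mean shift
    (1,0,0): D^2 must equal Delta^T Delta = 1."""
    rng = np.random.default_rng(1)
    n = 4000
    base = rng.normal(size=(n, 3))
    A = base - base.mean(0)
    B = A.copy()
    B[:, 0] += 1.0
    d2 = mahalanobis_blocks(A, B)
    assert d2 == pytest.approx(1.0, rel=0.02)


def test_matches_explicit_elimination_oracle():
    rng = np.random.default_rng(7)
    A = rng.normal(size=(15, 10))
    B = rng.normal(0.3, 1.0, size=(15, 10))
    d2 = mahalanobis_blocks(A, B)
    delta = A.mean(0) - B.mean(0)
    SA = np.cov(A, rowvar=False, ddof=1)
    SB = np.cov(B, rowvar=False, ddof=1)
    C = (14 * SA + 14 * SB) / 28
    oracle = float(delta @ _gauss_solve(C, delta))
    assert d2 == pytest.approx(oracle, rel=1e-10)


def test_unequal_or_tiny_blocks_rejected():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        mahalanobis_blocks(rng.normal(size=(10, 10)), rng.normal(size=(12, 10)))
    with pytest.raises(ValueError):
        mahalanobis_blocks(rng.normal(size=(1, 10)), rng.normal(size=(1, 10)))


def test_constant_features_raise_after_max_shrinkage():
    A = np.ones((12, 10))
    B = np.ones((12, 10)) * 2
    with pytest.raises(np.linalg.LinAlgError):
        mahalanobis_blocks(A, B)


# ---------------------------------------------------------------------------
# Hotelling

def test_hotelling_null_and_formula_values():
    t2, f, df1, df2, p = hotelling_test(0.0, 20, 20)
    assert (t2, f, p) == (0.0, 0.0, 1.0)
    t2, f, df1, df2, p = hotelling_test(2.0, 20, 20, p=10)
    assert t2 == pytest.approx(20.0)
    assert f == pytest.approx(20 * 29 / (38 * 10), rel=1e-12)
    assert (df1, df2) == (10, 29)


def test_hotelling_pvalue_monotone_in_d2():
    ps = [hotelling_test(d2, 15, 15)[4] for d2 in (0.5, 1.0, 2.0, 4.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_hotelling_df_guard():
    with pytest.raises(ValueError, match="block size"):
        hotelling_test(1.0, 5, 5, p=10)


# ---------------------------------------------------------------------------
# distance functions

def _iid_features(rng, n=80, p=10):
    return rng.normal(size=(n, p))


def test_md_function_agrees_with_pairwise_op():
    """The vectorized sliding-window path must equal the standalone
    two-block operation at every position (z-scored features)."""
    rng = np.random.default_rng(3)
    X = _iid_features(rng, 60)
    dist = md_function(X, 15, standardize=True)
    mu, sd = X.mean(0), X.std(0, ddof=1)
    Z = (X - mu) / sd
    for i, k in enumerate(dist.positions[::4]):
        d2 = mahalanobis_blocks(Z[k - 15:k], Z[k:k + 15])
        assert dist.d2[np.nonzero(dist.positions == k)[0][0]] == pytest.approx(d2, rel=1e-9)


def test_translation_equivariance():
    rng = np.random.default_rng(4)
    X = _iid_features(rng, 90)
    d_full = md_function(X, 20)
    d_shift = md_function(X[10:], 20)
    # same comparisons shifted by 10 positions
    np.testing.assert_allclose(d_full.d2[10:len(d_shift.d2) + 10], d_shift.d2, rtol=1e-9)


def test_null_family_error_rate_controlled():
    """Homogeneous i.i.d. profiles: runs with any significant position occur
    at most at twice the family level (Monte-Carlo slack) over 500 runs."""
    rng = np.random.default_rng(5)
    n_runs, hits = 500, 0
    for _ in range(n_runs):
        X = _iid_features(rng, 70)
        dist = md_function(X, 20, alpha=1e-3)
        hits += bool(dist.significant.any())
    assert hits / n_runs <= 0.002


def test_step_change_localized():
    """A 2-sigma step in the mean of every feature at k0: the global D^2
    maximum falls within +/-3 of k0 in >= 95% of 200 runs at b=20."""
    rng = np.random.default_rng(6)
    k0, good = 40, 0
    for _ in range(200):
        X = _iid_features(rng, 80)
        X[k0:] += 2.0
        dist = md_function(X, 20)
        kmax = dist.positions[np.argmax(dist.d2)]
        good += abs(kmax - k0) <= 3
    assert good / 200 >= 0.95


# ---------------------------------------------------------------------------
# maxima and acceptance

def _dist_stub(d2, significant=None, b=20):
    from cytoborder.borders import DistanceFunction

    d2 = np.asarray(d2, float)
    pos = np.arange(b, b + len(d2))
    sig = np.ones(len(d2), bool) if significant is None else np.asarray(significant)
    z = np.zeros(len(d2))
    return DistanceFunction(block_size=b, positions=pos, d2=d2, t2=z, f=z,
                            p_values=z, alpha=1e-3, alpha_corrected=1e-3 / len(d2),
                            significant=sig, shrinkage=z)


def test_monotone_curve_yields_only_endpoint():
    d = _dist_stub(np.linspace(0, 5, 30))
    assert detect_maxima(d) == [int(d.positions[-1])]


def test_two_separated_peaks_both_returned():
    vals = np.zeros(40)
    vals[10], vals[30] = 5.0, 4.0
    d = _dist_stub(vals)
    assert detect_maxima(d) == [int(d.positions[10]), int(d.positions[30])]


def test_plateau_returns_leftmost_index():
    vals = np.zeros(20)
    vals[8:11] = 3.0
    d = _dist_stub(vals)
    assert detect_maxima(d) == [int(d.positions[8])]


def test_insignificant_maxima_filtered():
    vals = np.zeros(20)
    vals[10] = 5.0
    sig = np.zeros(20, bool)
    d = _dist_stub(vals, sig)
    assert detect_maxima(d) == []


def test_accept_borders_block_size_rules():
    got = accept_borders({14: [100], 20: [100], 26: [100]})
    assert len(got) == 1 and got[0].position == 100
    assert accept_borders({20: [100], 21: [100]}) == []


def test_accept_borders_single_linkage_cluster():
    got = accept_borders({12: [100], 18: [102], 24: [103]}, position_tol=4)
    assert len(got) == 1
    assert got[0].position == 102
    assert got[0].block_sizes == (12, 18, 24)


def test_accept_borders_far_positions_not_merged():
    got = accept_borders({12: [100], 18: [120], 24: [140]}, position_tol=4)
    assert got == []


def _cand(pos, sec, sizes=(12, 18, 24)):
    return ConsensusCandidate(position=float(pos), block_sizes=tuple(sizes),
                              member_positions=(pos,), section_id=sec)


def test_confirm_requires_adjacent_sections():
    per_sec = [[_cand(50, 0)], [_cand(51, 1)], [_cand(50, 2)]]
    out = confirm_across_sections(per_sec, min_sections=3, section_tol=4)
    assert len(out) == 1 and out[0].position == 50.0
    # gap in section 1 breaks the chain
    per_sec = [[_cand(50, 0)], [], [_cand(50, 2)], [_cand(50, 3)]]
    assert confirm_across_sections(per_sec, min_sections=3, section_tol=4) == []


def test_confirm_matches_nearest_candidate_first():
    # a distant candidate must not steal the chain from a near one
    per_sec = [[_cand(50, 0)], [_cand(45, 1), _cand(51, 2)], [_cand(52, 2)]]
    out = confirm_across_sections(per_sec, min_sections=3, section_tol=6)
    assert len(out) == 1
    assert out[0].position == pytest.approx(51.0)
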