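"""Constrained DTW vs. independent oracles.

The path oracle enumerates every monotone continuous warping path by
depth-first search and maximizes the weighted similarity sum directly —
no dynamic programming, no shared code with the implementation.
"""

import itertools
import math

import numpy as np
import pytest

from chromalign.cemapp_dtw import (
    AlignmentPath,
    DTWWeights,
    PartitionedArray,
    build_layout,
    cemapp_dtw_align,
    dtw_align,
    extract_similarity_maxima,
    filter_anchors,
    full_layout,
    select_center,
    similarity_maxima,
)
from chromalign.chromdata import Chromatogram
from chromalign.similarity import SimilarityConfig, spectral_similarity

from conftest import make_peak


def brute_force_best_score(F: np.ndarray, wts: DTWWeights) -> float:
    """Max over all monotone continuous paths of the weighted similarity
    sum; F[i-1, j-1] is the similarity at path cell (i, j)."""
    M, N = F.shape
    best = [-math.inf]

    def dfs(i, j, acc):
        if (i, j) == (M, N):
            best[0] = max(best[0], acc)
            return
        if i < M and j < N:
            dfs(i + 1, j + 1, acc + wts.w_match * F[i, j])
        if j < N:
            dfs(i, j + 1, acc + wts.w_comp * F[i - 1, j])
        if i < M:
            dfs(i + 1, j, acc + wts.w_exp * F[i, j - 1])

    dfs(1, 1, wts.w_match * F[0, 0])
    return best[0]


def sim_matrix(A, B, kind):
    return np.array([
        [spectral_similarity(a, b, kind) for b in B] for a in A
    ])


class TestFilterAnchors:
    def test_inverted_order_removed(self):
        assert filter_anchors([(10, 12), (20, 18), (15, 25)]) == [(10, 12), (20, 18)]

    def test_monotone_nonadjacent_unchanged(self):
        anchors = [(2, 3), (10, 8), (20, 30)]
        assert filter_anchors(anchors) == anchors

    def test_empty(self):
        assert filter_anchors([]) == []

    def test_adjacent_pairs_collapsed(self):
        assert filter_anchors([(5, 5), (6, 6), (10, 9)]) == [(5, 5), (10, 9)]

    def test_lis_is_maximal_on_spaced_points(self, rng):
        # points spaced >1 apart so adjacency collapse is a no-op; the kept
        # chain must be as long as the best strictly-increasing subset
        for _ in range(20):
            pts = [(int(a), int(b)) for a, b in
                   zip(rng.choice(50, 8, replace=False) * 3,
                       rng.choice(50, 8, replace=False) * 3)]
            out = filter_anchors(pts)
            assert all(x1 > x0 and y1 > y0
                       for (x0, y0), (x1, y1) in zip(out, out[1:]))
            best = max(
                (len(s) for r in range(len(pts) + 1)
                 for s in itertools.combinations(sorted(set(pts)), r)
                 if all(x1 > x0 and y1 > y0
                        for (x0, y0), (x1, y1) in zip(s, s[1:]))),
            )
            assert len(out) == best


class TestBuildLayout:
    def test_unconstrained_limit_is_full(self):
        lay = build_layout([], r=0, band=(1.0, "global"), M=10, N=10)
        assert lay.lo[0] == lay.hi[0] == 0
        assert all(lay.lo[i] == 1 and lay.hi[i] == 10 for i in range(1, 11))

    def test_band_width_monotone_in_w(self, rng):
        narrow = build_layout([], 0, (0.1, "local"), 60, 60).n_cells
        wide = build_layout([], 0, (0.5, "local"), 60, 60).n_cells
        assert narrow <= wide

    def test_stored_cell_budget_local_band(self):
        for M, w in [(50, 0.1), (80, 0.2), (120, 0.05)]:
            lay = build_layout([], 0, (w, "local"), M, M)
            assert lay.n_cells <= math.ceil(w * M) * (M + 1)

    def test_anchor_cells_admissible_and_pinched(self):
        anchors = [(10, 10), (20, 22)]
        lay = build_layout(anchors, r=0, band=(0.1, "local"), M=30, N=30)
        for a, b in anchors:
            assert lay.contains(a + 1, b + 1)
            assert lay.lo[a + 1] == lay.hi[a + 1] == b + 1

    def test_bounds_monotone_and_connected(self, rng):
        lay = build_layout([(5, 7), (15, 14), (25, 28)], r=2,
                           band=(0.15, "local"), M=40, N=40)
        assert np.all(np.diff(lay.lo) >= 0)
        assert np.all(np.diff(lay.hi) >= 0)
        for i in range(1, 41):
            assert lay.lo[i] <= lay.hi[i - 1] + 1

    def test_nonmonotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            build_layout([(10, 12), (12, 9)], 0, None, 20, 20)


class TestPartitionedArray:
    def test_get_set_semantics(self):
        lay = build_layout([(4, 4)], r=0, band=(0.3, "local"), M=10, N=10)
        arr = PartitionedArray(lay, default_value=-np.inf)
        for i in range(11):
            for j in range(11):
                if lay.contains(i, j):
                    arr.set(i, j, i * 100.0 + j)
                    assert arr.get(i, j) == i * 100.0 + j
                else:
                    assert arr.get(i, j) == -np.inf
                    arr.set(i, j, 42.0)  # must be a no-op
                    assert arr.get(i, j) == -np.inf

    def test_rcs_indexing_is_contiguous(self):
        lay = build_layout([], 0, (0.2, "local"), 20, 20)
        arr = PartitionedArray(lay)
        assert arr.d.size == lay.n_cells
        assert arr.idx[5] + arr.len[5] == arr.idx[6]


class TestDtwAlign:
    def test_single_element_series(self, rng):
        a = rng.uniform(size=(1, 6))
        b = rng.uniform(size=(1, 6))
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        wts = DTWWeights(w_match=2.25)
        path = dtw_align(a, b, cfg, wts)
        assert path.pairs == [(1, 1)]
        f = spectral_similarity(a[0], b[0], "cosine")
        assert math.isclose(path.score, 2.25 * f)

    def test_identical_series_diagonal(self, rng):
        A = rng.uniform(0.1, 1.0, size=(12, 6))
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        path = dtw_align(A, A, cfg, DTWWeights(w_match=2.25))
        assert path.pairs == [(i, i) for i in range(1, 13)]

    @pytest.mark.parametrize("kind", ["cosine", "dot", "euclidean"])
    def test_matches_brute_force(self, kind, rng):
        cfg = SimilarityConfig(kind=kind, use_rt_penalty=False)
        for _ in range(10):
            M, N = rng.integers(1, 7, size=2)
            A = rng.uniform(size=(M, 5))
            B = rng.uniform(size=(N, 5))
            wts = DTWWeights(w_match=float(rng.uniform(1.0, 3.0)))
            path = dtw_align(A, B, cfg, wts)
            expected = brute_force_best_score(sim_matrix(A, B, kind), wts)
            assert math.isclose(path.score, expected, abs_tol=1e-9)

    def test_path_invariants(self, rng):
        A = rng.uniform(size=(9, 5))
        B = rng.uniform(size=(14, 5))
        cfg = SimilarityConfig(kind="dot", use_rt_penalty=False)
        path = dtw_align(A, B, cfg, DTWWeights())
        assert path.pairs[0] == (1, 1)
        assert path.pairs[-1] == (9, 14)
        assert len(path) < 2 * 14
        for (i, j), (i2, j2) in zip(path.pairs, path.pairs[1:]):
            assert 0 <= i2 - i <= 1 and 0 <= j2 - j <= 1
            assert (i2 - i) + (j2 - j) > 0

    def test_partitioned_equals_dense_bit_for_bit(self, rng):
        # independent dense DP over the full matrix, same cell values
        from chromalign.cemapp_dtw import _row_similarities
        from chromalign.similarity import prepare_vectors

        A = rng.uniform(size=(15, 6))
        B = rng.uniform(size=(11, 6))
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        wts = DTWWeights(w_match=2.25)
        pa, pb = prepare_vectors(A, "cosine"), prepare_vectors(B, "cosine")
        M, N = 15, 11
        Q = np.full((M + 1, N + 1), -np.inf)
        Q[0, 0] = 0.0
        for i in range(1, M + 1):
            f = _row_similarities(pa, pb, i, 1, N, cfg, None, None, "cosine")
            for j in range(1, N + 1):
                Q[i, j] = max(
                    Q[i - 1, j - 1] + wts.w_match * f[j - 1],
                    Q[i, j - 1] + wts.w_comp * f[j - 1],
                    Q[i - 1, j] + wts.w_exp * f[j - 1],
                )
        path = dtw_align(A, B, cfg, wts, full_layout(M, N))
        assert path.score == Q[M, N]  # exact equality, same fp operations

    def test_r0_anchors_are_visited(self, rng):
        A = rng.uniform(size=(30, 5))
        B = rng.uniform(size=(30, 5))
        anchors = [(7, 7), (14, 15), (22, 21)]
        lay = build_layout(anchors, r=0, band=(0.2, "local"), M=30, N=30)
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        path = dtw_align(A, B, cfg, DTWWeights(), lay)
        for a, b in anchors:
            assert (a + 1, b + 1) in path.pairs

    def test_rt_penalty_requires_rts(self, rng):
        A = rng.uniform(size=(3, 4))
        with pytest.raises(ValueError):
            dtw_align(A, A, SimilarityConfig(use_rt_penalty=True), DTWWeights())

    def test_corrected_score_symmetric_for_equal_comp_exp(self, rng):
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        wts = DTWWeights(w_match=2.25, w_comp=1.0, w_exp=1.0)
        for _ in range(5):
            A = rng.uniform(size=(8, 5))
            B = rng.uniform(size=(12, 5))
            fwd = dtw_align(A, B, cfg, wts)
            rev = dtw_align(B, A, cfg, wts)
            assert math.isclose(fwd.corrected_score, rev.corrected_score,
                                abs_tol=1e-12)


class TestSimilarityMaxima:
    def test_single_interior_maximum(self):
        assert similarity_maxima([0.1, 0.9, 0.1]) == [1]

    def test_monotone_terminal_maximum(self):
        assert similarity_maxima([0.1, 0.2, 0.5, 0.9]) == [3]

    def test_plateau_reports_first_index(self):
        assert similarity_maxima([0.1, 0.7, 0.7, 0.2]) == [1]

    def test_matches_neighbor_scan_oracle(self, rng):
        for _ in range(30):
            v = list(rng.choice([0.1, 0.3, 0.5, 0.8], size=12))
            got = similarity_maxima(v)
            expected = []
            k = 0
            while k < len(v):
                end = k
                while end + 1 < len(v) and v[end + 1] == v[k]:
                    end += 1
                left = v[k - 1] if k > 0 else -np.inf
                right = v[end + 1] if end + 1 < len(v) else -np.inf
                if v[k] > left and v[k] > right:
                    expected.append(k)
                k = end + 1
            assert got == expected

    def test_extract_returns_path_positions(self, rng):
        A = rng.uniform(size=(6, 5))
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        path = dtw_align(A, A, cfg, DTWWeights())
        maxima = extract_similarity_maxima(path)
        assert set(maxima) <= set(path.pairs)


class TestSelectCenter:
    def test_hand_summed_example(self):
        s = np.array([[0.0, 0.9, 0.2], [0.9, 0.0, 0.8], [0.2, 0.8, 0.0]])
        assert select_center(s) == 1  # sums: 1.1, 1.7, 1.0

    def test_two_way_tie_prefers_lowest(self):
        assert select_center(np.array([[0.0, 0.5], [0.5, 0.0]])) == 0

    def test_shift_invariance(self, rng):
        s = rng.uniform(size=(4, 4))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0.0)
        shifted = s + 0.37 * (1 - np.eye(4))
        assert select_center(s) == select_center(shifted)

    def test_too_small(self):
        with pytest.raises(ValueError):
            select_center(np.zeros((1, 1)))


class TestCemappMultipleAlignment:
    def _identical_chroms(self, rng, K=3, n=20):
        scans = rng.uniform(0.1, 1.0, size=(n, 7))
        rts = np.linspace(0.0, n - 1.0, n)
        return [
            Chromatogram(id=f"C{k}", scans=scans.copy(), scan_rts=rts.copy(),
                         mass_range=(50, 56))
            for k in range(K)
        ]

    def test_identical_chromatograms_identity_mapping(self, rng):
        chroms = self._identical_chroms(rng)
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        res = cemapp_dtw_align(chroms, cfg, DTWWeights(2.25), band=(0.5, "global"))
        for i, row in enumerate(res.table.rows):
            assert all(v == i for v in row.values())

    def test_table_is_dense(self, rng):
        chroms = self._identical_chroms(rng)
        cfg = SimilarityConfig(kind="cosine", use_rt_penalty=False)
        res = cemapp_dtw_align(chroms, cfg, DTWWeights(2.25), band=(0.5, "global"))
        assert len(res.table) == 20
        for row in res.table.rows:
            assert all(v is not None for v in row.values())

    def test_needs_scan_series(self):
        c = Chromatogram(id="A", mass_range=(50, 56))
        with pytest.raises(ValueError):
            cemapp_dtw_align([c, c], SimilarityConfig(use_rt_penalty=False))
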