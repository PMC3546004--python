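"""Center-star multiple alignment by anchor-partitioned dynamic time warping.

Two scan series A = (a_1..a_M) and B = (b_1..b_N) of binned mass spectra
are aligned by maximizing the summed pairwise similarity f along a warping
path: a monotone, continuous sequence of index pairs from (1, 1) to (M, N)
in an (M+1) x (N+1) dynamic-programming matrix Q,

    Q(i, j) = max( Q(i-1, j-1) + w_match * f(a_i, b_j),
                   Q(i,   j-1) + w_comp  * f(a_i, b_j),
                   Q(i-1, j  ) + w_exp   * f(a_i, b_j) ),

with row 0 and column 0 initialized to -inf except Q(0, 0) = 0, which
forces a global alignment of (a_1, b_1).  A match weight above
w_comp + w_exp discourages the stair-stepping overadaptation that pure
similarity maximization would otherwise favor.

The matrix is never materialized densely.  A :class:`ConstraintLayout`
lists the admissible cells — built from pre-matched scan pairs (anchors,
e.g. BIPACE clique peaks) with a flexibility radius r, plus a global or
per-partition (local) Sakoe-Chiba band — and the recursion runs only over
those cells, stored row-compressed in a :class:`PartitionedArray`.  Scores
are corrected for the path's step weights so that series of different
lengths are comparable; the chromatogram with the highest summed corrected
score to all others becomes the center-star reference, and all remaining
chromatograms are aligned to it independently to yield a dense multiple
alignment with no missing entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chromdata import Chromatogram, MultipleAlignmentTable
from .similarity import SimilarityConfig, pairwise_matrix, prepare_vectors, rt_penalty

__all__ = [
    "DTWWeights",
    "ConstraintLayout",
    "PartitionedArray",
    "AlignmentPath",
    "CemappResult",
    "filter_anchors",
    "build_layout",
    "full_layout",
    "dtw_align",
    "similarity_maxima",
    "extract_similarity_maxima",
    "select_center",
    "anchors_from_table",
    "cemapp_dtw_align",
]

_MATCH, _COMP, _EXP = 1, 2, 3


@dataclass(frozen=True)
class DTWWeights:
    """Step weights for diagonal (match), horizontal (compression) and
    vertical (expansion) moves.  w_match = 2.25 with unit w_comp/w_exp
    keeps the path close to the diagonal without forbidding warping."""

    w_match: float = 2.25
    w_comp: float = 1.0
    w_exp: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_match, self.w_comp, self.w_exp) <= 0:
            raise ValueError("all DTW weights must be positive")


def filter_anchors(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Reduce raw anchor pairs to a monotone chain usable as constraints.

    Anchors are sorted by their first coordinate; pairs whose order is
    inverted on the second coordinate are removed by keeping a longest
    strictly-increasing subsequence (minimizing deletions), and directly
    neighbouring anchors (adjacent in both coordinates) are collapsed to
    the earlier one, since they would over-constrain the path.
    """
    if not pairs:
        return []
    pts = sorted(set((int(a), int(b)) for a, b in pairs))
    # longest chain strictly increasing in both coordinates (O(n^2))
    n = len(pts)
    best_len = [1] * n
    prev = [-1] * n
    for k in range(n):
        for m in range(k):
            if pts[m][0] < pts[k][0] and pts[m][1] < pts[k][1]:
                if best_len[m] + 1 > best_len[k]:
                    best_len[k] = best_len[m] + 1
                    prev[k] = m
    end = n - 1 - int(np.argmax(best_len[::-1]))  # last among equal-length chains
    chain = []
    while end != -1:
        chain.append(pts[end])
        end = prev[end]
    chain.reverse()
    # drop anchors directly adjacent to their predecessor in both coords
    out: list[tuple[int, int]] = []
    for a in chain:
        if out and a[0] - out[-1][0] == 1 and a[1] - out[-1][1] == 1:
            continue
        out.append(a)
    return out


@dataclass
class ConstraintLayout:
    """Per-row admissible column intervals of the (M+1) x (N+1) DP grid.

    ``lo[i]``/``hi[i]`` bound the admissible columns of row i (inclusive);
    bounds are nondecreasing in i, cell (0, 0) and cell (M, N) are always
    admissible, and consecutive rows overlap or abut diagonally so a valid
    warping path exists.
    """

    M: int
    N: int
    lo: np.ndarray
    hi: np.ndarray
    anchors: list[tuple[int, int]] = field(default_factory=list)

    def contains(self, i: int, j: int) -> bool:
        return 0 <= i <= self.M and self.lo[i] <= j <= self.hi[i]

    @property
    def n_cells(self) -> int:
        """Number of stored (admissible) cells."""
        return int(np.sum(self.hi - self.lo + 1))


def full_layout(M: int, N: int) -> ConstraintLayout:
    """Layout admitting every cell (dense, unconstrained DTW)."""
    return build_layout([], r=0, band=None, M=M, N=N)


def build_layout(
    anchors: Sequence[tuple[int, int]],
    r: int,
    band: Optional[tuple[float, str]],
    M: int,
    N: int,
) -> ConstraintLayout:
    """Construct the admissible-cell layout from anchors and a band.

    ``anchors`` are 0-based (scan in A, scan in B) pairs, assumed already
    monotone (see :func:`filter_anchors`); ``r`` is the flexibility radius
    in scans around each anchor cell (r = 0 forces the path through the
    anchors); ``band`` is ``None`` for no band or ``(w, scope)`` with
    0 < w <= 1 a fraction of max(M, N) scans and scope ``"global"`` (one
    band over the whole matrix) or ``"local"`` (one band per inter-anchor
    partition).  Rows are minimally widened afterwards so consecutive rows
    stay reachable under the DTW moves.
    """
    if M < 1 or N < 1:
        raise ValueError("series must be non-empty")
    if band is not None:
        w, scope = band
        if not 0 < w <= 1:
            raise ValueError("band width must lie in (0, 1]")
        if scope not in ("global", "local"):
            raise ValueError("band scope must be 'global' or 'local'")
    cells = [(a + 1, b + 1) for a, b in anchors]
    for (i0, j0), (i1, j1) in zip(cells, cells[1:]):
        if i1 <= i0 or j1 <= j0:
            raise ValueError("anchors must be strictly increasing in both coordinates")
    if cells and not (1 <= cells[0][0] <= M and 1 <= cells[0][1] <= N
                      and cells[-1][0] <= M and cells[-1][1] <= N):
        raise ValueError("anchor indices out of range")

    lo = np.full(M + 1, N + 1, dtype=int)
    hi = np.full(M + 1, -1, dtype=int)

    def admit(i: int, a: int, b: int) -> None:
        lo[i] = min(lo[i], a)
        hi[i] = max(hi[i], b)

    anchor_rows: set[int] = set()
    for ai, aj in cells:
        for i in range(max(0, ai - r), min(M, ai + r) + 1):
            anchor_rows.add(i)

    nodes = [(0, 0)] + cells + [(M, N)]
    for (i0, j0), (i1, j1) in zip(nodes, nodes[1:]):
        di, dj = i1 - i0, j1 - j0
        if band is not None and scope == "local":
            w_cells = max(1, math.ceil(w * max(di, dj, 1)))
        else:
            w_cells = None
        for i in range(i0, i1 + 1):
            if i in anchor_rows:
                continue
            if w_cells is None or di == 0:
                a, b = j0, j1
            else:
                # fixed-width window containing the partition diagonal,
                # shifted (not truncated) to fit inside the rectangle
                c = j0 + round(dj * (i - i0) / di)
                j0c = max(j0, 1)  # column 0 only holds the origin cell
                a = min(max(c - (w_cells - 1) // 2, j0c),
                        max(j0c, j1 - w_cells + 1))
                b = min(j1, a + w_cells - 1)
            admit(i, a, b)

    if band is not None and scope == "global":
        w_cells = max(1, math.ceil(w * max(M, N)))
        for i in range(M + 1):
            if i in anchor_rows:
                continue
            c = round(i * N / M)
            a = min(max(c - (w_cells - 1) // 2, 1), max(1, N - w_cells + 1))
            b = min(N, a + w_cells - 1)
            lo[i] = max(lo[i], a)
            hi[i] = min(hi[i], b)

    # anchor rows admit exactly the radius box (pinched at r = 0)
    for ai, aj in cells:
        for i in range(max(0, ai - r), min(M, ai + r) + 1):
            admit(i, max(0, aj - r), min(N, aj + r))

    # boundary rows: only (0,0) lives in row 0; column 0 is closed above it
    lo[0], hi[0] = 0, 0
    lo[1:] = np.clip(lo[1:], 1, N)
    hi[1:] = np.clip(hi[1:], 1, N)
    hi = np.maximum(hi, lo)
    hi[M] = max(hi[M], N)
    lo[M] = min(lo[M], N)

    # monotone bounds, then minimal widening for diagonal connectivity
    lo = np.maximum.accumulate(lo)
    hi = np.maximum.accumulate(hi)
    for i in range(1, M + 1):
        if lo[i] > hi[i - 1] + 1:
            lo[i] = hi[i - 1] + 1
        if hi[i] < lo[i - 1]:
            hi[i] = lo[i - 1]

    layout = ConstraintLayout(M=M, N=N, lo=lo, hi=hi, anchors=list(anchors))
    if not (layout.contains(0, 0) and layout.contains(M, N)):
        raise ValueError("constraint layout disconnects (0,0) from (M,N)")
    if np.any(layout.lo > layout.hi):
        raise ValueError("constraint layout contains an empty row")
    return layout


class PartitionedArray:
    """Row-compressed storage of a partitioned DP matrix.

    All admissible cells live contiguously in a linear array ``d``;
    ``idx[i]`` is the offset of row i and ``len[i]`` its stored-cell
    count, so cell (i, j) sits at ``d[idx[i] + (j - lo[i])]``.  Reading an
    unstored cell returns ``default_value``; writing one is a no-op (the
    layout is fixed before initialization).
    """

    def __init__(self, layout: ConstraintLayout, default_value: float = -np.inf,
                 dtype=float):
        self.layout = layout
        self.default_value = default_value
        self.len = (layout.hi - layout.lo + 1).astype(int)
        self.idx = np.concatenate([[0], np.cumsum(self.len[:-1])])
        self.d = np.full(int(self.len.sum()), default_value, dtype=dtype)

    def get(self, i: int, j: int):
        lay = self.layout
        if 0 <= i <= lay.M and lay.lo[i] <= j <= lay.hi[i]:
            return self.d[self.idx[i] + (j - lay.lo[i])]
        return self.default_value

    def set(self, i: int, j: int, value) -> None:
        lay = self.layout
        if 0 <= i <= lay.M and lay.lo[i] <= j <= lay.hi[i]:
            self.d[self.idx[i] + (j - lay.lo[i])] = value

    def row(self, i: int) -> np.ndarray:
        """View of the stored cells of row i (columns lo[i]..hi[i])."""
        return self.d[self.idx[i]: self.idx[i] + self.len[i]]


@dataclass
class AlignmentPath:
    """An optimal warping path with its scores.

    ``pairs`` are 1-based (i, j) matrix coordinates from (1, 1) to (M, N);
    ``moves`` name each step's type (the first cell counts as a match, the
    forced alignment of a_1 with b_1); ``score`` is Q(M, N) and
    ``corrected_score`` is score divided by the summed step weights, a
    per-step average similarity comparable across series lengths.
    """

    pairs: list[tuple[int, int]]
    moves: list[str]
    score: float
    corrected_score: float
    similarities: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def _row_similarities(prepped_a, prepped_b, i, j0, j1, cfg, a_rt, b_rts, kind):
    """f(a_i, b_j) for j in [j0, j1] (1-based matrix coords), vectorized."""
    seg = pairwise_matrix(prepped_a[i - 1: i], prepped_b[j0 - 1: j1], kind)[0]
    if cfg.use_rt_penalty and a_rt is not None and b_rts is not None:
        pen = rt_penalty(a_rt, b_rts[j0 - 1: j1], cfg.D)
        seg = np.where(pen >= cfg.T, seg * pen, 0.0)
    return seg


def dtw_align(
    A: np.ndarray,
    B: np.ndarray,
    cfg: SimilarityConfig,
    wts: DTWWeights,
    layout: Optional[ConstraintLayout] = None,
    a_rts: Optional[np.ndarray] = None,
    b_rts: Optional[np.ndarray] = None,
) -> AlignmentPath:
    """Optimal constrained DTW alignment of two scan series.

    ``A`` (M x L) and ``B`` (N x L) are stacks of binned spectra; when the
    similarity config enables the RT penalty, per-scan retention times must
    be supplied and cells whose penalty falls below T contribute
    similarity 0 (their spectral term is skipped).  Traceback prefers
    match over compression over expansion on ties, keeping paths
    deterministic and diagonal-leaning.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    M, N = A.shape[0], B.shape[0]
    if M < 1 or N < 1:
        raise ValueError("both series must be non-empty")
    if layout is None:
        layout = full_layout(M, N)
    if (layout.M, layout.N) != (M, N):
        raise ValueError("layout shape does not match the series")
    if cfg.use_rt_penalty and (a_rts is None or b_rts is None):
        raise ValueError("RT penalty requires scan retention times")

    pa = prepare_vectors(A, cfg.kind)
    pb = prepare_vectors(B, cfg.kind)
    Q = PartitionedArray(layout, default_value=-np.inf)
    moves = PartitionedArray(layout, default_value=0, dtype=np.uint8)
    Q.set(0, 0, 0.0)
    wm, wc, we = wts.w_match, wts.w_comp, wts.w_exp

    for i in range(1, M + 1):
        j0, j1 = int(layout.lo[i]), int(layout.hi[i])
        f_seg = _row_similarities(
            pa, pb, i, j0, j1, cfg,
            None if a_rts is None else float(a_rts[i - 1]), b_rts, cfg.kind,
        )
        qrow = Q.row(i)
        mrow = moves.row(i)
        for k, j in enumerate(range(j0, j1 + 1)):
            f = f_seg[k]
            diag = Q.get(i - 1, j - 1) + wm * f
            comp = (qrow[k - 1] if k > 0 else Q.get(i, j - 1)) + wc * f
            expn = Q.get(i - 1, j) + we * f
            # tie preference: match > compression > expansion
            if diag >= comp and diag >= expn:
                qrow[k], mrow[k] = diag, _MATCH
            elif comp >= expn:
                qrow[k], mrow[k] = comp, _COMP
            else:
                qrow[k], mrow[k] = expn, _EXP

    score = float(Q.get(M, N))
    if not np.isfinite(score):
        raise ValueError("no admissible warping path reaches (M, N)")

    # traceback
    names = {_MATCH: "match", _COMP: "compression", _EXP: "expansion"}
    i, j = M, N
    rpairs: list[tuple[int, int]] = []
    rmoves: list[str] = []
    while True:
        rpairs.append((i, j))
        mv = int(moves.get(i, j))
        rmoves.append(names[mv])
        if (i, j) == (1, 1):
            break
        if mv == _MATCH:
            i, j = i - 1, j - 1
        elif mv == _COMP:
            j -= 1
        else:
            i -= 1
    rpairs.reverse()
    rmoves.reverse()

    sims = np.array([
        float(_row_similarities(
            pa, pb, pi, pj, pj, cfg,
            None if a_rts is None else float(a_rts[pi - 1]), b_rts, cfg.kind,
        )[0])
        for pi, pj in rpairs
    ])
    wsum = sum({"match": wm, "compression": wc, "expansion": we}[m] for m in rmoves)
    return AlignmentPath(
        pairs=rpairs,
        moves=rmoves,
        score=score,
        corrected_score=score / wsum,
        similarities=sims,
    )


def similarity_maxima(values: Sequence[float]) -> list[int]:
    """Indices of strict local maxima of a sequence (plateaus report their
    first index; endpoints qualify with a single neighbor)."""
    v = list(values)
    if not v:
        return []
    runs: list[tuple[int, float]] = []  # (first index, value)
    for k, x in enumerate(v):
        if not runs or runs[-1][1] != x:
            runs.append((k, x))
    out = []
    for k, (start, x) in enumerate(runs):
        left_ok = k == 0 or runs[k - 1][1] < x
        right_ok = k == len(runs) - 1 or runs[k + 1][1] < x
        if left_ok and right_ok:
            out.append(start)
    return out


def extract_similarity_maxima(path: AlignmentPath) -> list[tuple[int, int]]:
    """Path positions where the similarity along the alignment trace is a
    local maximum — the aligned, highly similar mass spectra."""
    return [path.pairs[k] for k in similarity_maxima(path.similarities)]


def select_center(scores: np.ndarray) -> int:
    """Center-star reference: argmax of summed off-diagonal scores.

    Ties resolve to the lowest index (np.argmax convention)."""
    scores = np.asarray(scores, dtype=float)
    K = scores.shape[0]
    if K < 2 or scores.shape != (K, K):
        raise ValueError("need a K x K score matrix with K >= 2")
    sums = scores.sum(axis=1) - np.diag(scores)
    return int(np.argmax(sums))


def anchors_from_table(table: MultipleAlignmentTable) -> dict:
    """Convert a peak-clique alignment table to per-pair anchor lists.

    Each row yields one anchor (scan_a, scan_b) for every pair of
    chromatograms in which the row is present; chromatograms absent from a
    clique get no anchors from it.  Keys are ``(id_a, id_b)`` with
    ``id_a`` preceding ``id_b`` in the table's column order.
    """
    ids = table.chromatogram_ids
    anchors: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in table.rows:
        present = [cid for cid in ids if row.get(cid) is not None]
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                a, b = present[x], present[y]
                anchors.setdefault((a, b), []).append((row[a], row[b]))
    return anchors


@dataclass
class CemappResult:
    """Outcome of a center-star multiple DTW alignment."""

    table: MultipleAlignmentTable
    center_index: int
    center_id: str
    pairwise_scores: np.ndarray
    paths: dict[str, AlignmentPath]
    aux_ranges: list[dict]
    stored_cells: int


def _pair_anchors(anchors, id_a: str, id_b: str) -> list[tuple[int, int]]:
    if not anchors:
        return []
    if (id_a, id_b) in anchors:
        return [(a, b) for a, b in anchors[(id_a, id_b)]]
    if (id_b, id_a) in anchors:
        return [(b, a) for a, b in anchors[(id_b, id_a)]]
    return []


def _invert_path(path: AlignmentPath) -> AlignmentPath:
    swap = {"match": "match", "compression": "expansion", "expansion": "compression"}
    return AlignmentPath(
        pairs=[(j, i) for i, j in path.pairs],
        moves=[swap[m] for m in path.moves],
        score=path.score,
        corrected_score=path.corrected_score,
        similarities=path.similarities,
    )


def cemapp_dtw_align(
    chroms: list[Chromatogram],
    cfg: SimilarityConfig,
    wts: DTWWeights = DTWWeights(),
    band: Optional[tuple[float, str]] = (0.1, "local"),
    anchors: Optional[dict] = None,
    r: int = 0,
) -> CemappResult:
    """Center-star multiple alignment of whole scan series.

    All pairwise weight-corrected DTW scores are computed first (reusing
    anchor constraints when given), the chromatogram with the highest
    summed score becomes the reference, and every other chromatogram's
    path to it fills one table column.  Each table row corresponds to one
    reference scan; when several scans of another chromatogram map to the
    same reference scan, the cell records the scan with maximal similarity
    to the reference scan and the full mapped range is kept per row in
    ``aux_ranges``.  The table never contains absent entries.
    """
    K = len(chroms)
    if K < 2:
        raise ValueError("need at least two chromatograms")
    for c in chroms:
        if c.scans is None:
            raise ValueError(f"chromatogram {c.id!r} has no scan series")
    ids = [c.id for c in chroms]
    symmetric = wts.w_comp == wts.w_exp

    scores = np.zeros((K, K))
    paths: dict[tuple[int, int], AlignmentPath] = {}
    stored = 0
    for i in range(K):
        for j in range(i + 1, K):
            pa = filter_anchors(_pair_anchors(anchors, ids[i], ids[j]))
            lay = build_layout(pa, r=r, band=band,
                               M=chroms[i].n_scans, N=chroms[j].n_scans)
            stored += lay.n_cells
            path = dtw_align(
                chroms[i].scans, chroms[j].scans, cfg, wts, lay,
                a_rts=chroms[i].scan_rts, b_rts=chroms[j].scan_rts,
            )
            paths[(i, j)] = path
            scores[i, j] = scores[j, i] = path.corrected_score

    center = select_center(scores)
    cen = chroms[center]
    M = cen.n_scans

    center_paths: dict[str, AlignmentPath] = {}
    for k in range(K):
        if k == center:
            continue
        key = (center, k) if center < k else (k, center)
        path = paths[key]
        if key[0] != center:
            if symmetric:
                path = _invert_path(path)
            else:
                pa = filter_anchors(_pair_anchors(anchors, ids[center], ids[k]))
                lay = build_layout(pa, r=r, band=band,
                                   M=M, N=chroms[k].n_scans)
                stored += lay.n_cells
                path = dtw_align(
                    cen.scans, chroms[k].scans, cfg, wts, lay,
                    a_rts=cen.scan_rts, b_rts=chroms[k].scan_rts,
                )
        center_paths[ids[k]] = path

    # assemble the dense table: one row per center scan
    mapped: dict[str, list[list[int]]] = {
        cid: [[] for _ in range(M)] for cid in center_paths
    }
    best: dict[str, list[int]] = {}
    for cid, path in center_paths.items():
        sims = path.similarities
        choice = [(-np.inf, -1)] * M
        for (pi, pj), s in zip(path.pairs, sims):
            mapped[cid][pi - 1].append(pj - 1)
            if s > choice[pi - 1][0]:
                choice[pi - 1] = (s, pj - 1)
        best[cid] = [c[1] for c in choice]

    rows, med_rts, aux = [], [], []
    for i in range(M):
        row = {ids[center]: i}
        ranges = {}
        for cid in center_paths:
            row[cid] = best[cid][i]
            js = mapped[cid][i]
            ranges[cid] = (min(js), max(js))
        rows.append(row)
        aux.append(ranges)
        med_rts.append(
            float(cen.scan_rts[i]) if cen.scan_rts is not None else float(i)
        )
    table = MultipleAlignmentTable(
        chromatogram_ids=ids, rows=rows, row_median_rt=med_rts
    )
    return CemappResult(
        table=table,
        center_index=center,
        center_id=ids[center],
        pairwise_scores=scores,
        paths=center_paths,
        aux_ranges=aux,
        stored_cells=stored,
    )
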