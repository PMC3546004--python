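"""Multiple peak alignment via bidirectional best hits and clique merging.

Peaks from K chromatograms form a K-partite similarity graph: vertices are
peaks, partitions are chromatograms, and edge weights are the RT-penalized
spectral similarity f.  Enumerating cliques of the full weighted graph is
NP-hard, so the graph is pruned in two steps:

1. For every peak, keep only its best hit (argmax of f) in each *other*
   chromatogram — at most K - 1 hits per peak.  Pairs whose RT penalty
   falls below the threshold T never enter candidacy.
2. Keep only *bidirectional* best hits (BBHs): pairs (p, q) where each is
   the other's best hit.  On the resulting unweighted K-partite graph the
   maximum vertex degree is at most K - 1 and maximal cliques can be found
   greedily in polynomial time.

BBH edges are then merged into cliques of mutually-best-hitting peaks, at
most one peak per chromatogram.  Cliques with at least ``mcs`` members
(minimum clique size) become rows of the multiple peak alignment, ordered
by their median retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromdata import ABSENT, Chromatogram, MultipleAlignmentTable
from .similarity import SimilarityConfig, pairwise_matrix, prepare_vectors, rt_penalty

__all__ = [
    "PeakRef",
    "BestHitStore",
    "BBHGraph",
    "Clique",
    "compute_best_hits",
    "find_bbhs",
    "merge_cliques",
    "bipace_align",
]

#: A peak is referenced as (chromatogram position, peak position).
PeakRef = tuple[int, int]


@dataclass
class BestHitStore:
    """Per-peak best hits: for peak (ci, pi), ``hits[(ci, pi)][cj]`` is
    ``(pj, similarity, |Δrt|)`` for the best-matching peak in chromatogram
    cj — at most K - 1 entries per peak.  ``pruned_pairs`` counts ordered
    peak pairs excluded by the RT-penalty threshold."""

    n_chromatograms: int
    hits: dict[PeakRef, dict[int, tuple[int, float, float]]] = field(default_factory=dict)
    pruned_pairs: int = 0
    evaluated_pairs: int = 0


@dataclass
class BBHGraph:
    """Unweighted K-partite graph of bidirectional best hits.

    ``edges`` maps each unordered BBH pair (as a sorted tuple of PeakRefs)
    to ``(similarity, |Δrt|)``; ``adjacency`` maps each participating peak
    to the set of its BBH partners.
    """

    edges: dict[tuple[PeakRef, PeakRef], tuple[float, float]] = field(default_factory=dict)
    adjacency: dict[PeakRef, set[PeakRef]] = field(default_factory=dict)

    def has_edge(self, p: PeakRef, q: PeakRef) -> bool:
        return q in self.adjacency.get(p, ())


@dataclass
class Clique:
    """A set of peaks, at most one per chromatogram, pairwise BBHs."""

    members: set[PeakRef] = field(default_factory=set)

    @property
    def chromatograms(self) -> set[int]:
        return {c for c, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


def _best_in_row(f_row: np.ndarray, drt_row: np.ndarray, valid_row: np.ndarray):
    """Argmax of a similarity row with deterministic tie-breaking:
    highest similarity, then smallest |Δrt|, then lowest peak index."""
    if not valid_row.any():
        return None
    masked = np.where(valid_row, f_row, -np.inf)
    best = masked.max()
    if not np.isfinite(best):
        return None
    cand = np.flatnonzero(masked == best)
    if cand.size > 1:
        cand = cand[drt_row[cand] == drt_row[cand].min()]
    j = int(cand[0])
    return j, float(f_row[j]), float(drt_row[j])


def compute_best_hits(chroms: list[Chromatogram], cfg: SimilarityConfig) -> BestHitStore:
    """All-pairs inter-chromatogram similarities reduced to best-hit sets.

    Only peaks from *different* chromatograms are compared (no
    self-similarities within a run).  Pairs outside the RT window implied
    by the threshold T are pruned before the spectral similarity is
    evaluated and counted in ``pruned_pairs``.
    """
    K = len(chroms)
    if K < 2:
        raise ValueError("need at least two chromatograms")
    ranges = {c.mass_range for c in chroms}
    if len(ranges) != 1:
        raise ValueError(f"chromatograms disagree on mass_range: {ranges}")

    store = BestHitStore(n_chromatograms=K)
    prepped = []
    rts = []
    for c in chroms:
        if not c.peaks:
            prepped.append(np.zeros((0, 1)))
            rts.append(np.zeros(0))
            continue
        X = np.stack([p.intensities for p in c.peaks])
        prepped.append(prepare_vectors(X, cfg.kind))
        rts.append(np.array([p.rt for p in c.peaks]))

    for i in range(K):
        for j in range(i + 1, K):
            if rts[i].size == 0 or rts[j].size == 0:
                continue
            drt = np.abs(rts[i][:, None] - rts[j][None, :])
            if cfg.use_rt_penalty:
                pen = rt_penalty(rts[i][:, None], rts[j][None, :], cfg.D)
                valid = pen >= cfg.T
                store.pruned_pairs += int((~valid).sum())
                if not valid.any():
                    continue
                f = pairwise_matrix(prepped[i], prepped[j], cfg.kind) * pen
                store.evaluated_pairs += int(valid.sum())
            else:
                valid = np.ones(drt.shape, dtype=bool)
                f = pairwise_matrix(prepped[i], prepped[j], cfg.kind)
                store.evaluated_pairs += f.size
            for pi in range(f.shape[0]):
                hit = _best_in_row(f[pi], drt[pi], valid[pi])
                if hit is not None:
                    store.hits.setdefault((i, pi), {})[j] = hit
            for pj in range(f.shape[1]):
                hit = _best_in_row(f[:, pj], drt[:, pj], valid[:, pj])
                if hit is not None:
                    store.hits.setdefault((j, pj), {})[i] = hit
    return store


def find_bbhs(store: BestHitStore) -> BBHGraph:
    """Mutual-argmax pairs of the best-hit store.

    (p, q) is a BBH iff q is p's best hit in q's chromatogram *and* p is
    q's best hit in p's chromatogram.  Once a peak is matched to a
    chromatogram, its remaining (non-mutual) hits toward that chromatogram
    are dead: they can never win a later argmax, which the store realizes
    by simply not re-ranking them.
    """
    g = BBHGraph()
    for (ci, pi), hits in store.hits.items():
        for cj, (pj, sim, drt) in hits.items():
            if cj < ci:
                continue  # handle each unordered pair once
            back = store.hits.get((cj, pj), {}).get(ci)
            if back is not None and back[0] == pi:
                a, b = (ci, pi), (cj, pj)
                g.edges[(a, b)] = (sim, drt)
                g.adjacency.setdefault(a, set()).add(b)
                g.adjacency.setdefault(b, set()).add(a)
    return g


def merge_cliques(g: BBHGraph, K: int) -> list[Clique]:
    """Greedy bottom-up merging of BBH edges into cliques.

    Edges are processed in descending order of similarity (ties by smaller
    |Δrt|, then lexicographic peak reference), so the strongest evidence is
    consumed first.  For each edge, the cliques of its endpoints (a lone
    peak counts as an unassigned singleton) are merged iff the union stays
    a complete BBH subgraph with at most one peak per chromatogram;
    otherwise committed cliques are left untouched and an unassigned peak
    stays free to seed a later clique.  Every peak ends up in at most one
    clique.
    """
    order = sorted(
        g.edges.items(),
        key=lambda kv: (-kv[1][0], kv[1][1], kv[0]),
    )
    clique_of: dict[PeakRef, Clique] = {}
    cliques: list[Clique] = []

    def can_join(peak: PeakRef, clique: Clique) -> bool:
        if (peak[0]) in clique.chromatograms:
            return False
        return all(g.has_edge(peak, m) for m in clique.members)

    for (p, q), _ in order:
        cp, cq = clique_of.get(p), clique_of.get(q)
        if cp is None and cq is None:
            c = Clique(members={p, q})
            cliques.append(c)
            clique_of[p] = clique_of[q] = c
        elif cp is cq:
            continue
        elif cp is None or cq is None:
            lone, c = (p, cq) if cp is None else (q, cp)
            if len(c) < K and can_join(lone, c):
                c.members.add(lone)
                clique_of[lone] = c
        else:
            if cp.chromatograms & cq.chromatograms:
                continue
            if len(cp) + len(cq) > K:
                continue
            if all(g.has_edge(a, b) for a in cp.members for b in cq.members):
                cp.members |= cq.members
                for m in cq.members:
                    clique_of[m] = cp
                cq.members = set()
    return [c for c in cliques if len(c) >= 2]


def bipace_align(
    chroms: list[Chromatogram],
    cfg: SimilarityConfig,
    mcs: int = 2,
    *,
    return_details: bool = False,
):
    """Run the full peak-clique pipeline and build the alignment table.

    Cliques with fewer than ``mcs`` members are dropped; each surviving
    clique becomes one table row holding the apex scan index of its member
    peak per chromatogram (ABSENT where the clique has no member), and rows
    are ordered by the median retention time of their members.
    """
    K = len(chroms)
    if not 2 <= mcs <= K:
        raise ValueError(f"mcs must lie in [2, {K}], got {mcs}")
    store = compute_best_hits(chroms, cfg)
    g = find_bbhs(store)
    cliques = merge_cliques(g, K)
    kept = [c for c in cliques if len(c) >= mcs]

    ids = [c.id for c in chroms]
    rows, med_rts = [], []
    for c in kept:
        row = {cid: ABSENT for cid in ids}
        rts = []
        for ci, pi in c.members:
            peak = chroms[ci].peaks[pi]
            row[ids[ci]] = peak.apex_scan
            rts.append(peak.rt)
        rows.append(row)
        med_rts.append(float(np.median(rts)))
    table = MultipleAlignmentTable(
        chromatogram_ids=ids, rows=rows, row_median_rt=med_rts
    ).sorted_by_median_rt()
    if return_details:
        return table, {"store": store, "bbh_graph": g, "cliques": cliques}
    return table
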