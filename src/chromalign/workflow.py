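"""Parameter sweeps and the three-way evaluation workflow.

Three configurations are orchestrated: the peak-clique alignment alone,
the DTW profile alignment alone, and the hybrid in which the best
(highest-F1) peak-clique table supplies anchors that partition the DTW
search space.  Sweeps are plain Cartesian grids over the documented
parameters; each parameterization yields one row of an evaluation table
(parameters + confusion counts + metrics), and the best-by-criterion
alignment is kept for anchor use.  Results are a pure function of the
data, the grid and the seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .bipace import bipace_align
from .cemapp_dtw import DTWWeights, anchors_from_table, cemapp_dtw_align
from .chromdata import Chromatogram, MultipleAlignmentTable
from .evaluation import evaluate_alignment
from .similarity import SimilarityConfig

__all__ = ["SweepSpec", "run_bipace_sweep", "run_cemapp_sweep", "run_hybrid",
           "run_workflow"]


@dataclass
class SweepSpec:
    """Cartesian parameter grid for the two aligners.

    Peak-clique axes: similarity kind, RT-penalty on/off, D, T, MCS.
    DTW axes: match weight W, band width BC, band scope, anchor radius R,
    anchors on/off.  The selection criterion is F1 in peak mode and TP in
    profile mode.
    """

    kinds: list[str] = field(default_factory=lambda: ["cosine"])
    use_rt_penalty: list[bool] = field(default_factory=lambda: [True])
    D: list[float] = field(default_factory=lambda: [2.5])
    T: list[float] = field(default_factory=lambda: [0.0])
    mcs: list[int] = field(default_factory=lambda: [2])
    match_weight: list[float] = field(default_factory=lambda: [2.25])
    band_width: list[float] = field(default_factory=lambda: [0.1])
    band_scope: list[str] = field(default_factory=lambda: ["local"])
    anchor_radius: list[int] = field(default_factory=lambda: [0])
    tolerance_scans: int = 0

    def bipace_grid(self):
        return itertools.product(self.kinds, self.use_rt_penalty, self.D,
                                 self.T, self.mcs)

    def cemapp_grid(self):
        return itertools.product(self.kinds, self.use_rt_penalty, self.D,
                                 self.T, self.match_weight, self.band_width,
                                 self.band_scope, self.anchor_radius)


def run_bipace_sweep(
    chroms: list[Chromatogram],
    truth: MultipleAlignmentTable,
    sweep: SweepSpec,
):
    """Evaluate every peak-clique parameterization against the truth.

    Returns ``(results DataFrame, best alignment table by F1)``; the best
    table is the one the hybrid configuration uses as anchors.
    """
    rows = []
    best_f1, best_table = -1.0, None
    for kind, pen, D, T, mcs in sweep.bipace_grid():
        cfg = SimilarityConfig(kind=kind, use_rt_penalty=pen, D=D, T=T)
        table = bipace_align(chroms, cfg, mcs=mcs)
        ev = evaluate_alignment(table, truth, tolerance=sweep.tolerance_scans,
                                mode="peak")
        rows.append({"kind": kind, "use_rt_penalty": pen, "D": D, "T": T,
                     "MCS": mcs, **ev})
        f1 = ev["f1"] if ev["f1"] is not None else -1.0
        if f1 > best_f1:
            best_f1, best_table = f1, table
    return pd.DataFrame(rows), best_table


def run_cemapp_sweep(
    chroms: list[Chromatogram],
    truth: MultipleAlignmentTable,
    sweep: SweepSpec,
    anchors: Optional[dict] = None,
):
    """Evaluate every DTW parameterization (profile mode: TP/FP only)."""
    rows = []
    for kind, pen, D, T, W, bc, scope, r in sweep.cemapp_grid():
        cfg = SimilarityConfig(kind=kind, use_rt_penalty=pen, D=D, T=T)
        res = cemapp_dtw_align(chroms, cfg, DTWWeights(w_match=W),
                               band=(bc, scope), anchors=anchors, r=r)
        ev = evaluate_alignment(res.table, truth,
                                tolerance=sweep.tolerance_scans,
                                mode="profile")
        rows.append({"kind": kind, "use_rt_penalty": pen, "D": D, "T": T,
                     "W": W, "BC": bc, "scope": scope, "R": r,
                     "anchors": anchors is not None,
                     "stored_cells": res.stored_cells,
                     "center": res.center_id, **ev})
    return pd.DataFrame(rows)


def run_hybrid(
    chroms: list[Chromatogram],
    truth: MultipleAlignmentTable,
    bipace_table: MultipleAlignmentTable,
    cfg: SimilarityConfig,
    wts: DTWWeights = DTWWeights(),
    band: Optional[tuple[float, str]] = (0.1, "local"),
    r: int = 0,
    tolerance: int = 0,
):
    """DTW profile alignment constrained by peak-clique anchors.

    A clique row covering only a subset of chromatograms contributes
    anchors only to pairs within that subset.  Returns the alignment
    result plus its profile-mode evaluation (TP/FP and unassignable
    rows)."""
    anchors = anchors_from_table(bipace_table) if len(bipace_table) else None
    res = cemapp_dtw_align(chroms, cfg, wts, band=band, anchors=anchors, r=r)
    ev = evaluate_alignment(res.table, truth, tolerance=tolerance,
                            mode="profile")
    return res, ev


def run_workflow(config: dict, chroms: list[Chromatogram],
                 truth: MultipleAlignmentTable) -> dict:
    """Drive the three evaluation configurations from a config mapping.

    ``config`` mirrors the YAML layout: optional ``sweep`` section with
    the grid axes, ``cemapp_dtw`` section with the DTW parameters used for
    the anchor-free and hybrid runs.  Returns the sweep table, the two
    profile evaluations and the stored-cell counts.
    """
    sweep = SweepSpec(**config.get("sweep", {}))
    bipace_df, best_table = run_bipace_sweep(chroms, truth, sweep)

    dtw_cfg = config.get("cemapp_dtw", {})
    cfg = SimilarityConfig(
        kind=dtw_cfg.get("kind", "dot"),
        use_rt_penalty=dtw_cfg.get("use_rt_penalty", True),
        D=dtw_cfg.get("D", 2.5),
        T=dtw_cfg.get("T", 0.0),
    )
    wts = DTWWeights(w_match=dtw_cfg.get("match_weight", 2.25))
    band = (dtw_cfg.get("band_width", 0.1), dtw_cfg.get("band_scope", "local"))
    r = dtw_cfg.get("anchor_radius", 0)
    tol = sweep.tolerance_scans

    free_res, free_ev = run_hybrid(
        chroms, truth,
        MultipleAlignmentTable(truth.chromatogram_ids, [], []),
        cfg, wts, band=band, r=r, tolerance=tol,
    )
    hyb_res, hyb_ev = run_hybrid(chroms, truth, best_table, cfg, wts,
                                 band=band, r=r, tolerance=tol)
    return {
        "bipace_results": bipace_df,
        "bipace_best_table": best_table,
        "cemapp_free": {"result": free_res, "eval": free_ev},
        "cemapp_hybrid": {"result": hyb_res, "eval": hyb_ev},
    }
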