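"""Synthetic GC-MS chromatogram generator with known ground truth.

Emulates K chromatograms that share a set of planted peak groups: each
group has a sparse EI-like fragment spectrum (its template) and a
reference retention time; each chromatogram observes the group at a
smoothly, monotonically warped retention time — the locally
order-preserving nonlinear RT distortion real columns exhibit — with a
lognormal intensity factor, Gaussian spectral noise and optional dropout.
Scan matrices are built from Gaussian elution profiles over an even scan
grid plus a flat baseline.  The generator returns the true multiple peak
alignment and the warp functions themselves, so both peak-clique and
profile alignments can be scored exactly.

Everything is deterministic under the configured seed; per-chromatogram
substreams are spawned from it with fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .chromdata import ABSENT, Chromatogram, MultipleAlignmentTable, Peak

__all__ = ["SynthConfig", "Warp", "SynthResult", "make_templates", "make_warp",
           "generate", "write_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic dataset.

    Defaults describe a desk-scale experiment shaped like a small GC-MS
    batch: 5 runs of 600 scans over a 600 s separation, 50 shared
    compounds over the 50-550 Da nominal-mass range, warps of up to 10 s
    (real batches in this field show deviations up to tens of seconds),
    30% intensity CV between runs and mild spectral noise.
    """

    K: int = 5
    n_groups: int = 50
    mass_range: tuple[int, int] = (50, 550)
    scans_per_chrom: int = 600
    rt_span: float = 600.0
    warp_amplitude: float = 10.0
    warp_knots: int = 4
    dropout_prob: float = 0.0
    intensity_cv: float = 0.3
    spectral_noise_sd: float = 0.01
    baseline_level: float = 0.005
    peak_sigma_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.warp_amplitude < 0:
            raise ValueError("warp_amplitude must be non-negative")
        if self.K < 1 or self.n_groups < 1:
            raise ValueError("K and n_groups must be positive")


class Warp:
    """A strictly increasing RT mapping reference -> observed, tabulated on
    a fine grid for cheap evaluation and inversion."""

    def __init__(self, grid_t: np.ndarray, grid_y: np.ndarray):
        if np.any(np.diff(grid_y) <= 0):
            raise ValueError("warp must be strictly increasing")
        self._t = grid_t
        self._y = grid_y

    def __call__(self, t):
        return np.interp(t, self._t, self._y)

    def inverse(self, y):
        return np.interp(y, self._y, self._t)

    @property
    def max_shift(self) -> float:
        return float(np.max(np.abs(self._y - self._t)))


def make_templates(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Draw spectral templates and reference retention times.

    Each template is a sparse non-negative unit-norm vector with 5-30
    nonzero fragment bins; templates are rejection-sampled so that no two
    have cosine >= 0.95 (distinct compounds must be distinguishable).
    Reference RTs sit on a jittered grid over the central 90% of the run,
    which guarantees a minimum spacing.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.mass_range
    n_bins = hi - lo + 1
    templates: list[np.ndarray] = []
    tries = 0
    while len(templates) < cfg.n_groups:
        tries += 1
        if tries > 100 * cfg.n_groups:
            raise RuntimeError("template rejection sampling failed to converge")
        k = int(rng.integers(5, 31))
        t = np.zeros(n_bins)
        pos = rng.choice(n_bins, size=k, replace=False)
        t[pos] = rng.uniform(0.05, 1.0, size=k)
        t /= np.linalg.norm(t)
        if all(float(t @ u) < 0.95 for u in templates):
            templates.append(t)

    t0, t1 = 0.05 * cfg.rt_span, 0.95 * cfg.rt_span
    step = (t1 - t0) / cfg.n_groups
    if step <= 4.0 * cfg.peak_sigma_s:
        raise ValueError(
            "rt_span too crowded: group spacing must exceed 4 peak widths"
        )
    base = t0 + (np.arange(cfg.n_groups) + 0.5) * step
    rts = base + rng.uniform(-0.2, 0.2, size=cfg.n_groups) * step
    return templates, rts


def make_warp(cfg: SynthConfig, chrom_index: int,
              rng: np.random.Generator | None = None) -> Warp:
    """Monotone smooth RT distortion for one chromatogram.

    Chromatogram 0 is the undistorted reference.  Others get a monotone
    piecewise-cubic (PCHIP) shift through ``warp_knots`` random offsets
    bounded by ``warp_amplitude``, pinned to zero at both run ends; PCHIP
    never overshoots its data, so the maximum absolute shift stays within
    the amplitude.  Offsets are halved and redrawn into monotonicity if an
    extreme draw would fold time back on itself.
    """
    grid = np.linspace(0.0, cfg.rt_span, 2048)
    if chrom_index == 0 or cfg.warp_amplitude == 0:
        return Warp(grid, grid.copy())
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1, chrom_index])
    knot_t = np.linspace(0.0, cfg.rt_span, cfg.warp_knots + 2)
    offsets = np.zeros(cfg.warp_knots + 2)
    offsets[1:-1] = rng.uniform(-cfg.warp_amplitude, cfg.warp_amplitude,
                                size=cfg.warp_knots)
    for _ in range(20):
        shift = PchipInterpolator(knot_t, offsets)
        y = grid + shift(grid)
        if np.all(np.diff(y) > 0):
            return Warp(grid, y)
        offsets[1:-1] *= 0.5
    raise RuntimeError("could not construct a monotone warp")  # pragma: no cover


@dataclass
class SynthResult:
    """A generated dataset plus everything needed to score against it."""

    chromatograms: list[Chromatogram]
    truth: MultipleAlignmentTable
    warps: list[Warp]
    templates: list[np.ndarray]
    reference_rts: np.ndarray
    config: SynthConfig

    def true_scan_map(self, center: int, other: int) -> np.ndarray:
        """For every scan of chromatogram ``center``, the scan index of
        ``other`` that observes the same reference time under the true
        warps."""
        cen = self.chromatograms[center]
        oth = self.chromatograms[other]
        ref_t = self.warps[center].inverse(cen.scan_rts)
        obs_t = self.warps[other](ref_t)
        dt = oth.scan_rts[1] - oth.scan_rts[0]
        idx = np.rint((obs_t - oth.scan_rts[0]) / dt).astype(int)
        return np.clip(idx, 0, oth.n_scans - 1)


def generate(cfg: SynthConfig) -> SynthResult:
    """Generate K chromatograms with peaks, scans and the true alignment."""
    templates, ref_rts = make_templates(cfg)
    warps = [make_warp(cfg, k) for k in range(cfg.K)]

    rng_presence = np.random.default_rng([cfg.seed, 3])
    present = rng_presence.uniform(size=(cfg.n_groups, cfg.K)) >= cfg.dropout_prob
    for g in range(cfg.n_groups):
        if not present[g].any():
            present[g, int(rng_presence.integers(cfg.K))] = True

    scan_rts = np.linspace(0.0, cfg.rt_span, cfg.scans_per_chrom)
    sigma = cfg.peak_sigma_s
    ln_sigma = math.sqrt(math.log(1.0 + cfg.intensity_cv ** 2))
    n_bins = cfg.mass_range[1] - cfg.mass_range[0] + 1

    chroms: list[Chromatogram] = []
    apex_of = np.full((cfg.n_groups, cfg.K), -1, dtype=int)
    obs_rt = np.full((cfg.n_groups, cfg.K), np.nan)
    for k in range(cfg.K):
        rng = np.random.default_rng([cfg.seed, 2, k])
        scans = np.full((cfg.scans_per_chrom, n_bins), cfg.baseline_level)
        for g in range(cfg.n_groups):
            amp = math.exp(rng.normal(0.0, ln_sigma))
            noise = rng.normal(0.0, cfg.spectral_noise_sd, size=n_bins)
            if not present[g, k]:
                continue
            rt = float(warps[k](ref_rts[g]))
            spectrum = np.clip(templates[g] * amp + noise, 0.0, None)
            shape = np.exp(-((scan_rts - rt) ** 2) / (2.0 * sigma * sigma))
            scans += np.outer(shape, spectrum)
            apex = int(np.argmin(np.abs(scan_rts - rt)))
            apex_of[g, k] = apex
            obs_rt[g, k] = scan_rts[apex]
        apexes = sorted(a for a in apex_of[:, k] if a >= 0)
        peaks = [
            Peak(
                chromatogram_id=f"C{k}",
                index=i,
                apex_scan=a,
                mass_bins=np.arange(cfg.mass_range[0], cfg.mass_range[1] + 1),
                intensities=scans[a].copy(),
                rt=float(scan_rts[a]),
            )
            for i, a in enumerate(apexes)
        ]
        chroms.append(Chromatogram(
            id=f"C{k}", peaks=peaks, scans=scans, scan_rts=scan_rts.copy(),
            mass_range=cfg.mass_range,
        ))

    ids = [c.id for c in chroms]
    rows, med = [], []
    for g in range(cfg.n_groups):
        row = {
            ids[k]: (int(apex_of[g, k]) if present[g, k] else ABSENT)
            for k in range(cfg.K)
        }
        rows.append(row)
        med.append(float(np.nanmedian(obs_rt[g])))
    truth = MultipleAlignmentTable(
        chromatogram_ids=ids, rows=rows, row_median_rt=med
    ).sorted_by_median_rt()
    return SynthResult(
        chromatograms=chroms, truth=truth, warps=warps,
        templates=templates, reference_rts=ref_rts, config=cfg,
    )


def write_dataset(result: SynthResult, out_dir) -> None:
    """Write scan-matrix TSVs, peak-list TSVs and truth.tsv to a directory."""
    from .chromdata import write_peak_list, write_scan_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in result.chromatograms:
        write_scan_matrix(out / f"{c.id}_scans.tsv", c)
        write_peak_list(out / f"{c.id}_peaks.tsv", c)
    result.truth.to_tsv(out / "truth.tsv")
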