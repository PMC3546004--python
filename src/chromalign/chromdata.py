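"""Domain types and I/O for GC-MS chromatogram alignment.

A chromatogram is the time-ordered series of binned mass spectra (scans)
acquired during one GC-MS run.  Peaks are apexes of analyte traces, each
carrying the binned EI fragmentation spectrum of its apex scan and the
retention time at which it elutes.  This module holds the in-memory types
shared by every alignment algorithm in the package, the standard
preprocessing steps (nominal-mass binning, per-scan unit-length
normalization, derivatization-mass masking), and plain-text readers and
writers for peak lists, dense scan matrices and multiple-alignment tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ABSENT",
    "Peak",
    "Chromatogram",
    "MultipleAlignmentTable",
    "bin_masses",
    "normalize_scan",
    "mask_masses",
    "read_peak_list",
    "write_peak_list",
    "read_scan_matrix",
    "write_scan_matrix",
    "read_andi_netcdf",
]

#: Marker for a chromatogram with no member in an alignment-table row.
ABSENT = None


@dataclass(frozen=True)
class Peak:
    """A detected peak p = (m, i, t): mass vector, intensity vector, RT.

    Parameters
    ----------
    chromatogram_id : str
        Identifier of the parent chromatogram.
    index : int
        0-based position of the peak within its parent's ordered peak list.
    apex_scan : int
        0-based scan index of the peak apex.
    mass_bins : ndarray of int
        Nominal masses (Da) of the binned spectrum, ascending.
    intensities : ndarray of float
        Non-negative intensities, one per mass bin.
    rt : float
        Retention time of the apex scan, in seconds.
    """

    chromatogram_id: str
    index: int
    apex_scan: int
    mass_bins: np.ndarray
    intensities: np.ndarray
    rt: float

    def __post_init__(self) -> None:
        mb = np.asarray(self.mass_bins, dtype=int)
        it = np.asarray(self.intensities, dtype=float)
        if mb.shape != it.shape:
            raise ValueError("mass_bins and intensities must have equal length")
        if np.any(it < 0):
            raise ValueError("peak intensities must be non-negative")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        object.__setattr__(self, "mass_bins", mb)
        object.__setattr__(self, "intensities", it)


@dataclass
class Chromatogram:
    """An ordered set of peaks with an optional dense scan matrix.

    ``scans`` has one row per scan and one column per integer mass bin in
    ``mass_range`` (inclusive); ``scan_rts`` gives acquisition time in
    seconds per scan and must be strictly increasing.
    """

    id: str
    peaks: list[Peak] = field(default_factory=list)
    scans: Optional[np.ndarray] = None
    scan_rts: Optional[np.ndarray] = None
    mass_range: tuple[int, int] = (50, 550)

    def __post_init__(self) -> None:
        lo, hi = self.mass_range
        if lo >= hi:
            raise ValueError("mass_range must satisfy min < max")
        if self.scans is not None:
            self.scans = np.asarray(self.scans, dtype=float)
            if self.scans.ndim != 2:
                raise ValueError("scan matrix must be 2-dimensional")
            if self.scans.shape[1] != hi - lo + 1:
                raise ValueError(
                    f"scan matrix has {self.scans.shape[1]} mass bins, "
                    f"mass_range {self.mass_range} implies {hi - lo + 1}"
                )
        if self.scan_rts is not None:
            self.scan_rts = np.asarray(self.scan_rts, dtype=float)
            if np.any(np.diff(self.scan_rts) <= 0):
                raise ValueError("scan_rts must be strictly increasing")
        self._check_peaks()

    def _check_peaks(self) -> None:
        rts = [p.rt for p in self.peaks]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("peaks must be ordered by nondecreasing rt")
        if self.scans is not None:
            n = self.scans.shape[0]
            for p in self.peaks:
                if not 0 <= p.apex_scan < n:
                    raise ValueError(
                        f"peak apex scan {p.apex_scan} out of range for "
                        f"{n} scans in chromatogram {self.id!r}"
                    )

    @property
    def mass_bins(self) -> np.ndarray:
        lo, hi = self.mass_range
        return np.arange(lo, hi + 1)

    @property
    def n_scans(self) -> int:
        return 0 if self.scans is None else self.scans.shape[0]


@dataclass
class MultipleAlignmentTable:
    """Rows of grouped peak/scan indices across K chromatograms.

    Each row maps every chromatogram either to a scan index (int) or to
    :data:`ABSENT`.  Peak-clique alignments may contain ABSENT cells;
    profile (DTW) alignments never do.
    """

    chromatogram_ids: list[str]
    rows: list[dict]
    row_median_rt: list[float]

    def __post_init__(self) -> None:
        for r in self.rows:
            if not any(v is not ABSENT for v in r.values()):
                raise ValueError("alignment row with no present entry")

    def __len__(self) -> int:
        return len(self.rows)

    def sorted_by_median_rt(self) -> "MultipleAlignmentTable":
        order = np.argsort(np.asarray(self.row_median_rt), kind="stable")
        return MultipleAlignmentTable(
            chromatogram_ids=list(self.chromatogram_ids),
            rows=[self.rows[i] for i in order],
            row_median_rt=[self.row_median_rt[i] for i in order],
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.chromatogram_ids) + "\tmedian_rt\n")
            for row, rt in zip(self.rows, self.row_median_rt):
                cells = [
                    "-" if row.get(cid) is ABSENT else str(row[cid])
                    for cid in self.chromatogram_ids
                ]
                fh.write("\t".join(cells) + f"\t{rt:.6g}\n")

    @classmethod
    def from_tsv(cls, path) -> "MultipleAlignmentTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[-1] != "median_rt":
                raise ValueError("alignment table must end with a median_rt column")
            ids = header[:-1]
            rows, rts = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                row = {
                    cid: (ABSENT if c == "-" else int(c))
                    for cid, c in zip(ids, parts[:-1])
                }
                rows.append(row)
                rts.append(float(parts[-1]))
        return cls(chromatogram_ids=ids, rows=rows, row_median_rt=rts)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bin_masses(raw_mz, raw_intensity, mass_range: tuple[int, int]) -> np.ndarray:
    """Bin raw m/z readings into integer nominal-mass bins.

    Each m/z is rounded half-up to the nearest integer ("arithmetic
    rounding", the convention of chromatography software — not banker's
    rounding); intensities mapping to the same bin are summed and m/z
    outside ``mass_range`` are discarded.  The output covers every bin of
    the inclusive range, so its length is ``max - min + 1``.
    """
    mz = np.asarray(raw_mz, dtype=float)
    inten = np.asarray(raw_intensity, dtype=float)
    if mz.shape != inten.shape:
        raise ValueError("raw m/z and intensity arrays must have equal length")
    if not (np.all(np.isfinite(mz)) and np.all(np.isfinite(inten))):
        raise ValueError("non-finite values in raw spectrum")
    lo, hi = mass_range
    if lo >= hi:
        raise ValueError("mass_range must satisfy min < max")
    out = np.zeros(hi - lo + 1)
    if mz.size == 0:
        return out
    bins = np.floor(mz + 0.5).astype(int)  # round half-up
    keep = (bins >= lo) & (bins <= hi)
    np.add.at(out, bins[keep] - lo, inten[keep])
    return out


def normalize_scan(v) -> np.ndarray:
    """Scale an intensity vector to unit Euclidean length.

    Removes linear intensity-scaling effects between runs.  An all-zero
    vector is returned unchanged.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        return v.copy()
    return v / n


def mask_masses(chrom: Chromatogram, masses) -> Chromatogram:
    """Zero the listed nominal-mass bins in every spectrum of a chromatogram.

    Used to remove signal of the derivatization agent (conventionally
    masses 73 and 147 for TMS derivatives) that is present in nearly every
    scan and would otherwise dominate spectral similarities.  Masses outside
    the chromatogram's range are ignored; the operation is idempotent.
    """
    lo, hi = chrom.mass_range
    cols = [m - lo for m in masses if lo <= m <= hi]
    scans = None
    if chrom.scans is not None:
        scans = chrom.scans.copy()
        scans[:, cols] = 0.0
    peaks = []
    for p in chrom.peaks:
        inten = p.intensities.copy()
        sel = np.isin(p.mass_bins, [m for m in masses if lo <= m <= hi])
        inten[sel] = 0.0
        peaks.append(replace(p, intensities=inten))
    return Chromatogram(
        id=chrom.id,
        peaks=peaks,
        scans=scans,
        scan_rts=None if chrom.scan_rts is None else chrom.scan_rts.copy(),
        mass_range=chrom.mass_range,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_peak_list(path, chrom: Chromatogram, one_based: bool = False) -> Chromatogram:
    """Attach peaks from a tab-delimited apex-scan-index file.

    The first column of every line is the integer apex scan index of one
    peak (further columns are ignored).  Spectra and retention times are
    looked up in the chromatogram's scan matrix.  ``one_based`` converts
    files whose indices start at 1.
    """
    if chrom.scans is None or chrom.scan_rts is None:
        raise ValueError("chromatogram needs scans and scan_rts to attach peaks")
    n = chrom.n_scans
    apexes: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            first = line.split("\t")[0]
            try:
                idx = int(first)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: first field {first!r} is not an integer"
                ) from None
            if one_based:
                idx -= 1
            if not 0 <= idx < n:
                raise ValueError(
                    f"{path}:{lineno}: apex scan index {idx} out of range "
                    f"for {n} scans"
                )
            apexes.append(idx)
    apexes.sort(key=lambda i: chrom.scan_rts[i])
    peaks = [
        Peak(
            chromatogram_id=chrom.id,
            index=k,
            apex_scan=a,
            mass_bins=chrom.mass_bins,
            intensities=chrom.scans[a].copy(),
            rt=float(chrom.scan_rts[a]),
        )
        for k, a in enumerate(apexes)
    ]
    return Chromatogram(
        id=chrom.id,
        peaks=peaks,
        scans=chrom.scans,
        scan_rts=chrom.scan_rts,
        mass_range=chrom.mass_range,
    )


def write_peak_list(path, chrom: Chromatogram) -> None:
    """Write one apex scan index per line, tab-delimited."""
    with open(path, "w") as fh:
        for p in chrom.peaks:
            fh.write(f"{p.apex_scan}\n")


def write_scan_matrix(path, chrom: Chromatogram) -> None:
    """Write the dense scan matrix as TSV: header of mass bins, then one
    row per scan with the retention time in the first column."""
    if chrom.scans is None or chrom.scan_rts is None:
        raise ValueError("chromatogram has no scan matrix")
    with open(path, "w") as fh:
        fh.write("rt\t" + "\t".join(str(m) for m in chrom.mass_bins) + "\n")
        for rt, row in zip(chrom.scan_rts, chrom.scans):
            fh.write(f"{rt:.6g}\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def read_scan_matrix(path, chrom_id: Optional[str] = None) -> Chromatogram:
    """Read a dense scan-matrix TSV written by :func:`write_scan_matrix`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header[0] != "rt":
            raise ValueError("scan matrix header must start with 'rt'")
        bins = [int(m) for m in header[1:]]
        data = np.loadtxt(fh, ndmin=2)
    if bins != list(range(bins[0], bins[-1] + 1)):
        raise ValueError("mass bins in header must be consecutive integers")
    return Chromatogram(
        id=chrom_id or path.stem,
        peaks=[],
        scans=data[:, 1:],
        scan_rts=data[:, 0],
        mass_range=(bins[0], bins[-1]),
    )


def read_andi_netcdf(path, mass_range: tuple[int, int],
                     chrom_id: Optional[str] = None) -> Chromatogram:
    """Read an ANDI-MS (netCDF-3 classic) chromatogram into a dense matrix.

    Uses the standard ANDI variables ``mass_values``, ``intensity_values``,
    ``scan_index`` and ``scan_acquisition_time``; each scan's centroided
    m/z list is binned to nominal mass over ``mass_range``.
    """
    from scipy.io import netcdf_file

    with netcdf_file(str(path), "r", mmap=False) as nc:
        mz = np.asarray(nc.variables["mass_values"][:], dtype=float)
        inten = np.asarray(nc.variables["intensity_values"][:], dtype=float)
        starts = np.asarray(nc.variables["scan_index"][:], dtype=int)
        rts = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=float)
    bounds = np.append(starts, mz.size)
    scans = np.stack([
        bin_masses(mz[a:b], inten[a:b], mass_range)
        for a, b in zip(bounds[:-1], bounds[1:])
    ])
    return Chromatogram(
        id=chrom_id or Path(path).stem,
        peaks=[],
        scans=scans,
        scan_rts=rts,
        mass_range=mass_range,
    )
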