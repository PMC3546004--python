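import numpy as np
import pytest

from chromalign.chromdata import Chromatogram, Peak


def make_peak(cid="A", index=0, apex=0, intensities=(1.0, 2.0, 3.0), rt=10.0,
              mass_lo=50):
    inten = np.asarray(intensities, dtype=float)
    return Peak(
        chromatogram_id=cid,
        index=index,
        apex_scan=apex,
        mass_bins=np.arange(mass_lo, mass_lo + inten.size),
        intensities=inten,
        rt=rt,
    )


def random_chromatograms(rng, K, n_peaks, n_bins=8, rt_spread=60.0):
    """Small random chromatograms for oracle comparisons: random sparse-ish
    spectra, sorted random retention times."""
    chroms = []
    for k in range(K):
        rts = np.sort(rng.uniform(0.0, rt_spread, size=n_peaks))
        peaks = [
            make_peak(cid=f"C{k}", index=i, apex=i,
                      intensities=rng.uniform(0.0, 1.0, size=n_bins),
                      rt=float(rts[i]))
            for i in range(n_peaks)
        ]
        chroms.append(Chromatogram(
            id=f"C{k}", peaks=peaks, mass_range=(50, 50 + n_bins - 1)
        ))
    return chroms


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
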