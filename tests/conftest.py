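import numpy as np
import pytest

from modmap import SequenceRecord
from modmap.dssim import SsimParams

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_residues(rng, length):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def make_records(rng):
    """Factory for lists of random cleaned SequenceRecords."""

    def _make(n, min_len=50, max_len=200):
        recs = []
        for i in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            recs.append(
                SequenceRecord(id=f"seq{i}", residues=random_residues(rng, length))
            )
        return recs

    return _make


def naive_ssim_terms(a, b, params: SsimParams):
    """Per-window SSIM factors by direct (unvectorized) summation.

    Returns (luminance, contrast_structure) maps over the fully-interior
    window positions.  Independent oracle for the separable-filter
    implementation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    w1 = params.kernel()
    W = np.outer(w1, w1)
    r = (params.window_side - 1) // 2
    H, Wd = a.shape
    lum = np.empty((H - 2 * r, Wd - 2 * r))
    cs = np.empty_like(lum)
    C1, C2 = params.C1, params.C2
    for i in range(r, H - r):
        for j in range(r, Wd - r):
            wa = a[i - r : i + r + 1, j - r : j + r + 1]
            wb = b[i - r : i + r + 1, j - r : j + r + 1]
            mu_a = float((W * wa).sum())
            mu_b = float((W * wb).sum())
            var_a = float((W * wa * wa).sum()) - mu_a**2
            var_b = float((W * wb * wb).sum()) - mu_b**2
            cov = float((W * wa * wb).sum()) - mu_a * mu_b
            lum[i - r, j - r] = (2 * mu_a * mu_b + C1) / (mu_a**2 + mu_b**2 + C1)
            cs[i - r, j - r] = (2 * cov + C2) / (var_a + var_b + C2)
    return lum, cs


def naive_mean_ssim(a, b, params: SsimParams = SsimParams()):
    lum, cs = naive_ssim_terms(a, b, params)
    return float((lum * cs).mean())
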