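"""Structural dissimilarity (DSSIM) between grayscale images.

The structural similarity index s(A, B) compares two images through local
luminance, contrast and correlation statistics taken over Gaussian-weighted
windows:

    SSIM(x) = (2 mu_A mu_B + C1)(2 sigma_AB + C2)
              -------------------------------------
              (mu_A^2 + mu_B^2 + C1)(sigma_A^2 + sigma_B^2 + C2)

with C1 = (K1 L)^2, C2 = (K2 L)^2 stabilising constants for dynamic range L.
The mean over all window positions gives s(A, B) in [-1, 1]; the DSSIM
distance is 1 - s(A, B) in [0, 2]: 0 for identical images, ~1 between an
all-black and an all-white image, approaching 2 for anti-correlated images
of equal luminance.

Conventions fixed here (they shift values at the 3rd-4th decimal and are
therefore recorded in the run manifest): 11x11 Gaussian window with
sigma = 1.5, K1 = 0.01, K2 = 0.03, L = 255; weighted moments use the
normalised Gaussian window; only windows fully inside the image contribute
("valid" borders); the plain (unweighted) mean of the local map is returned;
no pre-downsampling — CGR pixel identity is meaningful and downsampling
would merge k-mers.  Images enter as 8-bit intensities (black = 0), never
as {0, 1} booleans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

from .cgr import CGRImage


@dataclass(frozen=True)
class SsimParams:
    """Windowing and stabilisation constants of the SSIM computation."""

    window_side: int = 11
    window_sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    dynamic_range: float = 255.0

    def __post_init__(self) -> None:
        if self.window_side < 3 or self.window_side % 2 == 0:
            raise ValueError("window_side must be odd and >= 3")
        if self.K1 <= 0 or self.K2 <= 0 or self.dynamic_range <= 0:
            raise ValueError("K1, K2 and dynamic_range must be positive")

    @property
    def C1(self) -> float:
        return (self.K1 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.dynamic_range) ** 2

    @property
    def C3(self) -> float:
        # Folds the structure term into the two-term formula.
        return self.C2 / 2.0

    def kernel(self) -> np.ndarray:
        """Normalised 1-D Gaussian window (separable 2-D weighting)."""
        r = (self.window_side - 1) // 2
        x = np.arange(-r, r + 1, dtype=np.float64)
        w = np.exp(-(x**2) / (2.0 * self.window_sigma**2))
        return w / w.sum()


DEFAULT_PARAMS = SsimParams()


def _as_array(image: CGRImage | np.ndarray) -> np.ndarray:
    pix = image.pixels if isinstance(image, CGRImage) else np.asarray(image)
    return pix.astype(np.float64)


def _valid_filter(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Separable windowed mean, cropped to fully-interior positions."""
    r = (kernel.size - 1) // 2
    out = correlate1d(arr, kernel, axis=0, mode="constant")
    out = correlate1d(out, kernel, axis=1, mode="constant")
    return out[r:-r, r:-r]


def _check_pair(a: np.ndarray, b: np.ndarray, params: SsimParams) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image size mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("images must be 2-D grayscale")
    if min(a.shape) < params.window_side:
        raise ValueError(
            f"image {a.shape} smaller than the {params.window_side}-pixel window"
        )


def mean_ssim(
    A: CGRImage | np.ndarray,
    B: CGRImage | np.ndarray,
    params: SsimParams = DEFAULT_PARAMS,
) -> float:
    """Mean structural similarity of two equally-sized grayscale images."""
    a, b = _as_array(A), _as_array(B)
    _check_pair(a, b, params)
    w = params.kernel()
    mu_a = _valid_filter(a, w)
    mu_b = _valid_filter(b, w)
    var_a = _valid_filter(a * a, w) - mu_a * mu_a
    var_b = _valid_filter(b * b, w) - mu_b * mu_b
    cov = _valid_filter(a * b, w) - mu_a * mu_b
    C1, C2 = params.C1, params.C2
    s = ((2.0 * mu_a * mu_b + C1) * (2.0 * cov + C2)) / (
        (mu_a * mu_a + mu_b * mu_b + C1) * (var_a + var_b + C2)
    )
    return float(s.mean())


def dssim(
    A: CGRImage | np.ndarray,
    B: CGRImage | np.ndarray,
    params: SsimParams = DEFAULT_PARAMS,
) -> float:
    """DSSIM distance 1 - s(A, B), in [0, 2] and symmetric in its arguments."""
    return 1.0 - mean_ssim(A, B, params)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix indexed by sequence id."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        """Distances over unordered pairs i < j, row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def mean_distance(self) -> float:
        """Mean over unordered pairs (diagonal excluded)."""
        return float(self.upper_triangle().mean())


def pairwise_distances(
    images: Sequence[CGRImage],
    params: SsimParams = DEFAULT_PARAMS,
    progress: Callable[[int, int], None] | None = None,
) -> DistanceMatrix:
    """DSSIM distances for all pairs of a list of CGR images.

    Per-image window statistics (means and variances) are precomputed once,
    so each pair costs a single windowed cross-moment; the result is
    identical to the brute-force loop of :func:`dssim` calls.  ``progress``
    is called as ``progress(done_pairs, total_pairs)`` after each pair.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images for a distance matrix")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) > 1:
        first = images[0]
        culprit = next(im for im in images if im.pixels.shape != first.pixels.shape)
        raise ValueError(
            f"mixed image dimensions: {first.source_id!r} {first.pixels.shape} vs "
            f"{culprit.source_id!r} {culprit.pixels.shape}"
        )
    arrays = [_as_array(im) for im in images]
    _check_pair(arrays[0], arrays[0], params)
    w = params.kernel()
    mus = [_valid_filter(a, w) for a in arrays]
    variances = [
        _valid_filter(a * a, w) - mu * mu for a, mu in zip(arrays, mus)
    ]
    C1, C2 = params.C1, params.C2
    n = len(images)
    values = np.zeros((n, n))
    total = n * (n - 1) // 2
    done = 0
    for i in range(n):
        for j in range(i + 1, n):
            cov = _valid_filter(arrays[i] * arrays[j], w) - mus[i] * mus[j]
            s = ((2.0 * mus[i] * mus[j] + C1) * (2.0 * cov + C2)) / (
                (mus[i] ** 2 + mus[j] ** 2 + C1) * (variances[i] + variances[j] + C2)
            )
            values[i, j] = values[j, i] = 1.0 - float(s.mean())
            done += 1
            if progress is not None:
                progress(done, total)
    return DistanceMatrix(ids=[im.source_id for im in images], values=values)


# ---------------------------------------------------------------------------
# Matrix persistence: TSV (square, with header row + id column) and PHYLIP.

def write_distances_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_distances_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return DistanceMatrix(ids=[str(c) for c in df.columns], values=df.to_numpy())


def write_distances_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance format, for external phylogenetics tools."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(matrix)}\n")
        for name, row in zip(matrix.ids, matrix.values):
            label = name[:10].ljust(10)
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
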