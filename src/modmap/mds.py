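"""Classical (Torgerson) multidimensional scaling with Stress-1 reporting.

Given an n x n distance matrix D, double centering

    B = -1/2 * J (D o D) J,    J = I - (1/n) 11^T

yields a Gram matrix whose top-q eigenpairs give point coordinates
(eigenvector columns scaled by the square roots of their eigenvalues).
DSSIM matrices are generally non-Euclidean, so negative eigenvalues occur;
they are clamped to zero for coordinate construction (the standard
Torgerson treatment) but reported in full for diagnostics.

Map quality is summarised by Kruskal's Stress-1,

    sigma_1 = sqrt( sum_{i<j} [f(D_ij) - d_ij]^2 / sum_{i<j} d_ij^2 )

where d_ij are the realised map distances and f(D) = a*D + b is fitted by
ordinary least squares of d on D over unordered pairs.  Values below 0.20
are conventionally considered acceptable.  Stress is evaluated on the
unscaled configuration; the subsequent per-axis scaling onto [-1, 1] is
anisotropic and would change d_ij, so the order (stress, then scale) is
fixed and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist

from .dssim import DistanceMatrix


@dataclass
class MapConfiguration:
    """n points in q dimensions with diagnostics.

    ``eigenvalues`` is the full descending spectrum of the doubly-centered
    matrix; ``stress1`` and ``regression`` (a, b) are filled by
    :func:`stress1`; ``scaling_record`` stores the per-axis (min, max) used
    by :func:`scale_map`.
    """

    ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    stress1: float | None = None
    regression: tuple[float, float] | None = None
    scaled: bool = False
    scaling_record: list[tuple[float, float]] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def q(self) -> int:
        return self.coords.shape[1]

    def map_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances d(i, j) over unordered pairs i < j."""
        return pdist(self.coords)


def classical_mds(D: DistanceMatrix, q: int = 2) -> MapConfiguration:
    """Embed a distance matrix into q dimensions by Torgerson scaling.

    Eigenvector signs are fixed (largest-magnitude entry of each column
    positive) so maps are reproducible across runs and platforms; the
    embedding is otherwise unique only up to rotation/reflection.
    """
    n = len(D)
    if not 1 <= q <= n - 1:
        raise ValueError(f"q={q} out of range [1, {n - 1}] for n={n} points")
    d2 = D.values**2
    row_mean = d2.mean(axis=1, keepdims=True)
    col_mean = d2.mean(axis=0, keepdims=True)
    B = -0.5 * (d2 - row_mean - col_mean + d2.mean())

    eigvals, eigvecs = eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    top = eigvals[:q]
    # Relative tolerance so numerically-zero eigenvalues of exactly low-rank
    # configurations are treated as non-positive (and their axes zeroed).
    tol = max(float(np.abs(eigvals).max()), 1.0) * 1e-12
    n_positive = int(np.sum(top > tol))
    if n_positive < q:
        warnings.warn(
            f"only {n_positive} positive eigenvalues for q={q}; "
            "deficient axes filled with zeros",
            stacklevel=2,
        )
    coords = eigvecs[:, :q] * np.sqrt(np.where(top > tol, top, 0.0))
    for axis in range(q):
        col = coords[:, axis]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MapConfiguration(ids=list(D.ids), coords=coords, eigenvalues=eigvals)


def stress1(D: DistanceMatrix, config: MapConfiguration) -> tuple[float, float, float]:
    """Kruskal Stress-1 of a configuration against its source distances.

    Returns (sigma_1, a, b) with the disparity line f(D) = a*D + b fitted by
    OLS of map distances on input distances.  Degenerate cases: if all input
    distances are equal the regression is undefined and (a, b) = (0, mean d)
    is used; if all map points coincide sigma_1 is defined as 0.  Both emit
    a warning.
    """
    if config.scaled:
        raise ValueError("Stress-1 must be computed on the unscaled configuration")
    if list(D.ids) != list(config.ids):
        raise ValueError("configuration ids do not match distance matrix ids")
    delta = D.upper_triangle()
    d = config.map_distances()
    if np.ptp(delta) == 0.0:
        warnings.warn("all input distances equal; disparity regression undefined",
                      stacklevel=2)
        a, b = 0.0, float(d.mean())
    else:
        a, b = np.polyfit(delta, d, 1)
    denom = float(np.sum(d**2))
    if denom == 0.0:
        warnings.warn("all map points coincide; Stress-1 defined as 0", stacklevel=2)
        return 0.0, float(a), float(b)
    sigma1 = float(np.sqrt(np.sum((a * delta + b - d) ** 2) / denom))
    return sigma1, float(a), float(b)


def evaluate_stress(D: DistanceMatrix, config: MapConfiguration) -> MapConfiguration:
    """Return a copy of ``config`` with stress1 and regression filled in."""
    s, a, b = stress1(D, config)
    return replace(config, stress1=s, regression=(a, b))


def scale_map(config: MapConfiguration) -> MapConfiguration:
    """Affinely map each axis so its min/max land on -1/+1.

    x_sca = 2*(x - x_min)/(x_max - x_min) - 1, independently per axis.  An
    axis with max == min is degenerate and is set to all zeros (warning).
    """
    if config.scaled:
        raise ValueError("configuration is already scaled")
    coords = config.coords.copy()
    record: list[tuple[float, float]] = []
    for axis in range(config.q):
        lo, hi = float(coords[:, axis].min()), float(coords[:, axis].max())
        record.append((lo, hi))
        if hi == lo:
            warnings.warn(f"axis {axis} is degenerate (max == min); set to 0",
                          stacklevel=2)
            coords[:, axis] = 0.0
        else:
            coords[:, axis] = 2.0 * (coords[:, axis] - lo) / (hi - lo) - 1.0
    return replace(config, coords=coords, scaled=True, scaling_record=record)


def embed(D: DistanceMatrix, q: int = 2, scale: bool = True) -> MapConfiguration:
    """classical_mds -> stress1 -> scale_map, as one call."""
    config = evaluate_stress(D, classical_mds(D, q))
    return scale_map(config) if scale else config
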