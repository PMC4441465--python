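import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ortho_group

from modmap import (
    DistanceMatrix,
    classical_mds,
    embed,
    evaluate_stress,
    scale_map,
    stress1,
)
from modmap.mds import MapConfiguration


def matrix_from_points(pts):
    ids = [f"p{i}" for i in range(len(pts))]
    return DistanceMatrix(ids=ids, values=squareform(pdist(pts)))


def random_distance_matrix(rng, n):
    """A symmetric, hollow, generally non-Euclidean dissimilarity matrix."""
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(ids=[f"p{i}" for i in range(n)], values=v)


# ------------------------------------------------------------ classical MDS

def test_all_zero_distances_give_origin():
    D = DistanceMatrix(ids=["a", "b", "c"], values=np.zeros((3, 3)))
    cfg = classical_mds(D, 2)
    np.testing.assert_allclose(cfg.coords, 0.0, atol=1e-12)


def test_unit_square_recovery():
    pts = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
    D = matrix_from_points(pts)
    cfg = evaluate_stress(D, classical_mds(D, 2))
    np.testing.assert_allclose(cfg.map_distances(), pdist(pts), atol=1e-9)
    assert cfg.stress1 <= 1e-6


def test_exact_recovery_in_native_dimension(rng):
    pts = rng.normal(size=(10, 3))
    D = matrix_from_points(pts)
    cfg = classical_mds(D, 3)
    np.testing.assert_allclose(cfg.map_distances(), pdist(pts), atol=1e-9)
    # Only 3 meaningful axes: eigenvalues beyond rank 3 vanish.
    np.testing.assert_allclose(cfg.eigenvalues[3:], 0.0, atol=1e-9)


def test_rank_truncation_keeps_leading_axes(rng):
    # For an exactly Euclidean matrix the q=2 solution is the q=3 solution
    # with its smallest-eigenvalue axis dropped (spectral truncation).
    pts = rng.normal(size=(10, 3))
    D = matrix_from_points(pts)
    c3 = classical_mds(D, 3)
    c2 = classical_mds(D, 2)
    np.testing.assert_allclose(np.abs(c2.coords), np.abs(c3.coords[:, :2]),
                               atol=1e-9)


def test_double_centering(rng):
    # Recompute B from the definition and check row/column sums vanish.
    D = random_distance_matrix(rng, 8)
    d2 = D.values**2
    n = 8
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    np.testing.assert_allclose(B.sum(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(B.sum(axis=1), 0.0, atol=1e-9)
    # And the implementation's spectrum matches this B.
    cfg = classical_mds(D, 2)
    np.testing.assert_allclose(cfg.eigenvalues, np.sort(np.linalg.eigvalsh(B))[::-1],
                               atol=1e-9)


def test_sign_convention_is_deterministic(rng):
    D = random_distance_matrix(rng, 7)
    a = classical_mds(D, 2)
    b = classical_mds(D, 2)
    np.testing.assert_array_equal(a.coords, b.coords)
    for axis in range(2):
        col = a.coords[:, axis]
        assert col[np.argmax(np.abs(col))] >= 0


def test_q_out_of_range():
    D = DistanceMatrix(ids=["a", "b", "c"], values=np.zeros((3, 3)))
    with pytest.raises(ValueError):
        classical_mds(D, 3)
    with pytest.raises(ValueError):
        classical_mds(D, 0)


def test_deficient_axes_warn_and_zero_fill():
    # 3 equidistant points are 2-D; asking for q=2 is fine, but a degenerate
    # matrix with one positive eigenvalue must warn for q=2.
    v = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    D = DistanceMatrix(ids=["a", "b", "c"], values=v)  # collinear points
    with pytest.warns(UserWarning, match="positive eigenvalues"):
        cfg = classical_mds(D, 2)
    np.testing.assert_allclose(cfg.coords[:, 1], 0.0, atol=1e-12)


# ----------------------------------------------------------------- Stress-1

def test_perfect_configuration_has_zero_stress(rng):
    pts = rng.normal(size=(8, 2))
    D = matrix_from_points(pts)
    cfg = MapConfiguration(ids=list(D.ids), coords=pts, eigenvalues=np.zeros(8))
    s, a, b = stress1(D, cfg)
    assert s == pytest.approx(0.0, abs=1e-12)
    assert a == pytest.approx(1.0, abs=1e-9)
    assert b == pytest.approx(0.0, abs=1e-9)


def test_stress_nonincreasing_in_q(rng):
    for _ in range(5):
        D = random_distance_matrix(rng, 9)
        stresses = [evaluate_stress(D, classical_mds(D, q)).stress1
                    for q in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 1e-12
        assert stresses[1] >= stresses[2] - 1e-12


def test_stress_invariant_under_rigid_motion(rng):
    D = random_distance_matrix(rng, 8)
    cfg = classical_mds(D, 2)
    s0, _, _ = stress1(D, cfg)
    Q = ortho_group.rvs(2, random_state=np.random.default_rng(4))
    moved = MapConfiguration(ids=cfg.ids, coords=cfg.coords @ Q + np.array([3.0, -7.0]),
                             eigenvalues=cfg.eigenvalues)
    s1, _, _ = stress1(D, moved)
    assert s1 == pytest.approx(s0, abs=1e-9)


def test_degenerate_stress_cases():
    # All input distances equal: regression undefined, a=0, b=mean(d).
    v = np.ones((3, 3)) - np.eye(3)
    D = DistanceMatrix(ids=["a", "b", "c"], values=v)
    cfg = classical_mds(D, 2)
    with pytest.warns(UserWarning, match="regression undefined"):
        s, a, b = stress1(D, cfg)
    assert a == 0.0 and b == pytest.approx(float(cfg.map_distances().mean()))
    # All points coincide: stress defined as 0.
    Dz = DistanceMatrix(ids=["a", "b", "c"], values=np.zeros((3, 3)))
    cz = classical_mds(Dz, 2)
    with pytest.warns(UserWarning):
        sz, _, _ = stress1(Dz, cz)
    assert sz == 0.0


def test_stress_requires_unscaled_configuration(rng):
    D = random_distance_matrix(rng, 5)
    cfg = scale_map(classical_mds(D, 2))
    with pytest.raises(ValueError, match="unscaled"):
        stress1(D, cfg)


# ------------------------------------------------------------------ scaling

def test_scale_example_from_formula():
    cfg = MapConfiguration(ids=["a", "b", "c"],
                           coords=np.array([[2.0, 0.0], [3.0, 1.0], [4.0, 2.0]]),
                           eigenvalues=np.zeros(3))
    scaled = scale_map(cfg)
    np.testing.assert_allclose(scaled.coords[:, 0], [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(scaled.coords[:, 1], [-1.0, 0.0, 1.0])
    assert scaled.scaling_record == [(2.0, 4.0), (0.0, 2.0)]
    assert scaled.scaled


def test_scaling_already_spanning_axis_is_fixed_point(rng):
    coords = np.column_stack([np.array([-1.0, 0.3, 1.0]), np.array([-1.0, 1.0, 0.0])])
    cfg = MapConfiguration(ids=["a", "b", "c"], coords=coords, eigenvalues=np.zeros(3))
    np.testing.assert_allclose(scale_map(cfg).coords, coords)


def test_scaled_axes_attain_bounds(rng):
    D = random_distance_matrix(rng, 12)
    cfg = embed(D, 2)
    for axis in range(2):
        assert cfg.coords[:, axis].min() == pytest.approx(-1.0)
        assert cfg.coords[:, axis].max() == pytest.approx(1.0)
    assert np.all(np.abs(cfg.coords) <= 1.0 + 1e-12)


def test_degenerate_axis_set_to_zero():
    coords = np.column_stack([np.array([1.0, 2.0, 3.0]), np.full(3, 5.0)])
    cfg = MapConfiguration(ids=["a", "b", "c"], coords=coords, eigenvalues=np.zeros(3))
    with pytest.warns(UserWarning, match="degenerate"):
        scaled = scale_map(cfg)
    np.testing.assert_allclose(scaled.coords[:, 1], 0.0)


def test_double_scaling_rejected(rng):
    D = random_distance_matrix(rng, 5)
    cfg = scale_map(classical_mds(D, 2))
    with pytest.raises(ValueError):
        scale_map(cfg)
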