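"""Granule-to-ASI geometry: nearest-vertex distance, window, coverage."""

import numpy as np
import pandas as pd
import pytest

from glycopap import (AsiMesh, GranuleAnnotation, apply_window,
                      coverage_fraction, mean_roi_distance,
                      nearest_vertex_distance)
from glycopap.errors import GeometryError, ValidationError
from glycopap.geometry import nearest_vertex_distances


def _mesh(vertices, perimeter=None, labels=None):
    vertices = np.asarray(vertices, dtype=float)
    faces = np.zeros((0, 3), dtype=int)
    if perimeter is None:
        perimeter, labels = np.empty(0, int), np.empty(0, bool)
    return AsiMesh(vertices=vertices, faces=faces,
                   perimeter=np.asarray(perimeter, int),
                   contact_labels=np.asarray(labels, bool))


def _granule(center, diameter=20.0):
    return GranuleAnnotation("g0", "r0", np.asarray(center, float), diameter)


def test_center_mode_examples():
    assert nearest_vertex_distance(_granule([0, 0, 0]),
                                   _mesh([[500, 0, 0], [0, 800, 0]])) == 500.0
    assert nearest_vertex_distance(_granule([0, 0, 0]), _mesh([[3, 4, 0]])) == 5.0


def test_empty_mesh_raises():
    with pytest.raises(GeometryError):
        nearest_vertex_distance(_granule([0, 0, 0]), _mesh(np.zeros((0, 3))))


def test_matches_bruteforce_oracle():
    """200 random granules vs a 500-vertex mesh equal the exhaustive scan exactly."""
    rng = np.random.default_rng(3)
    verts = rng.uniform(-1000, 1000, (500, 3))
    mesh = _mesh(verts)
    centers = rng.uniform(-1500, 1500, (200, 3))
    got = nearest_vertex_distances(centers, mesh)
    for c, d in zip(centers, got):
        oracle = min(np.sqrt(((c - v) ** 2).sum()) for v in verts)
        assert d == oracle


def test_surface_mode_bounded_by_center_mode():
    rng = np.random.default_rng(4)
    verts = rng.uniform(-500, 500, (50, 3))
    mesh = _mesh(verts)
    for _ in range(50):
        g = _granule(rng.uniform(-800, 800, 3), diameter=rng.uniform(1, 60))
        dc = nearest_vertex_distance(g, mesh, "center")
        ds = nearest_vertex_distance(g, mesh, "surface")
        assert ds <= dc
        assert ds == max(0.0, dc - g.diameter / 2.0)


def test_rigid_transform_invariance():
    """Distances are invariant under 100 random rotations + translations."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(5)
    verts = rng.uniform(-500, 500, (40, 3))
    centers = rng.uniform(-800, 800, (20, 3))
    base = nearest_vertex_distances(centers, _mesh(verts))
    for _ in range(100):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-1e5, 1e5, 3)
        moved = nearest_vertex_distances(centers @ R.T + t, _mesh(verts @ R.T + t))
        assert np.allclose(moved, base, rtol=1e-9, atol=1e-9 * np.abs(base).max())


def _records(distances):
    return pd.DataFrame({
        "granule_id": [f"g{i}" for i in range(len(distances))],
        "roi_id": "r0",
        "distance_nm": distances,
        "within_window": np.asarray(distances) <= 500.0,
    })


def test_window_boundary_is_inclusive():
    kept = apply_window(_records([100.0, 499.9, 500.0, 500.1]), 500.0)
    assert list(kept["distance_nm"]) == [100.0, 499.9, 500.0]


def test_window_all_beyond_gives_empty():
    assert len(apply_window(_records([600.0, 700.0]), 500.0)) == 0


def test_window_counting_oracle_and_monotonicity():
    rng = np.random.default_rng(6)
    d = rng.uniform(0, 1000, 1000)
    recs = _records(d)
    assert len(apply_window(recs, 500.0)) == int(np.sum(d <= 500.0))
    prev = -1
    for w in (100.0, 250.0, 500.0, 750.0, 1000.0):
        n = len(apply_window(recs, w))
        assert n >= prev   # enlarging the window never drops records
        prev = n


def test_mean_roi_distance():
    assert mean_roi_distance(_records([300.0, 400.0]), 500.0) == 350.0
    assert mean_roi_distance(_records([600.0, 700.0]), 500.0) is None
    rng = np.random.default_rng(7)
    d = rng.uniform(0, 800, 200)
    got = mean_roi_distance(_records(d), 500.0)
    expect = d[d <= 500].sum() / (d <= 500).sum()
    assert got == pytest.approx(expect, rel=1e-12)


def test_mean_roi_distance_rejects_mixed_rois():
    recs = _records([100.0, 200.0])
    recs.loc[1, "roi_id"] = "r1"
    with pytest.raises(ValidationError):
        mean_roi_distance(recs, 500.0)


def _square_perimeter(labels):
    verts = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
    return _mesh(verts, perimeter=[0, 1, 2, 3], labels=labels)


def test_coverage_examples():
    assert coverage_fraction(_square_perimeter([1, 1, 1, 1])) == 1.0
    assert coverage_fraction(_square_perimeter([1, 0, 1, 0])) == 0.5


def test_coverage_oracle_and_traversal_invariance():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(3, 30))
        verts = rng.uniform(-100, 100, (n, 3))
        labels = rng.random(n) < 0.5
        mesh = _mesh(verts, perimeter=np.arange(n), labels=labels)
        seg = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)
        oracle = seg[labels].sum() / seg.sum()
        got = coverage_fraction(mesh)
        assert got == pytest.approx(oracle, abs=1e-12)
        # reversed traversal: segment k of the reverse is original segment (n-2-k) mod n
        rev_perim = np.arange(n)[::-1]
        rev_labels = labels[(n - 2 - np.arange(n)) % n]
        rev = _mesh(verts, perimeter=rev_perim, labels=rev_labels)
        assert coverage_fraction(rev) == pytest.approx(got, abs=1e-12)
        # rotation of the starting vertex
        shift = int(rng.integers(0, n))
        rot = _mesh(verts, perimeter=np.roll(np.arange(n), -shift),
                    labels=np.roll(labels, -shift))
        assert coverage_fraction(rot) == pytest.approx(got, abs=1e-12)


def test_coverage_zero_length_perimeter_raises():
    mesh = _mesh([[0, 0, 0], [0, 0, 0.0]], perimeter=[0, 0], labels=[1, 0])
    with pytest.raises(GeometryError):
        coverage_fraction(mesh)
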