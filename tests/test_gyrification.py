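"""Outer hull construction, ROI area ratios, LGI propagation."""

import numpy as np
import pytest

from cortmorph.gyrification import (
    LGISamples,
    _patch_area,
    build_outer_hull,
    lgi_at_samples,
    propagate_lgi,
    region_mean_lgi,
)
from cortmorph.io import RegionLabeling
from cortmorph.mesh import TriangleMesh, validate_mesh
from cortmorph.synthetic import grid_sheet, gyrified_sphere, icosphere
from cortmorph.thickness import vertex_areas


@pytest.fixture(scope="module")
def convex_hull_setup():
    pial = icosphere(level=4, radius=30.0)
    hull = build_outer_hull(pial)
    return pial, hull


def test_convex_hull_matches_pial(convex_hull_setup):
    pial, hull = convex_hull_setup
    ratio = hull.mesh.total_area() / pial.total_area()
    assert 0.98 <= ratio <= 1.05
    report = validate_mesh(hull.mesh)
    assert report.is_closed and report.euler_characteristic == 2
    assert hull.contains(pial.vertices).all()
    assert hull.provenance["closing_diameter_mm"] == 15.0


def test_convex_sphere_roi_ratios_near_one(convex_hull_setup):
    pial, hull = convex_hull_setup
    samples = lgi_at_samples(pial, hull, roi_diameter=10.0, stride=100)
    assert abs(samples.ratios.mean() - 1.0) <= 0.02


def test_folding_shrinks_hull_relative_to_pial():
    pial = gyrified_sphere(30.0, 4.0, 12, level=4)
    hull = build_outer_hull(pial)
    assert hull.mesh.total_area() < pial.total_area()
    assert hull.contains(pial.vertices, slack_voxels=1.5).mean() > 0.99


def test_degenerate_closing_still_encloses():
    pial = gyrified_sphere(20.0, 2.0, 6, level=4)
    hull = build_outer_hull(pial, closing_diameter=0.5, voxel_size=1.0)
    assert hull.contains(pial.vertices, slack_voxels=1.5).mean() > 0.99


def test_patch_area_matches_analytic_folded_to_flat_ratio():
    """Egg-crate sheet area inside a ball vs flat sheet, against the
    closed-form graph-surface area integral of sqrt(1 + |grad f|^2)."""
    lam, A, ext = 10.0, 1.5, 30.0
    w = 2 * np.pi / lam
    f = lambda x, y: A * np.sin(w * x) * np.sin(w * y)
    folded = grid_sheet(ext, 0.25, f)
    flat = grid_sheet(ext, 0.25)
    center = np.array([15.0, 15.0, 0.0])
    radius = 5.0

    d2_folded = np.einsum("ij,ij->i", folded.vertices - center, folded.vertices - center)
    d2_flat = np.einsum("ij,ij->i", flat.vertices - center, flat.vertices - center)
    measured = _patch_area(folded, center, radius, d2_folded) / _patch_area(
        flat, center, radius, d2_flat
    )

    # analytic oracle: quadrature of the area element over the disk,
    # clipped by the 3D ball (effective radius sqrt(r^2 - f^2))
    xs = np.linspace(center[0] - radius, center[0] + radius, 801)
    ys = np.linspace(center[1] - radius, center[1] + radius, 801)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = f(X, Y)
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + Z**2 <= radius**2
    fx = A * w * np.cos(w * X) * np.sin(w * Y)
    fy = A * w * np.sin(w * X) * np.cos(w * Y)
    dA = (xs[1] - xs[0]) * (ys[1] - ys[0])
    area_folded = np.sum(np.sqrt(1 + fx**2 + fy**2)[inside]) * dA
    flat_inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
    area_flat = flat_inside.sum() * dA
    expected = area_folded / area_flat
    assert abs(measured - expected) / expected <= 0.05


def test_large_roi_ratio_approaches_global(convex_hull_setup):
    pial = gyrified_sphere(30.0, 4.0, 12, level=4)
    hull = build_outer_hull(pial)
    samples = lgi_at_samples(pial, hull, roi_diameter=200.0, stride=200)
    global_ratio = pial.total_area() / hull.mesh.total_area()
    assert np.abs(samples.ratios.mean() - global_ratio) / global_ratio <= 0.03


def _fake_samples(centers, values, radius=10.0):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    normals = np.tile([0.0, 0.0, 1.0], (len(centers), 1))
    return LGISamples(
        hull_vertex_indices=np.arange(len(centers)),
        centers=centers,
        normals=normals,
        ratios=np.asarray(values, dtype=float),
        roi_radius=radius,
    )


def test_constant_samples_propagate_to_constant_field():
    pial = icosphere(level=2, radius=5.0)
    hull = build_outer_hull(pial, closing_diameter=5.0)
    samples = _fake_samples(pial.vertices[[0, 100, 50]], [1.7, 1.7, 1.7], radius=20.0)
    field = propagate_lgi(samples, hull, pial)
    assert np.allclose(field.lgi, 1.7)


def test_single_sample_fills_everything():
    pial = icosphere(level=2, radius=5.0)
    hull = build_outer_hull(pial, closing_diameter=5.0)
    samples = _fake_samples([pial.vertices[0]], [1.3], radius=2.0)
    field = propagate_lgi(samples, hull, pial)
    assert np.allclose(field.lgi, 1.3)  # uncovered vertices take nearest sample
    assert not field.covered.all()


def test_two_cluster_propagation_stays_in_hull_of_values():
    pial = icosphere(level=3, radius=5.0)
    hull = build_outer_hull(pial, closing_diameter=5.0)
    top = pial.vertices[pial.vertices[:, 2] > 4.5][:3]
    bottom = pial.vertices[pial.vertices[:, 2] < -4.5][:3]
    centers = np.vstack([top, bottom])
    values = [1.0] * len(top) + [2.0] * len(bottom)
    field = propagate_lgi(_fake_samples(centers, values, radius=6.0), hull, pial)
    assert field.lgi.min() >= 1.0 - 1e-12
    assert field.lgi.max() <= 2.0 + 1e-12


def test_region_mean_lgi_weighted_oracle():
    pial = icosphere(level=2, radius=5.0)
    areas = vertex_areas(pial)
    rng = np.random.default_rng(0)
    lgi = 1.0 + rng.uniform(0, 1, pial.n_vertices)
    from cortmorph.gyrification import LGIField

    field = LGIField(lgi=lgi, sampled_outer_vertices=np.array([0]),
                     roi_values=np.array([1.0]), covered=np.ones(pial.n_vertices, bool))
    labels = np.where(pial.vertices[:, 0] > 0, "east", "west").astype(object)
    lab = RegionLabeling(labels, ("east", "west"))
    idx = lab.vertices_of("east")
    expected = float(np.sum(lgi[idx] * areas[idx]) / np.sum(areas[idx]))
    assert region_mean_lgi(field, areas, lab, "east") == pytest.approx(expected, abs=1e-12)
    # two-vertex equal-area sanity case
    assert region_mean_lgi(
        LGIField(lgi=np.array([1.0, 3.0]), sampled_outer_vertices=np.array([0]),
                 roi_values=np.array([1.0]), covered=np.ones(2, bool)),
        np.array([2.0, 2.0]),
        RegionLabeling(np.array(["r", "r"], dtype=object), ("r",)),
        "r",
    ) == pytest.approx(2.0)


def test_lgi_dimensionless_under_scaling():
    from cortmorph.gyrification import compute_lgi

    pial = gyrified_sphere(30.0, 3.0, 8, level=4)
    f1 = compute_lgi(pial, stride=200)
    scaled = TriangleMesh(pial.vertices * 2.0, pial.faces.copy())
    f2 = compute_lgi(scaled, closing_diameter=30.0, voxel_size=2.0, roi_diameter=20.0,
                     stride=200)
    assert abs(f1.lgi.mean() - f2.lgi.mean()) <= 0.02


def test_empty_sample_set_raises():
    pial = icosphere(level=2, radius=5.0)
    hull = build_outer_hull(pial, closing_diameter=5.0)
    empty = _fake_samples(np.zeros((0, 3)), [])
    with pytest.raises(ValueError, match="no samples"):
        propagate_lgi(empty, hull, pial)
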