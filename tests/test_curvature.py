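"""Principal/intrinsic curvature estimation, resolution filtering, skew."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from cortmorph.curvature import (
    ICField,
    angle_deficit_curvature,
    filter_ic,
    ic_skew,
    intrinsic_curvature,
    moment_skewness,
    principal_curvatures,
)
from cortmorph.mesh import TriangleMesh
from cortmorph.synthetic import (
    ParametricSurfaceSpec,
    analytic_curvature,
    grid_sheet,
    icosphere,
    make_surface,
)
from cortmorph.thickness import vertex_areas


def interior_mask(mesh, margin=3):
    """Vertices at least `margin` graph steps from any boundary."""
    from cortmorph.mesh import validate_mesh

    report = validate_mesh(mesh)
    boundary = set()
    for a, b in report.boundary_edges:
        boundary.update((a, b))
    adj = mesh.vertex_neighbors()
    current = boundary
    for _ in range(margin):
        nxt = set(current)
        for v in current:
            nxt.update(adj[v].tolist())
        current = nxt
    mask = np.ones(mesh.n_vertices, dtype=bool)
    mask[list(current)] = False
    return mask


def test_sphere_principal_curvatures_within_two_percent():
    mesh = icosphere(level=4, radius=10.0)
    pc = principal_curvatures(mesh)
    assert pc.valid.all()
    for k in (pc.k1, pc.k2):
        assert np.abs(k - 0.1).max() / 0.1 <= 0.02


def test_flat_sheet_is_flat():
    sheet = grid_sheet(20.0, 1.0)
    pc = principal_curvatures(sheet)
    inner = interior_mask(sheet, margin=1) & pc.valid
    assert np.abs(pc.k1[inner]).max() <= 1e-6
    assert np.abs(pc.k2[inner]).max() <= 1e-6


def _cylinder(radius=5.0, length=30.0, n_theta=64, n_z=31):
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(0, length, n_z)
    T, Z = np.meshgrid(theta, z, indexing="ij")
    verts = np.column_stack(
        [radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()]
    )
    faces = []
    for i in range(n_theta):
        for j in range(n_z - 1):
            a = i * n_z + j
            b = ((i + 1) % n_theta) * n_z + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return TriangleMesh(verts, np.array(faces), boundary_allowed=True)


def test_cylinder_curvatures_one_over_r_and_zero():
    mesh = _cylinder(radius=5.0)
    pc = principal_curvatures(mesh)
    inner = interior_mask(mesh, margin=2) & pc.valid
    k1, k2 = np.abs(pc.k1[inner]), np.abs(pc.k2[inner])
    assert np.abs(k1 - 0.2).max() / 0.2 <= 0.02
    assert k2.max() <= 0.01 * 0.2


def test_eggcrate_crest_matches_closed_form(eggcrate):
    spec, mesh = eggcrate
    pc = principal_curvatures(mesh)
    K = intrinsic_curvature(pc)
    # crest of the first bump: x = y = wavelength/4
    crest = np.array([spec.wavelength / 4, spec.wavelength / 4])
    d = np.linalg.norm(mesh.vertices[:, :2] - crest, axis=1)
    v = int(np.argmin(d))
    K_true, _, _ = analytic_curvature(spec, *mesh.vertices[v, :2])
    assert K.valid[v]
    assert abs(K.ic[v] - K_true) / abs(K_true) <= 0.05


def test_developable_wave_has_zero_gaussian_curvature():
    spec = ParametricSurfaceSpec(kind="developable_wave", amplitude=2.0, wavelength=10.0,
                                 extent=10.0, spacing=0.125)
    mesh = make_surface(spec)
    pc = principal_curvatures(mesh)
    K = intrinsic_curvature(pc)
    inner = interior_mask(mesh, margin=8) & K.valid
    bending = np.abs(pc.k1[inner]).max()
    assert np.abs(K.ic[inner]).max() <= 1e-3 * bending**2


def test_gauss_bonnet_quadric_estimate_tightens_with_refinement():
    errors = []
    for level in (3, 4, 5):
        mesh = icosphere(level=level, radius=10.0)
        K = intrinsic_curvature(principal_curvatures(mesh))
        A = vertex_areas(mesh)
        total = float(np.sum(K.ic[K.valid] * A[K.valid]))
        errors.append(abs(total - 4 * np.pi) / (4 * np.pi))
    assert errors[1] <= 0.03
    assert errors[0] > errors[1] > errors[2]


def test_gauss_bonnet_angle_deficit_is_exact():
    mesh = icosphere(level=3, radius=7.0)
    K = angle_deficit_curvature(mesh)
    A = vertex_areas(mesh)
    assert abs(np.sum(K * A) - 4 * np.pi) <= 1e-9


def test_quadric_and_angle_deficit_agree_on_gyrified_sphere():
    from cortmorph.synthetic import gyrified_sphere

    mesh = gyrified_sphere(30.0, 2.0, 4, level=4)
    Kq = intrinsic_curvature(principal_curvatures(mesh))
    Kad = angle_deficit_curvature(mesh)
    A = vertex_areas(mesh)
    total_q = float(np.sum(Kq.ic[Kq.valid] * A[Kq.valid]))
    assert abs(total_q - 4 * np.pi) / (4 * np.pi) <= 0.03
    # pointwise correlation between the two independent estimators
    r = np.corrcoef(Kq.ic[Kq.valid], Kad[Kq.valid])[0, 1]
    assert r > 0.95


def test_gyrified_sphere_matches_analytic_oracle():
    from cortmorph.synthetic import ParametricSurfaceSpec, gyrified_sphere

    spec = ParametricSurfaceSpec(kind="gyrified_sphere", radius=30.0, amplitude=2.0,
                                 angular_frequency=4, level=5)
    mesh = gyrified_sphere(spec.radius, spec.amplitude, spec.angular_frequency, spec.level)
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    theta = np.arccos(np.clip(u[:, 2], -1, 1))
    phi = np.arctan2(u[:, 1], u[:, 0])
    K_true, _, _ = analytic_curvature(spec, theta, phi)
    K = intrinsic_curvature(principal_curvatures(mesh))
    # oracle Gauss-Bonnet closes, and the estimate tracks it pointwise
    A = vertex_areas(mesh)
    assert abs(np.sum(K_true * A) - 4 * np.pi) / (4 * np.pi) <= 0.01
    rms_true = np.sqrt(np.mean(K_true**2))
    rms_err = np.sqrt(np.mean((K.ic[K.valid] - K_true[K.valid]) ** 2))
    assert rms_err <= 0.15 * max(rms_true, 1e-12)


def test_rigid_motion_invariance():
    mesh = icosphere(level=3, radius=10.0)
    pc = principal_curvatures(mesh)
    R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = TriangleMesh(mesh.vertices @ R.T + np.array([5.0, -3.0, 11.0]), mesh.faces.copy())
    pc2 = principal_curvatures(moved)
    assert np.abs(pc.k1 - pc2.k1).max() <= 1e-9
    assert np.abs(pc.k2 - pc2.k2).max() <= 1e-9


def test_uniform_scaling_scales_curvatures():
    mesh = icosphere(level=3, radius=10.0)
    s = 2.5
    scaled = TriangleMesh(mesh.vertices * s, mesh.faces.copy())
    pc = principal_curvatures(mesh)
    pcs = principal_curvatures(scaled)
    assert np.allclose(pcs.k1, pc.k1 / s, rtol=1e-9, atol=1e-12)
    K = intrinsic_curvature(pc)
    Ks = intrinsic_curvature(pcs)
    assert np.allclose(Ks.ic, K.ic / s**2, rtol=1e-9, atol=1e-15)


def test_filter_keeps_smooth_sphere_removes_spike():
    mesh = icosphere(level=3, radius=10.0)
    smooth = filter_ic(intrinsic_curvature(principal_curvatures(mesh)), mesh, 1.0)
    assert smooth.fraction_removed == 0.0

    el = mesh.mean_edge_length()
    verts = mesh.vertices.copy()
    verts[0] *= 1 + 3 * el / 10.0  # spike: one vertex out by 3 edge lengths
    spiked = TriangleMesh(verts, mesh.faces.copy())
    ic = intrinsic_curvature(principal_curvatures(spiked))
    filtered = filter_ic(ic, spiked, 1.0)
    removed = set(np.where(ic.valid & ~filtered.valid)[0])
    one_ring = set(spiked.vertex_neighbors()[0].tolist()) | {0}
    assert one_ring <= removed
    assert len(removed) < 0.05 * mesh.n_vertices  # remainder retained


def test_filter_factor_zero_is_identity():
    mesh = icosphere(level=2, radius=10.0)
    ic = intrinsic_curvature(principal_curvatures(mesh))
    out = filter_ic(ic, mesh, 0.0)
    assert np.array_equal(out.valid, ic.valid)
    with pytest.raises(ValueError, match="already filtered"):
        filter_ic(out, mesh, 1.0)


def _field(values):
    v = np.asarray(values, dtype=float)
    return ICField(ic=v, valid=np.ones(len(v), bool), abs_applied=True, filtered=True)


def test_skew_symmetric_distribution_is_zero():
    summary = ic_skew(_field(np.arange(1.0, 102.0)))
    assert abs(summary.skew) <= 1e-12
    assert summary.usable and summary.n_valid == 101


def test_skew_exponential_draws_near_two():
    rng = np.random.default_rng(7)
    summary = ic_skew(_field(rng.exponential(size=100_000)))
    assert abs(summary.skew - 2.0) <= 0.05


def test_skew_matches_three_pass_moment_oracle():
    rng = np.random.default_rng(3)
    vals = rng.lognormal(size=500)
    mean = vals.sum() / len(vals)
    m2 = ((vals - mean) ** 2).sum() / len(vals)
    m3 = ((vals - mean) ** 3).sum() / len(vals)
    assert abs(moment_skewness(vals) - m3 / m2**1.5) <= 1e-12


def test_skew_small_region_flagged_unusable():
    summary = ic_skew(_field([1, 2, 3, 4, 5]))
    assert not summary.usable and np.isnan(summary.skew)


def test_skew_zero_variance_raises():
    with pytest.raises(ValueError, match="zero variance"):
        ic_skew(_field(np.ones(50)))


@given(st.floats(min_value=1e-6, max_value=1e6))
def test_skew_invariant_under_positive_scaling(scale):
    rng = np.random.default_rng(11)
    vals = rng.exponential(size=200)
    s0 = moment_skewness(vals)
    s1 = moment_skewness(vals * scale)
    assert abs(s0 - s1) <= 1e-9 * max(1.0, abs(s0))
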