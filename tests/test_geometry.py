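"""Synthetic torso/spine/sensor generator: invariants and study layout."""

import numpy as np
import pytest

from spinefield import spatial
from spinefield.geometry import (GeometryConfig, SpineCurve, build_geometry,
                                 build_organ_meshes, build_sensor_array,
                                 build_source_space, build_spine_curve,
                                 build_torso_surface, build_tube_mesh,
                                 parallel_transport_frames, save_geometry,
                                 load_geometry, LEFT_RING, RIGHT_RING)
from spinefield.mesh import MeshInvariantError, TriMesh


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"torso_width": -1.0}, {"spine_depth": 0.0}, {"density": 0.0},
        {"density": 2.5}, {"spine_span": 800.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeometryConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = GeometryConfig(density=0.4, bow_amplitude=15.0)
        cfg.to_yaml(tmp_path / "g.yaml")
        assert GeometryConfig.from_yaml(tmp_path / "g.yaml") == cfg


class TestTorso:
    def test_invariants_and_reference_count(self):
        torso = build_torso_surface(GeometryConfig())
        torso.validate()    # closed, manifold, outward, non-degenerate
        assert abs(torso.n_vertices - 3160) / 3160 < 0.25

    def test_density_scaling(self):
        full = build_torso_surface(GeometryConfig()).n_vertices
        half = build_torso_surface(GeometryConfig(density=0.5)).n_vertices
        assert abs(half - full / 2) / (full / 2) < 0.15

    def test_density_monotone(self):
        counts = [build_torso_surface(GeometryConfig(density=d)).n_vertices
                  for d in (0.25, 0.5, 1.0, 1.5)]
        assert counts == sorted(counts)


class TestSpineCurve:
    def test_depth_from_back_surface(self, small_bundle):
        """Every medial sample sits 50 +- 1 mm along +Y from the back."""
        med, _ = small_bundle.curve.resample(10.0)
        origins = med - np.array([0.0, 300.0, 0.0])
        hit, pts, _ = spatial.raycast_first_hit(
            origins, np.array([0.0, 1.0, 0.0]),
            small_bundle.torso.vertices, small_bundle.torso.faces)
        assert len(hit) == len(med)
        depth = med[hit][:, 1] - pts[:, 1]
        assert depth.min() > 49.0 and depth.max() < 51.0

    def test_resample_gives_61_medial_points(self, small_config):
        pts, _ = build_spine_curve(small_config).resample(10.0)
        assert len(pts) == 61

    def test_straight_spine_constant_tangent(self):
        coeff = np.zeros((3, 6))
        coeff[0, :2] = (-300.0, 600.0)
        coeff[1, 0] = -70.0
        curve = SpineCurve(coeff)
        t = np.linspace(0, 1, 17)
        tan = curve.tangent(t)
        assert np.allclose(tan, tan[0])

    def test_curve_is_degree_five(self, small_config):
        assert build_spine_curve(small_config).coefficients.shape == (3, 6)


class TestSourceSpace:
    def test_layout_counts(self, small_bundle):
        src = small_bundle.sources
        assert src.n_sources == 549 == 61 * 9
        assert src.medial_mask().sum() == 61

    def test_ring_radius_exact(self, small_bundle):
        src = small_bundle.sources
        for s in (0, 17, 36, 60):
            med = src.positions[src.index_of(s, 0)]
            ring = np.array([src.positions[src.index_of(s, r)]
                             for r in range(1, 9)])
            d = np.linalg.norm(ring - med, axis=1)
            assert np.all(np.abs(d - 4.0) < 0.01)
            # ring lies in the plane normal to the local tangent
            tangent = src.frames[src.index_of(s, 0), 0]
            assert np.abs((ring - med) @ tangent).max() < 1e-9

    def test_medial_spacing(self, small_bundle):
        src = small_bundle.sources
        med = src.positions[src.medial_mask()]
        gaps = np.linalg.norm(np.diff(med, axis=0), axis=1)
        assert np.all(np.abs(gaps - 10.0) < 0.1)

    def test_frames_never_flip(self, small_bundle):
        src = small_bundle.sources
        lr = src.frames[src.medial_mask(), 1]
        assert np.all(np.einsum("ij,ij->i", lr[:-1], lr[1:]) > 0)

    def test_straight_spine_identical_frames(self):
        tangents = np.tile([1.0, 0, 0], (20, 1))
        lr, ap = parallel_transport_frames(tangents)
        assert np.allclose(lr, lr[0]) and np.allclose(ap, ap[0])

    def test_left_right_ring_positions(self, small_bundle):
        src = small_bundle.sources
        med = src.positions[src.index_of(30, 0)]
        left = src.positions[src.index_of(30, LEFT_RING)]
        right = src.positions[src.index_of(30, RIGHT_RING)]
        assert left[2] > med[2] > right[2]        # +Z is subject left
        assert np.linalg.norm(left - right) == pytest.approx(8.0, abs=0.01)

    def test_ring_radius_must_fit_in_cord(self, small_config):
        import dataclasses
        bad = dataclasses.replace(small_config, ring_radius=9.0)
        with pytest.raises(ValueError):
            build_source_space(build_spine_curve(bad), bad)


class TestTubes:
    def test_sources_inside_cord(self, small_bundle):
        src = small_bundle.sources
        med = src.positions[src.medial_mask()]
        sd = small_bundle.cord.signed_distance(med)
        assert sd.max() < -2.0        # strictly interior with margin
        ring = small_bundle.cord.signed_distance(
            src.positions[~src.medial_mask()][::7])
        assert ring.max() < 0.0

    def test_cord_inside_bone_inside_torso(self, small_bundle):
        assert small_bundle.bone.signed_distance(
            small_bundle.cord.vertices[::5]).max() < 0.0
        assert small_bundle.torso.signed_distance(
            small_bundle.bone.vertices[::5]).max() < 0.0

    def test_cord_reference_count(self, default_bundle):
        assert abs(default_bundle.cord.n_vertices - 5161) / 5161 < 0.30

    def test_self_intersection_rejected(self, small_config):
        coeff = np.zeros((3, 6))
        coeff[0, :2] = (0.0, 100.0)
        coeff[1, 2:5] = (-960.0, 1920.0, -960.0)   # 60 mm bow over 100 mm
        tight = SpineCurve(coeff)
        with pytest.raises(ValueError, match="self-intersect"):
            build_tube_mesh(tight, 50.0, small_config, name="bad")

    def test_nonpositive_radius_rejected(self, small_bundle, small_config):
        with pytest.raises(ValueError):
            build_tube_mesh(small_bundle.curve, 0.0, small_config)


class TestOrgans:
    def test_reference_counts(self, default_bundle):
        assert abs(default_bundle.heart.n_vertices - 1052) / 1052 < 0.30
        assert abs(default_bundle.lungs.n_vertices - 914) / 914 < 0.30

    def test_lungs_are_two_closed_components(self, small_bundle):
        comps = small_bundle.lungs.as_trimesh().split(only_watertight=False)
        assert len(comps) == 2
        assert all(c.euler_number == 2 for c in comps)

    def test_organs_clear_of_bone(self, small_bundle):
        pts = np.vstack([small_bundle.heart.vertices[::5],
                         small_bundle.lungs.vertices[::5]])
        assert small_bundle.bone.signed_distance(pts).min() > 0.0


class TestSensors:
    def test_site_count_and_channels(self, default_bundle):
        sens = default_bundle.sensors
        assert abs(sens.n_sites - 250) / 250 < 0.10
        assert sens.n_channels == 3 * sens.n_sites

    def test_standoff_distance(self, small_bundle):
        d = small_bundle.torso.signed_distance(small_bundle.sensors.positions)
        assert d.min() > 9.5 and d.max() < 10.5

    def test_triads_orthonormal(self, small_bundle):
        t = small_bundle.sensors.triads
        gram = np.einsum("sij,skj->sik", t, t)
        assert np.abs(gram - np.eye(3)).max() < 1e-10

    def test_doubling_grid_spacing_quarters_sites(self, small_config):
        import dataclasses
        torso = build_torso_surface(small_config)
        n1 = build_sensor_array(torso, small_config).n_sites
        wide = dataclasses.replace(small_config, grid_spacing=60.0)
        n2 = build_sensor_array(torso, wide).n_sites
        assert 3.0 < n1 / n2 < 5.2

    def test_empty_grid_rejected(self, small_config):
        # a 1 mm mesh between grid nodes: every 2 m-spaced ray misses it
        v, f = _tetrahedron()
        tiny = TriMesh(v + np.array([500.0, 0.0, 500.0]), f, name="t")
        import dataclasses
        far = dataclasses.replace(small_config, grid_spacing=2000.0)
        with pytest.raises(ValueError):
            build_sensor_array(tiny, far)


class TestDeterminismAndIO:
    def test_bit_identical_rebuild(self, small_config):
        a = build_geometry(small_config)
        b = build_geometry(small_config)
        assert np.array_equal(a.torso.vertices, b.torso.vertices)
        assert np.array_equal(a.cord.faces, b.cord.faces)
        assert np.array_equal(a.sources.positions, b.sources.positions)
        assert np.array_equal(a.sensors.positions, b.sensors.positions)
        assert np.array_equal(a.sensors.triads, b.sensors.triads)

    def test_save_load_roundtrip(self, small_bundle, tmp_path):
        out = save_geometry(small_bundle, tmp_path / "geo")
        assert (out / "torso.stl").exists()
        loaded = TriMesh.load(out / "cord.stl")
        assert loaded.n_faces == small_bundle.cord.n_faces
        re_bundle = load_geometry(out)
        assert np.array_equal(re_bundle.sources.positions,
                              small_bundle.sources.positions)

    def test_source_sensor_tables(self, small_bundle):
        src = small_bundle.sources.to_frame()
        for col in ("x_mm", "y_mm", "z_mm", "slice_index", "ring_position"):
            assert col in src.columns
        chan = small_bundle.sensors.channel_table()
        for col in ("site", "axis", "ox", "oy", "oz"):
            assert col in chan.columns
        assert set(chan.axis) == {"X", "Y", "Z"}


class TestMeshValidation:
    def test_open_mesh_rejected(self, sphere_mesh):
        broken = TriMesh(sphere_mesh.vertices, sphere_mesh.faces[:-1])
        with pytest.raises(MeshInvariantError, match="watertight"):
            broken.validate()

    def test_inverted_mesh_rejected(self, sphere_mesh):
        flipped = TriMesh(sphere_mesh.vertices, sphere_mesh.faces[:, ::-1])
        with pytest.raises(MeshInvariantError):
            flipped.validate()


def _tetrahedron():
    v = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return v, f
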