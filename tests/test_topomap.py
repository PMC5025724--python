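import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ersp_attn.topomap import (
    Mesh,
    hemisphere_mesh,
    nearest_neighbor_field,
    render_panel,
)


def brute_force_field(mesh, xyz, values, radius):
    out = np.empty(len(mesh.vertices))
    src = np.empty(len(mesh.vertices), int)
    for vi, v in enumerate(mesh.vertices):
        best, best_d = 0, np.inf
        for ei, e in enumerate(xyz):
            d = float(np.linalg.norm(v - e))
            if d < best_d:  # strict: ties keep the lowest electrode index
                best, best_d = ei, d
        out[vi] = values[best] * max(0.0, 1.0 - best_d / radius)
        src[vi] = best
    return out, src


class TestMesh:
    def test_hemisphere_mesh_is_valid_and_brain_sized(self):
        mesh = hemisphere_mesh("R")
        assert (mesh.vertices[:, 0] >= 0).all()
        span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        assert (span > 50).all() and (span < 220).all()

    def test_invalid_meshes_rejected(self):
        v = np.zeros((3, 3))
        with pytest.raises(ValueError, match="out of range"):
            Mesh(vertices=v, triangles=np.array([[0, 1, 5]]))
        with pytest.raises(ValueError, match="degenerate"):
            Mesh(vertices=v, triangles=np.array([[0, 1, 1]]))


class TestNearestNeighborField:
    def test_vertex_on_electrode_gets_full_value(self):
        mesh = Mesh(vertices=np.array([[1.0, 2.0, 3.0]]), triangles=np.zeros((0, 3), int))
        field = nearest_neighbor_field(mesh, np.array([[1.0, 2.0, 3.0]]), np.array([-4.2]))
        assert field.values[0] == pytest.approx(-4.2)

    def test_vertex_beyond_fade_radius_is_zero(self):
        mesh = Mesh(vertices=np.array([[100.0, 0, 0]]), triangles=np.zeros((0, 3), int))
        field = nearest_neighbor_field(mesh, np.zeros((1, 3)), np.array([5.0]),
                                       fade_radius_mm=15.0)
        assert field.values[0] == 0.0

    def test_matches_allpairs_oracle(self, rng):
        mesh = hemisphere_mesh("R")
        xyz = rng.uniform(-80, 80, size=(20, 3))
        values = rng.normal(size=20)
        field = nearest_neighbor_field(mesh, xyz, values, fade_radius_mm=25.0)
        exp_vals, exp_src = brute_force_field(mesh, xyz, values, 25.0)
        np.testing.assert_array_equal(field.source_electrode, exp_src)
        np.testing.assert_allclose(field.values, exp_vals, atol=1e-12)

    def test_tie_broken_by_lowest_electrode_index(self):
        mesh = Mesh(vertices=np.array([[0.0, 0, 0]]), triangles=np.zeros((0, 3), int))
        xyz = np.array([[0.0, 0, 5.0], [0.0, 0, -5.0]])
        field = nearest_neighbor_field(mesh, xyz, np.array([1.0, -1.0]), 20.0)
        assert field.source_electrode[0] == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fade_never_amplifies(self, seed):
        r = np.random.default_rng(seed)
        mesh = Mesh(vertices=r.uniform(-50, 50, (30, 3)), triangles=np.zeros((0, 3), int))
        xyz = r.uniform(-50, 50, (5, 3))
        values = r.normal(size=5)
        field = nearest_neighbor_field(mesh, xyz, values, fade_radius_mm=r.uniform(1, 40))
        assert (np.abs(field.values) <= np.abs(values[field.source_electrode]) + 1e-12).all()

    def test_empty_electrode_set_rejected(self):
        mesh = hemisphere_mesh("R")
        with pytest.raises(ValueError, match="non-empty"):
            nearest_neighbor_field(mesh, np.zeros((0, 3)), np.zeros(0))


class TestRenderPanel:
    def _field(self, mesh, value):
        from ersp_attn.topomap import VertexField

        return VertexField(values=np.full(len(mesh.vertices), value),
                           source_electrode=np.zeros(len(mesh.vertices), int))

    def test_identical_inputs_byte_identical_files(self, tmp_path, rng):
        mesh = hemisphere_mesh("R")
        xyz = rng.uniform(-60, 60, (10, 3))
        field = nearest_neighbor_field(mesh, xyz, rng.normal(size=10), 20.0)
        a, b = tmp_path / "a.png", tmp_path / "b.png"
        render_panel(mesh, field, a)
        render_panel(mesh, field, b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_field_renders_uniform_neutral_surface(self, tmp_path):
        import matplotlib.image

        mesh = hemisphere_mesh("R")
        path = tmp_path / "zero.png"
        render_panel(mesh, self._field(mesh, 0.0), path)
        img = matplotlib.image.imread(path)
        h, w = img.shape[:2]
        crop = img[h // 2 - 10 : h // 2 + 10, 2 * w // 5 - 10 : 2 * w // 5 + 10]
        assert np.unique(crop.reshape(-1, crop.shape[-1]), axis=0).shape[0] == 1

    def test_values_beyond_vmax_clip_to_colormap_extreme(self, tmp_path):
        import matplotlib
        import matplotlib.image

        mesh = hemisphere_mesh("R")
        path = tmp_path / "sat.png"
        render_panel(mesh, self._field(mesh, 10.0), path, vmax=1.0)
        img = matplotlib.image.imread(path)
        h, w = img.shape[:2]
        center = img[h // 2, 2 * w // 5, :3]
        extreme = np.array(matplotlib.colormaps["RdBu_r"](1.0))[:3]
        np.testing.assert_allclose(center, extreme, atol=0.02)
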