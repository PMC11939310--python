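"""Mesh I/O, embedding and skinning."""

import numpy as np
import pytest
import trimesh

from lumbomech.fem import (FEMesh, ElementBlock, MaterialLinear, write_vtk,
                           read_vtk, write_surface, read_surface,
                           embed_surfaces, embedded_masses, element_volumes,
                           make_skin, bind_points, skinned_positions,
                           skin_forces_to_masters, Attachment,
                           OpenSurfaceError)
from lumbomech.mb import RigidBody


def _unit_grid(n=5, size=50.0):
    xs = np.linspace(0, size, n + 1)
    nodes = np.array([(x, y, z) for z in xs for y in xs for x in xs])

    def nid(i, j, k):
        return k * (n + 1) ** 2 + j * (n + 1) + i

    conn = [[nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
             nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
             nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
            for k in range(n) for j in range(n) for i in range(n)]
    return FEMesh(nodes, [ElementBlock("Hex8", np.array(conn))],
                  [MaterialLinear(1.0, 0.3)])


class TestVTKRoundtrip:
    def test_mixed_blocks(self, tmp_path):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1.0]])
        tets = ElementBlock("Tet4", [[0, 1, 2, 3]], [2])
        tris = ElementBlock("Tri3", [[0, 1, 2], [1, 2, 4]], [0, 1])
        mesh = FEMesh(nodes, [tets, tris])
        path = tmp_path / "m.vtk"
        write_vtk(mesh, path, cell_fields={"E": [100.0, 1.0, 2.0]})
        back, fields = read_vtk(path)
        assert back.n_nodes == 5
        assert np.allclose(back.nodes, nodes)
        assert back.block("Tet4").material_id.tolist() == [2]
        assert back.block("Tri3").conn.tolist() == [[0, 1, 2], [1, 2, 4]]
        assert np.allclose(fields["E"], [100.0, 1.0, 2.0])

    def test_surface_roundtrip(self, tmp_path):
        s = trimesh.creation.icosphere(subdivisions=1, radius=7.0)
        path = tmp_path / "s.stl"
        write_surface(s, path)
        back = read_surface(path)
        assert back.volume == pytest.approx(s.volume, rel=1e-6)


class TestEmbedding:
    def test_total_mass_matches_volume(self):
        """Embedded mass equals density x surface volume (MC oracle, 2%)."""
        grid = _unit_grid(5, 60.0)
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=18.0)
        sphere.apply_translation([30, 30, 30])
        rho = 1e-6   # kg/mm^3
        regions = embed_surfaces(grid, [sphere], [rho], [0], samples=5, seed=7)
        m = embedded_masses(grid, regions).sum()
        assert m == pytest.approx(rho * sphere.volume, rel=0.02)

    def test_outside_elements_massless(self):
        grid = _unit_grid(4, 40.0)
        box = trimesh.creation.box(extents=[10, 10, 10])
        box.apply_translation([5, 5, 5])   # occupies exactly element (0,0,0)
        regions = embed_surfaces(grid, [box], [1e-6], [0], samples=3)
        frac = regions[0].element_fraction
        assert frac[0] == pytest.approx(1.0)
        assert np.count_nonzero(frac) == 1

    def test_open_surface_rejected(self):
        grid = _unit_grid(3, 30.0)
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [5, 0, 0], [0, 5, 0]],
                              faces=[[0, 1, 2]])
        with pytest.raises(OpenSurfaceError):
            embed_surfaces(grid, [tri], [1e-6], [0])

    def test_element_volumes(self):
        grid = _unit_grid(2, 20.0)
        assert np.allclose(element_volumes(grid), 1000.0)


class TestSkinning:
    def _two_bodies(self):
        a = RigidBody("a", [0, 0, 0])
        b = RigidBody("b", [0, 0, 100.0])
        return a, b

    def test_single_master_translation(self):
        a, _ = self._two_bodies()
        s = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        skin = make_skin(s, [a], np.ones((len(s.vertices), 1)))
        a.position = a.position + np.array([3.0, -1.0, 2.0])
        moved = skin.current().vertices
        assert np.allclose(moved - s.vertices, [3.0, -1.0, 2.0])

    def test_offset_duplicate_distance(self):
        a, _ = self._two_bodies()
        s = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        skin = make_skin(s, [a], np.ones((len(s.vertices), 1)), offset=0.25)
        d = np.linalg.norm(skin.current().vertices, axis=1)
        assert d.min() == pytest.approx(10.25, abs=0.01)

    def test_two_masters_opposite_translations_cancel(self):
        a, b = self._two_bodies()
        pts = np.array([[0.0, 0.0, 50.0]])
        att = bind_points(pts, [a, b], np.array([[0.5, 0.5]]))
        a.position = a.position + np.array([0, 0, 4.0])
        b.position = b.position + np.array([0, 0, -4.0])
        assert np.allclose(skinned_positions(att), pts)

    def test_forces_to_masters_equal_opposite(self):
        a, b = self._two_bodies()
        pts = np.array([[10.0, 0.0, 30.0], [-10.0, 0.0, 70.0]])
        att = bind_points(pts, [a, b], np.array([[0.7, 0.3], [0.2, 0.8]]))
        f = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 1.0]])
        wr = skin_forces_to_masters(att, f)
        total = wr[0][0] + wr[1][0]
        assert np.allclose(total, f.sum(axis=0))

    def test_zero_weight_vertex_rejected(self):
        with pytest.raises(ValueError):
            Attachment(np.array([0]), [], np.array([[0.0, 0.0]]))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Attachment(np.array([0]), [], np.array([[-0.5, 1.5]]))
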