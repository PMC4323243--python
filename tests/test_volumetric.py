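import warnings

import numpy as np
import pytest
import trimesh

from cephaloplane.errors import (
    DegenerateGeometryError,
    EmptyRegionWarning,
    TopologyError,
    UndefinedRatioError,
    UsageError,
)
from cephaloplane.geometry import Plane
from cephaloplane.synthetic import make_mesh_phantom, make_subject, make_tissue_phantoms
from cephaloplane.volumetric import (
    RegionSpec,
    SurfaceModel,
    clip_region,
    color_bin_labels,
    region_surface_area,
    soft_to_hard_ratio,
    superimpose_models,
    volume_difference,
    voxel_occupancy,
)
from conftest import random_rigid


def slab_models(offset=2.0, size=20.0, tissue="hard"):
    pre, post, truth = make_mesh_phantom("slab", size_mm=size, offset_mm=offset)
    return (
        SurfaceModel(pre, tissue=tissue, session="preop"),
        SurfaceModel(post, tissue=tissue, session="postop"),
        truth,
    )


class TestClipRegion:
    def test_half_cube(self):
        cube = SurfaceModel(trimesh.creation.box(extents=[1, 1, 1]))
        region = RegionSpec("half", [(Plane((1, 0, 0), 0.0), True)])
        half = clip_region(cube, region)
        assert half.mesh.is_watertight
        assert half.mesh.volume == pytest.approx(0.5, abs=1e-9)

    def test_region_outside_is_empty_with_warning(self):
        cube = SurfaceModel(trimesh.creation.box(extents=[1, 1, 1]))
        region = RegionSpec("far", [(Plane((1, 0, 0), 100.0), True)])
        with pytest.warns(EmptyRegionWarning):
            out = clip_region(cube, region)
        assert len(out.mesh.faces) == 0

    def test_multiple_halfspaces_octant(self):
        cube = SurfaceModel(trimesh.creation.box(extents=[2, 2, 2]))
        region = RegionSpec("octant", [
            (Plane((1, 0, 0), 0.0), True),
            (Plane((0, 1, 0), 0.0), True),
            (Plane((0, 0, 1), 0.0), True),
        ])
        octant = clip_region(cube, region)
        assert octant.mesh.is_watertight
        assert octant.mesh.volume == pytest.approx(1.0, abs=1e-9)

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]]
        )
        with pytest.raises(TopologyError):
            clip_region(SurfaceModel(tri), RegionSpec("r", [(Plane((1, 0, 0), 0), True)]))

    def test_convex_polytope_volume_vs_monte_carlo(self):
        # seeded convex hull clipped by a half-space: the exact mesh volume
        # must agree with a 1e6-point point-in-polytope Monte Carlo estimate
        rng = np.random.default_rng(31)
        pts = rng.uniform(-10, 10, (40, 3))
        hull = trimesh.convex.convex_hull(pts)
        plane = Plane((1, 0, 0), 1.0)
        clipped = clip_region(
            SurfaceModel(hull), RegionSpec("c", [(plane, True)])
        )
        assert clipped.mesh.is_watertight
        lo, hi = hull.bounds
        n_mc = 1_000_000
        samples = rng.uniform(lo, hi, (n_mc, 3))
        # inside the hull: satisfies every face half-space; then the clip plane
        face_n = hull.face_normals
        face_o = np.einsum("ij,ij->i", face_n, hull.triangles[:, 0])
        inside_hull = np.all(samples @ face_n.T <= face_o + 1e-12, axis=1)
        inside = inside_hull & (plane.signed_distance(samples) >= 0)
        mc_volume = inside.mean() * np.prod(hi - lo)
        assert clipped.mesh.volume == pytest.approx(mc_volume, rel=0.01)


class TestVoxelOccupancy:
    def test_box_volume(self):
        # voxel-multiple extents: centre sampling is exact up to grid offset
        box = trimesh.creation.box(extents=[4.0, 3.2, 2.4])
        lo = box.bounds[0] - 0.8
        shape = (14, 12, 10)
        occ = voxel_occupancy(box, lo, 0.4, shape)
        assert occ.sum() * 0.4**3 == pytest.approx(box.volume, rel=0.02)

    def test_empty_mesh(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        occ = voxel_occupancy(empty, np.zeros(3), 0.5, (4, 4, 4))
        assert not occ.any()


class TestVolumeDifference:
    def test_identical_models_zero(self):
        pre, _, truth = slab_models(offset=2.0)
        region = RegionSpec("all", [(Plane((0, 1, 0), -50.0), True)])
        entry = volume_difference(pre, pre, region, voxel_mm=0.5)
        assert entry.volume_difference_mm3 == 0.0
        assert entry.net_change_mm3 == 0.0

    def test_slab_closed_form(self):
        pre, post, truth = slab_models(offset=2.0)
        region = RegionSpec("moved", [(truth.region_plane, True)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyRegionWarning)
            entry = volume_difference(pre, post, region, voxel_mm=0.4)
        assert entry.volume_difference_mm3 == pytest.approx(800.0, rel=0.05)
        assert entry.region_surface_area_mm2 == pytest.approx(400.0, abs=1e-9)
        assert entry.average_movement_mm == pytest.approx(2.0, rel=0.05)
        assert entry.net_change_mm3 == pytest.approx(800.0, rel=0.05)

    def test_voxel_refinement_converges(self):
        pre, post, truth = slab_models(offset=2.0)
        region = RegionSpec("moved", [(truth.region_plane, True)])
        errors = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyRegionWarning)
            for voxel in (0.8, 0.4, 0.2):
                e = volume_difference(pre, post, region, voxel_mm=voxel)
                errors.append(abs(e.average_movement_mm - 2.0))
        assert errors == sorted(errors, reverse=True) or max(errors) < 1e-9

    def test_symmetric_in_pre_post(self):
        pre, post, truth = slab_models(offset=2.0)
        region = RegionSpec("moved", [(truth.region_plane, True)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyRegionWarning)
            a = volume_difference(pre, post, region, voxel_mm=0.4)
            b = volume_difference(
                SurfaceModel(post.mesh, tissue="hard", session="preop"),
                SurfaceModel(pre.mesh, tissue="hard", session="postop"),
                region, voxel_mm=0.4,
            )
        assert a.volume_difference_mm3 == pytest.approx(b.volume_difference_mm3)
        assert a.net_change_mm3 == pytest.approx(-b.net_change_mm3)

    def test_cell_budget_enforced(self):
        pre, post, truth = slab_models()
        region = RegionSpec("moved", [(truth.region_plane, True)])
        with pytest.raises(UsageError, match="voxel"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyRegionWarning)
                volume_difference(pre, post, region, voxel_mm=0.4, max_cells=10)

    def test_region_surface_area_excludes_straddling_faces(self):
        pre, _, truth = slab_models()
        region = RegionSpec("moved", [(truth.region_plane, True)])
        # only the moved 20x20 face lies entirely inside x >= 10
        assert region_surface_area(pre, region) == pytest.approx(400.0)
        whole = RegionSpec("all", [(Plane((0, 1, 0), -50.0), True)])
        assert region_surface_area(pre, whole) == pytest.approx(2400.0)


class TestSoftToHardRatio:
    def test_slab_pair_recovers_generator_ratio(self):
        (sp, spost), (hp, hpost), truth = make_tissue_phantoms(1.6, 2.0)
        rs = RegionSpec("s", [(truth["soft"].region_plane, True)])
        rh = RegionSpec("h", [(truth["hard"].region_plane, True)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyRegionWarning)
            es = volume_difference(
                SurfaceModel(sp, tissue="soft"),
                SurfaceModel(spost, tissue="soft", session="postop"), rs)
            eh = volume_difference(
                SurfaceModel(hp, tissue="hard"),
                SurfaceModel(hpost, tissue="hard", session="postop"), rh)
        assert soft_to_hard_ratio(es, eh) == pytest.approx(0.8, rel=0.05)

    def test_equal_movements_give_unity(self):
        pre, post, truth = slab_models(offset=2.0)
        region = RegionSpec("moved", [(truth.region_plane, True)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyRegionWarning)
            e = volume_difference(pre, post, region, voxel_mm=0.4)
        assert soft_to_hard_ratio(e, e) == pytest.approx(1.0)

    def test_zero_hard_movement_rejected(self):
        pre, post, truth = slab_models(offset=2.0)
        region = RegionSpec("moved", [(truth.region_plane, True)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyRegionWarning)
            moved = volume_difference(pre, post, region, voxel_mm=0.4)
            unmoved = volume_difference(pre, pre, region, voxel_mm=0.4)
        with pytest.raises(UndefinedRatioError):
            soft_to_hard_ratio(moved, unmoved)


class TestSuperimposeModels:
    def test_exact_rigid_copy_recovered(self, symmetric_subject):
        pre_ls, _ = symmetric_subject
        T = random_rigid(np.random.default_rng(41))
        post_ls = pre_ls.transformed(T, session="postop")
        mesh = trimesh.creation.box(extents=[10, 10, 10])
        moved_mesh = mesh.copy()
        moved_mesh.vertices = T.apply(moved_mesh.vertices)
        models = [SurfaceModel(moved_mesh, session="postop")]
        out, transform, rmsd = superimpose_models(pre_ls, post_ls, models)
        assert rmsd < 1e-9
        assert np.allclose(out[0].mesh.vertices, mesh.vertices, atol=1e-6)

    def test_noisy_landmarks_small_rmsd(self, symmetric_subject):
        from cephaloplane.synthetic import observe

        pre_ls, _ = symmetric_subject
        T = random_rigid(np.random.default_rng(43))
        post_ls = observe(
            pre_ls.transformed(T, session="postop"), (0.1,) * 3,
            observer="obs1", trial=1, seed=43,
        )
        out, transform, rmsd = superimpose_models(pre_ls, post_ls, [])
        assert rmsd <= 0.3

    def test_two_landmark_basis_rejected(self, symmetric_subject):
        pre_ls, _ = symmetric_subject
        with pytest.raises(DegenerateGeometryError):
            superimpose_models(pre_ls, pre_ls, [], basis=("N", "Ba"))


class TestColorBins:
    def test_bin_edges(self):
        d = [0.0, 0.2, 0.4, 0.6, 1.0, 1.4, 1.8, 2.0, 2.5]
        labels = list(color_bin_labels(d))
        assert labels == [
            "green", "green", "green", "yellow", "orange",
            "red", "purple", "purple", "out_of_range",
        ]

    def test_sign_ignored(self):
        assert list(color_bin_labels([-0.5])) == ["yellow"]
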