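"""Distance fields, orientations, spatial profiles, neck width."""

import numpy as np
import pytest

from spinemesh.graph import BranchRecord, NodeRecord, SkeletonGraph
from spinemesh.spatial import (
    boundary_distance_field,
    branch_orientation,
    cytoskeleton_volume_fraction,
    neck_width_estimate,
    profile_vs_distance,
)
from spinemesh.volume import (
    DOMAIN_HEAD,
    DOMAIN_NECK,
    LABEL_CYTOSOL,
    LABEL_EXTRACELLULAR,
    LabelMask,
)


def cylinder_mask(radius_vox=12, length=40, pad=4, domain=DOMAIN_NECK):
    side = 2 * (radius_vox + pad) + 1
    shape = (length, side, side)
    zz, yy, xx = np.indices(shape)
    c = side // 2
    cyl = (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    labels = np.where(cyl, LABEL_CYTOSOL, LABEL_EXTRACELLULAR).astype(np.uint8)
    domains = np.where(cyl, domain, 0).astype(np.uint8)
    return LabelMask(labels, voxel_pitch=2.0, domains=domains)


class TestDistanceField:
    def test_cylinder_max_on_axis(self):
        mask = cylinder_mask(radius_vox=12)
        f = boundary_distance_field(mask)
        assert f.dt.max() == pytest.approx(12 * 2.0, abs=2 * 2.0)
        c = mask.shape[1] // 2
        assert f.dt[20, c, c] == f.dt[20].max()

    def test_gradient_near_flat_wall(self):
        labels = np.full((30, 20, 20), LABEL_CYTOSOL, dtype=np.uint8)
        labels[:6] = LABEL_EXTRACELLULAR  # wall at low z
        mask = LabelMask(labels, voxel_pitch=2.0)
        f = boundary_distance_field(mask)
        g = f.grad[:, 12, 10, 10]  # point 6 voxels above the wall
        angle = np.degrees(np.arccos(np.clip(abs(g[0]), -1, 1)))
        assert angle < 5.0  # perpendicular to the wall

    def test_dt_norm_max_is_one_per_domain(self, small_phantom):
        _, mask, _ = small_phantom
        f = boundary_distance_field(mask)
        for tag in (DOMAIN_HEAD, DOMAIN_NECK):
            dom = mask.domain_of(tag)
            assert f.dt_norm[dom].max() == pytest.approx(1.0)

    def test_zero_on_boundary_adjacent_voxels(self):
        mask = cylinder_mask(radius_vox=6)
        f = boundary_distance_field(mask)
        from scipy import ndimage

        cyt = mask.cytosol()
        # border_value=1: open analysis-box faces are not membrane
        rim = cyt & ~ndimage.binary_erosion(cyt, border_value=1)
        # face-adjacent rim voxels carry zero distance
        assert np.all(f.dt[rim] <= f.voxel_pitch * np.sqrt(3))
        assert (f.dt[rim] == 0).mean() > 0.5


def straight_line_graph(p0, p1, n=50):
    g = SkeletonGraph()
    g.nodes[0] = NodeRecord(0, np.asarray(p0, float))
    g.nodes[1] = NodeRecord(1, np.asarray(p1, float))
    poly = np.linspace(p0, p1, n)
    b = BranchRecord(0, 0, 1, poly)
    b.finalize()
    g.branches[0] = b
    g.recompute_ranks()
    return g


class TestVolumeFraction:
    def test_single_line_reconstructs_tube(self):
        labels = np.full((20, 20, 60), LABEL_CYTOSOL, dtype=np.uint8)
        mask = LabelMask(labels, voxel_pitch=2.0)
        L = 100.0
        g = straight_line_graph([20.0, 20, 10], [20.0, 20, 110])
        frac = cytoskeleton_volume_fraction(g, mask, sigma_vol=4.0)["all"]
        expected = np.pi * 4.0**2 * L / (20 * 20 * 60 * 8.0)
        assert frac == pytest.approx(expected, rel=0.10)

    def test_empty_graph_gives_zero(self):
        mask = cylinder_mask()
        assert cytoskeleton_volume_fraction(SkeletonGraph(), mask)["all"] == 0.0


class TestBranchOrientation:
    def test_radial_branch_in_sphere_is_parallel(self):
        shape = (41, 41, 41)
        zz, yy, xx = np.indices(shape)
        r = np.sqrt((zz - 20.0) ** 2 + (yy - 20.0) ** 2 + (xx - 20.0) ** 2)
        labels = np.where(r <= 18, LABEL_CYTOSOL, LABEL_EXTRACELLULAR).astype(np.uint8)
        mask = LabelMask(labels, voxel_pitch=2.0)
        f = boundary_distance_field(mask)
        centre = 20.5 * 2.0
        g = straight_line_graph(
            [centre, centre, centre - 24], [centre, centre, centre - 6]
        )
        ang = branch_orientation(g.branches[0], f)
        assert ang < 10.0

    def test_tangential_branch_is_perpendicular(self):
        shape = (41, 41, 41)
        zz, yy, xx = np.indices(shape)
        r = np.sqrt((zz - 20.0) ** 2 + (yy - 20.0) ** 2 + (xx - 20.0) ** 2)
        labels = np.where(r <= 18, LABEL_CYTOSOL, LABEL_EXTRACELLULAR).astype(np.uint8)
        mask = LabelMask(labels, voxel_pitch=2.0)
        f = boundary_distance_field(mask)
        centre = 20.5 * 2.0
        # circular arc at constant radius: everywhere tangential
        theta = np.linspace(-0.6, 0.6, 50)
        poly = np.stack(
            [
                np.full_like(theta, centre),
                centre + 20.0 * np.sin(theta),
                centre - 20.0 * np.cos(theta),
            ],
            axis=1,
        )
        b = BranchRecord(0, 0, 1, poly)
        b.finalize()
        ang = branch_orientation(b, f)
        assert ang > 80.0

    def test_45_degree_rod_near_flat_wall(self):
        labels = np.full((40, 30, 30), LABEL_CYTOSOL, dtype=np.uint8)
        labels[:4] = LABEL_EXTRACELLULAR
        mask = LabelMask(labels, voxel_pitch=2.0)
        f = boundary_distance_field(mask)
        g = straight_line_graph([20.0, 10.0, 10.0], [48.0, 38.0, 10.0])
        ang = branch_orientation(g.branches[0], f)
        assert ang == pytest.approx(45.0, abs=2.0)


class TestProfiles:
    def test_uniform_points_give_flat_density(self):
        labels = np.full((40, 40, 40), LABEL_CYTOSOL, dtype=np.uint8)
        labels[:2] = LABEL_EXTRACELLULAR  # single wall; dt = distance to it
        mask = LabelMask(labels, voxel_pitch=2.0)
        f = boundary_distance_field(mask)
        rng = np.random.default_rng(0)
        pts = rng.uniform([6, 2, 2], [76, 78, 78], size=(6000, 3))
        df = profile_vs_distance(pts, None, f, bin_width=6.0, mask=mask)
        inner = df[(df.bin_low >= 6) & (df.bin_high <= 54)]
        dens = inner.density_um3.to_numpy()
        assert dens.std() / dens.mean() < 0.15

    def test_constant_values_everywhere(self):
        mask = cylinder_mask()
        f = boundary_distance_field(mask)
        pts = np.argwhere(mask.cytosol())[::7] * 2.0 + 1.0
        df = profile_vs_distance(pts, np.full(len(pts), 3.3), f, bin_width=4.0)
        assert np.allclose(df["mean"], 3.3)

    def test_membrane_end_enrichment_on_phantom(self, small_phantom):
        """Branch ends concentrate near the membrane while junction
        density dips there."""
        _, mask, net = small_phantom
        f = boundary_distance_field(mask)
        ends = np.array([n.position for n in net.rank1_nodes()])
        juncs = np.array([n.position for n in net.junction_nodes()])
        e = profile_vs_distance(ends, None, f, bin_width=10.0, mask=mask)
        j = profile_vs_distance(juncs, None, f, bin_width=10.0, mask=mask)
        # compare the membrane bin against the interior plateau (10-30 nm);
        # deeper bins cover tiny central volumes and are noisy
        plateau = lambda df: df[(df.bin_low >= 10) & (df.bin_low < 30)]
        assert e.density_um3.iloc[0] > plateau(e).density_um3.mean()
        assert j.density_um3.iloc[0] < plateau(j).density_um3.mean()

    def test_rotation_invariance_of_profiles(self, small_phantom):
        _, mask, net = small_phantom
        f = boundary_distance_field(mask)
        juncs = np.array([n.position for n in net.junction_nodes()])
        base = profile_vs_distance(juncs, None, f, bin_width=10.0, mask=mask)
        # rotate volume and positions by 90 degrees about z: (z,y,x)->(z,x,S-y)
        rot_labels = np.rot90(mask.labels, k=1, axes=(1, 2))
        rot_dom = np.rot90(mask.domains, k=1, axes=(1, 2))
        rmask = LabelMask(
            np.ascontiguousarray(rot_labels), voxel_pitch=2.0,
            domains=np.ascontiguousarray(rot_dom),
        )
        rf = boundary_distance_field(rmask)
        ny = mask.shape[1]
        rpts = np.stack(
            [juncs[:, 0], ny * 2.0 - juncs[:, 2], juncs[:, 1]], axis=1
        )
        rot = profile_vs_distance(rpts, None, rf, bin_width=10.0, mask=rmask)
        assert np.array_equal(base["count"].to_numpy(), rot["count"].to_numpy())
        assert np.allclose(
            base.density_um3.to_numpy(), rot.density_um3.to_numpy()
        )


class TestNeckWidth:
    def test_cylinder_diameter(self):
        mask = cylinder_mask(radius_vox=12)  # 25 nm radius at 2 nm pitch
        w = neck_width_estimate(mask)
        assert w == pytest.approx(2 * 12 * 2.0, abs=2 * 2.0 * 2)

    def test_hourglass_waist(self):
        length, side = 60, 41
        shape = (length, side, side)
        zz, yy, xx = np.indices(shape)
        c = side // 2
        rad = 15.0 - 7.5 * np.cos(2 * np.pi * (zz - 30) / 60.0)  # waist 7.5 vox
        cyl = (yy - c) ** 2 + (xx - c) ** 2 <= rad**2
        labels = np.where(cyl, LABEL_CYTOSOL, LABEL_EXTRACELLULAR).astype(np.uint8)
        domains = np.where(cyl, DOMAIN_NECK, 0).astype(np.uint8)
        mask = LabelMask(labels, voxel_pitch=2.0, domains=domains)
        w = neck_width_estimate(mask)
        assert w == pytest.approx(2 * 7.5 * 2.0, abs=2 * 2.0 * 2)

    def test_stubby_phantom_has_no_neck(self):
        from spinemesh.synthetic import SpinePhantomSpec, generate_spine_geometry

        spec = SpinePhantomSpec(head_radius=60.0, neck_length=0.0, neck_radius=30.0)
        mask = generate_spine_geometry(spec, seed=0)
        assert neck_width_estimate(mask) is None
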