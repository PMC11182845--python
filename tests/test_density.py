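"""Object assignment, shell volumes, densities, NFT fractions."""

import numpy as np
import pandas as pd
import pytest

from perivasc.density import (
    assign_objects,
    compute_densities,
    compute_shell_volumes,
    mark_nft_bearing,
    nft_fraction_by_decile,
    segment_objects,
)
from perivasc.geometry import build_vessel_model
from perivasc.io import ImageVolume

from conftest import cylinder_mask


@pytest.fixture(scope="module")
def shell_vessel():
    """Cylinder r=5 whose full 30 um shell fits laterally in the grid."""
    spacing = (1.0, 1.0, 1.0)
    mask = cylinder_mask((73, 73, 60), spacing, (36.0, 36.0), 5.0, (3.0, 57.0))
    return build_vessel_model(mask, spacing, vessel_id=0)


class TestSegmentObjects:
    def test_single_blob_centroid(self):
        data = np.zeros((20, 20, 10))
        data[5:10, 5:10, 2:7] = 10.0
        vol = ImageVolume(data, (1.0, 1.0, 1.0), channel="neuron")
        objs = segment_objects(vol, threshold=5.0, min_size=10, object_class="neuron")
        assert len(objs) == 1
        assert objs.iloc[0]["x_um"] == pytest.approx(7.0)
        assert objs.iloc[0]["z_um"] == pytest.approx(4.0)
        assert objs.iloc[0]["class"] == "neuron"

    def test_two_separated_blobs(self):
        data = np.zeros((20, 20, 10))
        data[2:5, 2:5, 2:5] = 10.0
        data[12:15, 12:15, 5:8] = 10.0
        vol = ImageVolume(data, (1.0, 1.0, 1.0), channel="nft")
        objs = segment_objects(vol, 5.0, min_size=5, object_class="nft")
        assert len(objs) == 2

    def test_small_components_discarded(self):
        data = np.zeros((10, 10, 10))
        data[1, 1, 1] = 10.0  # single voxel: noise
        data[5:8, 5:8, 5:8] = 10.0
        vol = ImageVolume(data, (1.0, 1.0, 1.0))
        assert len(segment_objects(vol, 5.0, min_size=5, object_class="neuron")) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_component_count_matches_scipy_label_oracle(self, seed):
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        data = (rng.random((24, 24, 24)) < 0.08).astype(float)
        vol = ImageVolume(data, (1.0, 1.0, 1.0))
        objs = segment_objects(vol, 0.5, min_size=1, object_class="neuron")
        _, n = ndimage.label(data > 0.5, structure=np.ones((3, 3, 3)))
        assert len(objs) == n


class TestAssignObjects:
    def objects_at(self, points):
        pts = np.asarray(points, dtype=float)
        return pd.DataFrame(
            {"id": np.arange(len(pts)), "x_um": pts[:, 0], "y_um": pts[:, 1],
             "z_um": pts[:, 2], "class": "neuron"}
        )

    def test_centroid_on_mask_voxel_has_zero_distance(self, shell_vessel, config):
        out = assign_objects(self.objects_at([(36, 36, 30)]), [shell_vessel], config)
        assert out.loc[0, "d_surface_um"] == 0.0
        assert out.loc[0, "vessel_id"] == 0

    def test_shell_boundary_closed_at_30(self, shell_vessel, config):
        # surface at lateral offset 5 -> d = offset - 5 on grid points
        out = assign_objects(
            self.objects_at([(36 + 35, 36, 30), (36 + 35.5, 36, 30)]),
            [shell_vessel], config,
        )
        assert out.loc[0, "d_surface_um"] == pytest.approx(30.0, abs=1e-9)
        assert out.loc[0, "vessel_id"] == 0
        assert out.loc[0, "s_along_um"] == pytest.approx(27.0, abs=1.5)
        assert pd.isna(out.loc[1, "vessel_id"])  # 30.5 um: retained, unassigned

    def test_grid_objects_match_brute_force_scan(self, shell_vessel, config):
        rng = np.random.default_rng(4)
        idx = rng.integers(0, (72, 72, 59), size=(500, 3))
        out = assign_objects(self.objects_at(idx), [shell_vessel], config)
        mask_pos = np.argwhere(shell_vessel.mask).astype(float)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mask_pos).query(idx.astype(float))
        d[shell_vessel.mask[idx[:, 0], idx[:, 1], idx[:, 2]]] = 0.0
        assert np.allclose(out["d_surface_um"], d, atol=1e-9)
        assert np.array_equal(
            out["vessel_id"].notna().to_numpy(), d <= config.shell_max_um
        )

    def test_equidistant_object_goes_to_lower_vessel_id(self, config):
        spacing = (1.0, 1.0, 1.0)
        m1 = cylinder_mask((60, 30, 40), spacing, (10.0, 15.0), 4.0, (4.0, 36.0))
        m2 = cylinder_mask((60, 30, 40), spacing, (50.0, 15.0), 4.0, (4.0, 36.0))
        v1 = build_vessel_model(m1, spacing, 0)
        v2 = build_vessel_model(m2, spacing, 1)
        out = assign_objects(self.objects_at([(30, 15, 20)]), [v1, v2], config)
        assert out.loc[0, "vessel_id"] == 0


class TestShellVolumes:
    def test_interior_bins_match_analytic_annulus(self, shell_vessel, config):
        vols = compute_shell_volumes(shell_vessel, config)
        analytic = np.pi * ((5 + 30) ** 2 - 5**2) * 10 / 1e9  # mm^3 per 10 um bin
        interior = vols[(vols["bin_index"] >= 1) & (vols["bin_index"] <= 3)]
        assert np.allclose(interior["shell_volume_mm3"], analytic, rtol=0.05)

    def test_truncated_end_bin_smaller_than_interior(self, shell_vessel, config):
        # the short final bin past the last full 10 um interval holds less tissue
        vols = compute_shell_volumes(shell_vessel, config).set_index("bin_index")
        last = vols.index.max()
        assert vols.loc[last, "shell_volume_mm3"] < vols.loc[2, "shell_volume_mm3"]

    def test_bin_counts_sum_to_whole_shell(self, shell_vessel, config):
        vols = compute_shell_volumes(shell_vessel, config)
        d = shell_vessel.distance_field
        whole = int(((d <= config.shell_max_um) & ~shell_vessel.mask).sum())
        assert int(vols["shell_voxel_count"].sum()) == whole

    def test_volume_consistent_across_resolutions(self, config):
        total = {}
        for h in (1.0, 2.0):
            mask = cylinder_mask(
                (int(72 / h) + 1, int(72 / h) + 1, int(60 / h)),
                (h, h, h), (36.0, 36.0), 5.0, (4.0, 56.0),
            )
            v = build_vessel_model(mask, (h, h, h), 0)
            vols = compute_shell_volumes(v, config)
            total[h] = vols["shell_volume_mm3"].sum()
        assert total[2.0] == pytest.approx(total[1.0], rel=0.1)


class TestDensities:
    def make_tables(self):
        objects = pd.DataFrame(
            {
                "id": range(10),
                "x_um": np.linspace(0, 9, 10), "y_um": 0.0, "z_um": 0.0,
                "class": "neuron",
                "vessel_id": pd.array([0] * 6 + [1] * 4, dtype="Int64"),
                "bin_index": pd.array([0] * 6 + [0] * 4, dtype="Int64"),
                "s_along_um": 1.0,
                "nft_bearing": [True] * 3 + [False] * 7,
            }
        )
        volumes = pd.DataFrame(
            {"vessel_id": [0, 1], "bin_index": [0, 0],
             "shell_voxel_count": [2000, 1000],
             "shell_volume_mm3": [0.002, 0.001]}
        )
        return objects, volumes

    def test_density_and_pct(self, config):
        objects, volumes = self.make_tables()
        table = compute_densities(objects, volumes, config)
        row0 = table.set_index(["vessel_id", "bin_index"]).loc[(0, 0)]
        assert row0["neuron_density_per_mm3"] == pytest.approx(3000.0)
        assert row0["pct_neurons_with_nft"] == pytest.approx(50.0)
        row1 = table.set_index(["vessel_id", "bin_index"]).loc[(1, 0)]
        assert row1["pct_neurons_with_nft"] == 0.0

    def test_object_in_zero_volume_bin_raises(self, config):
        objects, volumes = self.make_tables()
        volumes.loc[0, "shell_volume_mm3"] = 0.0
        with pytest.raises(ValueError, match="zero shell volume"):
            compute_densities(objects, volumes, config)

    def test_nft_bearing_via_colocalization_radius(self, config):
        objects = pd.DataFrame(
            {
                "id": [0, 1, 2],
                "x_um": [10.0, 40.0, 13.0], "y_um": [10.0, 10.0, 10.0],
                "z_um": [5.0, 5.0, 5.0],
                "class": ["neuron", "neuron", "nft"],
            }
        )
        out = mark_nft_bearing(objects, config)
        flags = out.set_index("id")["nft_bearing"]
        assert bool(flags[0]) is True  # NFT 3 um away (<= 5 um radius)
        assert bool(flags[1]) is False  # 27 um away
        assert bool(flags[2]) is False  # NFTs themselves are not neurons


class TestNftFractionByDecile:
    def test_pooled_counts_per_donor_and_decile(self):
        density = pd.DataFrame(
            {
                "donor": "d0",
                "vessel_id": [0, 0, 0],
                "bin_index": [0, 1, 2],
                "neurons_with_nft": [2, 2, 0],
                "neuron_count": [5, 5, 3],
            }
        )
        bins = pd.DataFrame(
            {"donor": "d0", "vessel_id": 0, "bin_index": [0, 1, 2],
             "decile": pd.array([10, 10, 3], dtype="Int64")}
        )
        out = nft_fraction_by_decile(density, bins)
        top = out[out["decile"] == 10].iloc[0]
        assert top["pct_neurons_with_nft"] == pytest.approx(40.0)  # 4 of 10
        low = out[out["decile"] == 3].iloc[0]
        assert low["pct_neurons_with_nft"] == 0.0

    def test_decile_without_neurons_is_missing(self):
        density = pd.DataFrame(
            {"donor": "d0", "vessel_id": [0], "bin_index": [0],
             "neurons_with_nft": [0], "neuron_count": [0]}
        )
        bins = pd.DataFrame(
            {"donor": "d0", "vessel_id": 0, "bin_index": [0],
             "decile": pd.array([3], dtype="Int64")}
        )
        out = nft_fraction_by_decile(density, bins)
        assert np.isnan(out.loc[0, "pct_neurons_with_nft"])


def test_uniform_neuron_density_recovered(default_scene, default_result):
    """Poisson-placed neurons in the 30 um shell recover the placement rate."""
    density = default_result.density
    n = density["neuron_count"].sum()
    vol = density["shell_volume_mm3"].sum()
    rate = default_scene.spec.neuron_rate_per_mm3
    se = np.sqrt(rate * vol) / vol
    assert n / vol == pytest.approx(rate, abs=3 * se)
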