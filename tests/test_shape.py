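import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage.measure import regionprops

from duoview import (
    GenerationError,
    LabelVolume,
    ValidationError,
    ellipsoid_labels,
    filter_regions,
    region_features,
    stitch_planes,
)


def disk(shape, center, radius, label=1):
    yy, xx = np.indices(shape)
    return label * (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius**2)


class TestStitchPlanes:
    def test_identical_disk_spans_all_planes(self):
        planes = [disk((32, 32), (16, 16), 6) for _ in range(10)]
        vol = stitch_planes(planes, 0.25)
        assert len(vol.ids) == 1
        assert np.all(vol.labels.sum(axis=(1, 2)) > 0)

    def test_disjoint_disks_get_two_labels(self):
        planes = [
            disk((40, 40), (10, 10), 5) + disk((40, 40), (30, 30), 5, label=2)
            for _ in range(6)
        ]
        vol = stitch_planes(planes, 0.25)
        assert len(vol.ids) == 2

    def test_sphere_slices_match_3d_component_oracle(self):
        # half-integer radius keeps the polar caps large enough that every
        # consecutive-slice IoU clears the 0.25 link threshold
        zz, yy, xx = np.indices((24, 32, 32))
        sphere = ((zz - 12) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2) <= 9.5**2
        planes = [(sphere[z] * 1).astype(int) for z in range(24)]
        vol = stitch_planes(planes, 0.25)
        n_components = ndimage.label(sphere)[1]
        assert len(vol.ids) == n_components == 1

    def test_duplicated_sphere_gives_two_labels(self):
        zz, yy, xx = np.indices((24, 64, 32))
        two = (((zz - 12) ** 2 + (yy - 14) ** 2 + (xx - 16) ** 2) <= 8.5**2) | (
            ((zz - 12) ** 2 + (yy - 48) ** 2 + (xx - 16) ** 2) <= 8.5**2
        )
        planes = [ndimage.label(two[z])[0] for z in range(24)]
        vol = stitch_planes(planes, 0.25)
        assert len(vol.ids) == ndimage.label(two)[1] == 2

    def test_low_overlap_starts_new_label(self):
        # disks jump across the plane: IoU 0 between consecutive planes
        planes = [disk((40, 40), (10, 10), 4), disk((40, 40), (30, 30), 4)]
        vol = stitch_planes(planes, 0.25)
        assert len(vol.ids) == 2

    def test_labels_are_consecutive_from_one(self):
        planes = [
            disk((40, 40), (10, 10), 4) + disk((40, 40), (30, 30), 4, label=7)
            for _ in range(3)
        ]
        vol = stitch_planes(planes, 0.25)
        np.testing.assert_array_equal(vol.ids, [1, 2])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            stitch_planes([np.zeros((8, 8), int), np.zeros((8, 9), int)])


class TestRegionFeatures:
    def test_ellipsoid_axis_ratio(self):
        vol = ellipsoid_labels((40, 40, 40), [(20, 20, 20)], [(10, 5, 5)])
        feats = region_features(vol)
        assert feats["axis_ratio"].iloc[0] == pytest.approx(2.0, rel=0.05)

    def test_cube_ratio_is_one(self):
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[5:15, 5:15, 5:15] = 1
        feats = region_features(LabelVolume(labels=labels))
        assert feats["axis_ratio"].iloc[0] == pytest.approx(1.0, rel=0.05)

    def test_anisotropic_spacing_folds_into_moments(self):
        vol = ellipsoid_labels(
            (40, 40, 40), [(20, 20, 20)], [(10, 5, 5)], spacing=(2.0, 1.0, 1.0)
        )
        feats = region_features(vol)
        # long axis along z: physical elongation doubles to 4.0
        assert feats["axis_ratio"].iloc[0] == pytest.approx(4.0, rel=0.05)

    def test_moment_oracle_agreement(self):
        # independent route: direct second-moment summation per label
        vol = ellipsoid_labels((30, 40, 40), [(15, 20, 20)], [(7, 9, 4)])
        feats = region_features(vol)
        coords = np.argwhere(vol.labels == 1).astype(float)
        cov = np.cov(coords.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))
        assert feats["major_axis_um"].iloc[0] == pytest.approx(4 * np.sqrt(eig[2]))
        assert feats["minor_axis_um"].iloc[0] == pytest.approx(4 * np.sqrt(eig[0]))

    def test_skimage_inertia_cross_check(self):
        # third route: axis ratio from regionprops inertia-tensor eigenvalues
        vol = ellipsoid_labels((40, 40, 40), [(20, 20, 20)], [(10, 5, 5)])
        feats = region_features(vol)
        props = regionprops(vol.labels)[0]
        mu = np.sort(props.inertia_tensor_eigvals)  # sums of paired moments
        lam_major = (mu[0] + mu[1] + mu[2]) / 2 - mu[0]
        lam_minor = (mu[0] + mu[1] + mu[2]) / 2 - mu[2]
        assert feats["axis_ratio"].iloc[0] == pytest.approx(
            np.sqrt(lam_major / lam_minor), rel=1e-6
        )

    def test_volume_and_centroid(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[2:4, 3:5, 4:6] = 1
        feats = region_features(LabelVolume(labels=labels, spacing=(2.0, 1.0, 0.5)))
        assert feats["volume_um3"].iloc[0] == pytest.approx(8 * 2.0 * 1.0 * 0.5)
        assert feats["centroid_z_um"].iloc[0] == pytest.approx(2.5 * 2.0)

    def test_empty_volume_gives_empty_table(self):
        feats = region_features(LabelVolume(labels=np.zeros((5, 5, 5), int)))
        assert feats.empty


class TestFilterRegions:
    def _table(self, rng, n=50):
        return pd.DataFrame({
            "label": np.arange(1, n + 1),
            "volume_um3": rng.uniform(0, 1000, n),
            "major_axis_um": rng.uniform(0, 40, n),
            "minor_axis_um": rng.uniform(0, 20, n),
            "axis_ratio": rng.uniform(1, 4, n),
            "centroid_z_um": rng.uniform(0, 50, n),
            "centroid_y_um": rng.uniform(0, 50, n),
            "centroid_x_um": rng.uniform(0, 50, n),
        })

    def test_agrees_with_brute_force_row_scan(self, rng):
        table = self._table(rng)
        vb, ab = (100.0, 800.0), (2.0, 15.0)
        kept, counts = filter_regions(table, vb, ab)
        expected = [
            row["label"]
            for _, row in table.iterrows()
            if vb[0] <= row["volume_um3"] <= vb[1]
            and ab[0] <= row["major_axis_um"] <= ab[1]
            and ab[0] <= row["minor_axis_um"] <= ab[1]
        ]
        assert list(kept["label"]) == expected
        assert counts["kept"] + counts["dropped"] == len(table)

    def test_unbounded_filter_is_identity(self, rng):
        table = self._table(rng)
        kept, counts = filter_regions(table, (0.0, np.inf), (0.0, np.inf))
        pd.testing.assert_frame_equal(kept, table)
        assert counts["dropped"] == 0

    def test_idempotent(self, rng):
        table = self._table(rng)
        once, _ = filter_regions(table, (100.0, 800.0), (2.0, 15.0))
        twice, counts = filter_regions(once, (100.0, 800.0), (2.0, 15.0))
        pd.testing.assert_frame_equal(once, twice)
        assert counts["dropped"] == 0

    def test_inverted_bounds_rejected(self, rng):
        with pytest.raises(ValidationError):
            filter_regions(self._table(rng), (10.0, 1.0), None)
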