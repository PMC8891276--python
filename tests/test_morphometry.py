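"""The 19 object parameters, global metrics, and object matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from noisescore.exceptions import InsufficientDataError
from noisescore.morphometry import (PARAMETER_NAMES, global_metrics,
                                    match_objects, measure_objects,
                                    measure_objects_3d, objects_frame,
                                    per_object_differences,
                                    wrap_angle_difference)
from noisescore.segmentation import label_objects


def _mask_to_records(mask):
    return measure_objects(label_objects(mask))


def _corner_cloud(coords):
    out = []
    for r, c in coords:
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                out.append((r + dr, c + dc))
    return np.array(out)


@pytest.fixture(scope="module")
def square10():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5:15, 5:15] = True
    return _mask_to_records(mask)[0]


@pytest.fixture(scope="module")
def disk30():
    y, x = np.mgrid[0:80, 0:80]
    mask = (y - 40) ** 2 + (x - 40) ** 2 <= 30 ** 2
    return mask, _mask_to_records(mask)[0]


class TestMeasureObjects:
    def test_square_exact_values(self, square10):
        assert square10.area == 100
        assert square10.extent == 1.0
        assert square10.solidity == 1.0
        assert square10.x_cm == pytest.approx(9.5)
        assert square10.y_cm == pytest.approx(9.5)

    def test_square_feret_matches_all_pairs_oracle(self, square10):
        """Max Feret equals the brute-force farthest corner pair."""
        coords = [(r, c) for r in range(5, 15) for c in range(5, 15)]
        cloud = _corner_cloud(coords)
        oracle = cdist(cloud, cloud).max()
        assert square10.feret == pytest.approx(oracle)   # 10 * sqrt(2)
        assert square10.min_feret == pytest.approx(10.0)

    def test_disk_circularity_near_one(self, disk30):
        _, rec = disk30
        assert 0.95 <= rec.circularity <= 1.0

    def test_disk_axes_match_diameter(self, disk30):
        _, rec = disk30
        assert rec.major_axis == pytest.approx(60, rel=0.05)
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert rec.roundness == pytest.approx(1.0, abs=0.07)
        assert rec.compactness == pytest.approx(1.0, abs=0.05)

    def test_all_nineteen_parameters_present(self, square10):
        for name in PARAMETER_NAMES:
            assert np.isfinite(getattr(square10, name)), name
        assert len(PARAMETER_NAMES) == 19

    def test_min_feret_never_exceeds_feret(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mask = rng.random((24, 24)) < 0.4
            for rec in _mask_to_records(mask):
                assert rec.min_feret <= rec.feret + 1e-9
                assert 0 < rec.solidity <= 1
                assert 0 < rec.extent <= 1
                assert 0 <= rec.circularity <= 1

    def test_translation_behavior(self):
        """Shape descriptors are translation invariant; coordinates and
        Feret endpoints shift with the object."""
        mask = np.zeros((40, 40), dtype=bool)
        mask[4:12, 6:16] = True
        mask[5, 6] = False
        a = _mask_to_records(mask)[0]
        b = _mask_to_records(np.roll(mask, (11, 7), axis=(0, 1)))[0]
        coord = {"x_cm", "y_cm", "feret_x", "feret_y"}
        for name in PARAMETER_NAMES:
            if name in coord:
                shift = 7 if name.startswith(("x", "feret_x")) else 11
                assert getattr(b, name) == pytest.approx(
                    getattr(a, name) + shift), name
            else:
                assert getattr(b, name) == pytest.approx(
                    getattr(a, name)), name

    def test_rotation_invariance_of_area_and_feret(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:14, 8:25] = True
        mask[6, 9] = False
        a = _mask_to_records(mask)[0]
        b = _mask_to_records(np.rot90(mask))[0]
        assert b.area == a.area
        assert b.feret == pytest.approx(a.feret)
        assert b.min_feret == pytest.approx(a.min_feret)
        assert b.perimeter == pytest.approx(a.perimeter, rel=1e-6)

    def test_empty_mask_gives_empty_list(self):
        assert measure_objects(np.zeros((8, 8), dtype=np.int32)) == []


class TestGlobalMetrics:
    def test_empty_mask(self):
        gm = global_metrics(np.zeros((16, 16), dtype=np.int32))
        assert gm.n_tot == 0 and gm.a_tot == 0

    def test_two_squares(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:7, 2:7] = True
        mask[20:25, 20:25] = True
        gm = global_metrics(label_objects(mask))
        assert gm.n_tot == 2 and gm.a_tot == 50

    def test_a_tot_conserved_as_sum_of_areas(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            mask = rng.random((40, 40)) < 0.3
            labeled = label_objects(mask)
            gm = global_metrics(labeled)
            areas = objects_frame(measure_objects(labeled))["area"]
            assert gm.a_tot == areas.sum()
            assert gm.n_tot == len(areas)

    def test_sphere_surface_area_matches_analytic(self):
        """Isosurface SA of a voxelized ball ~ 4 pi r^2 within 10%."""
        r = 10
        z, y, x = np.mgrid[0:32, 0:32, 0:32]
        ball = (z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2 <= r ** 2
        gm = global_metrics(label_objects(ball))
        assert gm.sa_tot == pytest.approx(4 * np.pi * r ** 2, rel=0.10)
        assert gm.v_tot == ball.sum()


class TestMatchObjects:
    @staticmethod
    def _table(centroids):
        return pd.DataFrame({
            "label": np.arange(1, len(centroids) + 1),
            "y_cm": [c[0] for c in centroids],
            "x_cm": [c[1] for c in centroids],
            "area": np.ones(len(centroids))})

    def test_identical_masks_all_exact(self):
        t = self._table([(5, 5), (10, 20), (30, 7)])
        m = match_objects(t, t)
        assert len(m.pairs) == 3
        assert (m.pairs["distance"] == 0).all()
        assert m.fallback_fraction == 0.0

    def test_five_pixel_shift_rejects_all(self):
        t = self._table([(5, 5), (10, 20)])
        shifted = self._table([(10, 5), (15, 20)])
        m = match_objects(t, shifted)
        assert len(m.pairs) == 0
        assert len(m.rejected) == 2

    def test_matches_brute_force_nearest_neighbor(self):
        """100 random constellations against the exhaustive oracle."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = self._table(rng.uniform(0, 50, (8, 2)))
            b = self._table(rng.uniform(0, 50, (10, 2)))
            m = match_objects(a, b, max_dist=np.inf)
            d = cdist(a[["y_cm", "x_cm"]], b[["y_cm", "x_cm"]])
            expect = d.argmin(axis=1) + 1
            got = m.pairs.set_index("raw_label")["other_label"]
            for i, lbl in enumerate(a["label"]):
                assert got[lbl] == expect[i]

    def test_empty_other_list_all_unmatched(self):
        a = self._table([(5, 5)])
        m = match_objects(a, self._table([]))
        assert m.unmatched == [1]
        assert len(m.pairs) == 0

    def test_order_independent_with_label_tie_break(self):
        a = self._table([(10, 10)])
        b = self._table([(10, 12), (10, 8)])
        m = match_objects(a, b)
        assert m.pairs.iloc[0]["other_label"] == 1  # equidistant: lower label
        b2 = b.iloc[::-1].reset_index(drop=True)
        m2 = match_objects(a, b2)
        assert m2.pairs.iloc[0]["other_label"] == 1


class TestPerObjectDifferences:
    def test_identical_masks_zero_deltas(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5:10, 5:10] = True
        mask[20:28, 18:29] = True
        t = objects_frame(_mask_to_records(mask))
        m = match_objects(t, t)
        dd = per_object_differences(m, "area", t, t)
        assert dd.mu == 0 and dd.sigma == 0

    def test_sign_convention_raw_minus_other(self):
        t1 = TestMatchObjects._table([(5, 5), (20, 20)])
        t2 = t1.copy()
        t2["area"] = t1["area"] + 3.0
        m = match_objects(t1, t2)
        dd = per_object_differences(m, "area", t1, t2)
        assert dd.mu == pytest.approx(-3.0)

    def test_no_pairs_rejected(self):
        t1 = TestMatchObjects._table([(5, 5)])
        t2 = TestMatchObjects._table([(40, 40)])
        m = match_objects(t1, t2)
        with pytest.raises(InsufficientDataError):
            per_object_differences(m, "area", t1, t2)


def test_wrap_angle_difference():
    assert wrap_angle_difference(179.0 - 1.0) == pytest.approx(-2.0)
    assert wrap_angle_difference(10.0) == pytest.approx(10.0)
    assert wrap_angle_difference(-100.0) == pytest.approx(80.0)


def test_measure_objects_3d_volume_and_centroid():
    vol = np.zeros((8, 8, 8), dtype=bool)
    vol[2:5, 2:5, 2:5] = True
    df = measure_objects_3d(label_objects(vol))
    assert df.loc[0, "volume"] == 27
    assert df.loc[0, "z_cm"] == pytest.approx(3.0)
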