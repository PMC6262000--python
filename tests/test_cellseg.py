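"""Nucleus segmentation, cytoplasm territories, shape thresholds, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rollfish as rf
from rollfish.cellseg import DEFAULT_SHAPE_THRESHOLDS
from rollfish.errors import InsufficientDataError, InvalidParameterError


def _disk_image(centers, radius_px, size=256, value=300.0, bg=50.0):
    yy, xx = np.mgrid[:size, :size]
    img = np.full((size, size), bg)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2] = value
    return img


def _ellipse_mask(a_px, b_px, size=512):
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    return ((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1.0


class TestSegmentNuclei:
    def test_blank_image_empty_table(self):
        labels, cells = rf.segment_nuclei(np.full((64, 64), 50.0), 0.325)
        assert len(cells) == 0
        assert labels.max() == 0

    def test_two_disks_area_recovered(self):
        img = _disk_image([(80, 80), (180, 180)], 20)
        labels, cells = rf.segment_nuclei(img, 1.0, min_area_um2=50)
        assert len(cells) == 2
        np.testing.assert_allclose(
            cells.area_um2, np.pi * 20**2, rtol=0.05
        )

    def test_disk_roundness_high(self):
        img = _disk_image([(128, 128)], 30)
        _, cells = rf.segment_nuclei(img, 1.0, min_area_um2=50)
        assert cells.roundness.iloc[0] >= 0.9

    def test_ellipse_circularity_matches_analytic(self):
        # 4:1 ellipse, semi-axes 60 x 15 px: analytic circularity
        # 4*pi*A/P^2 with Ramanujan perimeter ~= 0.536
        mask = _ellipse_mask(60, 15)
        img = np.where(mask, 300.0, 50.0)
        _, cells = rf.segment_nuclei(img, 1.0, min_area_um2=100)
        assert len(cells) == 1
        a, b = 60, 15
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        analytic = 4 * np.pi * (np.pi * a * b) / perim**2
        assert cells.roundness.iloc[0] == pytest.approx(analytic, abs=0.05)

    def test_very_elongated_ellipse_below_roundness_cutoff(self):
        # 6:1 ellipse: analytic circularity ~= 0.40 < 0.46
        img = np.where(_ellipse_mask(90, 15), 300.0, 50.0)
        _, cells = rf.segment_nuclei(img, 1.0, min_area_um2=100)
        assert cells.roundness.iloc[0] < DEFAULT_SHAPE_THRESHOLDS.roundness_cutoff


class TestDefineCytoplasm:
    def test_fixed_distance_disk_growth(self):
        labels = np.zeros((256, 256), dtype=np.int32)
        yy, xx = np.mgrid[:256, :256]
        labels[(yy - 128) ** 2 + (xx - 128) ** 2 <= 25] = 1  # r = 5 px = 5 µm
        terr = rf.define_cytoplasm(labels, None, 1.0, fixed_distance_um=10.0)
        # territory should be a disk of radius 15 µm
        assert (terr == 1).sum() == pytest.approx(np.pi * 15**2, rel=0.05)

    def test_two_nuclei_partition_midline(self):
        labels = np.zeros((128, 256), dtype=np.int32)
        yy, xx = np.mgrid[:128, :256]
        labels[(yy - 64) ** 2 + (xx - 100) ** 2 <= 9] = 1
        labels[(yy - 64) ** 2 + (xx - 110) ** 2 <= 9] = 2  # 10 px = 10 µm apart
        terr = rf.define_cytoplasm(labels, None, 1.0, fixed_distance_um=10.0)
        # disjoint, each contains its seed, split near the x=105 midline
        assert terr[64, 100] == 1 and terr[64, 110] == 2
        assert (terr[:, :105] != 2).all()
        assert (terr[:, 106:] != 1).all()

    def test_autofluorescence_seeded_territories(self):
        labels = np.zeros((128, 128), dtype=np.int32)
        yy, xx = np.mgrid[:128, :128]
        labels[(yy - 64) ** 2 + (xx - 64) ** 2 <= 16] = 1
        af = np.where((yy - 64) ** 2 + (xx - 64) ** 2 <= 40**2, 200.0, 10.0)
        terr = rf.define_cytoplasm(labels, af, 1.0)
        # follows the autofluorescent foreground, well beyond 10 µm default
        assert (terr == 1).sum() == pytest.approx(np.pi * 40**2, rel=0.1)

    def test_empty_mask_empty_territory(self):
        terr = rf.define_cytoplasm(np.zeros((32, 32), dtype=int), None, 1.0)
        assert terr.max() == 0

    def test_negative_distance_raises(self):
        with pytest.raises(InvalidParameterError):
            rf.define_cytoplasm(
                np.ones((8, 8), dtype=int), None, 1.0, fixed_distance_um=-1
            )


class TestCalibrateThresholds:
    def test_hand_computed_cutoff(self):
        df = pd.DataFrame({"ratio": [4.0, 5.0, 6.0], "roundness": [0.4, 0.5, 0.6]})
        th = rf.calibrate_shape_thresholds(df)
        assert th.ratio_cutoff == pytest.approx(2.0)
        assert th.roundness_cutoff == pytest.approx(0.2)

    def test_constant_measurements_cutoff_at_value(self):
        df = pd.DataFrame({"ratio": [5.0] * 4, "roundness": [0.7] * 4})
        th = rf.calibrate_shape_thresholds(df)
        assert th.ratio_cutoff == pytest.approx(5.0)
        assert th.roundness_cutoff == pytest.approx(0.7)

    def test_single_measurement_raises(self):
        df = pd.DataFrame({"ratio": [5.0], "roundness": [0.7]})
        with pytest.raises(InsufficientDataError):
            rf.calibrate_shape_thresholds(df)

    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance(self, k):
        df = pd.DataFrame(
            {"ratio": [3.0, 4.0, 5.5, 6.0], "roundness": [0.5, 0.6, 0.7, 0.8]}
        )
        base = rf.calibrate_shape_thresholds(df)
        scaled = rf.calibrate_shape_thresholds(df.assign(ratio=df.ratio * k))
        assert scaled.ratio_cutoff == pytest.approx(k * base.ratio_cutoff, rel=1e-9)

    def test_default_thresholds(self):
        assert DEFAULT_SHAPE_THRESHOLDS.ratio_cutoff == 4.08
        assert DEFAULT_SHAPE_THRESHOLDS.roundness_cutoff == 0.46

    def test_calibration_on_simulated_tumor_nuclei(self):
        df = rf.generate_shape_measurements(202, seed=12)
        th = rf.calibrate_shape_thresholds(df)
        # cutoffs ~ mean - 3*sd of the generating normals, within sampling error
        assert th.ratio_cutoff == pytest.approx(5.0 - 3 * 0.3, abs=0.3)
        assert th.roundness_cutoff == pytest.approx(0.7 - 3 * 0.08, abs=0.08)


class TestClassifyCells:
    @pytest.mark.parametrize(
        "ratio,roundness,expected",
        [
            (5.0, 0.6, "tumor"),
            (3.0, 0.6, "non-tumor"),  # fails ratio
            (5.0, 0.3, "non-tumor"),  # fails roundness
            (4.08, 0.46, "tumor"),  # inclusive at the cutoffs
        ],
    )
    def test_rule_application(self, ratio, roundness, expected):
        cells = pd.DataFrame({"ratio": [ratio], "roundness": [roundness]})
        assert rf.classify_cells(cells)["class"].iloc[0] == expected

    def test_empty_table(self):
        out = rf.classify_cells(pd.DataFrame(columns=["ratio", "roundness"]))
        assert len(out) == 0

    def test_missing_descriptor_unclassified(self):
        cells = pd.DataFrame({"ratio": [5.0, np.nan], "roundness": [np.nan, 0.6]})
        assert (rf.classify_cells(cells)["class"] == "unclassified").all()

    def test_accuracy_on_default_shape_distributions(self):
        tumor = rf.generate_shape_measurements(500, seed=20)
        stromal = rf.generate_shape_measurements(
            500, true_class="non-tumor", seed=21, **rf.simgen.STROMAL_SHAPE_PARAMS
        )
        df = pd.concat([tumor, stromal], ignore_index=True)
        out = rf.classify_cells(df)
        acc = (out["class"] == df["true_class"]).mean()
        assert acc >= 0.90
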