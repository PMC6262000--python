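"""Spot-to-cell assignment, localization, colocalization, detection efficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

import rollfish as rf
from rollfish.errors import InvalidParameterError
from rollfish.quantify import _greedy_mutual_matches


def _spots(xy, gene="HER2"):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "gene": gene})


def _single_territory(radius_px=10, size=128, center=(64, 64)):
    yy, xx = np.mgrid[:size, :size]
    terr = np.zeros((size, size), dtype=np.int32)
    terr[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2] = 1
    return terr


CELLS1 = pd.DataFrame({"cell_id": [1], "class": ["tumor"]})


class TestAssignment:
    def test_no_cells_all_outside(self):
        terr = np.zeros((64, 64), dtype=np.int32)
        counts, assign = rf.assign_spots_to_cells(
            _spots([(10, 10), (20, 20)]), terr, pd.DataFrame(columns=["cell_id", "class"]), 1.0
        )
        assert (assign == 0).all()
        assert len(counts) == 0

    def test_margin_geometry(self):
        # circular territory radius 10 µm at (64, 64), margin 9.75 µm
        terr = _single_territory(10)
        spots = _spots([(64 + 19, 64), (64 + 25, 64)])
        counts, assign = rf.assign_spots_to_cells(
            spots, terr, CELLS1, 1.0, margin_um=9.75
        )
        assert list(assign) == [1, 0]
        assert counts["count"].sum() == 1

    def test_zero_margin_is_containment(self):
        terr = _single_territory(10)
        spots = _spots([(64 + 9, 64), (64 + 11, 64)])
        _, assign = rf.assign_spots_to_cells(spots, terr, CELLS1, 1.0, margin_um=0.0)
        assert list(assign) == [1, 0]

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        terr = _single_territory(15)
        spots = _spots(rng.uniform(0, 128, size=(200, 2)))
        counts, assign = rf.assign_spots_to_cells(spots, terr, CELLS1, 1.0)
        assert (assign > 0).sum() + (assign == 0).sum() == len(spots)
        assert counts["count"].sum() == (assign > 0).sum()

    def test_contested_spot_goes_to_nearest_territory(self):
        terr = np.zeros((64, 128), dtype=np.int32)
        yy, xx = np.mgrid[:64, :128]
        terr[(yy - 32) ** 2 + (xx - 40) ** 2 <= 25] = 1
        terr[(yy - 32) ** 2 + (xx - 70) ** 2 <= 25] = 2
        cells = pd.DataFrame({"cell_id": [1, 2], "class": ["tumor", "non-tumor"]})
        # spot between both expanded territories but nearer territory 1
        _, assign = rf.assign_spots_to_cells(
            _spots([(50, 32)]), terr, cells, 1.0, margin_um=20.0
        )
        assert list(assign) == [1]

    def test_negative_margin_raises(self):
        with pytest.raises(InvalidParameterError):
            rf.assign_spots_to_cells(
                _spots([(1, 1)]), _single_territory(), CELLS1, 1.0, margin_um=-1
            )


class TestLocalizationFractions:
    def test_all_in_tumor(self):
        assign = pd.Series([1, 1, 1])
        fr = rf.localization_fractions(assign, CELLS1)
        assert fr == {"tumor": 1.0, "non_tumor": 0.0, "outside": 0.0}

    def test_counting_fractions(self):
        assign = pd.Series([1] * 9 + [0])
        fr = rf.localization_fractions(assign, CELLS1)
        assert fr["tumor"] == pytest.approx(0.9)
        assert fr["non_tumor"] == 0.0
        assert fr["outside"] == pytest.approx(0.1)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_zero_spots_undefined(self):
        fr = rf.localization_fractions(pd.Series([], dtype=int), CELLS1)
        assert all(np.isnan(v) for v in fr.values())

    def test_recovers_simulated_tumor_fraction(self):
        # 90% of spots placed in a tumor territory, 10% outside everything
        rng = np.random.default_rng(7)
        terr = _single_territory(30)
        cells = pd.DataFrame({"cell_id": [1], "class": ["tumor"]})
        inside = 64 + rng.uniform(-15, 15, size=(180, 2))
        outside = np.concatenate(
            [rng.uniform(0, 20, size=(20, 1)), rng.uniform(0, 128, size=(20, 1))], axis=1
        )
        spots = _spots(np.vstack([inside, outside]))
        _, assign = rf.assign_spots_to_cells(spots, terr, cells, 1.0, margin_um=0.0)
        fr = rf.localization_fractions(assign, cells)
        assert fr["tumor"] == pytest.approx(0.9, abs=0.03)


class TestZeroSignalFilter:
    def test_all_nonzero_included(self):
        counts = pd.DataFrame({"cell_id": [1, 2], "gene": "G", "count": [3, 1]})
        assert rf.filter_zero_signal_cells(counts)["included"].all()

    def test_zero_total_excluded(self):
        counts = pd.DataFrame(
            {"cell_id": ["A", "B", "C"], "gene": "G", "count": [3, 0, 1]}
        )
        out = rf.filter_zero_signal_cells(counts)
        assert list(out["included"]) == [True, False, True]
        assert out["count"].equals(counts["count"])

    def test_empty_table(self):
        out = rf.filter_zero_signal_cells(
            pd.DataFrame(columns=["cell_id", "gene", "count"])
        )
        assert len(out) == 0 and "included" in out


class TestColocalization:
    def test_identical_sets_full_colocalization(self):
        s = _spots([(0, 0), (5, 5), (9, 1)])
        res = rf.colocalize_channels(s, s.copy())
        assert res.c == 1.0 and res.q == 1.0

    def test_disjoint_sets_zero(self):
        res = rf.colocalize_channels(_spots([(0, 0)]), _spots([(50, 50)]))
        assert res.c == 0.0 and res.q == 0.0

    def test_hand_worked_matching(self):
        a = _spots([(0, 0), (10, 10)])
        b = _spots([(0.5, 0), (50, 50)])
        res = rf.colocalize_channels(a, b, max_distance_um=1.0)
        assert res.n_matched == 1
        assert res.c == pytest.approx(1 / 3)
        assert res.q == pytest.approx(0.5)

    def test_symmetric_in_channels(self):
        rng = np.random.default_rng(5)
        a = _spots(rng.uniform(0, 50, (40, 2)))
        b = _spots(rng.uniform(0, 50, (35, 2)))
        r1 = rf.colocalize_channels(a, b)
        r2 = rf.colocalize_channels(b, a)
        assert r1.n_matched == r2.n_matched
        assert r1.c == pytest.approx(r2.c)

    def test_both_empty_undefined(self):
        res = rf.colocalize_channels(_spots([]), _spots([]))
        assert np.isnan(res.c) and np.isnan(res.q)

    def test_greedy_matches_brute_force_optimum(self):
        # exhaustive maximum matching oracle on small random instances
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(0, 13))
            a, b, _ = rf.generate_two_color_dataset(
                n, 0.7, 0.2, field_size_um=20.0, seed=seed
            )
            xa = a[["x_um", "y_um"]].to_numpy()
            xb = b[["x_um", "y_um"]].to_numpy()
            greedy = len(_greedy_mutual_matches(xa, xb, 1.0))
            if len(xa) == 0 or len(xb) == 0:
                optimal = 0
            else:
                d = np.hypot(
                    xa[:, None, 0] - xb[None, :, 0], xa[:, None, 1] - xb[None, :, 1]
                )
                cost = np.where(d <= 1.0, d, 1e6)
                ri, ci = linear_sum_assignment(cost)
                optimal = int((cost[ri, ci] < 1e6).sum())
            assert greedy == optimal


class TestDetectionEfficiency:
    def test_half_colocalization_operating_point(self):
        # 50% colocalization implies ~70% per-channel efficiency
        q = rf.detection_efficiency(0.5)
        assert q == pytest.approx(2 / 3)
        assert round(q * 100, -1) == 70

    @pytest.mark.parametrize("c,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_limits(self, c, expected):
        assert rf.detection_efficiency(c) == expected

    @given(st.floats(0.0, 1.0))
    def test_roundtrip_identity(self, c):
        q = rf.detection_efficiency(c)
        assert rf.colocalization_from_efficiency(q) == pytest.approx(c, abs=1e-12)

    def test_monotone_increasing(self):
        cs = np.linspace(0, 1, 50)
        qs = [rf.detection_efficiency(c) for c in cs]
        assert np.all(np.diff(qs) > 0)

    def test_out_of_range_raises(self):
        with pytest.raises(InvalidParameterError):
            rf.detection_efficiency(1.5)

    @pytest.mark.parametrize("q_true", [0.3, 0.7])
    def test_recovery_from_simulated_assay(self, q_true):
        a, b, _ = rf.generate_two_color_dataset(10_000, q_true, 0.2, seed=17)
        res = rf.colocalize_channels(a, b)
        assert res.q == pytest.approx(q_true, abs=0.03)
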