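"""Quantification metrics against independent brute-force oracles."""

import numpy as np
import pytest

from cactuscover import AlignmentError, BinaryMask, InvalidParameterError
from cactuscover.field import default_pixel_area
from cactuscover.metrics import (EvalMetrics, area_from_count,
                                 build_area_report, count_foreground, iou,
                                 rmse)
from conftest import random_mask


def brute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Set-cardinality evaluation on pixel coordinate sets."""
    sa = {(i, j) for i, j in zip(*np.nonzero(a))}
    sb = {(i, j) for i, j in zip(*np.nonzero(b))}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / (len(sa) + len(sb) - len(sa & sb))


def brute_count(a: np.ndarray) -> int:
    total = 0
    for row in a:
        for v in row:
            total += int(v)
    return total


class TestCountForeground:
    def test_known_counts(self):
        assert count_foreground(BinaryMask(np.zeros((4, 4), np.uint8))) == 0
        assert count_foreground(BinaryMask(np.eye(3, dtype=np.uint8))) == 3

    def test_matches_double_loop_oracle(self, rng):
        m = random_mask(rng, 64, 64)
        assert count_foreground(m) == brute_count(m.values)

    def test_non_binary_rejected(self):
        with pytest.raises(InvalidParameterError):
            count_foreground(np.array([[0, 2]]))


class TestAreaFromCount:
    # survey-scale conversions: pixel counts published for a ~54 m^2 plot
    @pytest.mark.parametrize("count,expected", [
        (127_536, 53.5970),
        (124_451, 52.3005),
        (128_194, 53.8735),
        (128_959, 54.1950),
    ])
    def test_reference_scale_conversions(self, count, expected):
        assert round(area_from_count(count, default_pixel_area()), 4) == expected

    def test_zero_and_linearity(self):
        pa = default_pixel_area()
        assert area_from_count(0, pa) == 0.0
        assert area_from_count(700, pa) == pytest.approx(
            area_from_count(300, pa) + area_from_count(400, pa), abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            area_from_count(-1, 1.0)


class TestIoU:
    def test_identical_nonempty_is_one(self, rng):
        m = random_mask(rng, 8, 8, p=0.5)
        assert iou(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert iou(a, b) == 0.0

    def test_hand_worked_example(self):
        # |ref| = 4, |pred| = 6, intersection 3 -> 3/7
        ref = np.zeros((4, 4), np.uint8)
        ref.flat[:4] = 1
        pred = np.zeros((4, 4), np.uint8)
        pred.flat[1:7] = 1
        assert iou(pred, ref) == pytest.approx(3 / 7)

    def test_empty_empty_convention(self):
        z = np.zeros((3, 3), np.uint8)
        assert iou(z, z) == 1.0

    def test_matches_set_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = random_mask(rng, 16, 16, p=rng.uniform(0, 1))
            b = random_mask(rng, 16, 16, p=rng.uniform(0, 1))
            got = iou(a, b)
            assert got == pytest.approx(brute_iou(a.values, b.values))
            assert 0.0 <= got <= 1.0

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(AlignmentError):
            iou(random_mask(rng, 4, 4), random_mask(rng, 4, 5))


class TestRmse:
    def test_identical_vectors_zero(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_worked_example(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))

    def test_symmetry_and_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 20))
            y = rng.normal(0, 10, n)
            yhat = rng.normal(0, 10, n)
            brute = (sum((a - b) ** 2 for a, b in zip(y, yhat)) / n) ** 0.5
            assert rmse(y, yhat) == pytest.approx(brute)
            assert rmse(y, yhat) == pytest.approx(rmse(yhat, y))

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            rmse([1, 2], [1])
        with pytest.raises(InvalidParameterError):
            rmse([], [])


class TestAreaReport:
    def test_perfect_predictions_match_reference_row(self, rng):
        ref = random_mask(rng, 12, 12, p=0.4)
        report = build_area_report(
            {"A": ref, "B": BinaryMask(ref.values.copy())}, ref, 0.01)
        df = report.table.set_index("model")
        for name in ("A", "B"):
            assert df.loc[name, "iou"] == 1.0
            assert df.loc[name, "rmse"] == 0.0
            assert df.loc[name, "pixel_count"] == df.loc["reference",
                                                         "pixel_count"]

    def test_reference_row_convention_and_area_consistency(self, rng):
        ref = random_mask(rng, 10, 10, p=0.3)
        pred = random_mask(rng, 10, 10, p=0.3)
        pa = default_pixel_area()
        report = build_area_report({"m": pred}, ref, pa)
        df = report.table.set_index("model")
        assert df.loc["reference", "iou"] == 1.0
        assert df.loc["reference", "rmse"] == 0.0
        for name in df.index:
            assert df.loc[name, "area_m2"] == pytest.approx(
                area_from_count(int(df.loc[name, "pixel_count"]), pa),
                abs=1e-9)

    def test_reference_count_at_survey_scale(self):
        vals = np.zeros((400, 400), np.uint8)
        vals.flat[:128_959] = 1
        report = build_area_report({}, BinaryMask(vals), default_pixel_area())
        assert report.table.iloc[0]["area_m2"] == pytest.approx(54.1950,
                                                                abs=1e-9)

    def test_per_tile_rmse_used_when_supplied(self, rng):
        ref = random_mask(rng, 8, 8, p=0.5)
        pred = random_mask(rng, 8, 8, p=0.5)
        report = build_area_report({"m": pred}, ref, 1.0,
                                   {"m": ([10, 20], [13, 24])})
        row = report.table.set_index("model").loc["m"]
        assert row["rmse"] == pytest.approx(rmse([13, 24], [10, 20]))
        assert row["n_units"] == 2


def test_eval_metrics_bounds_enforced():
    with pytest.raises(InvalidParameterError):
        EvalMetrics(iou=1.2, rmse=0.0, n_units=1)
    with pytest.raises(InvalidParameterError):
        EvalMetrics(iou=0.5, rmse=-1.0, n_units=1)
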