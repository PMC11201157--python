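"""Metric suite vs an independent brute-force pixel-set implementation."""

import numpy as np
import pytest

from lapseg.metrics import (
    ConfusionAccumulator,
    accumulate,
    boundary_f1,
    class_metrics,
    default_theta,
    summarize,
)
from conftest import random_mask_pair


# -- independent oracle: explicit pixel sets and pairwise distances ---------

def oracle_counts(pred, truth, c):
    P = {(i, j) for i, j in zip(*np.where(pred == c))}
    T = {(i, j) for i, j in zip(*np.where(truth == c))}
    tp = len(P & T)
    fp = len(P - T)
    fn = len(T - P)
    tn = pred.size - tp - fp - fn
    return tp, fp, fn, tn


def oracle_boundary(mask, c):
    h, w = mask.shape
    out = set()
    for i in range(h):
        for j in range(w):
            if mask[i, j] != c:
                continue
            edge = i in (0, h - 1) or j in (0, w - 1)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] != c:
                    edge = True
            if edge:
                out.add((i, j))
    return out


def oracle_bfs(pred, truth, c, theta):
    bp = oracle_boundary(pred, c)
    bt = oracle_boundary(truth, c)
    if not bp and not bt:
        return None
    if not bp or not bt:
        return 0.0

    def hits(src, dst):
        n = 0
        for p in src:
            if min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in dst) <= theta:
                n += 1
        return n / len(src)

    pc, r = hits(bp, bt), hits(bt, bp)
    return 0.0 if pc + r == 0 else 2 * pc * r / (pc + r)


# -- confusion bookkeeping ---------------------------------------------------

class TestAccumulate:
    def test_perfect_pair_hits_diagonal(self, rng):
        m = rng.integers(0, 3, (3, 3))
        acc = accumulate(m, m, ConfusionAccumulator(3))
        assert np.trace(acc.counts) == 9 and acc.counts.sum() == 9

    def test_hand_bookkeeping(self):
        acc = accumulate(
            np.array([[1], [1]]), np.array([[0], [1]]), ConfusionAccumulator(2)
        )
        assert acc.counts[0, 1] == 1 and acc.counts[1, 1] == 1 and acc.counts.sum() == 2

    def test_commutative_accumulation(self, rng):
        a_p, a_t = random_mask_pair(rng), random_mask_pair(rng)
        pairs = [a_p, a_t]
        acc1 = ConfusionAccumulator(4)
        for p, t in pairs:
            accumulate(p, t, acc1)
        acc2 = ConfusionAccumulator(4)
        for p, t in reversed(pairs):
            accumulate(p, t, acc2)
        assert (acc1.counts == acc2.counts).all()

    def test_shape_and_label_validation(self):
        with pytest.raises(ValueError):
            accumulate(np.zeros((2, 2), int), np.zeros((3, 3), int),
                       ConfusionAccumulator(2))
        with pytest.raises(ValueError):
            accumulate(np.full((2, 2), 5), np.zeros((2, 2), int),
                       ConfusionAccumulator(2))


class TestClassMetrics:
    def test_hand_counts(self):
        """TP=3 FP=1 FN=1 TN=5 -> acc 0.8, iou 0.6, dice 0.75, p=r=0.75."""
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]).reshape(2, 5)
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0]).reshape(2, 5)
        acc = accumulate(pred, truth, ConfusionAccumulator(2))
        cm = class_metrics(acc, 1)
        assert cm.acc_ovr == pytest.approx(0.8)
        assert cm.iou == pytest.approx(0.6)
        assert cm.dice == pytest.approx(0.75)
        assert cm.precision == pytest.approx(0.75)
        assert cm.recall == pytest.approx(0.75)
        assert cm.class_acc == cm.recall

    def test_perfect_prediction_all_ones(self, rng):
        m = rng.integers(0, 3, (4, 4))
        acc = accumulate(m, m, ConfusionAccumulator(3))
        for c in np.unique(m):
            cm = class_metrics(acc, int(c))
            for v in (cm.acc_ovr, cm.class_acc, cm.iou, cm.dice, cm.precision,
                      cm.recall):
                assert v == pytest.approx(1.0)

    def test_dice_iou_identity_on_random_states(self, rng):
        for _ in range(50):
            acc = ConfusionAccumulator(3, rng.integers(0, 20, (3, 3)))
            for c in range(3):
                cm = class_metrics(acc, c)
                if cm.defined:
                    assert cm.dice == pytest.approx(2 * cm.iou / (1 + cm.iou))

    def test_absent_class_undefined(self):
        acc = accumulate(np.zeros((2, 2), int), np.zeros((2, 2), int),
                         ConfusionAccumulator(3))
        assert not class_metrics(acc, 2).defined


def test_region_metrics_match_bruteforce_oracle(rng):
    """Confusion-matrix metrics agree exactly with explicit pixel sets."""
    for _ in range(300):
        pred, truth = random_mask_pair(rng)
        acc = accumulate(pred, truth, ConfusionAccumulator(4))
        for c in range(4):
            tp, fp, fn, tn = oracle_counts(pred, truth, c)
            cm = class_metrics(acc, c)
            if tp + fp + fn == 0:
                assert not cm.defined
                continue
            assert cm.iou == pytest.approx(tp / (tp + fp + fn), abs=1e-12)
            assert cm.dice == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
            assert cm.acc_ovr == pytest.approx((tp + tn) / pred.size, abs=1e-12)
            if tp + fn:
                assert cm.recall == pytest.approx(tp / (tp + fn), abs=1e-12)
            if tp + fp:
                assert cm.precision == pytest.approx(tp / (tp + fp), abs=1e-12)


class TestBoundaryF1:
    def test_perfect_match_is_one(self, rng):
        m = np.zeros((8, 8), int)
        m[2:5, 2:6] = 1
        assert boundary_f1(m, m, 1, theta=2.0) == pytest.approx(1.0)

    def test_one_pixel_shift_within_tolerance(self):
        truth = np.zeros((10, 10), int)
        truth[2:6, 2:6] = 1
        pred = np.zeros((10, 10), int)
        pred[3:7, 2:6] = 1  # shifted down by one pixel
        assert boundary_f1(pred, truth, 1, theta=2.0) == pytest.approx(1.0)

    def test_distant_regions_no_match(self):
        truth = np.zeros((3, 12), int)
        truth[1, 0] = 1
        pred = np.zeros((3, 12), int)
        pred[1, 10] = 1
        assert boundary_f1(pred, truth, 1, theta=2.0) == 0.0

    def test_absent_class_undefined(self):
        z = np.zeros((4, 4), int)
        assert boundary_f1(z, z, 1, theta=1.0) is None

    def test_swap_symmetry(self, rng):
        for _ in range(30):
            pred, truth = random_mask_pair(rng)
            for c in range(4):
                a = boundary_f1(pred, truth, c, theta=1.5)
                b = boundary_f1(truth, pred, c, theta=1.5)
                if a is None:
                    assert b is None
                else:
                    assert a == pytest.approx(b, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(60):
            pred, truth = random_mask_pair(rng)
            theta = 1.5
            for c in range(4):
                got = boundary_f1(pred, truth, c, theta=theta)
                want = oracle_bfs(pred, truth, c, theta)
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-9)

    def test_default_theta_tracks_diagonal(self):
        assert default_theta((480, 854)) == pytest.approx(
            0.0075 * np.hypot(480, 854)
        )


class TestSummarize:
    def test_perfect_dataset_all_aggregates_one(self, rng):
        acc = ConfusionAccumulator(3)
        bfs_rows = []
        for _ in range(4):
            m = rng.integers(0, 3, (6, 6))
            accumulate(m, m, acc)
            bfs_rows.append([boundary_f1(m, m, c, 2.0) for c in range(3)])
        rep = summarize(acc, bfs_rows)
        assert rep.gacc == rep.macc == rep.miou == 1.0
        assert rep.mbfs == pytest.approx(1.0)

    def test_miou_is_unweighted_mean(self):
        # class 1: iou 0.6 (3/5); class 0: iou 1.0; constructed directly
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]).reshape(2, 5)
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0]).reshape(2, 5)
        acc = accumulate(pred, truth, ConfusionAccumulator(2))
        rep = summarize(acc)
        iou0 = class_metrics(acc, 0).iou
        assert rep.miou == pytest.approx((iou0 + 0.6) / 2)

    def test_absent_class_excluded_from_means(self):
        m = np.zeros((3, 3), int)
        rep = summarize(accumulate(m, m, ConfusionAccumulator(5)))
        assert rep.miou == 1.0 and rep.macc == 1.0

    def test_gacc_weighted_mean_identity(self, rng):
        acc = ConfusionAccumulator(4)
        for _ in range(5):
            p, t = random_mask_pair(rng)
            accumulate(p, t, acc)
        rep = summarize(acc)
        df = rep.per_class
        w = (df["support"] * df["class_acc"].fillna(0)).sum() / acc.total
        assert rep.gacc == pytest.approx(w)

    def test_flipping_correct_pixel_never_increases_gacc(self, rng):
        truth = rng.integers(0, 3, (5, 5))
        pred = truth.copy()
        base = summarize(accumulate(pred, truth, ConfusionAccumulator(3))).gacc
        pred[2, 2] = (pred[2, 2] + 1) % 3
        worse = summarize(accumulate(pred, truth, ConfusionAccumulator(3))).gacc
        assert worse <= base

    def test_empty_accumulator_rejected(self):
        with pytest.raises(ValueError):
            summarize(ConfusionAccumulator(3))

    def test_csv_report_has_aggregate_footer(self, tmp_path, rng):
        m = rng.integers(0, 3, (4, 4))
        rep = summarize(accumulate(m, m, ConfusionAccumulator(3)))
        rep.to_csv(tmp_path / "r.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "r.csv")
        assert df.iloc[-1]["class"] == "AGGREGATE"
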