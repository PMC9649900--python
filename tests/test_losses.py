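"""Region losses against scalar-loop oracles, worked values, and metrics."""

import numpy as np
import pytest

from scintiseg.losses import (confusion_counts, fit_membership, metrics,
                              region_statistics, supervised_loss, total_loss,
                              total_variation, unsupervised_loss)


def loop_unsupervised(g, m, v):
    """Per-pixel scalar-loop oracle for the region energy."""
    h, w = g.shape
    sm = smg = so = sog = 0.0
    for i in range(h):
        for j in range(w):
            sm += m[i, j]
            smg += m[i, j] * g[i, j]
            so += 1 - m[i, j]
            sog += (1 - m[i, j]) * g[i, j]
    c1 = smg / sm if sm > 0 else 0.0
    c2 = sog / so if so > 0 else 0.0
    total = v * sm
    for i in range(h):
        for j in range(w):
            total += m[i, j] * (g[i, j] - c1) ** 2
            total += (1 - m[i, j]) * (g[i, j] - c2) ** 2
    return total


def loop_supervised(m, mu):
    """Per-pixel / per-edge scalar-loop oracle for the supervised loss."""
    h, w = m.shape
    tv = 0.0
    for i in range(h - 1):
        for j in range(w):
            tv += abs(m[i + 1, j] - m[i, j])
    for i in range(h):
        for j in range(w - 1):
            tv += abs(m[i, j + 1] - m[i, j])
    region = 0.0
    for i in range(h):
        for j in range(w):
            region += (1 - 2 * int(mu[i, j])) * m[i, j]
    return tv + region


class TestRegionStatistics:
    def test_piecewise_constant_two_level(self):
        g = np.full((8, 8), 0.1)
        g[2:6, 2:6] = 0.8
        m = np.zeros((8, 8))
        m[2:6, 2:6] = 1.0
        stats = region_statistics(g, m)
        assert stats.c1 == pytest.approx(0.8)
        assert stats.c2 == pytest.approx(0.1)
        assert stats.area_inside == pytest.approx(16.0)

    def test_empty_inside_region_convention(self, rng):
        g = rng.random((6, 6))
        stats = region_statistics(g, np.zeros((6, 6)))
        assert stats.c1 == 0.0
        assert stats.c2 == pytest.approx(g.mean())

    def test_soft_membership_matches_loop(self, rng):
        g, m = rng.random((9, 9)), rng.random((9, 9))
        stats = region_statistics(g, m)
        assert stats.c1 == pytest.approx((m * g).sum() / m.sum(), abs=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            region_statistics(rng.random((4, 4)), rng.random((4, 5)))


class TestUnsupervisedLoss:
    def test_worked_two_level_case(self):
        # hard mask matching a two-level image exactly: residuals vanish and
        # only the area term v * |inside| = 0.004 * 16 = 0.064 remains
        g = np.full((8, 8), 0.1)
        g[2:6, 2:6] = 0.8
        m = np.zeros((8, 8))
        m[2:6, 2:6] = 1.0
        assert unsupervised_loss(g, m, v=0.004) == pytest.approx(0.064)

    def test_zero_membership_constant_image(self):
        assert unsupervised_loss(np.full((5, 5), 0.3),
                                 np.zeros((5, 5))) == pytest.approx(0.0)

    def test_zero_membership_equals_total_variance(self, rng):
        g = rng.random((7, 7))
        expect = ((g - g.mean()) ** 2).sum()
        assert unsupervised_loss(g, np.zeros_like(g), v=0.004) == \
            pytest.approx(expect, abs=1e-10)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(20):
            g, m = rng.random((16, 16)), rng.random((16, 16))
            assert unsupervised_loss(g, m, v=0.004) == \
                pytest.approx(loop_unsupervised(g, m, 0.004), abs=1e-8)

    def test_constant_shift_moves_both_means_equally(self, rng):
        g, m = rng.random((8, 8)), rng.random((8, 8))
        s0, s1 = region_statistics(g, m), region_statistics(g + 0.5, m)
        assert s1.c1 - s0.c1 == pytest.approx(0.5, abs=1e-9)
        assert s1.c2 - s0.c2 == pytest.approx(0.5, abs=1e-9)
        # residual structure unchanged: loss differs only via nothing at all
        # (area term has no g dependence), so the shift cancels exactly
        l0 = unsupervised_loss(g, m, v=0.0)
        l1 = unsupervised_loss(g + 0.5, m, v=0.0)
        assert l0 == pytest.approx(l1, abs=1e-8)


class TestSupervisedLoss:
    def test_zero_membership_is_zero(self):
        mu = np.zeros((5, 5), dtype=np.uint8)
        mu[2, 2] = 1
        assert supervised_loss(np.zeros((5, 5)), mu) == 0.0

    def test_perfect_hard_prediction_single_pixel(self):
        # m = mu with one centered pixel: region term -1, anisotropic
        # forward-difference TV = 4 (two vertical + two horizontal jumps)
        mu = np.zeros((3, 3), dtype=np.uint8)
        mu[1, 1] = 1
        m = mu.astype(float)
        assert total_variation(m) == pytest.approx(4.0)
        assert supervised_loss(m, mu) == pytest.approx(3.0)

    def test_region_term_is_minus_area_for_perfect_prediction(self, rng):
        for _ in range(5):
            mu = (rng.random((10, 10)) > 0.6).astype(np.uint8)
            m = mu.astype(float)
            region = supervised_loss(m, mu) - total_variation(m)
            assert region == pytest.approx(-int(mu.sum()), abs=1e-9)

    def test_all_ones_prediction_on_empty_truth(self):
        m = np.ones((6, 6))
        mu = np.zeros((6, 6), dtype=np.uint8)
        assert supervised_loss(m, mu) == pytest.approx(36.0)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(20):
            m = rng.random((16, 16))
            mu = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            assert supervised_loss(m, mu) == \
                pytest.approx(loop_supervised(m, mu), abs=1e-8)

    def test_non_binary_label_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            supervised_loss(rng.random((4, 4)), rng.random((4, 4)))


class TestTotalLoss:
    def test_unlabeled_branch(self, rng):
        g, m = rng.random((8, 8)), rng.random((8, 8))
        lc = total_loss(g, m, mu=None)
        assert lc.l_s == 0.0
        assert lc.l_total == pytest.approx(lc.l_u)

    def test_labeled_branch_arithmetic(self):
        g = np.full((8, 8), 0.1)
        g[2:6, 2:6] = 0.8
        m = np.zeros((8, 8))
        m[2:6, 2:6] = 1.0
        mu = m.astype(np.uint8)
        lc = total_loss(g, m, mu, alpha=0.4, v=0.004)
        assert lc.l_u == pytest.approx(0.064)
        assert lc.l_total == pytest.approx(lc.l_u + 0.4 * lc.l_s, abs=1e-10)

    def test_alpha_zero_reduces_to_unsupervised(self, rng):
        g, m = rng.random((6, 6)), rng.random((6, 6))
        mu = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        lc = total_loss(g, m, mu, alpha=0.0)
        assert lc.l_total == pytest.approx(lc.l_u)


class TestMetrics:
    def test_worked_counts(self):
        sm = metrics(tp=30, fp=10, fn=20)
        assert sm.dsc == pytest.approx(60 / 90)
        assert sm.cpa == pytest.approx(0.75)
        assert sm.recall == pytest.approx(0.6)

    def test_perfect_and_empty_predictions(self):
        assert metrics(50, 0, 0).dsc == 1.0
        sm = metrics(0, 0, 25)
        assert sm.dsc == 0.0 and sm.recall == 0.0 and sm.cpa is None
        assert metrics(0, 0, 0).dsc == 1.0  # both masks empty

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(-1, 0, 0)

    def test_confusion_counts_cases(self, rng):
        truth = (rng.random((12, 12)) > 0.7).astype(np.uint8)
        tp, fp, fn, tn = confusion_counts(truth, truth)
        assert (tp, fp, fn) == (truth.sum(), 0, 0)
        assert tp + fp + fn + tn == truth.size
        # prediction strictly containing truth: FP = extra pixels, FN = 0
        pred = truth.copy()
        extra = np.flatnonzero(pred.ravel() == 0)[:10]
        pred.ravel()[extra] = 1
        tp, fp, fn, _ = confusion_counts(pred, truth)
        assert (fp, fn) == (10, 0)

    def test_dsc_symmetry(self, rng):
        a = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        b = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        tp1, fp1, fn1, _ = confusion_counts(a, b)
        tp2, fp2, fn2, _ = confusion_counts(b, a)
        assert metrics(tp1, fp1, fn1).dsc == pytest.approx(
            metrics(tp2, fp2, fn2).dsc)


class TestChanVeseFit:
    def test_recovers_two_level_region_quickly(self):
        g = np.full((32, 32), 0.1)
        g[8:20, 10:24] = 0.9
        m, history = fit_membership(g, v=0.004, iters=150)
        pred = (m > 0.5).astype(np.uint8)
        truth = (g > 0.5).astype(np.uint8)
        tp, fp, fn, _ = confusion_counts(pred, truth)
        assert metrics(tp, fp, fn).dsc >= 0.99
        assert history[-1] <= history[0]
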