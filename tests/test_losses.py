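"""Loss-function values, identities, monotonicity, and gradients."""

import numpy as np
import pytest

from lapseg.losses import (
    LossConfig,
    combined_loss,
    cross_entropy,
    dice_loss,
    focal_loss,
    loss_and_logit_grad,
    loss_value,
    softmax_probabilities,
    tversky_index,
    tversky_loss,
)


def one_hot(target, c):
    p = np.zeros(target.shape + (c,))
    idx = np.indices(target.shape)
    p[(*idx, target)] = 1.0
    return p


class TestSoftmax:
    def test_uniform_on_zero_logits(self):
        p = softmax_probabilities(np.zeros((2, 2, 4)))
        assert np.allclose(p, 0.25)

    def test_closed_form_two_class(self):
        p = softmax_probabilities(np.array([[[np.log(1.0), np.log(3.0)]]]))
        assert np.allclose(p[0, 0], [0.25, 0.75])

    def test_shift_invariance_and_stability(self, rng):
        z = rng.normal(0, 3, (3, 3, 5))
        assert np.allclose(
            softmax_probabilities(z), softmax_probabilities(z + 1234.5)
        )
        assert np.isfinite(softmax_probabilities(z * 200)).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_probabilities(np.array([[[np.inf, 0.0]]]))


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        t = np.array([[1]])
        assert cross_entropy(one_hot(t, 3), t) == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_is_log_two(self):
        p = np.array([[[0.5, 0.5]]])
        assert cross_entropy(p, np.array([[0]])) == pytest.approx(np.log(2), abs=1e-12)

    def test_two_pixel_mean(self):
        p = np.array([[[0.5, 0.5], [0.25, 0.75]]])
        t = np.array([[0, 0]])
        expected = (np.log(2) + np.log(4)) / 2
        assert cross_entropy(p, t) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_clamped_finite(self):
        p = np.array([[[0.0, 1.0]]])
        assert np.isfinite(cross_entropy(p, np.array([[0]])))

    def test_uniform_weights_reduce_to_plain_mean(self, rng):
        p = softmax_probabilities(rng.normal(0, 1, (4, 4, 3)))
        t = rng.integers(0, 3, (4, 4))
        assert cross_entropy(p, t, np.ones(3)) == pytest.approx(
            cross_entropy(p, t), abs=1e-12
        )


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self, rng):
        """FL reduces to CE at gamma=0, alpha=1 (to 1e-10, random inputs)."""
        for _ in range(10):
            p = softmax_probabilities(rng.normal(0, 2, (5, 6, 4)))
            t = rng.integers(0, 4, (5, 6))
            assert abs(
                focal_loss(p, t, alpha_t=1.0, gamma=0.0) - cross_entropy(p, t)
            ) < 1e-10

    def test_hand_value_easy_pixel(self):
        p = np.array([[[0.9, 0.1]]])
        expected = 0.25 * 0.1**2 * -np.log(0.9)
        assert focal_loss(p, np.array([[0]]), 0.25, 2.0) == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(2.634e-4, rel=1e-3)

    def test_perfect_prediction_zero_any_params(self):
        t = np.array([[2]])
        for gamma in (0.0, 2.0, 4.0):
            assert focal_loss(one_hot(t, 3), t, 0.25, gamma) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_monotone_in_pt_and_gamma(self):
        pts = np.linspace(0.05, 0.95, 19)
        for gamma in (0.5, 2.0, 4.0):
            vals = [
                focal_loss(np.array([[[pt, 1 - pt]]]), np.array([[0]]), 1.0, gamma)
                for pt in pts
            ]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        for pt in (0.2, 0.6, 0.9):
            p = np.array([[[pt, 1 - pt]]])
            t = np.array([[0]])
            v = [focal_loss(p, t, 1.0, g) for g in (0.0, 1.0, 2.0, 4.0)]
            assert all(a >= b for a, b in zip(v, v[1:]))


class TestTversky:
    # 5-pixel toy: truth has 4 pixels of class 1, pred gets 3 right (TP=3),
    # one wrong class-1 claim on a background pixel (FP=1), one miss (FN=1)
    truth = np.array([[1, 1, 1, 1, 0]])
    pred_labels = np.array([[1, 1, 1, 0, 1]])

    def test_hand_counts_give_three_quarters(self):
        p = one_hot(self.pred_labels, 2)
        ti = tversky_index(p, self.truth, 1, sigma=0.3, beta=0.7)
        assert ti == pytest.approx(3 / (3 + 0.3 + 0.7), abs=1e-6)

    def test_half_half_is_dice(self):
        p = one_hot(self.pred_labels, 2)
        ti = tversky_index(p, self.truth, 1, sigma=0.5, beta=0.5)
        assert ti == pytest.approx(2 * 3 / (2 * 3 + 1 + 1), abs=1e-6)

    def test_perfect_prediction_index_one(self):
        p = one_hot(self.truth, 2)
        assert tversky_index(p, self.truth, 1) == pytest.approx(1.0, abs=1e-5)

    def test_loss_perfect_zero_and_bounded(self, rng):
        t = rng.integers(0, 13, (6, 6))
        assert tversky_loss(one_hot(t, 13), t) == pytest.approx(0.0, abs=1e-3)
        p = softmax_probabilities(rng.normal(0, 1, (6, 6, 13)))
        assert 0.0 <= tversky_loss(p, t) <= 13.0

    def test_single_class_loss_from_index(self):
        p = one_hot(self.pred_labels, 2)
        tl = tversky_loss(p, self.truth, 0.3, 0.7)
        ti0 = tversky_index(p, self.truth, 0, 0.3, 0.7)
        ti1 = tversky_index(p, self.truth, 1, 0.3, 0.7)
        assert tl == pytest.approx((1 - ti0) + (1 - ti1), abs=1e-9)

    def test_fp_fn_monotonicity(self):
        base = one_hot(np.array([[1, 1, 0, 0, 0, 0]]), 2)
        truth = np.array([[1, 1, 1, 0, 0, 0]])
        ti0 = tversky_index(base, truth, 1, 0.3, 0.7)
        fp = base.copy()
        fp[0, 3] = [0, 1]  # claim a background pixel
        assert tversky_index(fp, truth, 1, 0.3, 0.7) < ti0
        truth_more = np.array([[1, 1, 1, 1, 0, 0]])  # one more missed pixel
        assert tversky_index(base, truth_more, 1, 0.3, 0.7) < ti0

    def test_dice_loss_is_tversky_at_half(self, rng):
        p = softmax_probabilities(rng.normal(0, 1, (5, 5, 3)))
        t = rng.integers(0, 3, (5, 5))
        assert dice_loss(p, t) == pytest.approx(
            tversky_loss(p, t, 0.5, 0.5), abs=1e-12
        )
        assert dice_loss(p, t, per_image=True) >= 0.0

    def test_hand_dice_value(self):
        p = one_hot(self.pred_labels, 2)
        # class 1 alone: 1 - 6/8 = 0.25
        ti = tversky_index(p, self.truth, 1, 0.5, 0.5)
        assert 1 - ti == pytest.approx(0.25, abs=1e-6)


class TestCombined:
    def test_delta_one_is_cross_entropy(self, rng):
        p = softmax_probabilities(rng.normal(0, 1, (4, 4, 3)))
        t = rng.integers(0, 3, (4, 4))
        cfg = LossConfig(kind="CETL", delta=1.0)
        assert combined_loss("CETL", p, t, cfg) == pytest.approx(
            cross_entropy(p, t), abs=1e-12
        )

    def test_delta_zero_is_region_term(self, rng):
        p = softmax_probabilities(rng.normal(0, 1, (4, 4, 3)))
        t = rng.integers(0, 3, (4, 4))
        cfg = LossConfig(kind="CETL", delta=0.0)
        assert combined_loss("CETL", p, t, cfg) == pytest.approx(
            tversky_loss(p, t, cfg.sigma, cfg.beta, cfg.epsilon), abs=1e-12
        )
        cfg = LossConfig(kind="CEDL", delta=0.0)
        assert combined_loss("CEDL", p, t, cfg) == pytest.approx(
            dice_loss(p, t, cfg.epsilon), abs=1e-12
        )

    def test_hand_mixture_value(self):
        """delta=0.7 blend of CE=ln2 and TL=0.25 gives 0.5602."""
        ce, tl = np.log(2), 0.25
        assert 0.7 * ce + 0.3 * tl == pytest.approx(0.5602, abs=1e-4)
        # and the implementation reproduces the algebra on a constructed case
        p = np.array([[[0.5, 0.5]]])
        t = np.array([[0]])
        cfg = LossConfig(kind="CETL", delta=0.7)
        expected = 0.7 * cross_entropy(p, t) + 0.3 * tversky_loss(
            p, t, cfg.sigma, cfg.beta, cfg.epsilon
        )
        assert combined_loss("CETL", p, t, cfg) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "cfg",
    [
        LossConfig(kind="CE"),
        LossConfig(kind="CE", class_weights=np.array([0.5, 2.0, 1.0])),
        LossConfig(kind="FL", alpha_t=0.25, gamma=2.0),
        LossConfig(kind="FL", alpha_t=1.0, gamma=0.0),
        LossConfig(kind="FL", alpha_t=0.25, gamma=4.0),
        LossConfig(kind="DiL"),
        LossConfig(kind="TL", sigma=0.3, beta=0.7),
        LossConfig(kind="TL", weight_tversky=True, class_weights=np.array([1.0, 3.0, 0.5])),
        LossConfig(kind="CEDL", delta=0.7),
        LossConfig(kind="CETL", delta=0.7, class_weights=np.array([0.5, 2.0, 1.0])),
    ],
    ids=lambda c: f"{c.kind}-g{c.gamma}-w{c.class_weights is not None}",
)
def test_analytic_gradient_matches_finite_differences(cfg, rng):
    """Gradient w.r.t. logits matches central differences to 1e-4 relative."""
    logits = rng.normal(0, 1.5, (4, 4, 3))
    target = rng.integers(0, 3, (4, 4))
    _, g = loss_and_logit_grad(logits, target, cfg)
    num = np.zeros_like(logits)
    eps = 1e-6
    for idx in np.ndindex(logits.shape):
        lp, lm = logits.copy(), logits.copy()
        lp[idx] += eps
        lm[idx] -= eps
        num[idx] = (
            loss_value(softmax_probabilities(lp), target, cfg)
            - loss_value(softmax_probabilities(lm), target, cfg)
        ) / (2 * eps)
    scale = np.abs(num).max()
    assert np.abs(g - num).max() <= 1e-4 * scale


def test_losses_nonnegative_and_zero_only_at_perfect(rng):
    t = rng.integers(0, 3, (5, 5))
    perfect = one_hot(t, 3)
    imperfect = softmax_probabilities(rng.normal(0, 1, (5, 5, 3)))
    for cfg in (LossConfig(kind=k) for k in ("CE", "FL", "DiL", "TL", "CEDL", "CETL")):
        assert loss_value(perfect, t, cfg) == pytest.approx(0.0, abs=1e-3)
        assert loss_value(imperfect, t, cfg) > 0.0


def test_config_validation_and_round_trip():
    with pytest.raises(ValueError):
        LossConfig(kind="XX")
    with pytest.raises(ValueError):
        LossConfig(delta=1.5)
    with pytest.raises(ValueError):
        LossConfig(gamma=-1)
    cfg = LossConfig(kind="CETL", class_weights=np.array([1.0, 2.0]))
    again = LossConfig.from_dict(cfg.to_dict())
    assert again.kind == "CETL" and np.allclose(again.class_weights, [1.0, 2.0])
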