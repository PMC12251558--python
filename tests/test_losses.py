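import numpy as np
import pytest

from gpbr import (ClassWeights, MaskField, bsp_loss, class_weights, focal_loss,
                  lambda_schedule, mask_from_cam, oap_loss, total_loss,
                  total_loss_grads)


def test_mask_from_cam_values():
    assert np.allclose(mask_from_cam(np.zeros((1, 2, 2))).a, 0.5)
    assert np.allclose(mask_from_cam(np.full((1, 1, 1), 20.0)).a, 1.0, atol=1e-8)
    assert np.allclose(mask_from_cam(np.full((1, 1, 1), np.log(3.0))).a, 0.75)
    with pytest.raises(ValueError):
        mask_from_cam(np.array([[[np.inf]]]))


def test_mask_field_open_interval():
    with pytest.raises(ValueError):
        MaskField(np.array([[[0.0]]]))
    with pytest.raises(ValueError):
        MaskField(np.array([[[1.0]]]))


@pytest.mark.parametrize("C", [2, 3, 5])
def test_oap_uniform_half_masks(C):
    a = MaskField(np.full((C, 2, 2), 0.5))
    assert oap_loss(a, a) == pytest.approx(1.0)   # 2*2*0.25 regardless of C


def test_oap_hand_case_and_disjoint():
    a1 = MaskField(np.array([0.8, 0.2]).reshape(2, 1, 1))
    a2 = MaskField(np.array([0.4, 0.9]).reshape(2, 1, 1))
    assert oap_loss(a1, a2) == pytest.approx((0.32 + 0.18) / 2)
    hi, lo = 1 - 1e-9, 1e-9
    d1 = np.full((2, 1, 4), lo)
    d2 = np.full((2, 1, 4), lo)
    d1[:, :, :2] = hi
    d2[:, :, 2:] = hi                              # spatially disjoint supports
    assert oap_loss(MaskField(d1), MaskField(d2)) < 1e-6


def test_oap_symmetry_and_overlap_monotonicity(rng):
    a1 = MaskField(rng.uniform(0.01, 0.99, (3, 4, 4)))
    a2 = MaskField(rng.uniform(0.01, 0.99, (3, 4, 4)))
    assert oap_loss(a1, a2) == pytest.approx(oap_loss(a2, a1))
    # making overlapping high-mask regions disjoint lowers the penalty
    both_hi = MaskField(np.full((1, 2, 2), 0.95))
    moved = np.full((1, 2, 2), 0.05)
    moved[0, 0, 0] = 0.95
    assert oap_loss(both_hi, MaskField(moved)) < oap_loss(both_hi, both_hi)
    with pytest.raises(ValueError):
        oap_loss(a1, MaskField(rng.uniform(0.1, 0.9, (3, 2, 2))))


def test_bsp_values_and_properties(rng):
    assert bsp_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
    assert bsp_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)
    s1, s2 = rng.normal(size=5), rng.normal(size=5)
    assert bsp_loss(3.0 * s1, 3.0 * s2) == pytest.approx(3.0 * bsp_loss(s1, s2))
    s3 = rng.normal(size=5)
    assert bsp_loss(s1, s3) <= bsp_loss(s1, s2) + bsp_loss(s2, s3) + 1e-12
    with pytest.raises(ValueError):
        bsp_loss(np.zeros(3), np.zeros(4))


def test_class_weights():
    assert np.allclose(class_weights([10, 10, 10]).alpha, 1.0)
    assert np.allclose(class_weights([1, 3]).alpha, [1.5, 0.5])
    counts = [100, 160, 30, 5, 2]
    alpha = class_weights(counts).alpha
    assert np.array_equal(np.argsort(alpha), np.argsort(counts)[::-1])
    assert alpha.sum() == pytest.approx(5.0)
    with pytest.raises(ValueError):
        class_weights([3, 0])


def test_focal_loss_values():
    alpha = ClassWeights(np.ones(2))
    assert focal_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]), alpha) == 0.0
    # gamma=0, alpha=1 reduces to cross-entropy
    y = np.array([0.7, 0.3])
    t = np.array([1.0, 0.0])
    assert focal_loss(y, t, alpha, gamma=0.0) == pytest.approx(-np.log(0.7))
    # hand case: y=(0.9, 0.1), true class first, gamma=2
    got = focal_loss(np.array([0.9, 0.1]), t, alpha, gamma=2.0)
    assert got == pytest.approx(0.01 * -np.log(0.9), rel=1e-9)
    with pytest.raises(ValueError):
        focal_loss(np.array([0.5, 0.2]), t, alpha)


def test_lambda_schedule_anchors_and_monotonicity():
    assert lambda_schedule(0, 40) == 1.0
    assert lambda_schedule(39, 40) == 0.0
    assert lambda_schedule(20, 41) == pytest.approx(0.5)
    vals = [lambda_schedule(e, 40) for e in range(40)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    cos = [lambda_schedule(e, 40, "cosine") for e in range(40)]
    assert cos[0] == 1.0 and cos[-1] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        lambda_schedule(0, 1)
    with pytest.raises(ValueError):
        lambda_schedule(40, 40)


def _toy_case():
    # C=2, h=w=1: everything reducible to scalars
    M1 = np.array([1.0, -0.5]).reshape(2, 1, 1)
    M2 = np.array([0.2, 0.4]).reshape(2, 1, 1)
    t = np.array([1.0, 0.0])
    alpha = ClassWeights(np.array([0.8, 1.2]))
    return M1, M2, t, alpha


def test_total_loss_composes_hand_evaluated_terms():
    M1, M2, t, alpha = _toy_case()
    lam = 0.7
    bd = total_loss(M1, M2, t, alpha, gamma=2.0, lambda_t=lam)
    # independent evaluation from the printed formulas
    S1, S2 = M1[:, 0, 0], M2[:, 0, 0]
    Sbar = 0.5 * (S1 + S2)
    e = np.exp(Sbar - Sbar.max())
    y = e / e.sum()
    l_fl = -(alpha.alpha * (1 - y) ** 2 * t * np.log(y)).sum()
    a1 = 1 / (1 + np.exp(-S1))
    a2 = 1 / (1 + np.exp(-S2))
    l_oap = (a1 * a2).sum() / 2
    l_bsp = np.abs(S1 - S2).mean()
    assert bd.l_fl == pytest.approx(l_fl, rel=1e-9)
    assert bd.l_oap == pytest.approx(l_oap, rel=1e-9)
    assert bd.l_bsp == pytest.approx(l_bsp, rel=1e-9)
    assert bd.l_total == pytest.approx(l_fl + lam * l_oap + l_bsp, rel=1e-9)


def test_total_loss_degenerate_weights():
    M1, M2, t, alpha = _toy_case()
    bd0 = total_loss(M1, M2, t, alpha, lambda_t=0.0)
    assert bd0.l_total == pytest.approx(bd0.l_fl + bd0.l_bsp)
    bd_same = total_loss(M1, M1, t, alpha, lambda_t=0.5)
    assert bd_same.l_bsp == 0.0
    assert bd_same.l_total == pytest.approx(bd_same.l_fl + 0.5 * bd_same.l_oap)


@pytest.mark.parametrize("lam, bsp_w", [(1.0, 1.0), (0.3, 1.0), (0.0, 0.0)])
def test_total_loss_gradients_match_finite_differences(lam, bsp_w, rng):
    M1 = rng.normal(size=(2, 3, 2, 2))
    M2 = rng.normal(size=(2, 3, 2, 2))
    t = np.eye(3)[[0, 2]]
    alpha = class_weights([4, 2, 1])
    _, g1, g2 = total_loss_grads(M1, M2, t, alpha, 2.0, lam, bsp_w)
    eps = 1e-6

    def loss_at(A, B):
        return total_loss(A, B, t, alpha, 2.0, lam, bsp_w).l_total

    for M, g in ((M1, g1), (M2, g2)):
        num = np.zeros_like(M)
        for idx in np.ndindex(M.shape):
            Mp, Mm = M.copy(), M.copy()
            Mp[idx] += eps
            Mm[idx] -= eps
            if M is M1:
                num[idx] = (loss_at(Mp, M2) - loss_at(Mm, M2)) / (2 * eps)
            else:
                num[idx] = (loss_at(M1, Mp) - loss_at(M1, Mm)) / (2 * eps)
        assert np.max(np.abs(num - g)) < 1e-4


def test_losses_nonnegative(rng):
    for _ in range(10):
        M1 = rng.normal(size=(2, 1, 1)) * 3
        M2 = rng.normal(size=(2, 1, 1)) * 3
        t = np.eye(2)[rng.integers(0, 2)]
        bd = total_loss(M1, M2, t, ClassWeights(np.ones(2)), lambda_t=0.5)
        assert bd.l_fl >= 0 and bd.l_oap >= 0 and bd.l_bsp >= 0
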