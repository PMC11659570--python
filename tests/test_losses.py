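"""Loss-family checks against naive-loop reference implementations.

Every reference here recomputes the loss with explicit Python loops from
the written definition (cosine/distance softmax over in-batch candidates,
label-similarity weighting, per-code cross-entropy) independently of the
vectorised implementations.
"""

import numpy as np
import pytest

from cocoder._autodiff import Tensor
from cocoder.losses import (dynamic_coefficients, label_similarity, loss_bce,
                            loss_ml_con, loss_step2, loss_step3, loss_us_con)

RNG = np.random.default_rng(7)


# -- naive references ---------------------------------------------------------

def cosine(a, b):
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))


def naive_us_con(z, pos, tau):
    b = len(z)
    total = 0.0
    for i in range(b):
        denom = sum(np.exp(cosine(z[i], pos[j]) / tau) for j in range(b))
        total += -np.log(np.exp(cosine(z[i], pos[i]) / tau) / denom)
    return total / b


def naive_ml_con(z, y, tau):
    b = len(z)
    total = 0.0
    for i in range(b):
        row_sum = sum(int(y[i] @ y[k]) for k in range(b) if k != i)
        if row_sum == 0:
            continue
        denom = sum(np.exp(-np.linalg.norm(z[i] - z[k]) / tau)
                    for k in range(b) if k != i)
        for j in range(b):
            if j == i:
                continue
            beta = int(y[i] @ y[j]) / row_sum
            p = np.exp(-np.linalg.norm(z[i] - z[j]) / tau) / denom
            total += -beta * np.log(p)
    return total / b


def naive_bce(p, y, eps=1e-7):
    p = np.clip(p, eps, 1 - eps)
    total = 0.0
    for i in range(p.shape[0]):
        for l in range(p.shape[1]):
            total += -y[i, l] * np.log(p[i, l]) - (1 - y[i, l]) * np.log(1 - p[i, l])
    return total / p.shape[0]


def random_batch(b, d, n_codes):
    z = RNG.normal(size=(b, d))
    pos = RNG.normal(size=(b, d))
    y = (RNG.random((b, n_codes)) < 0.3).astype(int)
    return z, pos, y


# -- closed-form examples -----------------------------------------------------

def test_us_con_uniform_similarities_give_log_b():
    # identical inputs and views: every similarity is 1, softmax is uniform
    z = np.tile(RNG.normal(size=3), (5, 1))
    assert float(loss_us_con(z, z.copy(), tau=1.0).data) == pytest.approx(np.log(5))


def test_us_con_single_pair_closed_form():
    # positive at sim 1, lone negative at sim 0, tau 1: -log(e / (e + 1))
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    expected = -np.log(np.e / (np.e + 1.0))
    assert float(loss_us_con(z, z.copy(), tau=1.0).data) == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(0.3133, abs=1e-4)


def test_us_con_rejects_degenerate_batch_and_temperature():
    z = RNG.normal(size=(1, 4))
    with pytest.raises(ValueError):
        loss_us_con(z, z, tau=1.0)
    z = RNG.normal(size=(3, 4))
    with pytest.raises(ValueError):
        loss_us_con(z, z, tau=0.0)


def test_label_similarity_counts_shared_labels():
    assert label_similarity([1, 1, 0, 0], [1, 0, 1, 0]) == 1
    assert label_similarity([1, 1, 0], [0, 0, 1]) == 0
    y = [1, 0, 1, 1]
    assert label_similarity(y, y) == 3
    with pytest.raises(ValueError):
        label_similarity([1, 0], [1, 0, 1])


def test_dynamic_coefficients_normalise_and_flag_zero_rows():
    C = np.array([[2.0, 2.0, 2.0], [2.0, 1.0, 0.0], [2.0, 0.0, 5.0]])
    beta, zero = dynamic_coefficients(C)
    assert np.allclose(beta[0], [0.0, 0.5, 0.5])
    assert not zero.any()
    C = np.array([[1.0, 0.0], [0.0, 3.0]])
    beta, zero = dynamic_coefficients(C)
    assert np.all(beta == 0.0)
    assert zero.all()


def test_ml_con_two_sample_batch_is_zero():
    # a single candidate makes the inner softmax 1, hence zero loss
    z = RNG.normal(size=(2, 4))
    y = np.array([[1, 1, 0], [1, 0, 1]])
    assert float(loss_ml_con(z, y, 0.5).data) == pytest.approx(0.0, abs=1e-9)


def test_ml_con_disjoint_labels_is_zero():
    z = RNG.normal(size=(4, 3))
    y = np.eye(4, dtype=int)
    assert float(loss_ml_con(z, y, 0.1).data) == pytest.approx(0.0, abs=1e-12)


def test_ml_con_pulls_positives_closer():
    # moving a positive pair closer (all else fixed) lowers the loss
    y = np.array([[1, 1], [1, 1], [0, 1]])
    z_far = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 2.0]])
    z_near = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    assert float(loss_ml_con(z_near, y, 0.5).data) < float(loss_ml_con(z_far, y, 0.5).data)


def test_bce_closed_forms():
    y = np.array([[1, 0, 1]])
    assert float(loss_bce(y.astype(float), y).data) == pytest.approx(0.0, abs=1e-5)
    p = np.full((2, 6), 0.5)
    y = (RNG.random((2, 6)) < 0.5).astype(int)
    assert float(loss_bce(p, y).data) == pytest.approx(6 * np.log(2))


def test_step_losses_weighted_arithmetic():
    # fabricated component values via degenerate weights
    z, pos, y = random_batch(4, 3, 5)
    y[:, 0] = 1  # guarantee overlap
    us = float(loss_us_con(z, pos, 0.05).data)
    ml = float(loss_ml_con(z, y, 0.05).data)
    s2 = float(loss_step2(z, pos, y, gamma=0.5, delta=0.02).data)
    assert s2 == pytest.approx(0.5 * ml + 0.02 * us, rel=1e-9)
    s2_no_ml = float(loss_step2(z, pos, y, gamma=0.0, delta=0.02).data)
    assert s2_no_ml == pytest.approx(0.02 * us, rel=1e-9)
    p = 1 / (1 + np.exp(-RNG.normal(size=y.shape)))
    bce = float(loss_bce(p, y).data)
    s3 = float(loss_step3(z, pos, y, p, theta=1.0, gamma=0.5, delta=0.02).data)
    assert s3 == pytest.approx(bce + 0.5 * ml + 0.02 * us, rel=1e-9)
    # with unit components the published weights give 1 + 0.5 + 0.02
    assert 1.0 * 1 + 0.5 * 1 + 0.02 * 1 == pytest.approx(1.52)


@pytest.mark.parametrize("b,d,n_codes", [(2, 3, 4), (4, 5, 6), (8, 6, 6)])
def test_losses_match_naive_loops(b, d, n_codes):
    for _ in range(40):
        z, pos, y = random_batch(b, d, n_codes)
        tau = float(RNG.uniform(0.05, 1.0))
        assert float(loss_us_con(z, pos, tau).data) == pytest.approx(
            naive_us_con(z, pos, tau), abs=1e-6)
        assert float(loss_ml_con(z, y, tau).data) == pytest.approx(
            naive_ml_con(z, y, tau), abs=1e-6)
        p = 1 / (1 + np.exp(-RNG.normal(size=(b, n_codes))))
        assert float(loss_bce(p, y).data) == pytest.approx(naive_bce(p, y), abs=1e-9)


def test_ml_con_invariant_to_joint_permutation():
    z, _, y = random_batch(6, 4, 5)
    y[:, 2] = 1
    base = float(loss_ml_con(z, y, 0.2).data)
    perm = RNG.permutation(6)
    assert float(loss_ml_con(z[perm], y[perm], 0.2).data) == pytest.approx(base, rel=1e-9)


def test_us_con_decreases_in_positive_similarity():
    z = RNG.normal(size=(3, 4))
    pos = RNG.normal(size=(3, 4))
    base = float(loss_us_con(z, pos, 0.5).data)
    pos_better = pos.copy()
    pos_better[0] = z[0]  # perfect positive for sample 0
    assert float(loss_us_con(z, pos_better, 0.5).data) < base


def test_step3_gradient_matches_finite_differences():
    z, pos, y = random_batch(3, 4, 4)
    y[:, 1] = 1
    logits = RNG.normal(size=(3, 4))

    def value(zv):
        t = Tensor(zv)
        p = Tensor(logits).sigmoid()
        return float(loss_step3(t, Tensor(pos), y, p).data)

    t = Tensor(z.copy(), requires_grad=True)
    loss = loss_step3(t, Tensor(pos), y, Tensor(logits).sigmoid())
    loss.backward()
    eps = 1e-5
    num = np.zeros_like(z)
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num[i, j] = (value(zp) - value(zm)) / (2 * eps)
    assert np.allclose(t.grad, num, atol=1e-4)
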