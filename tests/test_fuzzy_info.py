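"""Fuzzy membership, per-view similarity, joint fusion, and the
information-theoretic loss, each checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imvclust import _autodiff as ag
from imvclust.errors import DegenerateInputError
from imvclust.fuzzy_info import (
    EPS,
    JointDistribution,
    fcit_loss,
    fuse_joint,
    membership,
    membership_set,
    pairwise_sq_dists,
    view_similarity,
)

# ---- oracles -----------------------------------------------------------


def oracle_membership(points, m, mode):
    points = np.asarray(points, dtype=np.longdouble)
    n = len(points)
    u = np.zeros((n, n), dtype=np.longdouble)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d2 = np.sum((points[i] - points[j]) ** 2)
            if mode == "canonical":
                u[i, j] = (d2 + EPS) ** (-1.0 / (m - 1))
            else:
                u[i, j] = ((d2 + EPS) / m) ** (1.0 / (m - 1))
        u[i] /= u[i].sum()
    return u


def oracle_fcit(joint, alpha, mode):
    joint = np.asarray(joint, dtype=np.longdouble)
    rows = joint.sum(axis=1)
    cols = joint.sum(axis=0)
    total = np.longdouble(0)
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            s = joint[i, j]
            r = max(rows[i], EPS) ** (alpha + 1)
            c = max(cols[j], EPS) ** (alpha + 1)
            if mode == "canonical":
                if s > 0:
                    total += s * np.log(max(s, EPS) / (r * c))
            else:
                total += s / (r * c)
    return float(-total)


# ---- membership --------------------------------------------------------


def test_equilateral_triangle_memberships_are_half():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    u, _ = membership(pts, fuzziness=2.0)
    off = u[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 0.5, atol=1e-9)
    np.testing.assert_allclose(np.diag(u), 0.0)


def test_inverse_square_distance_ratio():
    # j at distance 1, k at distance 2: weights 1/1 vs 1/4
    pts = np.array([[0.0], [1.0], [2.0]])
    u, _ = membership(pts, fuzziness=2.0)
    assert u[0, 1] == pytest.approx(4 * u[0, 2], rel=1e-9)


@pytest.mark.parametrize("mode", ["canonical", "literal"])
@pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
def test_membership_matches_oracle(mode, m):
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(5, 3))
    u, _ = membership(pts, fuzziness=m, mode=mode)
    np.testing.assert_allclose(u, oracle_membership(pts, m, mode).astype(float),
                               atol=1e-8)


def test_literal_membership_grows_with_distance():
    pts = np.array([[0.0], [1.0], [3.0]])
    u, _ = membership(pts, fuzziness=2.0, mode="literal")
    assert u[0, 2] > u[0, 1]  # the printed form favors FAR samples


def test_membership_rigid_motion_invariance(rng):
    pts = rng.normal(size=(6, 3))
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    u1, _ = membership(pts)
    u2, _ = membership(pts @ rot + np.array([5.0, -2.0, 1.0]))
    np.testing.assert_allclose(u1, u2, atol=1e-8)


def test_single_row_is_degenerate():
    with pytest.raises(DegenerateInputError):
        membership(np.zeros((1, 3)))


def test_duplicate_points_guarded_by_eps(rng):
    pts = np.vstack([np.zeros((2, 2)), rng.normal(size=(2, 2))])
    u, _ = membership(pts)
    assert np.all(np.isfinite(u))
    np.testing.assert_allclose(u.sum(axis=1), 1.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(2, 10), st.integers(1, 4), st.integers(0, 10 ** 6))
def test_membership_rows_stochastic(n, d, seed):
    pts = np.random.default_rng(seed).normal(size=(n, d))
    u, d2 = membership(pts)
    np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((u >= 0) & (u <= 1))
    np.testing.assert_allclose(d2, d2.T, atol=1e-9)
    np.testing.assert_array_equal(np.diag(d2), 0.0)


# ---- similarity --------------------------------------------------------


def test_identical_points_give_zero_similarity():
    pts = np.ones((4, 2))
    u, d2 = membership(pts)
    s, obj, p = view_similarity(u, d2)
    np.testing.assert_allclose(s, 0.0, atol=1e-12)
    assert obj == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(p, 0.25)  # softmax of a zero matrix


def test_two_point_similarity_arithmetic():
    # printed d2 = 2, off-diagonal membership 1, V = 2 -> S off-diag = 1
    u = np.array([[0.0, 1.0], [1.0, 0.0]])
    d2 = np.array([[0.0, 2.0], [2.0, 0.0]])
    s, obj, _ = view_similarity(u, d2, n_views=2)
    np.testing.assert_allclose(s, [[0.0, 1.0], [1.0, 0.0]])
    assert obj == pytest.approx(2.0)


def test_similarity_scaling_with_frozen_membership(rng):
    pts = rng.normal(size=(5, 2))
    u, d2 = membership(pts)
    s1, obj1, _ = view_similarity(u, d2)
    s2, obj2, _ = view_similarity(u, 4.0 * d2)  # doubled coordinates
    np.testing.assert_allclose(s2, 4.0 * s1, atol=1e-10)
    assert obj2 == pytest.approx(4.0 * obj1)


# ---- fusion ------------------------------------------------------------


def test_identity_probability_fusion():
    p = np.eye(4)
    jd = fuse_joint(p, p)
    np.testing.assert_allclose(jd.joint, np.eye(4) / 4)
    np.testing.assert_allclose(jd.row_marginal.ravel(), 0.25)
    np.testing.assert_allclose(jd.col_marginal.ravel(), 0.25)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(2, 8), st.integers(0, 10 ** 6))
def test_joint_always_normalized(n, seed):
    rng = np.random.default_rng(seed)
    p1 = rng.dirichlet(np.ones(n), size=n)
    p2 = rng.dirichlet(np.ones(n), size=n)
    jd = fuse_joint(p1, p2)
    assert jd.joint.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(jd.joint >= 0)
    assert jd.row_marginal.sum() == pytest.approx(1.0, abs=1e-12)
    assert jd.col_marginal.sum() == pytest.approx(1.0, abs=1e-12)


def test_fusion_matches_oracle(rng):
    p1 = rng.dirichlet(np.ones(5), size=5)
    p2 = rng.dirichlet(np.ones(5), size=5)
    jd = fuse_joint(p1, p2)
    a = np.zeros((5, 5), dtype=np.longdouble)
    for i in range(5):
        for j in range(5):
            a[i, j] = np.dot(p1[i].astype(np.longdouble),
                             p2[j].astype(np.longdouble))
    np.testing.assert_allclose(jd.joint, (a / a.sum()).astype(float),
                               atol=1e-10)


def test_orthonormal_indicator_fusion_is_symmetric(rng):
    perm = np.random.default_rng(0).permutation(5)
    p = np.eye(5)[perm]
    jd = fuse_joint(p, p)
    np.testing.assert_allclose(jd.joint, jd.joint.T)


# ---- information loss --------------------------------------------------


@pytest.mark.parametrize("alpha", [0.0, 9.0])
@pytest.mark.parametrize("n", [4, 16])
def test_uniform_diagonal_closed_form(alpha, n):
    jd = fuse_joint(np.eye(n), np.eye(n))
    loss = float(ag.asdata(fcit_loss(jd, alpha=alpha)))
    assert loss == pytest.approx(-(2 * alpha + 1) * np.log(n), abs=1e-9)


def test_independent_joint_zero_mutual_information(rng):
    r = rng.dirichlet(np.ones(5))
    c = rng.dirichlet(np.ones(5))
    joint = np.outer(r, c)
    jd = JointDistribution(joint=joint,
                           row_marginal=joint.sum(axis=1, keepdims=True),
                           col_marginal=joint.sum(axis=0, keepdims=True))
    assert float(ag.asdata(fcit_loss(jd, alpha=0.0))) == pytest.approx(
        0.0, abs=1e-9)


@pytest.mark.parametrize("mode", ["canonical", "literal"])
def test_fcit_matches_oracle(mode, rng):
    joint = rng.dirichlet(np.ones(16)).reshape(4, 4)
    jd = JointDistribution(joint=joint,
                           row_marginal=joint.sum(axis=1, keepdims=True),
                           col_marginal=joint.sum(axis=0, keepdims=True))
    got = float(ag.asdata(fcit_loss(jd, alpha=9.0, mode=mode)))
    assert got == pytest.approx(oracle_fcit(joint, 9.0, mode), rel=1e-8)


def test_concentration_lowers_canonical_loss():
    n = 6
    diag = fuse_joint(np.eye(n), np.eye(n))
    uniform = JointDistribution(
        joint=np.full((n, n), 1.0 / n ** 2),
        row_marginal=np.full((n, 1), 1.0 / n),
        col_marginal=np.full((1, n), 1.0 / n))
    assert (float(ag.asdata(fcit_loss(diag, alpha=9.0)))
            < float(ag.asdata(fcit_loss(uniform, alpha=9.0))))


def test_fcit_gradient_is_finite(rng):
    pts = ag.Tensor(rng.normal(size=(6, 3)), requires_grad=True)
    u, d2 = membership(pts)
    _, _, p = view_similarity(u, d2)
    loss = fcit_loss(fuse_joint(p, p), alpha=9.0)
    loss.backward()
    assert np.all(np.isfinite(pts.grad))


def test_membership_set_bundle(rng):
    pts = rng.normal(size=(5, 2))
    ms = membership_set(pts, fuzziness=2.0)
    np.testing.assert_allclose(ms.membership.sum(axis=1), 1.0)
    assert ms.fcm_objective == pytest.approx(ms.similarity.sum())
    np.testing.assert_allclose(ms.probability.sum(axis=1), 1.0)
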