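"""Fuzzy-membership similarity per view and information-theoretic fusion.

Every sample of a batch acts as a cluster center: the membership matrix
U (N x N, row-stochastic) is the fuzzy c-means affinity of each sample
to every other, the per-view similarity summand S combines membership
and squared distance, a row-softmax of -S turns each view into a
probability matrix P, and the cross-view coupling P1 @ P2.T, normalized
to sum to 1, is scored by a mutual-information-style loss with
entropy-balanced marginals.

Membership and the fusion loss each come in a ``canonical`` form
(inverse-distance FCM membership; genuine mutual information with the
marginals raised to the power alpha+1) and a ``literal`` form (the raw
distance-power membership that grows with distance, and the log-free
ratio objective). Canonical is the default; literal is kept behind the
mode flag for exact comparison.

All functions accept numpy arrays or autodiff Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ag
from .errors import DegenerateInputError, ValidationError

EPS = 1e-12
MODES = ("canonical", "literal")


def _check_mode(mode):
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass
class MembershipSet:
    """Per-view fuzzy-membership bundle (detached values)."""

    sq_distances: np.ndarray   # N x N, symmetric, zero diagonal
    membership: np.ndarray     # U, N x N, row-stochastic
    similarity: np.ndarray     # S, N x N summand matrix
    probability: np.ndarray    # P = row-softmax(-S)
    fcm_objective: float       # sum of S
    fuzziness: float
    mode: str


@dataclass
class JointDistribution:
    """Cross-view coupling: joint matrix summing to 1 and its marginals.

    Fields may hold autodiff Tensors during training; ``detached()``
    yields a numpy-only copy.
    """

    joint: object          # N x N, nonnegative, sums to 1
    row_marginal: object   # N x 1
    col_marginal: object   # 1 x N

    def detached(self) -> "JointDistribution":
        return JointDistribution(
            joint=ag.detach(self.joint),
            row_marginal=ag.detach(self.row_marginal),
            col_marginal=ag.detach(self.col_marginal),
        )


def pairwise_sq_dists(latents):
    """N x N matrix of squared Euclidean distances between rows."""
    sq = ag.asum(latents * latents, axis=1, keepdims=True)
    d2 = sq + _transpose(sq) - 2.0 * (latents @ _transpose(latents))
    d2 = ag.clip_min(d2, 0.0)  # guard tiny negative round-off
    return d2


def _transpose(x):
    return x.T if ag.is_tensor(x) else ag.asdata(x).T


def membership(latents, fuzziness=2.0, mode="canonical"):
    """Row-stochastic fuzzy membership U among all samples of a batch.

    canonical: U_ij proportional to (d2_ij + eps)^(-1/(m-1)) off the
    diagonal — the inverse-distance FCM affinity, so nearer samples get
    larger membership. literal: U_ij proportional to
    ((1/m) d2_ij)^(1/(m-1)), the raw printed power law (grows with
    distance), row-normalized.
    """
    _check_mode(mode)
    if fuzziness <= 1.0:
        raise ValidationError("fuzziness must be > 1")
    n = ag.asdata(latents).shape[0]
    if n < 2:
        raise DegenerateInputError(
            "membership needs at least two samples in the batch"
        )
    off_diag = 1.0 - np.eye(n)
    d2 = pairwise_sq_dists(latents) * off_diag  # exact-zero diagonal
    expo = 1.0 / (fuzziness - 1.0)
    if mode == "canonical":
        w = (d2 + EPS) ** (-expo) * off_diag
    else:
        w = ((d2 + EPS) / fuzziness) ** expo * off_diag
    u = w / ag.asum(w, axis=1, keepdims=True)
    return u, d2


def view_similarity(U, d2, n_views=2):
    """Similarity summand S_ij = (1/V) U_ij^2 d2_ij, its scalar FCM
    objective (the full double sum), and the probability form
    P = row-softmax(-S) used for cross-view fusion."""
    if ag.asdata(U).shape != ag.asdata(d2).shape:
        raise ValidationError("membership and distance shapes disagree")
    s = (1.0 / n_views) * (U ** 2.0) * d2
    objective = ag.asum(s)
    p = ag.softmax_rows(-s)
    return s, objective, p


def fuse_joint(P1, P2) -> JointDistribution:
    """Cross-view joint distribution: normalize P1 @ P2.T to sum to 1."""
    p1d, p2d = ag.asdata(P1), ag.asdata(P2)
    if np.any(p1d < 0) or np.any(p2d < 0):
        raise ValidationError("probability matrices must be nonnegative")
    a = P1 @ _transpose(P2)
    total = ag.asum(a)
    if float(ag.asdata(total)) <= 0.0:
        raise DegenerateInputError("cross-view coupling sums to zero")
    joint = a / total
    return JointDistribution(
        joint=joint,
        row_marginal=ag.asum(joint, axis=1, keepdims=True),
        col_marginal=ag.asum(joint, axis=0, keepdims=True),
    )


def fcit_loss(joint: JointDistribution, alpha=9.0, mode="canonical"):
    """Information-theoretic fusion loss on the cross-view joint.

    canonical (default): negative mutual information with each marginal
    raised to the power alpha+1,

        - sum_ij J_ij log( J_ij / (R_i^(a+1) C_j^(a+1)) ),

    which at alpha=0 is exactly -I(joint) (zero for an independent
    joint) and rewards concentrated, diagonal-like couplings as alpha
    grows. literal: the log-free ratio - sum_ij J_ij / (R_i C_j)^(a+1).
    0*log 0 evaluates to 0; eps guards every log and denominator.
    """
    _check_mode(mode)
    j, r, c = joint.joint, joint.row_marginal, joint.col_marginal
    a1 = float(alpha) + 1.0
    if mode == "canonical":
        log_ratio = (
            ag.log(ag.clip_min(j, EPS))
            - a1 * ag.log(ag.clip_min(r, EPS))
            - a1 * ag.log(ag.clip_min(c, EPS))
        )
        return -ag.asum(j * log_ratio)
    denom = ag.clip_min(r, EPS) ** a1 * ag.clip_min(c, EPS) ** a1
    return -ag.asum(j / denom)


def membership_set(latents, fuzziness=2.0, mode="canonical",
                   n_views=2) -> MembershipSet:
    """Convenience: full detached membership bundle for one view."""
    u, d2 = membership(latents, fuzziness=fuzziness, mode=mode)
    s, obj, p = view_similarity(u, d2, n_views=n_views)
    return MembershipSet(
        sq_distances=ag.detach(d2),
        membership=ag.detach(u),
        similarity=ag.detach(s),
        probability=ag.detach(p),
        fcm_objective=float(ag.asdata(obj)),
        fuzziness=float(fuzziness),
        mode=mode,
    )
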