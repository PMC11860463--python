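"""Entropy-weight feature reconstruction of per-view latents.

Each latent feature column receives a weight from the dispersion of its
share distribution across samples: columns whose shares are nearly
uniform (maximum entropy) carry little discriminative information and
are shrunk, concentrated columns are amplified. The reweighted latents
L = Z * W (column scaling) feed the cross-view generators and the fuzzy
information-theoretic fusion.

Two conventions are provided:

``canonical`` (default)
    The standard entropy-weight method: per-column min-max scaling to
    [eps, 1], column-sum shares, normalized Shannon entropy
    E_j = -(1/ln N) sum_i p_ij ln p_ij in [0, 1], weights
    W_j = (1 - E_j) / sum_k (1 - E_k) — a convex combination.

``literal``
    The raw row-mean / column-mean variant: Y_ij = Z_ij / rowmean_i(Z),
    p_ij = Y_ij / colmean_j(Y), E_j = (1/N) sum_i p_ij ln p_ij. On
    sign-indefinite latents the shares may be negative (the entropy term
    is then evaluated on |p| and a warning is logged) and E_j may leave
    [0, 1], producing negative weights — kept, with a warning. The
    normalization sum_j W_j = 1 holds in both modes by construction.

All functions accept either plain numpy arrays or autodiff Tensors and
return the matching kind, so the same code is used for training and for
standalone analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ag
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

EPS = 1e-12
MODES = ("canonical", "literal")


def _check_mode(mode):
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass
class EntropyWeighting:
    """Diagnostic record of one entropy-weighting pass (detached values)."""

    distribution_matrix: np.ndarray  # Y, N x L
    shares: np.ndarray               # p, N x L
    entropy: np.ndarray              # E, length L
    weights: np.ndarray              # W, length L, sums to 1
    mode: str


def distribution_matrix(Z, mode="canonical"):
    """Per-sample share matrix Y of the latent matrix Z (N x L).

    canonical: per-column min-max scaling onto [eps, 1] (the column
    extremes are treated as constants in the gradient). literal: each
    entry divided by its row mean, with an eps guard on near-zero rows.
    """
    _check_mode(mode)
    zd = ag.asdata(Z)
    if not np.all(np.isfinite(zd)):
        raise ValidationError("latent matrix contains NaN or Inf")
    if zd.ndim != 2 or zd.size == 0:
        raise ValidationError("latent matrix must be 2-D and non-empty")
    if mode == "canonical":
        mn = zd.min(axis=0, keepdims=True)
        rng = zd.max(axis=0, keepdims=True) - mn
        rng_safe = np.where(rng < EPS, 1.0, rng)
        return EPS + (1.0 - EPS) * ((Z - mn) / rng_safe)
    row_mean = ag.amean(Z, axis=1, keepdims=True)
    rm = ag.asdata(row_mean)
    guard = np.where(np.abs(rm) < EPS, EPS, 0.0)
    if np.any(guard > 0):
        logger.warning(
            "distribution_matrix: %d row mean(s) below eps; guarded",
            int((guard > 0).sum()),
        )
    return Z / (row_mean + guard)


def entropy_values(Y, mode="canonical"):
    """Column entropies E (length L) of a share matrix Y.

    canonical: column-sum shares and normalized Shannon entropy, clipped
    into [0, 1] to absorb rounding. literal: column-mean shares and the
    unnormalized, unsigned-log form; shares may be negative on real
    latents, in which case |p| enters the log and a warning is logged.
    """
    _check_mode(mode)
    yd = ag.asdata(Y)
    n = yd.shape[0]
    if mode == "canonical":
        if np.any(yd < 0):
            raise ValidationError(
                "canonical entropy requires a nonnegative share matrix"
            )
        if n == 1:
            e = np.zeros(yd.shape[1])
            return ag.Tensor(e) if ag.is_tensor(Y) else e
        p = Y / ag.asum(Y, axis=0, keepdims=True)
        plogp = p * ag.log(ag.clip_min(p, EPS))
        e = -(1.0 / np.log(n)) * ag.asum(plogp, axis=0)
        return ag.clip(e, 0.0, 1.0)
    col_mean = ag.amean(Y, axis=0, keepdims=True)
    cm = ag.asdata(col_mean)
    guard = np.where(np.abs(cm) < EPS, EPS, 0.0)
    p = Y / (col_mean + guard)
    pd = ag.asdata(p)
    if np.any(pd <= 0):
        logger.warning(
            "entropy_values(literal): %d nonpositive share(s); "
            "log evaluated on |p|", int((pd <= 0).sum()),
        )
    sign = np.where(pd < 0, -1.0, 1.0)
    abs_p = p * sign
    return (1.0 / n) * ag.asum(p * ag.log(ag.clip_min(abs_p, EPS)), axis=0)


def entropy_weights(E, m=None, on_degenerate="raise"):
    """Weights W_j = (1 - E_j) / (m - sum_k E_k), summing to 1.

    ``m`` defaults to the number of features L. When the denominator
    vanishes (every feature maximally entropic) the operation is
    undefined: ``on_degenerate='raise'`` raises, ``'uniform'`` falls
    back to equal weights 1/L with a warning.
    """
    ed = ag.asdata(E)
    n_feat = ed.shape[-1]
    if m is None:
        m = n_feat
    denom_val = float(m - ed.sum())
    if abs(denom_val) < 1e-9:
        if on_degenerate == "uniform":
            logger.warning(
                "entropy_weights: all features maximally entropic; "
                "falling back to uniform weights"
            )
            w = np.full(n_feat, 1.0 / n_feat)
            return ag.Tensor(w) if ag.is_tensor(E) else w
        raise DegenerateInputError(
            "entropy-weight denominator m - sum(E) is zero "
            "(all features maximally entropic)"
        )
    w = (1.0 - E) / (m - ag.asum(E))
    wd = ag.asdata(w)
    if np.any(wd < 0):
        logger.warning(
            "entropy_weights: %d negative weight(s) (literal-mode entropy "
            "outside [0, 1]); kept as computed", int((wd < 0).sum()),
        )
    return w


def reconstruct(Z, W):
    """Column-scaled latents L_ij = W_j * Z_ij (shape preserved)."""
    zd, wd = ag.asdata(Z), ag.asdata(W)
    if zd.shape[-1] != wd.shape[-1]:
        raise ValidationError(
            f"weight length {wd.shape[-1]} does not match latent "
            f"width {zd.shape[-1]}"
        )
    return Z * W


def entropy_reweight(Z, mode="canonical", on_degenerate="uniform"):
    """Full pipeline Z -> (reweighted latents, EntropyWeighting record).

    The training loop calls this per view per batch; the record carries
    detached numpy copies for inspection and logging.
    """
    Y = distribution_matrix(Z, mode=mode)
    E = entropy_values(Y, mode=mode)
    W = entropy_weights(E, on_degenerate=on_degenerate)
    L = reconstruct(Z, W)
    yd = ag.asdata(Y)
    if mode == "canonical":
        shares = yd / yd.sum(axis=0, keepdims=True)
    else:
        cm = yd.mean(axis=0, keepdims=True)
        shares = yd / np.where(np.abs(cm) < EPS, EPS, cm)
    record = EntropyWeighting(
        distribution_matrix=yd.copy(),
        shares=shares,
        entropy=ag.detach(E),
        weights=ag.detach(W),
        mode=mode,
    )
    return L, record
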