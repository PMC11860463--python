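"""Per-view autoencoders, cross-view generators, and their losses.

Each view has a fully-connected autoencoder whose encoder ends in a
row softmax, so latents are probability vectors over L latent units.
Two generators map between the latent spaces of the views (G12: view 1
latents to view 2 latents and vice versa); they predict the latent of a
sample's missing view from its observed one.

Losses are averaged over batch rows (not summed) so the trade-off
weights transfer across batch sizes. The prediction loss uses paired
samples when any exist; with zero pairs (the fully incomplete regime,
where every sample has exactly one view) it falls back to cycle
consistency through both generators.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ag
from ._autodiff import Tensor
from .errors import StructuralError

DEFAULT_ENCODER_WIDTHS = (512, 256)
DEFAULT_GENERATOR_WIDTHS = (256,)
DEFAULT_LATENT_DIM = 128


class Linear:
    """Dense layer with Glorot-normal weights drawn from a seeded rng."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.n_in, self.n_out = n_in, n_out

    def __call__(self, x):
        if ag.asdata(x).shape[-1] != self.n_in:
            raise StructuralError(
                f"layer expects {self.n_in} inputs, got "
                f"{ag.asdata(x).shape[-1]}"
            )
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class MLP:
    """Fully-connected stack with tanh between layers.

    ``final`` selects the output nonlinearity: None (linear), "tanh",
    or "softmax" (row-stochastic output).
    """

    def __init__(self, widths, rng, final=None):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.final = final

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ag.tanh(x)
        if self.final == "tanh":
            x = ag.tanh(x)
        elif self.final == "softmax":
            x = ag.softmax_rows(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class ViewAutoencoder:
    """Encoder D_v -> L with softmax output, mirrored linear decoder."""

    def __init__(self, input_dim, latent_dim=DEFAULT_LATENT_DIM,
                 widths=DEFAULT_ENCODER_WIDTHS, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        widths = tuple(widths)
        self.input_dim, self.latent_dim = input_dim, latent_dim
        self.encoder = MLP((input_dim,) + widths + (latent_dim,), rng,
                           final="softmax")
        self.decoder = MLP((latent_dim,) + widths[::-1] + (input_dim,), rng,
                           final=None)

    def encode(self, x):
        """Latent rows; each is a softmax-normalized length-L vector."""
        return self.encoder(x)

    def decode(self, z):
        return self.decoder(z)

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()


class CrossViewGenerator:
    """Latent-to-latent generators G12 (view1 -> view2) and G21."""

    def __init__(self, latent_dim=DEFAULT_LATENT_DIM,
                 widths=DEFAULT_GENERATOR_WIDTHS, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        widths = tuple(widths)
        shape = (latent_dim,) + widths + (latent_dim,)
        self.g12 = MLP(shape, rng, final=None)
        self.g21 = MLP(shape, rng, final=None)
        self.latent_dim = latent_dim

    def parameters(self):
        return self.g12.parameters() + self.g21.parameters()


# ---- losses ------------------------------------------------------------

def _mean_sq_rows(x):
    """Mean over rows of the squared Euclidean row norms."""
    return ag.amean(ag.asum(x * x, axis=1))


def reconstruction_loss(view_rows, autoencoders):
    """Within-view autoencoder loss over available rows only.

    ``view_rows`` is one matrix per view holding the rows with that view
    present; views with no available rows in the batch contribute 0.
    Returns sum over views of the mean squared reconstruction error.
    """
    total = 0.0
    for x, ae in zip(view_rows, autoencoders):
        if ag.asdata(x).shape[0] == 0:
            continue
        xhat = ae.decode(ae.encode(x))
        total = total + _mean_sq_rows(xhat - x)
    return total


def prediction_loss(lat1, lat2, generators, pairing):
    """Two-directional cross-view prediction error.

    ``pairing`` is a pair of index arrays selecting the rows of ``lat1``
    and ``lat2`` that belong to the same samples. With at least one pair
    the loss is ||G12(L1) - L2||^2 + ||G21(L2) - L1||^2 averaged over
    pairs. With zero pairs (fully incomplete data) it is the
    cycle-consistency surrogate ||G21(G12(L1)) - L1||^2 +
    ||G12(G21(L2)) - L2||^2 over all available single-view rows.
    """
    idx1, idx2 = (np.asarray(i, dtype=np.intp) for i in pairing)
    if idx1.shape != idx2.shape:
        raise StructuralError("pairing index arrays must have equal length")
    if idx1.size > 0:
        p1 = ag.take_rows(lat1, idx1)
        p2 = ag.take_rows(lat2, idx2)
        return (_mean_sq_rows(generators.g12(p1) - p2)
                + _mean_sq_rows(generators.g21(p2) - p1))
    total = 0.0
    if ag.asdata(lat1).shape[0] > 0:
        total = total + _mean_sq_rows(generators.g21(generators.g12(lat1))
                                      - lat1)
    if ag.asdata(lat2).shape[0] > 0:
        total = total + _mean_sq_rows(generators.g12(generators.g21(lat2))
                                      - lat2)
    return total


def impute_missing(latents, mask, generators):
    """Complete both latent matrices using the generators.

    ``latents`` holds, per view, the latent rows of the samples with
    that view available (in mask order); ``mask`` is the N x 2
    availability matrix restricted to the same samples. Available
    latents are never overwritten; each missing latent is generated from
    the sample's other view. Returns the two completed N x L matrices.
    """
    mask = np.asarray(mask)
    n = mask.shape[0]
    avail = [np.flatnonzero(mask[:, v] == 1) for v in (0, 1)]
    pos = []
    for v in (0, 1):
        lookup = np.full(n, -1, dtype=np.intp)
        lookup[avail[v]] = np.arange(avail[v].size)
        pos.append(lookup)
    completed = []
    gen = {0: generators.g21, 1: generators.g12}  # other view -> this view
    for v in (0, 1):
        other = 1 - v
        parts = embed = ag.embed_rows(latents[v], avail[v], n)
        missing = np.flatnonzero(mask[:, v] == 0)
        if missing.size:
            src_rows = ag.take_rows(latents[other], pos[other][missing])
            parts = embed + ag.embed_rows(gen[v](src_rows), missing, n)
        completed.append(parts)
    return completed
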