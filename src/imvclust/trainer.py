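"""Joint optimization of the composite clustering objective.

Per epoch the samples are shuffled and processed in mini-batches; for
each batch the available rows of each view are encoded, the latents are
entropy-reweighted, missing latents are imputed by the cross-view
generators, and three losses are combined:

    total = L_fcit + lambda1 * L_rec + lambda2 * L_pre

where L_fcit is the fuzzy information-theoretic fusion loss on the
batch-local cross-view joint, L_rec the within-view autoencoder loss,
and L_pre the cross-view prediction (or cycle-consistency) loss. Adam
steps the autoencoder and generator parameters. Cluster extraction runs
seeded k-means on the fused (averaged) completed latents.

One master seed fans out to parameter initialization, shuffling and
k-means, so a run is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import _autodiff as ag
from .datasets import IncompleteMultiviewDataset
from .errors import DivergenceError, ParameterError
from .evaluation import ClusteringResult, score
from .fuzzy_info import fcit_loss, fuse_joint, membership, view_similarity
from .networks import (
    DEFAULT_ENCODER_WIDTHS,
    DEFAULT_GENERATOR_WIDTHS,
    DEFAULT_LATENT_DIM,
    CrossViewGenerator,
    ViewAutoencoder,
    impute_missing,
    prediction_loss,
    reconstruction_loss,
)
from .reconstruction import entropy_reweight

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the joint training run.

    Defaults follow the published schedule: Adam with learning rate
    1e-4, batch size 256 (clipped to N), 500 epochs, trade-offs
    lambda1 = 0.1 (reconstruction) and lambda2 = 0.01 (prediction),
    fuzziness 2, entropy-balance alpha 9, K = 2 clusters. The three
    ``use_*`` toggles support ablation; at least one must stay on.
    """

    lambda1: float = 0.1
    lambda2: float = 0.01
    learning_rate: float = 1e-4
    batch_size: int = 256
    epochs: int = 500
    n_clusters: int = 2
    latent_dim: int = DEFAULT_LATENT_DIM
    encoder_widths: tuple = DEFAULT_ENCODER_WIDTHS
    generator_widths: tuple = DEFAULT_GENERATOR_WIDTHS
    fuzziness: float = 2.0
    alpha: float = 9.0
    recon_mode: str = "canonical"
    membership_mode: str = "canonical"
    fcit_mode: str = "canonical"
    use_fcit: bool = True
    use_rec: bool = True
    use_pre: bool = True
    assign: str = "kmeans"
    kmeans_restarts: int = 10
    eval_every: int = 0  # 0 = no per-epoch metric evaluation
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ParameterError("trade-off weights must be nonnegative")
        if not (self.use_fcit or self.use_rec or self.use_pre):
            raise ParameterError("at least one loss must be enabled")
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be positive")
        if self.assign not in ("kmeans", "argmax"):
            raise ParameterError("assign must be 'kmeans' or 'argmax'")


@dataclass
class LossReport:
    """Per-epoch traces of the loss components and the weighted total."""

    fcit: list = field(default_factory=list)
    rec: list = field(default_factory=list)
    pre: list = field(default_factory=list)
    total: list = field(default_factory=list)
    metrics: list = field(default_factory=list)  # (epoch, acc, nmi, ari)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.total) + 1),
            "fcit": self.fcit, "rec": self.rec, "pre": self.pre,
            "total": self.total,
        })


@dataclass
class TrainedModel:
    """Trained autoencoders + generators and the config that made them."""

    autoencoders: list
    generators: CrossViewGenerator
    config: TrainConfig

    def state_arrays(self) -> dict:
        """Flat name -> array view of every parameter (for checkpoints)."""
        out = {}
        for v, ae in enumerate(self.autoencoders, start=1):
            for i, p in enumerate(ae.parameters()):
                out[f"ae{v}_{i}"] = p.data
        for i, p in enumerate(self.generators.parameters()):
            out[f"gen_{i}"] = p.data
        return out

    def load_state_arrays(self, arrays: dict):
        for name, p in self._named_params():
            p.data[...] = arrays[name]

    def _named_params(self):
        for v, ae in enumerate(self.autoencoders, start=1):
            for i, p in enumerate(ae.parameters()):
                yield f"ae{v}_{i}", p
        for i, p in enumerate(self.generators.parameters()):
            yield f"gen_{i}", p


def total_loss(components, config: TrainConfig):
    """Weighted sum  L_fcit + lambda1 L_rec + lambda2 L_pre of the
    enabled components (disabled components contribute zero)."""
    l_fcit, l_rec, l_pre = components
    total = 0.0
    if config.use_fcit:
        total = total + l_fcit
    if config.use_rec:
        total = total + config.lambda1 * l_rec
    if config.use_pre:
        total = total + config.lambda2 * l_pre
    return total


def build_model(dims, config: TrainConfig) -> TrainedModel:
    """Seeded parameter initialization for both views and the generators."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0,)))
    autoencoders = [
        ViewAutoencoder(d, latent_dim=config.latent_dim,
                        widths=config.encoder_widths, rng=rng)
        for d in dims
    ]
    generators = CrossViewGenerator(latent_dim=config.latent_dim,
                                    widths=config.generator_widths, rng=rng)
    return TrainedModel(autoencoders, generators, config)


def _batch_losses(batch_views, batch_mask, model, config):
    """The three loss components on one batch; returns autodiff scalars."""
    avail = [np.flatnonzero(batch_mask[:, v] == 1) for v in (0, 1)]
    x_rows = [ag.Tensor(batch_views[v][avail[v]]) for v in (0, 1)]

    l_rec = reconstruction_loss(x_rows, model.autoencoders)

    latents = [model.autoencoders[v].encode(x_rows[v]) for v in (0, 1)]
    weighted = [entropy_reweight(z, mode=config.recon_mode)[0]
                for z in latents]

    # rows paired in the batch, expressed as indices into each view's
    # available-row latent matrix
    both = np.flatnonzero(batch_mask.sum(axis=1) == 2)
    pos = []
    for v in (0, 1):
        lookup = np.full(batch_mask.shape[0], -1, dtype=np.intp)
        lookup[avail[v]] = np.arange(avail[v].size)
        pos.append(lookup)
    pairing = (pos[0][both], pos[1][both])
    l_pre = prediction_loss(weighted[0], weighted[1], model.generators,
                            pairing)

    completed = impute_missing(weighted, batch_mask, model.generators)
    probs = []
    for v in (0, 1):
        u, d2 = membership(completed[v], fuzziness=config.fuzziness,
                           mode=config.membership_mode)
        _, _, p = view_similarity(u, d2, n_views=2)
        probs.append(p)
    joint = fuse_joint(probs[0], probs[1])
    l_fcit = fcit_loss(joint, alpha=config.alpha, mode=config.fcit_mode)
    return l_fcit, l_rec, l_pre


def train(dataset: IncompleteMultiviewDataset,
          config: TrainConfig) -> tuple:
    """Optimize the composite objective; returns (model, LossReport)."""
    n = dataset.n_samples
    model = build_model([v.shape[1] for v in dataset.views], config)
    params = [p for ae in model.autoencoders for p in ae.parameters()]
    params += model.generators.parameters()
    opt = ag.Adam(params, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)))
    batch = min(config.batch_size, n)
    report = LossReport()

    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(n)
        sums = np.zeros(4)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            if idx.size < 2:
                continue  # membership is undefined on a single row
            batch_views = [v[idx] for v in dataset.views]
            batch_mask = dataset.mask[idx]
            components = _batch_losses(batch_views, batch_mask, model,
                                       config)
            loss = total_loss(components, config)
            values = [float(ag.asdata(c)) for c in components]
            names = ("fcit", "rec", "pre")
            for name, val, used in zip(
                    names, values,
                    (config.use_fcit, config.use_rec, config.use_pre)):
                if used and not np.isfinite(val):
                    raise DivergenceError(
                        f"loss term {name} became non-finite at epoch "
                        f"{epoch}"
                    )
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums += idx.size * np.array(
                values + [float(ag.asdata(loss))])
        means = sums / n
        report.fcit.append(means[0])
        report.rec.append(means[1])
        report.pre.append(means[2])
        report.total.append(means[3])
        if (config.eval_every and dataset.labels is not None
                and epoch % config.eval_every == 0):
            result = assign_clusters(model, dataset)
            report.metrics.append(
                (epoch, result.acc, result.nmi, result.ari))
            logger.info("epoch %d acc=%.3f nmi=%.3f ari=%.3f",
                        epoch, result.acc, result.nmi, result.ari)
    return model, report


def fused_latents(model: TrainedModel,
                  dataset: IncompleteMultiviewDataset) -> np.ndarray:
    """Encode, reweight, impute, then average the two completed latent
    matrices into one N x L representation (numpy, no gradients)."""
    config = model.config
    latents = []
    for v in (0, 1):
        rows = dataset.view_rows(v)
        z = ag.asdata(model.autoencoders[v].encode(ag.Tensor(rows)))
        weighted, _ = entropy_reweight(z, mode=config.recon_mode)
        latents.append(weighted)
    completed = impute_missing(latents, dataset.mask, model.generators)
    completed = [ag.asdata(c) for c in completed]
    return 0.5 * (completed[0] + completed[1])


def assign_clusters(model: TrainedModel,
                    dataset: IncompleteMultiviewDataset,
                    n_clusters: int | None = None) -> ClusteringResult:
    """Hard cluster labels from the fused latents.

    ``kmeans`` (default): seeded k-means with 10 restarts on the fused
    matrix. ``argmax``: argmax over latent units (requires the latent
    dimension to equal K, i.e. a K-way softmax head). Metrics are filled
    in when the dataset carries reference labels.
    """
    k = n_clusters if n_clusters is not None else model.config.n_clusters
    if k > dataset.n_samples:
        raise ParameterError(
            f"n_clusters ({k}) exceeds the number of samples "
            f"({dataset.n_samples})"
        )
    fused = fused_latents(model, dataset)
    if model.config.assign == "argmax":
        if fused.shape[1] != k:
            raise ParameterError(
                "argmax assignment requires latent_dim == n_clusters"
            )
        pred = fused.argmax(axis=1)
    else:
        km_seed = int(np.random.SeedSequence(
            entropy=model.config.seed, spawn_key=(2,)
        ).generate_state(1)[0] % (2 ** 31))
        km = KMeans(n_clusters=k, n_init=model.config.kmeans_restarts,
                    random_state=km_seed)
        pred = km.fit_predict(fused)
    if dataset.labels is not None:
        return score(pred, dataset.labels)
    return ClusteringResult(predicted=np.asarray(pred))
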