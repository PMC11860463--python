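"""Clustering metrics (ACC / NMI / ARI), missing-rate sweeps, ablations.

ACC is clustering accuracy under an optimal one-to-one matching of
predicted clusters to reference classes (linear assignment on the
confusion matrix, ties broken toward the lowest-index matching). NMI
uses the arithmetic mean of the two partition entropies as normalizer;
ARI is the pair-counting adjusted Rand index. All three are invariant
to relabeling of either partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .errors import StructuralError

NMI_NORMALIZATION = "arithmetic"


@dataclass
class ClusteringResult:
    """Hard assignments plus their agreement with reference labels."""

    predicted: np.ndarray
    reference: np.ndarray | None = None
    acc: float | None = None
    nmi: float | None = None
    ari: float | None = None

    def summary(self) -> dict:
        return {"acc": self.acc, "nmi": self.nmi, "ari": self.ari}


def _check_pair(pred, truth):
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise StructuralError(
            f"label vectors differ in length: {pred.size} vs {truth.size}"
        )
    return pred, truth


def accuracy(pred, truth) -> float:
    """Best fraction of agreement over one-to-one cluster<->class matchings."""
    pred, truth = _check_pair(pred, truth)
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    k = max(pu.size, tu.size)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (pi, ti), 1)
    row, col = linear_sum_assignment(-confusion)
    return float(confusion[row, col].sum()) / pred.size


def nmi(pred, truth) -> float:
    """Arithmetic-mean-normalized mutual information of the partitions."""
    pred, truth = _check_pair(pred, truth)
    if np.unique(pred).size == 1 and np.unique(truth).size == 1:
        warnings.warn("both partitions are single-cluster; NMI defined as 0")
        return 0.0
    return float(normalized_mutual_info_score(
        truth, pred, average_method=NMI_NORMALIZATION))


def ari(pred, truth) -> float:
    """Adjusted Rand index from the pair-counting contingency formula."""
    pred, truth = _check_pair(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def score(pred, truth) -> ClusteringResult:
    pred, truth = _check_pair(pred, truth)
    return ClusteringResult(
        predicted=pred, reference=truth,
        acc=accuracy(pred, truth), nmi=nmi(pred, truth), ari=ari(pred, truth),
    )


# ---- experiment harnesses ----------------------------------------------

def sweep(spec, rates, config, seeds) -> pd.DataFrame:
    """Train and evaluate once per (missing rate, seed).

    One complete synthetic draw is shared across all rates (only the
    mask differs); each seed re-initializes training. Returns one row
    per run with columns rate, seed, acc, nmi, ari.
    """
    from dataclasses import replace

    from .synthetic import make_benchmark
    from .trainer import assign_clusters, train

    rates = list(rates)
    datasets = make_benchmark(spec, rates)
    records = []
    for rate, ds in zip(rates, datasets):
        for seed in seeds:
            cfg = replace(config, seed=int(seed))
            model, _ = train(ds, cfg)
            result = assign_clusters(model, ds)
            records.append({"rate": rate, "seed": int(seed),
                            **result.summary()})
    return pd.DataFrame.from_records(records)


def aggregate_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of each metric per missing rate."""
    return (table.groupby("rate")[["acc", "nmi", "ari"]]
            .agg(["mean", "std"]).reset_index())


#: the seven non-empty loss subsets, in the conventional ablation order:
#: each loss alone, then each pair, then the full objective.
ABLATION_ROWS = (
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, True, True),
)


def ablate(spec, config, missing_rate=0.3, seeds=None) -> pd.DataFrame:
    """Run the seven loss-toggle combinations on one masked benchmark.

    Rows follow ``ABLATION_ROWS``; columns flag which of the fusion
    (fcit), within-view reconstruction (rec) and cross-view prediction
    (pre) losses were active, plus mean metrics over ``seeds``.
    """
    from dataclasses import replace

    from .synthetic import make_benchmark
    from .trainer import assign_clusters, train

    (ds,) = make_benchmark(spec, [missing_rate])
    seeds = [config.seed] if seeds is None else list(seeds)
    records = []
    for use_fcit, use_rec, use_pre in ABLATION_ROWS:
        scores = []
        for seed in seeds:
            cfg = replace(config, seed=int(seed), use_fcit=use_fcit,
                          use_rec=use_rec, use_pre=use_pre)
            model, _ = train(ds, cfg)
            scores.append(assign_clusters(model, ds).summary())
        records.append({
            "fcit": use_fcit, "rec": use_rec, "pre": use_pre,
            "acc": float(np.mean([s["acc"] for s in scores])),
            "nmi": float(np.mean([s["nmi"] for s in scores])),
            "ari": float(np.mean([s["ari"] for s in scores])),
        })
    return pd.DataFrame.from_records(records)


def export_embedding(model, dataset, path) -> pd.DataFrame:
    """Write the fused latent coordinates (for external 2-D plotting)."""
    from .trainer import fused_latents

    fused = fused_latents(model, dataset)
    cols = [f"z{i}" for i in range(fused.shape[1])]
    df = pd.DataFrame(fused, columns=cols)
    if dataset.labels is not None:
        df["label"] = dataset.labels
    df.to_csv(path, index=False)
    return df
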