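# imvclust

Incomplete two-view clustering for paired biomedical feature data —
e.g. two contrast phases of a liver-tumor CT study where many patients
have only one phase on record. The package groups unlabeled samples
into K clusters when each sample carries up to two feature views and an
arbitrary fraction of samples (up to all of them) is missing one view.

## Method

Let `X^v ∈ R^{N×D_v}` (v = 1, 2) be the view matrices with an N×2
availability mask. The pipeline optimizes, end to end,

```
L = L_fcit + λ1 · L_rec + λ2 · L_pre
```

with default trade-offs λ1 = 0.1, λ2 = 0.01:

1. **Within-view reconstruction** `L_rec`: a fully-connected
   autoencoder per view; the encoder ends in a row softmax, so latents
   `Z^v ∈ R^{N×L}` are probability vectors over L latent units.
   `L_rec = Σ_v mean_i ‖x_i^v − d_v(e_v(x_i^v))‖²` over available rows.
2. **Entropy-weight feature reconstruction**: each latent column j
   gets a weight `W_j = (1 − E_j)/Σ_k(1 − E_k)` from the normalized
   Shannon entropy `E_j` of its share distribution across the batch;
   the reweighted latents are `L^v = Z^v diag(W)`. Uniform
   (uninformative) columns are shrunk, concentrated ones amplified.
3. **Cross-view prediction** `L_pre`: generators `G12, G21` map between
   the two latent spaces; on samples with both views,
   `L_pre = ‖G12(L¹) − L²‖² + ‖G21(L²) − L¹‖²`. With *zero* paired
   samples (the fully incomplete regime) the loss falls back to cycle
   consistency `‖G21(G12(L¹)) − L¹‖² + ‖G12(G21(L²)) − L²‖²`, and the
   same generators impute every missing latent.
4. **Fuzzy information-theoretic fusion** `L_fcit`: with every batch
   sample acting as a cluster center, the fuzzy c-means membership
   `U_ij ∝ (‖l_i − l_j‖² + ε)^{−1/(m−1)}` (fuzziness m = 2) and the
   similarity summand `S_ij = (1/V) U_ij² ‖l_i − l_j‖²` give a row
   softmax probability matrix `P^v = softmax(−S^v)` per view. The
   cross-view joint `S^{ll'} = P¹(P²)ᵀ / Σ` is scored by
   `L_fcit = −Σ S^{ll'} log( S^{ll'} / (S_l^{α+1} S_{l'}^{α+1}) )`,
   a mutual information with entropy-balanced marginals (α = 9).

Training uses Adam (lr 1e-4), batch 256, 500 epochs by default; final
clusters come from seeded k-means (10 restarts) on the average of the
two completed, reweighted latent matrices. Quality against reference
labels is reported as ACC (optimal-assignment matching), NMI
(arithmetic-mean normalization) and ARI.

Equations printed ambiguously in the source method (entropy sign and
normalizer, distance-power membership, log-free fusion ratio) are
available verbatim behind `literal` mode flags; the self-consistent
`canonical` forms are the defaults. See `docs/methods.md`.

All differentiable math runs on a small in-repo reverse-mode autodiff
engine over numpy (`imvclust._autodiff`), so the package has no deep
learning framework dependency.

## Worked example

```python
from imvclust import (SyntheticSpec, MissingSpec, TrainConfig,
                      apply_missing, generate, train, assign_clusters)

spec = SyntheticSpec(n_samples=200, n_clusters=2, dims=(20, 24),
                     separation=6.0, seed=7)
dataset = apply_missing(generate(spec), MissingSpec(0.3, seed=7))
print("paired samples:", dataset.n_paired, "of", dataset.n_samples)

config = TrainConfig(epochs=100, seed=0)
model, report = train(dataset, config)
print(f"total loss: epoch 1 = {report.total[0]:.3f}, "
      f"epoch 100 = {report.total[-1]:.3f}")

result = assign_clusters(model, dataset)
print(f"ACC={result.acc:.3f}  NMI={result.nmi:.3f}  ARI={result.ari:.3f}")
```

prints

```
paired samples: 140 of 200
total loss: epoch 1 = -89.182, epoch 100 = -91.218
ACC=1.000  NMI=1.000  ARI=1.000
```

Two balanced clusters six within-cluster standard deviations apart,
30% of the 200 samples missing one view: the loss decreases over
training and the recovered clustering matches the generating labels
exactly. The same pipeline is available from the shell:

```
imvclust simulate --n 200 --seed 7 --out data/
imvclust train --data data/ --missing-rate 0.3 --epochs 100 --out run/
imvclust sweep  --rates 0.1,0.3,0.5,0.7,1.0 --seeds 0,1,2 --out sweep/
imvclust ablate --missing-rate 0.3 --out ablation/
```

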