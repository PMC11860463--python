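# Methods

## Problem and model

The package clusters N samples described by up to two real-valued
feature views (`X¹ ∈ R^{N×D₁}`, `X² ∈ R^{N×D₂}`) into K groups when a
fraction of samples — possibly all of them — is missing one view. The
motivating setting is multiphase contrast-enhanced CT of liver tumors,
where the two views are feature vectors from two contrast phases and
the latent two-class structure is a postoperative prognostic indicator;
the method itself is agnostic to how the feature vectors were obtained
and starts from matrices.

The model assumes the two views are noisy, view-specific images of one
shared cluster-dependent signal — consistent across views, complementary
in their noise. Four components operationalize this:

1. **Per-view autoencoders.** Encoder `e_v: D_v → L` (fully connected,
   tanh hidden layers, softmax output) and mirrored linear-output
   decoder `d_v`. The softmax head makes each latent row a probability
   vector over L latent units, which is what the downstream
   information-theoretic machinery expects. The within-view loss is the
   mean (over rows) squared reconstruction error, summed over views,
   computed only on rows whose view is available.
2. **Entropy-weight feature reconstruction.** For a batch latent
   matrix Z (N×L), each column receives a share distribution across
   samples; its normalized Shannon entropy `E_j ∈ [0,1]` measures how
   uninformative the column is, and the weight
   `W_j = (1 − E_j)/Σ_k(1 − E_k)` (a convex combination) rescales the
   column: `L = Z diag(W)`. Weights are recomputed per view per batch
   from that batch's available-sample latents.
3. **Cross-view generators.** `G12, G21: L → L` (fully connected)
   translate between the two latent spaces. On paired samples the
   prediction loss is the two-directional mean squared error
   `‖G12(L¹) − L²‖² + ‖G21(L²) − L¹‖²`. When the batch contains no
   paired sample — at 100% missingness no pair exists anywhere — the
   loss becomes cycle consistency through both generators,
   `‖G21(G12(L¹)) − L¹‖² + ‖G12(G21(L²)) − L²‖²`, the only pair-free
   surrogate consistent with the generators' role. The same generators
   impute each missing latent from the sample's observed view;
   observed latents are never overwritten.
4. **Fuzzy information-theoretic fusion.** Within a batch, every
   sample acts as a cluster center. The fuzzy c-means membership
   `U_ij ∝ (d²_ij + ε)^{−1/(m−1)}` (diagonal excluded, rows normalized)
   and the similarity summand `S_ij = (1/V) U²_ij d²_ij` yield a
   row-stochastic probability matrix `P^v = row-softmax(−S^v)`. The
   cross-view joint is `J = P¹(P²)ᵀ` normalized to sum to one, and the
   fusion loss is
   `L_fcit = −Σ_ij J_ij log( J_ij / (R_i^{α+1} C_j^{α+1}) )`
   with row/column marginals R, C. At α = 0 this is exactly the
   negative mutual information of the coupling (zero for an independent
   joint); larger α additionally rewards high marginal entropy, pushing
   toward balanced, diagonal-like couplings. On the uniform-diagonal
   joint I/N the loss has the closed form −(2α+1)·ln N, which the test
   suite checks to 1e−9.

The training objective is `L = L_fcit + λ1·L_rec + λ2·L_pre`,
optimized with Adam on shuffled mini-batches; membership and joint
matrices are batch-local (batch×batch), so memory never scales as N².

## Canonical vs literal modes

Three formulas in the source method are printed in forms that
contradict their own surrounding prose, so each operator carries two
modes. `canonical` (default) uses the self-consistent, field-standard
form; `literal` reproduces the printed arithmetic verbatim:

- **Entropy weighting.** The printed entropy lacks the minus sign and
  the 1/ln N normalizer, and mixes row-mean and column-mean share
  normalizations; on sign-indefinite latents its shares can be
  negative and its weights can leave [0, 1]. Canonical mode min-max
  scales each column to [ε, 1], uses column-sum shares and
  `E_j = −(1/ln N) Σ p ln p`, guaranteeing `E_j ∈ [0,1]` and
  nonnegative weights. Literal mode keeps the printed form; where the
  printed `p ln p` is undefined (p ≤ 0) it evaluates `p ln|p|` with an
  ε floor and logs a warning — the minimal finite extension that
  preserves the algebraic identity Σ W = 1, which holds in both modes
  by construction.
- **Membership.** The printed power law `((1/m) d²)^{1/(m−1)}` grows
  with distance, contradicting the stated reading that larger values
  mean more similar. Canonical mode uses the inverse-distance FCM
  affinity; literal keeps the printed growth.
- **Fusion loss.** The printed objective has no logarithm and is not a
  mutual information. Canonical inserts the log (the established form
  the expression abbreviates); literal evaluates the printed ratio.

Two further notational repairs are fixed (not mode-switched): the
latent map is the encoder, not the decoder, by type consistency
(D → L); and the weight application `Σ_j W_j Z` is read as per-column
scaling because the reconstructed latents are declared N×L — a true
sum over j would collapse the feature axis.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ1 | 0.1 | weight of the within-view reconstruction loss |
| λ2 | 0.01 | weight of the cross-view prediction loss |
| learning rate | 1e-4 | Adam step size |
| batch size | 256 | clipped to N; membership/joint are batch-local |
| epochs | 500 | full passes over the shuffled data |
| latent dim L | 128 | width of the softmax latent space |
| fuzziness m | 2 | FCM exponent; larger m softens memberships |
| α | 9 | entropy-balance power on the joint's marginals |
| K | 2 | number of clusters extracted |
| encoder widths | 512, 256 | hidden layers of e_v (mirrored in d_v) |
| generator widths | 256 | hidden layer of G12/G21 |

λ1 = 0.1, λ2 = 0.01 are the recommended operating point (the
alternative initial setting 0.1/0.1 is reachable by flag). The latent
dimensionality is not fixed by the method's description; 128 is the
package default, configurable down to K for `argmax` assignment.

## Cluster extraction

The method's description stops at the trained representation. The
package fuses the two completed, reweighted latent matrices by
averaging and runs seeded k-means (10 restarts) — the conventional
evaluation protocol for deep incomplete multiview clustering. When
`latent_dim == K`, `assign="argmax"` instead reads the softmax head
directly as cluster probabilities.

## Synthetic benchmark

The clinical cohorts behind the method are private, so the generator
emulates their structure: K centroids at the vertices of a scaled
simplex in R^K (pairwise distance `separation × view_noise`), balanced
labels, and per-view orthonormal-row linear maps (QR of a seeded
Gaussian matrix) plus spherical Gaussian noise. Orthonormal rows make
the difficulty knob exact: cluster centroids sit `separation`
within-cluster standard deviations apart in every view. Views are
conditionally independent given the shared signal.

The default benchmark (N = 200, K = 2, dims 20/24, separation 6,
unit noise) is deliberately well-separated: it verifies that the
pipeline preserves and recovers structure through encoding,
reweighting, imputation and fusion — including at 100% missingness,
where training runs entirely on cycle consistency. What it does not
emulate: heavy-tailed or structured imaging noise, class imbalance
(available as a spec knob but not default), nonlinear view maps, or
weak separability; passing results here do not predict absolute
accuracy on clinical features, only the integrity of the mechanism.
Missing-rate masks follow the study protocol {10, 30, 50, 70, 100}%:
each affected sample loses exactly one view, chosen uniformly; at 100%
every sample keeps exactly one view.

## Numerical choices

- ε = 1e−12 for every share, denominator and log guard; natural
  logarithm throughout; `0·log 0 := 0` (exact, since the factor is an
  exact zero).
- Canonical entropies are clipped into [0, 1] to absorb rounding, so
  weights are nonnegative by construction.
- The per-column min/max used in canonical scaling are treated as
  constants in the gradient (the weighting stays differentiable
  through Z everywhere else); likewise the row max inside softmax.
- An all-constant latent matrix makes every feature maximally
  entropic; the raw weight operator raises a degenerate-input error,
  while the training pipeline falls back to uniform weights 1/L with a
  logged warning (both views of the fact are tested).
- Squared distances are clamped at 0 and the diagonal zeroed exactly
  before membership; duplicate points are handled by the ε in the
  inverse-distance power.
- Losses are averaged over batch rows, not summed, so λ values
  transfer across batch sizes.
- Divergence (any enabled loss turning non-finite) aborts with an
  error naming the offending term.
- One master seed fans out (via independent spawn keys) to parameter
  initialization, shuffling, masking and k-means; runs are
  bit-reproducible.
- All gradients flow through a small in-repo reverse-mode autodiff
  engine over float64 numpy arrays; the engine's primitives are
  finite-difference-checked in the test suite.

## Known limitations

- Exactly two views; more views would require pairwise machinery the
  method does not define.
- The fusion loss is unbounded below as the joint concentrates;
  training relies on the fixed epoch budget rather than a convergence
  criterion (a divergence abort is the only early exit).
- Entropy weights computed per batch make the effective objective
  batch-size dependent (the description leaves the recomputation
  schedule open; per-batch is the choice here).
- The literal modes exist for comparison, not for use: literal
  membership actively favors distant samples and literal entropy can
  produce negative feature weights.
- Documented loss-trace values and benchmark metrics are computed by
  the test suite and `scripts/acceptance.py`; no other empirical
  claims are made.

## Test problem sizes

Unit and property tests run on instances of 2–40 samples with oracles
(loop-based extended-precision re-evaluations, exhaustive matchings,
pair counting). The end-to-end checks use the default benchmark at
100 epochs and five seeds — large enough for the recovery and ablation
directions to be stable, small enough to run comfortably on one CPU.
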