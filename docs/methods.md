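# Methods note

This note records the modelling assumptions, the default parameter choices
and their rationale, what the synthetic data generator emulates, the
numerical decisions, and the known limitations of the `kgetm` package.

## Model

### Generative assumptions

Each patient record is a bag of code tokens over two vocabularies: diagnosis
codes (ICD-9-like) and drug ingredient codes (ATC-like). The model assumes:

1. A patient `p` draws a latent topic mixture `theta_p = softmax(delta_p)`
   with `delta_p ~ N(0, I_K)` (logistic-normal prior).
2. Every token of modality `t` (ICD or ATC) is drawn independently from the
   categorical mixture `Cat(beta^(t) theta_p)`.
3. The per-modality topic-over-code distributions are parameterised through
   embeddings: `beta^(t)_k = softmax_v(rho^(t)_v . alpha^(t)_k)`, where
   `rho^(t)` is the code embedding and `alpha^(t)` the topic embedding.
4. The code embedding is not free: an initial embedding (pre-trained with
   node2vec on a merged ICD+ATC knowledge graph) is refined by a multi-head
   graph-attention network (GAT), so codes that are close in the taxonomy
   or bridged by disease–drug links receive related embeddings.

The token-exchangeability assumption means record length carries no signal:
the encoder normalises counts to per-modality proportions, so the inferred
posterior depends on code composition only.

### Inference

Inference is amortised variational: an encoder (two modality-specific ReLU
layers summed, one shared ReLU layer, linear heads for the posterior mean
and log standard deviation) maps counts to `q(delta_p) = N(mu_p,
diag(sigma_p^2))`. Training maximises the reparameterised ELBO with
minibatch Adam; the minibatch estimate is scaled by `D_train / |B|` so it is
an unbiased estimate of the corpus ELBO. The KL term has the closed
Gaussian form; the likelihood term uses one Monte-Carlo draw per document
per step by default.

Convergence is declared when the relative improvement of the validation
ELBO over the best value so far stays below `convergence_tol` for
`patience` consecutive epochs.

### Graph attention

Each GAT layer recomputes every node vector as an attention-weighted sum of
linearly mapped vectors of the node and its neighbours; the logit for pair
`(c, j)` is `LeakyReLU(a^T [W h_c || W h_j])`, normalised by softmax over
`{c} ∪ N(c)`. Attention at layer `i` is computed from the layer `i-1`
embeddings. Head outputs are averaged (keeping the dimension at `L`); a
concat-project rule is available. The final code embedding is the
elementwise max-pool over all layer outputs, which lets shallow and deep
neighbourhood summaries coexist.

### Knowledge graph

Two taxonomy forests (child→parent TSVs) are merged into one undirected
graph with typed edges (`icd-icd`, `atc-atc`, `icd-atc`); disease–drug
cross links bridge the modalities. *Augmentation* adds an edge from every
code to each of its ancestors, shortening information paths; it is
idempotent. Node order is all ICD codes sorted, then all ATC codes sorted,
and defines embedding row indices, so results do not depend on file
enumeration order.

## Defaults and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| topics `K` | 100 | standard operating point for full-size EHR corpora; desk-scale studies use `K = 5` |
| embedding dim `L` | 256 | standard for full-size runs; desk-scale studies use 32 (enough for 100 codes) |
| encoder hidden | 128 | two-layer encoder capacity matching the above |
| learning rate | 0.01 | Adam step that trains stably on count data at batch 512 |
| weight decay | 1.2e-6 | light L2 on the *encoder only*: regularises inference without biasing the generative parameters |
| batch size | 512 | full-size default; desk-scale tests use 256 |
| `max_epochs` | 100 | with patience-based early stopping the cap is rarely binding |
| `convergence_tol`, `patience` | 1e-4, 5 | declare convergence only after sustained stagnation of the validation ELBO |
| GAT layers / heads | 3 / 4 | three hops cover leaf→chapter→root plus a cross link; multiple heads stabilise attention |
| LeakyReLU slope | 0.2 | conventional GAT value |
| node2vec walks | 10 × length 80, window 5, 5 negatives, p = q = 1 | the original node2vec operating point; unbiased walks suffice because the graph is close to a tree |
| node2vec lr / batch | 0.0125 / 1024 | see numerical choices below |
| coherence/diversity top-s/r | 3 / 3 | small enough that top codes are meaningful on 50-code vocabularies |
| imputation k, top-N | 5, 30 | patient-wise@5 and drug-wise@30 are the standard reporting points |
| LASSO grid | 8 log-spaced λ in [0.01, 1] | covers weak-to-strong sparsity; chosen per repeat on a validation split |

### Ablation protocol

The initialisation ablation (node2vec-initialised vs random-initialised GAT
input) compares held-out document-completion NLL per token. Both arms are
trained to convergence under the same budget (`max_epochs = 80`,
patience-based stopping). This matters: the initialised model converges to
a better optimum but needs more epochs than the random-init variant, which
stalls early; truncating both at 30 epochs reverses the comparison purely
through under-training. The budget is a training-length choice applied
identically to both arms.

### Plain-ETM fallback

When `fit` is called with the GAT disabled, no graph and no initial
embedding, a frozen random `rho` would make `beta` untrainable in the code
direction. In that configuration `rho` becomes a free trainable parameter,
which is the standard embedded topic model.

## What the generator emulates

Real administrative claims data cannot be redistributed, so every stage is
exercised on generated data carrying the structure the model assumes:

- **Two taxonomies, topic-aligned.** Each topic owns a disjoint block of
  leaf codes under one chapter per modality (depth-2 trees), and cross
  links join corresponding blocks. This alignment is what makes the
  knowledge graph informative — and hence what the ablation can detect.
- **Heavy-tailed code usage.** Within a topic's block, code probabilities
  decay as a Zipf law (`1/rank`); `temperature` (default 0.15) controls
  how much mass leaks outside the block, i.e. how noisy topics are.
- **Logistic-normal mixtures** (or one-hot mixtures with `single_topic`,
  emulating single-disease patients).
- **Poisson record lengths** (mean 30 + 30 tokens) with empty records
  clamped to one token, since an empty document has no likelihood.
- **Phenotype labels** thresholded on a true topic proportion (median
  threshold, prevalence ≈ 0.5), the quantity a topic-mixture classifier
  should recover.

Defaults (`K = 5`, `V = 50 + 50`, `D = 2000`) are the desk-scale study
condition: large enough that topic recovery is identifiable, small enough
to run in seconds on one CPU.

## Numerical choices

- **Custom reverse-mode autodiff in numpy.** The environment provides no
  deep-learning framework, so the package ships a small Tensor class with
  explicit backward rules (broadcast arithmetic, matmul, softmax pieces,
  gather/scatter-add for graph aggregation) and an Adam optimiser. All
  backward rules are verified against central finite differences in the
  test suite.
- **Segment softmax with detached per-group max shift** keeps GAT attention
  stable; the shift is a constant so gradients are unaffected.
- **Log-softmax parameterisation of beta** (`log_softmax` then `exp`)
  avoids overflow in the code-by-topic logits.
- **Probability floors**: per-token mixture probabilities are floored at
  1e-12 before `log`.
- **Skip-gram stability**: the word2vec-style operating point (lr 0.025,
  large batches) diverges on small vocabularies because per-row updates
  accumulate within a batch. Defaults are lr 0.0125 with batch 1024, and
  accumulated per-row updates are clipped to [-1, 1] per batch; sigmoid
  inputs are clipped to ±35.
- **Determinism**: every stochastic component takes a seed;
  the pipeline expands one top seed into fixed per-stage offsets (all below
  2^31) recorded in the run manifests.
- **NPMI conventions**: defined as −1 when a pair never co-occurs and +1
  when it co-occurs in every document.

## Limitations

- Tokens are exchangeable: no visit structure, no temporal ordering, no
  code co-occurrence beyond what topics induce.
- The inference network is shared across patients (amortisation gap); no
  per-document optimisation of the posterior is attempted.
- The GAT forward pass runs on the full graph each minibatch; this is fine
  at desk scale (hundreds of nodes) but the full-size configuration
  (tens of thousands of codes) needs a machine with more memory and time
  than the test budget assumes.
- The synthetic generator's topic-block alignment is idealised; real
  taxonomies only partially align with phenotypes, so effect sizes measured
  on synthetic data (e.g. the ablation margin) do not transfer
  quantitatively to real data.
- Drug imputation assumes the missing modality is missing at random; the
  evaluation zeroes the ATC block, which ignores informative missingness.
- The LASSO classifier is evaluated with AUROC on random splits; no
  calibration or per-site transfer is assessed.
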