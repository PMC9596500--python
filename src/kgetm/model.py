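"""Multimodal embedded topic model over diagnosis and drug codes.

The generative story: each patient p draws a K-dimensional topic mixture
theta_p = softmax(delta_p), delta_p ~ N(0, I); each of their diagnosis (ICD)
and drug (ATC) code tokens is drawn from the categorical mixture
Cat(beta^(t) theta_p).  The per-modality topic-over-code distributions are
parameterised through embeddings:

    beta^(t)_k = softmax_v( rho^(t) . alpha^(t)_k )

where rho^(t) is the code embedding (refined from a knowledge graph by a
graph-attention network) and alpha^(t) the topic embedding.  Inference is
amortised: an encoder network maps the count vector to a Gaussian posterior
(mu_p, sigma_p) over delta_p, trained by maximising the reparameterised
evidence lower bound (ELBO) with minibatch Adam.

Organisation follows the statsmodels convention: ``MultimodalETM`` is the
model object built from data, ``fit()`` returns an ``ETMResults`` carrying
the estimates, traces and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .autodiff import Adam, Tensor
from .corpus import EHRCorpus
from .gat import CodeEmbedding, GATConfig, GATNetwork
from .graph import KnowledgeGraph
from .node2vec import InitialEmbedding

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TopicMixture", "MultimodalETM", "ETMResults",
    "compute_topic_distributions", "kl_divergence", "log_likelihood",
    "sample_mixture", "elbo_batch", "has_converged",
]

_EPS = 1e-12  # floor under per-token probabilities before log


# --------------------------------------------------------------- functional
def compute_topic_distributions(rho_t: np.ndarray,
                                alpha_t: np.ndarray) -> np.ndarray:
    """Per-modality topic distributions beta (K x V) from embeddings.

    ``rho_t`` is L x V (one column per code), ``alpha_t`` is L x K.  Row k of
    the result is softmax over codes of the inner products rho_v . alpha_k.
    """
    if not (np.all(np.isfinite(rho_t)) and np.all(np.isfinite(alpha_t))):
        raise ValueError("non-finite embedding inputs")
    logits = alpha_t.T @ rho_t                      # (K, V)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def kl_divergence(mu: np.ndarray, log_sigma: np.ndarray) -> float:
    """KL( N(mu, diag sigma^2) || N(0, I) ), closed form, >= 0."""
    mu = np.asarray(mu, dtype=float)
    log_sigma = np.asarray(log_sigma, dtype=float)
    return float(0.5 * np.sum(mu ** 2 + np.exp(2 * log_sigma)
                              - 1.0 - 2.0 * log_sigma))


def log_likelihood(v_icd: np.ndarray, v_atc: np.ndarray, theta: np.ndarray,
                   beta_icd: np.ndarray, beta_atc: np.ndarray) -> float:
    """Multinomial log-likelihood of one patient's counts given theta.

    Each token of code v in modality t contributes log(beta^(t)_{., v} theta).
    """
    theta = np.asarray(theta, dtype=float)
    if abs(theta.sum() - 1.0) > 1e-6 or np.any(theta < -1e-12):
        raise ValueError("theta is not on the simplex")
    total = 0.0
    for v, beta in ((v_icd, beta_icd), (v_atc, beta_atc)):
        v = np.asarray(v, dtype=float)
        mix = theta @ beta                          # (V,)
        total += float(v @ np.log(np.maximum(mix, _EPS)))
    return total


@dataclass
class TopicMixture:
    """Variational posterior and a sampled mixture for one patient."""

    mu: np.ndarray
    log_sigma: np.ndarray
    delta: np.ndarray
    theta: np.ndarray


def sample_mixture(mu: np.ndarray, log_sigma: np.ndarray,
                   seed: int | np.random.Generator = 0) -> TopicMixture:
    """Reparameterised draw: delta = mu + sigma * eps, theta = softmax(delta)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mu = np.asarray(mu, dtype=float)
    log_sigma = np.asarray(log_sigma, dtype=float)
    delta = mu + np.exp(log_sigma) * rng.standard_normal(mu.shape)
    return TopicMixture(mu, log_sigma, delta, _softmax(delta))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def has_converged(trace: list[float], tol: float = 1e-4,
                  patience: int = 5) -> bool:
    """True when relative improvement over the best-so-far validation ELBO
    stays below ``tol`` for ``patience`` consecutive epochs."""
    if len(trace) < 2:
        return False
    best = trace[0]
    stall = 0
    for value in trace[1:]:
        rel = (value - best) / max(abs(best), 1e-12)
        if rel < tol:
            stall += 1
            if stall >= patience:
                return True
        else:
            stall = 0
        best = max(best, value)
    return False


def elbo_batch(counts_icd: np.ndarray, counts_atc: np.ndarray,
               encoder: "Encoder", beta_icd: np.ndarray, beta_atc: np.ndarray,
               n_samples: int = 1, seed: int = 0,
               scale: float = 1.0) -> tuple[float, dict]:
    """Monte-Carlo ELBO of a batch of documents under fixed parameters.

    Returns the (optionally ``scale``-multiplied) estimate plus a breakdown
    into the likelihood and KL terms.  One reparameterised draw per document
    per sample.
    """
    counts_icd = np.atleast_2d(np.asarray(counts_icd, dtype=float))
    counts_atc = np.atleast_2d(np.asarray(counts_atc, dtype=float))
    if counts_icd.shape[0] == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    mu, ls = encoder.encode_mean(counts_icd, counts_atc)
    sigma = np.exp(ls)
    ll_total = kl_total = 0.0
    for _ in range(n_samples):
        delta = mu + sigma * rng.standard_normal(mu.shape)
        theta = _softmax(delta, axis=1)
        for counts, beta in ((counts_icd, beta_icd), (counts_atc, beta_atc)):
            mix = np.maximum(theta @ beta, _EPS)
            ll_total += float((counts * np.log(mix)).sum())
    ll = ll_total / n_samples
    kl = float(sum(kl_divergence(mu[i], ls[i]) for i in range(mu.shape[0])))
    kl_total = kl
    elbo = scale * (ll - kl_total)
    return elbo, {"log_likelihood": ll, "kl": kl_total, "scale": scale}


# ------------------------------------------------------------------ encoder
class Encoder:
    """Amortised inference network for the topic-mixture posterior.

    Two modality-specific ReLU input layers (to ``hidden`` dims) are summed,
    passed through one shared ReLU layer, then two linear heads emit the
    K-dimensional posterior mean and log standard deviation.  Inputs are
    normalised to per-modality proportions, so the posterior depends on the
    code composition of a record, not its raw volume.
    """

    def __init__(self, v_icd: int, v_atc: int, K: int, hidden: int = 128,
                 seed: int = 0):
        rng = np.random.default_rng(seed)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-s, s, size=(n_in, n_out)),
                          requires_grad=True)

        self.W_icd, self.b_icd = glorot(v_icd, hidden), Tensor(
            np.zeros(hidden), requires_grad=True)
        self.W_atc, self.b_atc = glorot(v_atc, hidden), Tensor(
            np.zeros(hidden), requires_grad=True)
        self.W_h, self.b_h = glorot(hidden, hidden), Tensor(
            np.zeros(hidden), requires_grad=True)
        self.W_mu, self.b_mu = glorot(hidden, K), Tensor(
            np.zeros(K), requires_grad=True)
        self.W_ls, self.b_ls = glorot(hidden, K), Tensor(
            np.zeros(K), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W_icd, self.b_icd, self.W_atc, self.b_atc,
                self.W_h, self.b_h, self.W_mu, self.b_mu,
                self.W_ls, self.b_ls]

    @staticmethod
    def normalise(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        tot = x.sum(axis=-1, keepdims=True)
        return x / np.maximum(tot, 1.0e-300)

    def forward(self, x_icd: np.ndarray, x_atc: np.ndarray
                ) -> tuple[Tensor, Tensor]:
        x_icd = np.atleast_2d(x_icd)
        x_atc = np.atleast_2d(x_atc)
        if np.any(x_icd.sum(axis=1) + x_atc.sum(axis=1) == 0):
            raise ValueError("a record with no tokens in either modality "
                             "has no defined posterior")
        xi = Tensor(self.normalise(x_icd))
        xa = Tensor(self.normalise(x_atc))
        e = (xi @ self.W_icd + self.b_icd).relu() + \
            (xa @ self.W_atc + self.b_atc).relu()
        h = (e @ self.W_h + self.b_h).relu()
        mu = h @ self.W_mu + self.b_mu
        log_sigma = h @ self.W_ls + self.b_ls
        return mu, log_sigma

    def encode_mean(self, x_icd: np.ndarray, x_atc: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        mu, ls = self.forward(x_icd, x_atc)
        return mu.data, ls.data


# -------------------------------------------------------------------- model
@dataclass
class TrainConfig:
    """Optimisation and ablation settings for :meth:`MultimodalETM.fit`."""

    learning_rate: float = 0.01
    weight_decay: float = 1.2e-6        # L2 on the variational (encoder) params
    batch_size: int = 512
    max_epochs: int = 100
    convergence_tol: float = 1e-4
    patience: int = 5
    n_samples: int = 1                  # Monte-Carlo draws per document
    validation_fraction: float = 0.1
    seed: int = 0
    use_node2vec_init: bool = True
    use_augmentation: bool = True       # consumed by the pipeline graph build
    use_gat: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


class MultimodalETM:
    """Knowledge-graph-informed embedded topic model of EHR code counts.

    Parameters
    ----------
    corpus : EHRCorpus
        Training counts over the concatenated ICD+ATC vocabulary.
    n_topics : int
        Number of latent phenotype topics K.
    embedding_dim : int
        Shared embedding dimension L of codes and topics.
    graph : KnowledgeGraph, optional
        Merged code graph; required when the GAT refinement is enabled.
    init_embedding : InitialEmbedding, optional
        node2vec pre-trained node embedding (rows in graph node order).
    gat_config : GATConfig, optional
        Depth/heads of the attention network (default 3 layers, 4 heads).
    shared_alpha : bool
        Share one topic-embedding matrix across modalities instead of the
        default separate alpha^(icd), alpha^(atc).
    """

    def __init__(self, corpus: EHRCorpus, n_topics: int = 100,
                 embedding_dim: int = 256, graph: KnowledgeGraph | None = None,
                 init_embedding: InitialEmbedding | None = None,
                 gat_config: GATConfig | None = None,
                 encoder_hidden: int = 128, shared_alpha: bool = False):
        self.corpus = corpus
        self.K = n_topics
        self.L = embedding_dim
        self.graph = graph
        self.init_embedding = init_embedding
        self.gat_config = gat_config or GATConfig()
        self.encoder_hidden = encoder_hidden
        self.shared_alpha = shared_alpha

    # ------------------------------------------------------------ components
    def _init_rho0(self, config: TrainConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
        """Initial node embedding matrix plus its row-name list."""
        if config.use_node2vec_init:
            if self.init_embedding is None:
                raise ValueError("use_node2vec_init=True requires an "
                                 "init_embedding")
            if self.init_embedding.dimension != self.L:
                raise ValueError("init embedding dimension "
                                 f"{self.init_embedding.dimension} != L={self.L}")
            return self.init_embedding.matrix.copy(), list(self.init_embedding.nodes)
        if self.graph is not None:
            nodes = list(self.graph.nodes)
        else:
            nodes = list(self.corpus.vocab_icd) + list(self.corpus.vocab_atc)
        return rng.standard_normal((len(nodes), self.L)) * 0.1, nodes

    def _vocab_rows(self, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
        index = {c: i for i, c in enumerate(nodes)}
        for code in [*self.corpus.vocab_icd, *self.corpus.vocab_atc]:
            if code not in index:
                raise KeyError(f"vocabulary code {code!r} missing from the "
                               "graph/init embedding")
        icd = np.array([index[c] for c in self.corpus.vocab_icd], dtype=np.intp)
        atc = np.array([index[c] for c in self.corpus.vocab_atc], dtype=np.intp)
        return icd, atc

    # ----------------------------------------------------------- ELBO pieces
    @staticmethod
    def _batch_elbo(counts_icd: np.ndarray, counts_atc: np.ndarray,
                    mu: Tensor, log_sigma: Tensor, beta_icd: Tensor,
                    beta_atc: Tensor, eps: np.ndarray) -> tuple[Tensor, Tensor]:
        """(log-likelihood, KL) Tensors summed over the batch.

        ``eps`` is the standard-normal draw used by the reparameterisation;
        passing it explicitly keeps evaluation deterministic under a seed.
        """
        sigma = (log_sigma * 2.0).exp() ** 0.5
        delta = mu + sigma * Tensor(eps)
        theta = delta.softmax(axis=1)                       # (B, K)
        ll = Tensor(np.zeros(()))
        for counts, beta in ((counts_icd, beta_icd), (counts_atc, beta_atc)):
            mix = theta @ beta                              # (B, V_t)
            mix = mix + _EPS
            ll = ll + (Tensor(counts) * mix.log()).sum()
        kl = ((mu ** 2 + (log_sigma * 2.0).exp() - 1.0 - log_sigma * 2.0)
              .sum() * 0.5)
        return ll, kl

    # ------------------------------------------------------------------- fit
    def fit(self, config: TrainConfig | None = None,
            verbose: bool = False) -> "ETMResults":
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)

        rho0, nodes = self._init_rho0(config, rng)
        icd_rows, atc_rows = self._vocab_rows(nodes)

        # trainable pieces
        encoder = Encoder(self.corpus.v_icd, self.corpus.v_atc, self.K,
                          self.encoder_hidden,
                          seed=int(rng.integers(2 ** 31)))
        alpha_icd = Tensor(rng.standard_normal((self.L, self.K)) * 0.02,
                           requires_grad=True)
        alpha_atc = (alpha_icd if self.shared_alpha else
                     Tensor(rng.standard_normal((self.L, self.K)) * 0.02,
                            requires_grad=True))
        gat: GATNetwork | None = None
        if config.use_gat:
            if self.graph is None:
                raise ValueError("use_gat=True requires a knowledge graph")
            gat = GATNetwork(self.L, self.gat_config,
                             seed=int(rng.integers(2 ** 31)))

        # with no graph and no pre-trained initialisation there is nothing to
        # freeze rho to: fall back to a plain embedded topic model in which
        # the code embedding itself is a free parameter
        rho_param: Tensor | None = None
        if gat is None and self.graph is None and self.init_embedding is None:
            rho_param = Tensor(rho0, requires_grad=True)

        params = [alpha_icd] + ([] if self.shared_alpha else [alpha_atc])
        if gat is not None:
            params += gat.parameters()
        if rho_param is not None:
            params.append(rho_param)
        optim = Adam(params, lr=config.learning_rate)
        optim.add_group(encoder.parameters(), lr=config.learning_rate,
                        weight_decay=config.weight_decay)

        from .autodiff import gather_rows

        def current_rho() -> tuple[Tensor, Tensor]:
            """Vocabulary code embeddings (V_t, L), ICD and ATC blocks."""
            if gat is not None:
                pooled = gat.forward(Tensor(rho0), self.graph)
                return gather_rows(pooled, icd_rows), gather_rows(pooled, atc_rows)
            if rho_param is not None:
                return (gather_rows(rho_param, icd_rows),
                        gather_rows(rho_param, atc_rows))
            return Tensor(rho0[icd_rows]), Tensor(rho0[atc_rows])

        def betas(rho_icd: Tensor, rho_atc: Tensor) -> tuple[Tensor, Tensor]:
            b_i = (rho_icd @ alpha_icd).log_softmax(axis=0).exp().T  # (K, V)
            b_a = (rho_atc @ alpha_atc).log_softmax(axis=0).exp().T
            return b_i, b_a

        # data split: hold out a validation slice for convergence assessment
        D = self.corpus.n_patients
        n_valid = max(1, int(round(config.validation_fraction * D))) \
            if config.validation_fraction > 0 and D >= 10 else 0
        order = rng.permutation(D)
        valid_idx, train_idx = order[:n_valid], order[n_valid:]
        X_icd = self.corpus.icd_counts
        X_atc = self.corpus.atc_counts
        D_train = len(train_idx)
        if D_train == 0:
            raise ValueError("empty training set")

        def dense(block: sp.csr_matrix, idx: np.ndarray) -> np.ndarray:
            return np.asarray(block[idx].todense(), dtype=float)

        def evaluate(idx: np.ndarray, eval_rng: np.random.Generator) -> dict:
            """Per-document-averaged ELBO pieces on a fixed index set."""
            if len(idx) == 0:
                return {"elbo": np.nan, "ll": np.nan, "kl": np.nan}
            xi, xa = dense(X_icd, idx), dense(X_atc, idx)
            mu, ls = encoder.forward(xi, xa)
            eps = eval_rng.standard_normal(mu.shape)
            rho_i, rho_a = current_rho()
            b_i, b_a = betas(rho_i, rho_a)
            ll, kl = self._batch_elbo(xi, xa, mu, ls, b_i, b_a, eps)
            n = len(idx)
            return {"elbo": (ll.item() - kl.item()) / n,
                    "ll": ll.item() / n, "kl": kl.item() / n}

        trace: list[dict] = []
        val_history: list[float] = []
        for epoch in range(config.max_epochs):
            t0 = time.time()
            perm = rng.permutation(D_train)
            epoch_ll = epoch_kl = 0.0
            for s in range(0, D_train, config.batch_size):
                batch = train_idx[perm[s:s + config.batch_size]]
                xi, xa = dense(X_icd, batch), dense(X_atc, batch)
                optim.zero_grad()
                mu, ls = encoder.forward(xi, xa)
                rho_i, rho_a = current_rho()
                b_i, b_a = betas(rho_i, rho_a)
                ll_acc, kl_acc = None, None
                for _ in range(config.n_samples):
                    eps = rng.standard_normal(mu.shape)
                    ll_s, kl_s = self._batch_elbo(xi, xa, mu, ls, b_i, b_a, eps)
                    ll_acc = ll_s if ll_acc is None else ll_acc + ll_s
                    kl_acc = kl_s if kl_acc is None else kl_acc + kl_s
                ll = ll_acc * (1.0 / config.n_samples)
                kl = kl_acc * (1.0 / config.n_samples)
                # unbiased stochastic estimate of the corpus ELBO, negated
                loss = (kl - ll) * (D_train / len(batch))
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; reduce the "
                        "learning rate or check the inputs")
                loss.backward()
                optim.step()
                epoch_ll += ll.item()
                epoch_kl += kl.item()
            eval_rng = np.random.default_rng(config.seed + 7919 + epoch)
            val = evaluate(valid_idx, eval_rng)
            record = {
                "epoch": epoch,
                "train_elbo": (epoch_ll - epoch_kl) / D_train,
                "val_elbo": val["elbo"],
                "kl": epoch_kl / D_train,
                "nll": -epoch_ll / D_train,
                "seconds": time.time() - t0,
            }
            trace.append(record)
            if verbose:
                log.info("epoch %d train_elbo %.4f val_elbo %.4f",
                         epoch, record["train_elbo"], record["val_elbo"])
            monitor = val["elbo"] if n_valid else record["train_elbo"]
            val_history.append(monitor)
            if has_converged(val_history, config.convergence_tol,
                             config.patience):
                break

        rho_i, rho_a = current_rho()
        b_i, b_a = betas(rho_i, rho_a)
        rho = CodeEmbedding(rho_icd=rho_i.data.copy(),
                            rho_atc=rho_a.data.copy())
        return ETMResults(
            model=self,
            encoder=encoder,
            alpha_icd=alpha_icd.data.copy(),
            alpha_atc=alpha_atc.data.copy(),
            rho=rho,
            beta_icd=b_i.data.copy(),
            beta_atc=b_a.data.copy(),
            trace=trace,
            config=config,
        )


# ------------------------------------------------------------------ results
@dataclass
class ETMResults:
    """Fitted parameters, traces and post-estimation utilities."""

    model: MultimodalETM
    encoder: Encoder
    alpha_icd: np.ndarray
    alpha_atc: np.ndarray
    rho: CodeEmbedding
    beta_icd: np.ndarray        # (K, V_icd) simplex rows
    beta_atc: np.ndarray        # (K, V_atc)
    trace: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None

    @property
    def n_topics(self) -> int:
        return self.beta_icd.shape[0]

    # -------------------------------------------------------------- inference
    def transform(self, counts_icd: np.ndarray,
                  counts_atc: np.ndarray) -> np.ndarray:
        """Expected topic mixture softmax(mu) for new count vectors."""
        mu, _ = self.encoder.encode_mean(counts_icd, counts_atc)
        return _softmax(mu, axis=-1)

    def transform_corpus(self, corpus: EHRCorpus,
                         batch_size: int = 2048) -> np.ndarray:
        thetas = []
        for s in range(0, corpus.n_patients, batch_size):
            xi = np.asarray(corpus.icd_counts[s:s + batch_size].todense(),
                            dtype=float)
            xa = np.asarray(corpus.atc_counts[s:s + batch_size].todense(),
                            dtype=float)
            thetas.append(self.transform(xi, xa))
        return np.vstack(thetas)

    def top_codes(self, modality: str, k: int, n: int = 5) -> list[str]:
        beta, vocab = ((self.beta_icd, self.model.corpus.vocab_icd)
                       if modality == "icd"
                       else (self.beta_atc, self.model.corpus.vocab_atc))
        order = np.lexsort((np.arange(len(vocab)), -beta[k]))
        return [vocab[i] for i in order[:n]]

    # ---------------------------------------------------------------- summary
    def summary(self) -> str:
        c = self.model.corpus
        lines = [
            "Multimodal embedded topic model",
            "=" * 46,
            f"patients                 {c.n_patients}",
            f"vocabulary (ICD, ATC)    {c.v_icd}, {c.v_atc}",
            f"topics K                 {self.n_topics}",
            f"embedding dim L          {self.model.L}",
            f"epochs run               {len(self.trace)}",
        ]
        if self.trace:
            last = self.trace[-1]
            lines += [
                f"final train ELBO/doc     {last['train_elbo']:.4f}",
                f"final valid ELBO/doc     {last['val_elbo']:.4f}",
            ]
        lines.append("-" * 46)
        for k in range(min(self.n_topics, 10)):
            lines.append(
                f"topic {k:2d}  icd: {', '.join(self.top_codes('icd', k, 3))}"
                f"  |  atc: {', '.join(self.top_codes('atc', k, 3))}")
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def save(self, prefix) -> None:
        """Write arrays to ``<prefix>.npz`` and a manifest to ``<prefix>.json``."""
        import hashlib
        enc = self.encoder
        arrays = {
            "alpha_icd": self.alpha_icd, "alpha_atc": self.alpha_atc,
            "rho_icd": self.rho.rho_icd, "rho_atc": self.rho.rho_atc,
            "beta_icd": self.beta_icd, "beta_atc": self.beta_atc,
        }
        for name in ("W_icd", "b_icd", "W_atc", "b_atc", "W_h", "b_h",
                     "W_mu", "b_mu", "W_ls", "b_ls"):
            arrays["enc_" + name] = getattr(enc, name).data
        np.savez(str(prefix) + ".npz", **arrays)
        vocab_hash = hashlib.sha256(
            ("\n".join(self.model.corpus.vocab_icd) + "\n|\n" +
             "\n".join(self.model.corpus.vocab_atc)).encode()).hexdigest()
        manifest = {
            "K": self.n_topics, "L": self.model.L,
            "v_icd": self.model.corpus.v_icd,
            "v_atc": self.model.corpus.v_atc,
            "vocab_sha256": vocab_hash,
            "config": asdict(self.config) if self.config else None,
            "epochs": len(self.trace),
        }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, prefix, corpus: EHRCorpus) -> "ETMResults":
        with open(str(prefix) + ".json") as fh:
            manifest = json.load(fh)
        data = np.load(str(prefix) + ".npz")
        model = MultimodalETM(corpus, n_topics=manifest["K"],
                              embedding_dim=manifest["L"])
        enc = Encoder(corpus.v_icd, corpus.v_atc, manifest["K"])
        for name in ("W_icd", "b_icd", "W_atc", "b_atc", "W_h", "b_h",
                     "W_mu", "b_mu", "W_ls", "b_ls"):
            getattr(enc, name).data = data["enc_" + name]
        cfg = TrainConfig(**manifest["config"]) if manifest["config"] else None
        return cls(model=model, encoder=enc,
                   alpha_icd=data["alpha_icd"], alpha_atc=data["alpha_atc"],
                   rho=CodeEmbedding(data["rho_icd"], data["rho_atc"]),
                   beta_icd=data["beta_icd"], beta_atc=data["beta_atc"],
                   trace=[], config=cfg)
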