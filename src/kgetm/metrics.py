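"""Topic quality and held-out predictive metrics.

Topic coherence (TC) is the mean normalised pointwise mutual information
(NPMI) of the top-s codes of each topic, with co-occurrence probabilities
estimated as document frequencies (presence/absence) over a reference
corpus.  Topic diversity (TD) is the fraction of unique codes among all
topics' top-r codes; topic quality is TQ = TC x TD, reported per modality
and averaged across the two modalities.

Document completion scores a model's predictive power: each held-out record
is split into halves, the posterior-mean mixture is inferred from the first
half and the mean negative log-likelihood per token of the second half is
reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .corpus import EHRCorpus

log = logging.getLogger(__name__)

__all__ = ["MetricsConfig", "TopicQualityReport", "topic_coherence",
           "topic_diversity", "topic_quality", "document_completion_nll",
           "top_codes"]

_EPS = 1e-12


@dataclass
class MetricsConfig:
    s: int = 3        # top codes per topic for coherence
    r: int = 3        # top codes per topic for diversity

    def __post_init__(self):
        if self.s < 1 or self.r < 1:
            raise ValueError("s and r must be >= 1")


@dataclass
class TopicQualityReport:
    tc_icd: float
    tc_atc: float
    td_icd: float
    td_atc: float

    @property
    def tq_icd(self) -> float:
        return self.tc_icd * self.td_icd

    @property
    def tq_atc(self) -> float:
        return self.tc_atc * self.td_atc

    @property
    def tq_average(self) -> float:
        return 0.5 * (self.tq_icd + self.tq_atc)

    def as_dict(self) -> dict:
        return {
            "tc_icd": self.tc_icd, "tc_atc": self.tc_atc,
            "td_icd": self.td_icd, "td_atc": self.td_atc,
            "tq_icd": self.tq_icd, "tq_atc": self.tq_atc,
            "tq_average": self.tq_average,
        }

    def write(self, json_path=None, tsv_path=None) -> None:
        if json_path:
            with open(json_path, "w") as fh:
                json.dump(self.as_dict(), fh, indent=2)
        if tsv_path:
            with open(tsv_path, "w") as fh:
                fh.write("metric\tmodality\tvalue\n")
                for name, value in self.as_dict().items():
                    metric, _, modality = name.partition("_")
                    fh.write(f"{metric}\t{modality}\t{value:.6f}\n")


def top_codes(beta_row: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest entries, ties broken by vocabulary index."""
    order = np.lexsort((np.arange(beta_row.size), -beta_row))
    return order[:k]


def _doc_presence(docs: sp.csr_matrix) -> sp.csr_matrix:
    presence = docs.copy().tocsr()
    presence.data = np.ones_like(presence.data)
    return presence


def npmi(p_i: float, p_j: float, p_ij: float) -> float:
    """Normalised PMI in [-1, 1]; defined as -1 in the zero-co-occurrence
    limit and +1 when the pair always co-occurs with its marginals."""
    if p_ij <= 0.0:
        return -1.0
    denom = -np.log(p_ij)
    if denom <= 0.0:      # p_ij == 1: codes co-occur in every document
        return 1.0
    return float(np.log(p_ij / (p_i * p_j)) / denom)


def topic_coherence(beta_t: np.ndarray, docs: sp.csr_matrix, s: int = 3) -> float:
    """Mean NPMI over the unordered top-s code pairs of each topic.

    ``docs`` is the reference corpus restricted to the same modality block
    as ``beta_t`` (documents x V_t counts; presence/absence is used).
    """
    K, V = beta_t.shape
    if s > V:
        raise ValueError(f"s={s} exceeds vocabulary size {V}")
    presence = _doc_presence(sp.csr_matrix(docs))
    n_docs = presence.shape[0]
    if n_docs == 0:
        raise ValueError("empty reference corpus")
    p_marg = np.asarray(presence.sum(axis=0)).ravel() / n_docs
    cooc = (presence.T @ presence) / n_docs        # joint document frequency
    cooc = np.asarray(cooc.todense())
    total = 0.0
    n_pairs = s * (s - 1) // 2
    for k in range(K):
        top = top_codes(beta_t[k], s)
        acc = 0.0
        for ii in range(s):
            for jj in range(ii + 1, s):
                i, j = top[ii], top[jj]
                acc += npmi(p_marg[i], p_marg[j], cooc[i, j])
        total += acc / n_pairs
    return total / K


def topic_diversity(beta_t: np.ndarray, r: int = 3) -> float:
    """Fraction of unique codes among all topics' top-r code lists."""
    K, V = beta_t.shape
    if r > V:
        raise ValueError(f"r={r} exceeds vocabulary size {V}")
    union = set()
    for k in range(K):
        union.update(top_codes(beta_t[k], r).tolist())
    return len(union) / (K * r)


def topic_quality(beta_icd: np.ndarray, beta_atc: np.ndarray,
                  corpus: EHRCorpus,
                  config: MetricsConfig | None = None) -> TopicQualityReport:
    """Per-modality TC, TD and TQ = TC x TD, plus the cross-modality average."""
    config = config or MetricsConfig()
    return TopicQualityReport(
        tc_icd=topic_coherence(beta_icd, corpus.icd_counts, config.s),
        tc_atc=topic_coherence(beta_atc, corpus.atc_counts, config.s),
        td_icd=topic_diversity(beta_icd, config.r),
        td_atc=topic_diversity(beta_atc, config.r),
    )


def _split_counts(row: np.ndarray, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Split one count vector's token multiset into two halves uniformly at
    random; the first half receives ceil(n/2) tokens."""
    tokens = np.repeat(np.arange(row.size), row.astype(int))
    rng.shuffle(tokens)
    n_first = int(np.ceil(tokens.size / 2))
    a = np.bincount(tokens[:n_first], minlength=row.size).astype(float)
    b = np.bincount(tokens[n_first:], minlength=row.size).astype(float)
    return a, b


def document_completion_nll(results, test_corpus: EHRCorpus,
                            split_seed: int = 0) -> float:
    """Mean held-out NLL per token under the completion protocol.

    Tokens of each test record are split at random into halves; the expected
    mixture softmax(mu) is inferred from the first half and the second half
    is scored under the mixture distribution beta theta-bar.  Records with
    fewer than two tokens are excluded (logged).
    """
    rng = np.random.default_rng(split_seed)
    v_icd = test_corpus.v_icd
    total_nll = 0.0
    total_tokens = 0
    skipped = 0
    X = test_corpus.dense()
    for p in range(test_corpus.n_patients):
        row = X[p]
        if row.sum() < 2:
            skipped += 1
            continue
        half_a, half_b = _split_counts(row, rng)
        if half_a.sum() == 0 or half_b.sum() == 0:
            skipped += 1
            continue
        theta = results.transform(half_a[None, :v_icd], half_a[None, v_icd:])[0]
        mix_icd = np.maximum(theta @ results.beta_icd, _EPS)
        mix_atc = np.maximum(theta @ results.beta_atc, _EPS)
        nll = -(half_b[:v_icd] @ np.log(mix_icd)
                + half_b[v_icd:] @ np.log(mix_atc))
        total_nll += float(nll)
        total_tokens += int(half_b.sum())
    if skipped:
        log.info("document completion: skipped %d records with <2 usable "
                 "tokens", skipped)
    if total_tokens == 0:
        raise ValueError("no scorable held-out tokens")
    return total_nll / total_tokens
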