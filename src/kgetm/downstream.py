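"""Downstream evaluation tasks on a fitted topic model.

* Drug imputation: rank a patient's ATC codes from the ICD portion of the
  record alone, via the expected mixture of the encoder; patient-wise
  precision/recall/F1 at k and drug-wise top-N precision binned by training
  frequency, plus frequency and K-nearest-neighbour baseline imputers.
* Phenotype classification: L1-penalised logistic regression (LASSO) on
  topic-mixture features with validation-selected penalty, scored by AUROC
  over repeated random splits.
* Case study: graph distances between imputed drugs and observed diagnoses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .corpus import EHRCorpus
from .graph import KnowledgeGraph, collapse_last_level, shortest_distance, UNREACHABLE
from .metrics import top_codes

log = logging.getLogger(__name__)

__all__ = ["impute_drugs", "patient_wise_metrics", "drug_wise_precision",
           "drug_wise_weighted_recall", "baseline_imputers",
           "phenotype_classification", "PhenotypeEvalResult",
           "case_study_distances"]


# -------------------------------------------------------------- imputation
def impute_drugs(results, icd_counts: np.ndarray) -> np.ndarray:
    """Score every ATC code for patients given only their ICD counts.

    Encodes the record with the ATC block zeroed, takes the expected mixture
    theta = softmax(mu), and returns theta @ beta_atc: a proper probability
    distribution over the ATC vocabulary per patient.
    """
    icd_counts = np.atleast_2d(np.asarray(icd_counts, dtype=float))
    if np.any(icd_counts.sum(axis=1) == 0):
        raise ValueError("imputation requires at least one ICD token")
    atc_zero = np.zeros((icd_counts.shape[0], results.beta_atc.shape[1]))
    theta = results.transform(icd_counts, atc_zero)
    return theta @ results.beta_atc


def patient_wise_metrics(scores: np.ndarray, truth_sets: list[set[int]],
                         k: int = 5, min_truth: int = 5
                         ) -> dict[str, float]:
    """Macro-averaged precision/recall/F1 of the top-k predictions.

    Patients with fewer than ``min_truth`` true ATC codes are excluded, as
    top-k metrics are uninformative on near-empty drug profiles.
    """
    scores = np.atleast_2d(scores)
    precs, recs, f1s = [], [], []
    for p, truth in enumerate(truth_sets):
        if len(truth) < min_truth:
            continue
        top = set(top_codes(scores[p], k).tolist())
        hits = len(top & truth)
        prec = hits / k
        rec = hits / len(truth)
        f1 = 0.0 if hits == 0 else 2 * prec * rec / (prec + rec)
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    if not precs:
        raise ValueError(f"all patients have fewer than {min_truth} true codes")
    return {f"precision@{k}": float(np.mean(precs)),
            f"recall@{k}": float(np.mean(recs)),
            f"f1@{k}": float(np.mean(f1s)),
            "n_patients": len(precs)}


def _frequency_bins(train_freq: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Equal-count bins of code indices by ascending training frequency.

    Ties broken toward the lower bin via stable rank order; bin 0 holds the
    rarest codes, the last bin the most frequent.
    """
    order = np.lexsort((np.arange(train_freq.size), train_freq))
    return [chunk for chunk in np.array_split(order, n_bins)]


def drug_wise_precision(scores: np.ndarray, truth_sets: list[set[int]],
                        train_freq: np.ndarray, n_bins: int = 5,
                        top_n: int = 30) -> list[float]:
    """Top-N precision per training-frequency quantile bin.

    For each code: TP = patients where the code is both in their top-N
    predictions and in their truth set; PP = patients where it is in their
    top-N.  Bin precision pools codes: sum TP / sum PP; NaN when no code in
    the bin is ever predicted.
    """
    scores = np.atleast_2d(scores)
    V = scores.shape[1]
    if top_n > V:
        raise ValueError(f"top_n={top_n} exceeds ATC vocabulary size {V}")
    tp = np.zeros(V)
    pp = np.zeros(V)
    for p, truth in enumerate(truth_sets):
        top = top_codes(scores[p], top_n)
        pp[top] += 1
        for v in top:
            if int(v) in truth:
                tp[v] += 1
    out = []
    for bin_codes in _frequency_bins(np.asarray(train_freq, float), n_bins):
        denom = pp[bin_codes].sum()
        out.append(float(tp[bin_codes].sum() / denom) if denom > 0
                   else float("nan"))
    return out


def drug_wise_weighted_recall(scores: np.ndarray, truth_sets: list[set[int]],
                              train_freq: np.ndarray, n_bins: int = 5,
                              top_n: int = 30) -> list[float]:
    """Secondary drug-wise view: per-code top-N recall averaged within each
    frequency bin, weighted by training frequency."""
    scores = np.atleast_2d(scores)
    V = scores.shape[1]
    hits = np.zeros(V)
    occur = np.zeros(V)
    for p, truth in enumerate(truth_sets):
        top = set(top_codes(scores[p], top_n).tolist())
        for v in truth:
            occur[v] += 1
            if v in top:
                hits[v] += 1
    train_freq = np.asarray(train_freq, dtype=float)
    out = []
    for bin_codes in _frequency_bins(train_freq, n_bins):
        mask = occur[bin_codes] > 0
        codes = bin_codes[mask]
        if codes.size == 0:
            out.append(float("nan"))
            continue
        recall = hits[codes] / occur[codes]
        w = train_freq[codes]
        w = w / w.sum() if w.sum() > 0 else np.full(codes.size, 1 / codes.size)
        out.append(float((recall * w).sum()))
    return out


def baseline_imputers(train_corpus: EHRCorpus, test_icd: np.ndarray,
                      mode: str = "frequency", n_neighbors: int = 100,
                      metric: str = "manhattan") -> np.ndarray:
    """Reference imputers: training-frequency ranking or K nearest neighbours.

    ``frequency`` scores every patient by the training ATC marginal counts;
    ``knn`` finds the nearest training patients by ICD count vector and
    averages their (normalised) ATC counts.
    """
    test_icd = np.atleast_2d(np.asarray(test_icd, dtype=float))
    n_test = test_icd.shape[0]
    atc_train = np.asarray(train_corpus.atc_counts.todense(), dtype=float)
    if mode == "frequency":
        marginal = atc_train.sum(axis=0)
        marginal = marginal / max(marginal.sum(), 1.0)
        return np.tile(marginal, (n_test, 1))
    if mode == "knn":
        if n_neighbors > train_corpus.n_patients:
            raise ValueError(
                f"n_neighbors={n_neighbors} exceeds training set size "
                f"{train_corpus.n_patients}")
        icd_train = np.asarray(train_corpus.icd_counts.todense(), dtype=float)
        nn = NearestNeighbors(n_neighbors=n_neighbors, metric=metric)
        nn.fit(icd_train)
        _, idx = nn.kneighbors(test_icd)
        scores = atc_train[idx].mean(axis=1)
        tot = scores.sum(axis=1, keepdims=True)
        return scores / np.maximum(tot, 1e-300)
    raise ValueError(f"unknown baseline mode {mode!r}")


def select_knn_params(train_corpus: EHRCorpus, valid_corpus: EHRCorpus,
                      k_grid=(100, 200, 500, 1000, 5000),
                      metrics=("manhattan", "minkowski"),
                      eval_k: int = 5) -> tuple[int, str]:
    """Choose the KNN neighbour count and distance on validation prec@k."""
    valid_icd = np.asarray(valid_corpus.icd_counts.todense(), dtype=float)
    truth = [set(np.flatnonzero(row).tolist())
             for row in np.asarray(valid_corpus.atc_counts.todense())]
    keep = [i for i in range(valid_corpus.n_patients)
            if valid_icd[i].sum() > 0]
    best = (-1.0, k_grid[0], metrics[0])
    for k in k_grid:
        if k > train_corpus.n_patients:
            continue
        for metric in metrics:
            scores = baseline_imputers(train_corpus, valid_icd[keep],
                                       mode="knn", n_neighbors=k, metric=metric)
            try:
                m = patient_wise_metrics(scores, [truth[i] for i in keep],
                                         k=eval_k)
            except ValueError:
                continue
            if m[f"precision@{eval_k}"] > best[0]:
                best = (m[f"precision@{eval_k}"], k, metric)
    return best[1], best[2]


# ----------------------------------------------------------- classification
@dataclass
class PhenotypeEvalResult:
    auroc_mean: float
    auroc_sd: float
    aurocs: list[float] = field(default_factory=list)
    chosen_lambdas: list[float] = field(default_factory=list)
    n_repeats_used: int = 0


def _lasso_auroc(theta_train, y_train, theta_eval, y_eval, lam: float) -> float:
    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0,
                             C=1.0 / lam, max_iter=2000)
    clf.fit(theta_train, y_train)
    return float(roc_auc_score(y_eval, clf.decision_function(theta_eval)))


def phenotype_classification(theta: np.ndarray, labels: np.ndarray,
                             lambda_grid=None, n_repeats: int = 10,
                             split=(0.72, 0.08, 0.20), seed: int = 0
                             ) -> PhenotypeEvalResult:
    """LASSO phenotype classifier on topic-mixture features.

    For each of ``n_repeats`` random splits: fit at every penalty in
    ``lambda_grid`` (default 8 log-spaced values in [0.01, 1]), choose the
    penalty by validation AUROC, report the test AUROC.  Repeats whose
    splits are single-class are skipped with a warning.
    """
    if lambda_grid is None:
        lambda_grid = np.logspace(np.log10(0.01), np.log10(1.0), 8)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n = theta.shape[0]
    rng = np.random.default_rng(seed)
    aurocs, lambdas = [], []
    for _ in range(n_repeats):
        order = rng.permutation(n)
        n_tr = int(round(split[0] * n))
        n_va = int(round(split[1] * n))
        tr, va, te = (order[:n_tr], order[n_tr:n_tr + n_va],
                      order[n_tr + n_va:])
        if any(len(np.unique(labels[idx])) < 2 for idx in (tr, va, te)):
            log.warning("phenotype eval: skipping repeat with single-class split")
            continue
        best_lam, best_val = None, -np.inf
        for lam in lambda_grid:
            val = _lasso_auroc(theta[tr], labels[tr], theta[va], labels[va], lam)
            if val > best_val:
                best_val, best_lam = val, lam
        aurocs.append(_lasso_auroc(theta[tr], labels[tr],
                                   theta[te], labels[te], best_lam))
        lambdas.append(float(best_lam))
    if not aurocs:
        raise ValueError("every repeat had a single-class split")
    return PhenotypeEvalResult(
        auroc_mean=float(np.mean(aurocs)),
        auroc_sd=float(np.std(aurocs)),
        aurocs=aurocs,
        chosen_lambdas=lambdas,
        n_repeats_used=len(aurocs),
    )


# ------------------------------------------------------------- case study
def case_study_distances(results, graph: KnowledgeGraph,
                         icd_codes: list[str], top_m: int = 10,
                         collapse: bool = True) -> dict:
    """Graph distances from top imputed drugs to a patient's diagnoses.

    For each of the top-M imputed ATC codes, reports the minimum shortest-path
    distance to any observed ICD code (codes optionally collapsed by one
    taxonomy level first).  The reference value is the same minimum distance
    averaged over *all* ATC codes in the vocabulary, so an informative
    imputation should sit well below it.  Unreachable pairs are reported with
    an infinite sentinel and excluded from the mean (with a warning).
    """
    vocab_icd = results.model.corpus.vocab_icd
    vocab_atc = results.model.corpus.vocab_atc
    counts = np.zeros(len(vocab_icd))
    for code in icd_codes:
        if code not in vocab_icd:
            raise KeyError(f"observed ICD code {code!r} not in vocabulary")
        counts[vocab_icd.index(code)] += 1.0
    scores = impute_drugs(results, counts[None, :])[0]
    top = top_codes(scores, top_m)

    def resolve(code: str, modality: str) -> str:
        if not collapse:
            return code
        collapsed = collapse_last_level(code, modality)
        return collapsed if collapsed in graph.node_index else code

    observed = [resolve(c, "icd") for c in icd_codes]

    def min_distance(atc_code: str) -> float:
        node = resolve(atc_code, "atc")
        return min(shortest_distance(graph, node, o) for o in observed)

    imputed = []
    for rank, v in enumerate(top, start=1):
        code = vocab_atc[int(v)]
        imputed.append({"rank": rank, "atc_code": code,
                        "score": float(scores[v]),
                        "min_distance": min_distance(code)})
    all_d = np.array([min_distance(c) for c in vocab_atc])
    reachable = all_d[np.isfinite(all_d)]
    if reachable.size < all_d.size:
        log.warning("case study: %d ATC codes unreachable from the observed "
                    "ICD codes; excluded from the mean",
                    all_d.size - reachable.size)
    return {
        "imputed": imputed,
        "mean_distance_all_atc": float(reachable.mean()) if reachable.size
        else UNREACHABLE,
    }
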