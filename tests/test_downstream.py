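"""Drug imputation, baselines, classification and the case study."""

import numpy as np
import pytest

from kgetm.downstream import (baseline_imputers, case_study_distances,
                              drug_wise_precision, drug_wise_weighted_recall,
                              impute_drugs, patient_wise_metrics,
                              phenotype_classification, select_knn_params)
from kgetm.metrics import top_codes


# ------------------------------------------------------- patient-wise oracle
def oracle_patient_metrics(scores, truth_sets, k, min_truth):
    precs, recs, f1s = [], [], []
    for p, truth in enumerate(truth_sets):
        if len(truth) < min_truth:
            continue
        row = scores[p]
        top = sorted(range(len(row)), key=lambda v: (-row[v], v))[:k]
        hits = sum(1 for v in top if v in truth)
        prec, rec = hits / k, hits / len(truth)
        f1s.append(0.0 if hits == 0 else 2 * prec * rec / (prec + rec))
        precs.append(prec)
        recs.append(rec)
    return np.mean(precs), np.mean(recs), np.mean(f1s)


def test_patient_wise_hand_case():
    # one patient, k=5, 8 true codes, 2 hits: prec 0.4, recall 0.25,
    # F1 = 2*0.4*0.25/0.65 = 4/13
    scores = np.zeros((1, 20))
    scores[0, [0, 1, 2, 3, 4]] = [5, 4, 3, 2, 1]       # predicted top-5
    truth = [set([0, 1] + list(range(10, 16)))]         # hits: 0, 1
    m = patient_wise_metrics(scores, truth, k=5, min_truth=5)
    assert m["precision@5"] == pytest.approx(0.4)
    assert m["recall@5"] == pytest.approx(0.25)
    assert m["f1@5"] == pytest.approx(4 / 13)
    assert m["n_patients"] == 1


def test_patient_wise_matches_oracle_on_random_fixture():
    rng = np.random.default_rng(0)
    scores = rng.random((10, 15))
    truth = [set(rng.choice(15, size=rng.integers(2, 10),
                            replace=False).tolist()) for _ in range(10)]
    m = patient_wise_metrics(scores, truth, k=5, min_truth=5)
    prec, rec, f1 = oracle_patient_metrics(scores, truth, 5, 5)
    assert m["precision@5"] == pytest.approx(prec)
    assert m["recall@5"] == pytest.approx(rec)
    assert m["f1@5"] == pytest.approx(f1)


def test_patient_wise_filters_thin_profiles():
    scores = np.ones((2, 8))
    truth = [set([0]), set(range(6))]
    m = patient_wise_metrics(scores, truth, k=3, min_truth=5)
    assert m["n_patients"] == 1
    with pytest.raises(ValueError, match="fewer than"):
        patient_wise_metrics(scores, [set([0]), set([1])], k=3, min_truth=5)


# -------------------------------------------------------- drug-wise binning
def oracle_drug_precision(scores, truth_sets, train_freq, n_bins, top_n):
    V = scores.shape[1]
    tp = np.zeros(V)
    pp = np.zeros(V)
    for p, truth in enumerate(truth_sets):
        row = scores[p]
        top = sorted(range(V), key=lambda v: (-row[v], v))[:top_n]
        for v in top:
            pp[v] += 1
            if v in truth:
                tp[v] += 1
    order = sorted(range(V), key=lambda v: (train_freq[v], v))
    bins = np.array_split(np.array(order), n_bins)
    out = []
    for b in bins:
        out.append(tp[b].sum() / pp[b].sum() if pp[b].sum() else np.nan)
    return out


def test_drug_wise_precision_matches_oracle():
    rng = np.random.default_rng(1)
    scores = rng.random((8, 15))
    truth = [set(rng.choice(15, size=6, replace=False).tolist())
             for _ in range(8)]
    freq = rng.integers(0, 50, size=15).astype(float)
    ours = drug_wise_precision(scores, truth, freq, n_bins=5, top_n=6)
    expected = oracle_drug_precision(scores, truth, freq, 5, 6)
    assert np.allclose(ours, expected, equal_nan=True)
    with pytest.raises(ValueError):
        drug_wise_precision(scores, truth, freq, top_n=16)


def test_drug_wise_perfect_predictor_scores_one():
    """If every patient's top-N equals their truth set, precision is 1."""
    V, N = 10, 3
    truth = [set([0, 1, 2]), set([3, 4, 5])]
    scores = np.zeros((2, V))
    for p, t in enumerate(truth):
        scores[p, list(t)] = 1.0
    out = drug_wise_precision(scores, truth, np.arange(V, dtype=float),
                              n_bins=2, top_n=N)
    for v in out:
        assert np.isnan(v) or v == 1.0
    recall = drug_wise_weighted_recall(scores, truth,
                                       np.arange(V, dtype=float),
                                       n_bins=2, top_n=N)
    for v in recall:
        assert np.isnan(v) or v == 1.0


# ------------------------------------------------------------- baselines
def test_frequency_baseline_is_training_marginal(small_sim):
    corpus, _ = small_sim
    test_icd = np.asarray(corpus.icd_counts[:4].todense(), dtype=float)
    scores = baseline_imputers(corpus, test_icd, mode="frequency")
    marginal = np.asarray(corpus.atc_counts.sum(axis=0)).ravel()
    marginal = marginal / marginal.sum()
    assert scores.shape == (4, corpus.v_atc)
    assert np.allclose(scores, marginal)


def test_knn_baseline_limits_and_validation(small_sim):
    corpus, _ = small_sim
    test_icd = np.asarray(corpus.icd_counts[:3].todense(), dtype=float)
    # with K = n_train every query sees the same neighbourhood: all rows equal
    scores = baseline_imputers(corpus, test_icd, mode="knn",
                               n_neighbors=corpus.n_patients)
    assert np.allclose(scores[0], scores[1]) and np.allclose(scores[1],
                                                             scores[2])
    assert np.allclose(scores.sum(axis=1), 1.0)
    with pytest.raises(ValueError, match="exceeds"):
        baseline_imputers(corpus, test_icd, mode="knn",
                          n_neighbors=corpus.n_patients + 1)
    with pytest.raises(ValueError, match="unknown baseline"):
        baseline_imputers(corpus, test_icd, mode="oracle")


def test_select_knn_params_returns_grid_member(small_sim):
    corpus, _ = small_sim
    train = corpus.subset(np.arange(0, 200))
    valid = corpus.subset(np.arange(200, 300))
    k, metric = select_knn_params(train, valid, k_grid=(10, 50),
                                  metrics=("manhattan",))
    assert k in (10, 50)
    assert metric == "manhattan"


# ------------------------------------------------------------- imputation
def test_impute_drugs_returns_distribution(tiny_results, small_sim):
    corpus, _ = small_sim
    test_icd = np.asarray(corpus.icd_counts[:6].todense(), dtype=float)
    scores = impute_drugs(tiny_results, test_icd)
    assert scores.shape == (6, corpus.v_atc)
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-8)
    assert np.all(scores >= 0)
    with pytest.raises(ValueError, match="ICD token"):
        impute_drugs(tiny_results, np.zeros((1, corpus.v_icd)))


# --------------------------------------------------------- classification
def test_phenotype_classification_separable_features():
    rng = np.random.default_rng(0)
    n = 400
    y = rng.integers(0, 2, size=n)
    theta = rng.random((n, 4)) * 0.1
    theta[:, 0] += y            # first feature separates the classes
    res = phenotype_classification(theta, y, n_repeats=3, seed=0)
    assert res.auroc_mean > 0.95
    assert res.n_repeats_used == 3
    assert all(0.01 <= lam <= 1.0 for lam in res.chosen_lambdas)


def test_phenotype_classification_validates_labels():
    theta = np.random.default_rng(0).random((20, 3))
    with pytest.raises(ValueError, match="binary"):
        phenotype_classification(theta, np.arange(20), n_repeats=1)


# --------------------------------------------------------------- case study
def test_case_study_distances_structure(tiny_results, small_sim):
    corpus, truth = small_sim
    graph = truth.merged_graph(augment=False)
    icd_codes = [corpus.vocab_icd[0], corpus.vocab_icd[1]]
    report = case_study_distances(tiny_results, graph, icd_codes, top_m=4)
    assert len(report["imputed"]) == 4
    ranks = [item["rank"] for item in report["imputed"]]
    assert ranks == [1, 2, 3, 4]
    for item in report["imputed"]:
        assert item["min_distance"] >= 1
        assert np.isfinite(item["min_distance"])
    assert report["mean_distance_all_atc"] > 0
    with pytest.raises(KeyError):
        case_study_distances(tiny_results, graph, ["999"], top_m=2)


def test_case_study_top_scores_are_sorted(tiny_results, small_sim):
    corpus, truth = small_sim
    graph = truth.merged_graph(augment=False)
    report = case_study_distances(tiny_results, graph,
                                  [corpus.vocab_icd[3]], top_m=5)
    scores = [item["score"] for item in report["imputed"]]
    assert scores == sorted(scores, reverse=True)
    predicted = {item["atc_code"] for item in report["imputed"]}
    row = np.zeros(corpus.v_icd)
    row[3] = 1.0
    expected = top_codes(impute_drugs(tiny_results, row[None])[0], 5)
    assert predicted == {corpus.vocab_atc[int(v)] for v in expected}
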