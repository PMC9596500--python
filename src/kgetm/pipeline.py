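"""End-to-end pipeline stages over an output directory.

Stages (in order): simulate | build-graph -> pretrain -> train -> evaluate ->
impute -> classify -> distances.  Every stage reads its inputs from the
directory, writes its artifacts plus a JSON manifest, and can be rerun
independently; a missing upstream artifact raises an error naming the stage
that produces it.  All randomness flows from one top-level seed expanded
into fixed per-stage offsets recorded in the manifests.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .corpus import EHRCorpus, read_corpus, write_corpus
from .downstream import (baseline_imputers, case_study_distances,
                         drug_wise_precision, drug_wise_weighted_recall,
                         impute_drugs, patient_wise_metrics,
                         phenotype_classification)
from .gat import GATConfig
from .graph import (augment_with_ancestors, load_hierarchy,
                    merge_knowledge_graph)
from .io import (RunManifest, read_cross_links, read_labels, write_cross_links,
                 write_hierarchy, write_labels)
from .metrics import MetricsConfig, document_completion_nll, topic_quality
from .model import ETMResults, MultimodalETM, TrainConfig
from .node2vec import node2vec_embedding, read_embedding, write_embedding
from .simulate import (SimulationConfig, generate_corpus,
                       generate_phenotype_labels)

__all__ = ["Pipeline", "run_pipeline"]

# fixed per-stage seed offsets (top seed + offset, kept below 2**31)
_STAGE_SEED = {"simulate": 11, "pretrain": 23, "train": 37, "evaluate": 53,
               "impute": 71, "classify": 89, "split": 97}


class MissingArtifact(FileNotFoundError):
    pass


class Pipeline:
    def __init__(self, out_dir, seed: int = 0, config: dict | None = None):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed) % (2 ** 30)
        self.config = config or {}

    # ------------------------------------------------------------- utilities
    def _path(self, name: str) -> Path:
        return self.out / name

    def _require(self, name: str, produced_by: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise MissingArtifact(
                f"missing artifact {name!r}: run the {produced_by!r} stage first")
        return p

    def _stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED[stage]) % (2 ** 31)

    def _manifest(self, stage: str, config: dict) -> RunManifest:
        return RunManifest(stage=stage, seed=self._stage_seed(stage),
                           config=config, version=__version__)

    def load_corpus(self) -> EHRCorpus:
        return read_corpus(self._require("corpus.mtx", "simulate"),
                           self._require("vocab_icd.tsv", "simulate"),
                           self._require("vocab_atc.tsv", "simulate"))

    def splits(self, corpus: EHRCorpus):
        """Deterministic train/validation/test split shared by all stages."""
        fractions = tuple(self.config.get("split", (0.6, 0.3, 0.1)))
        return corpus.split(fractions, seed=self._stage_seed("split"))

    # ---------------------------------------------------------------- stages
    def simulate(self, **overrides) -> None:
        t0 = time.time()
        sim_conf = {**self.config.get("simulate", {}), **overrides}
        sim_conf.setdefault("seed", self._stage_seed("simulate"))
        config = SimulationConfig(**sim_conf)
        corpus, truth = generate_corpus(config)
        write_corpus(corpus, self._path("corpus.mtx"),
                     self._path("vocab_icd.tsv"), self._path("vocab_atc.tsv"))
        write_hierarchy(truth.icd_hierarchy, self._path("icd_hierarchy.tsv"))
        write_hierarchy(truth.atc_hierarchy, self._path("atc_hierarchy.tsv"))
        write_cross_links(truth.cross_links, self._path("cross_links.tsv"))
        np.savez(self._path("truth.npz"), beta_icd=truth.beta_icd,
                 beta_atc=truth.beta_atc, theta=truth.theta)
        # one phenotype label per topic at the median-theta threshold
        with open(self._path("labels.tsv"), "w") as fh:
            fh.write("# patient_id\tphenotype\tlabel\n")
            for k in range(config.n_topics):
                labels, _ = generate_phenotype_labels(truth, k)
                for pid, y in zip(corpus.patient_ids, labels):
                    fh.write(f"{pid}\ttopic{k}\t{int(y)}\n")
        m = self._manifest("simulate", sim_conf)
        m.time_stage("simulate", t0)
        m.write(self._path("manifest_simulate.json"))

    def build_graph(self, augment: bool = True):
        icd = load_hierarchy(self._require("icd_hierarchy.tsv", "simulate"),
                             "icd")
        atc = load_hierarchy(self._require("atc_hierarchy.tsv", "simulate"),
                             "atc")
        links = read_cross_links(self._require("cross_links.tsv", "simulate"))
        raw = merge_knowledge_graph(icd, atc, links)
        raw.write_edgelist(self._path("graph_edges.tsv"))
        if augment:
            merged = merge_knowledge_graph(augment_with_ancestors(icd),
                                           augment_with_ancestors(atc), links)
            merged.write_edgelist(self._path("graph_edges_augmented.tsv"))
        else:
            merged = raw
        return merged, raw

    def pretrain(self, dim: int | None = None) -> None:
        t0 = time.time()
        conf = dict(self.config.get("node2vec", {}))
        train_conf = self.config.get("train", {})
        graph, _ = self.build_graph(
            augment=train_conf.get("use_augmentation", True))
        emb = node2vec_embedding(
            graph, dim=dim or self.config.get("embedding_dim", 256),
            seed=self._stage_seed("pretrain"), **conf)
        write_embedding(emb, self._path("rho0.txt"))
        m = self._manifest("pretrain", conf)
        m.time_stage("pretrain", t0)
        m.write(self._path("manifest_pretrain.json"))

    def train(self) -> ETMResults:
        t0 = time.time()
        corpus = self.load_corpus()
        train_corpus, _, _ = self.splits(corpus)
        conf = dict(self.config.get("train", {}))
        config = TrainConfig(**{**conf, "seed": self._stage_seed("train")})
        graph, _ = self.build_graph(augment=config.use_augmentation)
        init = None
        if config.use_node2vec_init:
            init = read_embedding(self._require("rho0.txt", "pretrain"))
        gat_conf = GATConfig(**self.config.get("gat", {}))
        model = MultimodalETM(
            train_corpus,
            n_topics=self.config.get("n_topics", 100),
            embedding_dim=self.config.get("embedding_dim", 256),
            graph=graph, init_embedding=init, gat_config=gat_conf)
        results = model.fit(config)
        results.save(self._path("model"))
        with open(self._path("training_log.tsv"), "w") as fh:
            fh.write("epoch\ttrain_elbo\tval_elbo\tkl\tnll\tseconds\n")
            for r in results.trace:
                fh.write(f"{r['epoch']}\t{r['train_elbo']:.6f}\t"
                         f"{r['val_elbo']:.6f}\t{r['kl']:.6f}\t"
                         f"{r['nll']:.6f}\t{r['seconds']:.3f}\n")
        m = self._manifest("train", conf)
        m.add_input(self._path("corpus.mtx"))
        m.time_stage("train", t0)
        m.write(self._path("manifest_train.json"))
        self._results = results
        return results

    def _load_results(self) -> tuple[ETMResults, EHRCorpus]:
        corpus = self.load_corpus()
        train_corpus, _, _ = self.splits(corpus)
        self._require("model.npz", "train")
        results = ETMResults.load(self._path("model"), train_corpus)
        return results, corpus

    def evaluate(self) -> dict:
        t0 = time.time()
        results, corpus = self._load_results()
        train_corpus, _, test_corpus = self.splits(corpus)
        mc = MetricsConfig(**self.config.get("metrics", {}))
        report = topic_quality(results.beta_icd, results.beta_atc,
                               train_corpus, mc)
        nll = document_completion_nll(results, test_corpus,
                                      split_seed=self._stage_seed("evaluate"))
        out = {**report.as_dict(), "document_completion_nll": nll}
        with open(self._path("metrics.json"), "w") as fh:
            json.dump(out, fh, indent=2)
        report.write(tsv_path=self._path("metrics.tsv"))
        m = self._manifest("evaluate", {})
        m.time_stage("evaluate", t0)
        m.write(self._path("manifest_evaluate.json"))
        return out

    def impute(self, k: int = 5, top_n: int = 30) -> dict:
        t0 = time.time()
        results, corpus = self._load_results()
        train_corpus, _, test_corpus = self.splits(corpus)
        test_icd = np.asarray(test_corpus.icd_counts.todense(), dtype=float)
        keep = np.flatnonzero(test_icd.sum(axis=1) > 0)
        truth = [set(np.flatnonzero(row).tolist()) for row in
                 np.asarray(test_corpus.atc_counts.todense())]
        truth = [truth[i] for i in keep]
        scores = impute_drugs(results, test_icd[keep])
        freq_scores = baseline_imputers(train_corpus, test_icd[keep],
                                        mode="frequency")
        train_freq = np.asarray(train_corpus.atc_counts.sum(axis=0)).ravel()
        out = {
            "model": patient_wise_metrics(scores, truth, k=k),
            "frequency_baseline": patient_wise_metrics(freq_scores, truth, k=k),
            "drug_wise_precision_bins": drug_wise_precision(
                scores, truth, train_freq, top_n=min(top_n,
                                                     test_corpus.v_atc)),
            "drug_wise_weighted_recall_bins": drug_wise_weighted_recall(
                scores, truth, train_freq, top_n=min(top_n,
                                                     test_corpus.v_atc)),
        }
        with open(self._path("imputation_metrics.json"), "w") as fh:
            json.dump(out, fh, indent=2)
        with open(self._path("imputation.tsv"), "w") as fh:
            fh.write("patient_id\trank\tatc_code\tscore\n")
            for row, p in enumerate(keep):
                order = np.argsort(-scores[row])[:k]
                for rank, v in enumerate(order, 1):
                    fh.write(f"{test_corpus.patient_ids[p]}\t{rank}\t"
                             f"{test_corpus.vocab_atc[v]}\t"
                             f"{scores[row, v]:.6g}\n")
        m = self._manifest("impute", {"k": k, "top_n": top_n})
        m.time_stage("impute", t0)
        m.write(self._path("manifest_impute.json"))
        return out

    def classify(self, n_repeats: int = 10) -> dict:
        t0 = time.time()
        results, corpus = self._load_results()
        labels_by_pheno = read_labels(self._require("labels.tsv", "simulate"))
        theta = results.transform_corpus(corpus)
        pid_index = {p: i for i, p in enumerate(corpus.patient_ids)}
        out = {}
        for pheno, by_pid in sorted(labels_by_pheno.items()):
            idx = [pid_index[p] for p in by_pid if p in pid_index]
            y = np.array([by_pid[p] for p in by_pid if p in pid_index])
            res = phenotype_classification(theta[idx], y,
                                           n_repeats=n_repeats,
                                           seed=self._stage_seed("classify"))
            out[pheno] = {"auroc_mean": res.auroc_mean,
                          "auroc_sd": res.auroc_sd,
                          "n_repeats": res.n_repeats_used}
        with open(self._path("classification.tsv"), "w") as fh:
            fh.write("phenotype\tauroc_mean\tauroc_sd\tn_repeats\n")
            for pheno, r in out.items():
                fh.write(f"{pheno}\t{r['auroc_mean']:.4f}\t"
                         f"{r['auroc_sd']:.4f}\t{r['n_repeats']}\n")
        m = self._manifest("classify", {"n_repeats": n_repeats})
        m.time_stage("classify", t0)
        m.write(self._path("manifest_classify.json"))
        return out

    def distances(self, patient: int = 0, top_m: int = 10) -> dict:
        results, corpus = self._load_results()
        _, raw_graph = self.build_graph(augment=True)
        _, _, test_corpus = self.splits(corpus)
        row = np.asarray(
            test_corpus.icd_counts[patient].todense()).ravel()
        icd_codes = [test_corpus.vocab_icd[v] for v in np.flatnonzero(row)]
        report = case_study_distances(results, raw_graph, icd_codes,
                                      top_m=top_m)
        with open(self._path("distances.tsv"), "w") as fh:
            fh.write("patient_id\trank\tatc_code\tscore\tmin_distance\n")
            for item in report["imputed"]:
                fh.write(f"{test_corpus.patient_ids[patient]}\t"
                         f"{item['rank']}\t{item['atc_code']}\t"
                         f"{item['score']:.6g}\t{item['min_distance']}\n")
        return report


def run_pipeline(out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Run every stage in order on synthetic data; returns collected metrics."""
    pipe = Pipeline(out_dir, seed=seed, config=config)
    pipe.simulate()
    pipe.pretrain()
    pipe.train()
    metrics = pipe.evaluate()
    imputation = pipe.impute()
    classification = pipe.classify()
    distances = pipe.distances()
    return {"metrics": metrics, "imputation": imputation,
            "classification": classification, "distances": distances}
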