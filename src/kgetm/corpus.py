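"""Patient x code count corpus.

Each patient's record is a bag of code "tokens": the row of a sparse
count matrix over the concatenated ICD-then-ATC vocabulary.  On disk the
counts travel as MatrixMarket (MTX) with two vocabulary TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = ["EHRCorpus", "read_corpus", "write_corpus"]


@dataclass
class EHRCorpus:
    """Sparse D x (V_icd + V_atc) count matrix with vocabulary metadata.

    Columns 0..V_icd-1 are the ICD block, the rest the ATC block.  Rows with
    zero total count are not admitted (an empty document has no likelihood).
    """

    counts: sp.csr_matrix
    vocab_icd: list[str]
    vocab_atc: list[str]
    patient_ids: list[str] | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[1] != self.v_icd + self.v_atc:
            raise ValueError(
                f"count matrix has {self.counts.shape[1]} columns but "
                f"vocabularies total {self.v_icd + self.v_atc}")
        if len(set(self.vocab_icd)) != self.v_icd:
            raise ValueError("duplicate codes in ICD vocabulary")
        if len(set(self.vocab_atc)) != self.v_atc:
            raise ValueError("duplicate codes in ATC vocabulary")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        row_tot = np.asarray(self.counts.sum(axis=1)).ravel()
        if np.any(row_tot == 0):
            raise ValueError("all-zero patient rows are not admitted; "
                             "drop them before constructing the corpus")
        if self.patient_ids is None:
            self.patient_ids = [f"P{i:06d}" for i in range(self.n_patients)]
        elif len(self.patient_ids) != self.n_patients:
            raise ValueError("patient_ids length mismatch")

    # ------------------------------------------------------------- properties
    @property
    def n_patients(self) -> int:
        return self.counts.shape[0]

    @property
    def v_icd(self) -> int:
        return len(self.vocab_icd)

    @property
    def v_atc(self) -> int:
        return len(self.vocab_atc)

    @property
    def icd_counts(self) -> sp.csr_matrix:
        return self.counts[:, :self.v_icd]

    @property
    def atc_counts(self) -> sp.csr_matrix:
        return self.counts[:, self.v_icd:]

    def tokens_per_modality(self) -> tuple[np.ndarray, np.ndarray]:
        """(N_p,icd, N_p,atc): per-patient token totals per modality."""
        n_icd = np.asarray(self.icd_counts.sum(axis=1)).ravel()
        n_atc = np.asarray(self.atc_counts.sum(axis=1)).ravel()
        return n_icd, n_atc

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=np.float64)

    def subset(self, rows: np.ndarray) -> "EHRCorpus":
        rows = np.asarray(rows)
        return EHRCorpus(self.counts[rows],
                         self.vocab_icd, self.vocab_atc,
                         [self.patient_ids[i] for i in rows])

    def split(self, fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
              seed: int = 0) -> tuple["EHRCorpus", "EHRCorpus", "EHRCorpus"]:
        """Random train/validation/test split by patient."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        rng = np.random.default_rng(seed)
        order = rng.permutation(self.n_patients)
        n_train = int(round(fractions[0] * self.n_patients))
        n_valid = int(round(fractions[1] * self.n_patients))
        return (self.subset(order[:n_train]),
                self.subset(order[n_train:n_train + n_valid]),
                self.subset(order[n_train + n_valid:]))


def _read_vocab(path) -> list[str]:
    vocab = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            vocab.append(line.split("\t")[0])
    return vocab


def read_corpus(mtx_path, vocab_icd_path, vocab_atc_path,
                patient_ids_path=None) -> EHRCorpus:
    """Load an MTX count matrix plus vocabulary TSVs; drop all-zero rows."""
    vocab_icd = _read_vocab(vocab_icd_path)
    vocab_atc = _read_vocab(vocab_atc_path)
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    if counts.shape[1] != len(vocab_icd) + len(vocab_atc):
        raise ValueError(
            f"{mtx_path}: {counts.shape[1]} columns but vocabularies total "
            f"{len(vocab_icd) + len(vocab_atc)}")
    patient_ids = _read_vocab(patient_ids_path) if patient_ids_path else None
    row_tot = np.asarray(counts.sum(axis=1)).ravel()
    keep = row_tot > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d all-zero patient rows", dropped)
        counts = counts[keep]
        if patient_ids is not None:
            patient_ids = [p for p, k in zip(patient_ids, keep) if k]
    return EHRCorpus(counts, vocab_icd, vocab_atc, patient_ids)


def write_corpus(corpus: EHRCorpus, mtx_path, vocab_icd_path,
                 vocab_atc_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(corpus.counts), field="integer")
    for path, vocab in ((vocab_icd_path, corpus.vocab_icd),
                        (vocab_atc_path, corpus.vocab_atc)):
        with open(path, "w") as fh:
            for code in vocab:
                fh.write(code + "\n")
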