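"""On-disk formats, run configuration and manifests.

Formats (all plain text):
  * hierarchy TSV: ``child<TAB>parent`` rows, '#' comments allowed
  * cross-link TSV: ``icd_code<TAB>atc_code``
  * corpus: MatrixMarket counts + one-code-per-line vocabulary TSVs
  * embeddings: word2vec-style text (header ``N L``, then code + floats)
  * graph export: edge-list TSV with an ``edge_type`` third column
  * labels TSV: ``patient_id<TAB>phenotype<TAB>{0,1}``
  * manifest: JSON snapshot of config, input checksums, seeds and timings
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .graph import CrossLinkSet, TaxonomyHierarchy

__all__ = ["RunManifest", "write_hierarchy", "write_cross_links",
           "read_cross_links", "write_labels", "read_labels", "load_config"]


def write_hierarchy(h: TaxonomyHierarchy, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {h.modality} hierarchy: child<TAB>parent\n")
        for child in sorted(h.parent_of):
            fh.write(f"{child}\t{h.parent_of[child]}\n")


def write_cross_links(links: CrossLinkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# icd_code<TAB>atc_code\n")
        for icd_code, atc_code in sorted(links.links):
            fh.write(f"{icd_code}\t{atc_code}\n")


def read_cross_links(path) -> CrossLinkSet:
    links = CrossLinkSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            icd_code, atc_code = line.split("\t")
            links.add(icd_code, atc_code)
    return links


def write_labels(patient_ids: list[str], phenotype: str,
                 labels: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("# patient_id\tphenotype\tlabel\n")
        for pid, y in zip(patient_ids, labels):
            fh.write(f"{pid}\t{phenotype}\t{int(y)}\n")


def read_labels(path) -> dict[str, dict[str, int]]:
    """phenotype -> {patient_id: label}."""
    out: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, pheno, y = line.split("\t")
            out.setdefault(pheno, {})[pid] = int(y)
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every produced artifact."""

    stage: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)      # path -> sha256
    timings: dict = field(default_factory=dict)     # stage -> seconds
    version: str = __version__

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def time_stage(self, name: str, t0: float) -> None:
        self.timings[name] = round(time.time() - t0, 3)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def load_config(path) -> dict:
    """YAML (or JSON) run configuration as a plain dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}
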