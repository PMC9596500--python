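"""Shared fixtures and numerical helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kgetm.autodiff import Tensor
from kgetm.model import MultimodalETM, TrainConfig
from kgetm.simulate import SimulationConfig, generate_corpus


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        f_plus = f(x)
        flat[i] = orig - eps
        f_minus = f(x)
        flat[i] = orig
        gflat[i] = (f_plus - f_minus) / (2 * eps)
    return g


def check_gradient(build_loss, param: Tensor, rtol: float = 1e-4,
                   eps: float = 1e-6) -> float:
    """Max relative error between autodiff and finite-difference gradients.

    ``build_loss()`` must construct a fresh scalar loss Tensor from the
    current value of ``param``.
    """
    param.zero_grad()
    loss = build_loss()
    loss.backward()
    analytic = param.grad.copy()

    def f(_):
        return build_loss().item()

    numeric = finite_difference_grad(f, param.data, eps=eps)
    scale = np.maximum(np.abs(analytic) + np.abs(numeric), 1e-8)
    rel = np.abs(analytic - numeric) / scale
    assert rel.max() < rtol, f"max relative gradient error {rel.max():.2e}"
    return float(rel.max())


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated corpus plus its ground truth (shared, read-only)."""
    corpus, truth = generate_corpus(
        SimulationConfig(n_patients=300, n_topics=3, v_icd=15, v_atc=15,
                         mean_tokens_icd=12, mean_tokens_atc=12, seed=42))
    return corpus, truth


@pytest.fixture(scope="session")
def tiny_results(small_sim):
    """A quickly fitted plain embedded topic model for API-level tests."""
    corpus, _ = small_sim
    model = MultimodalETM(corpus, n_topics=3, embedding_dim=8)
    return model.fit(TrainConfig(batch_size=128, max_epochs=12, seed=0,
                                 use_node2vec_init=False, use_gat=False))
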