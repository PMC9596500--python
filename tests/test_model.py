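"""Topic-model closed forms, encoder behaviour, training and persistence."""

import numpy as np
import pytest

from kgetm.model import (Encoder, ETMResults, MultimodalETM, TrainConfig,
                         compute_topic_distributions, elbo_batch,
                         has_converged, kl_divergence, log_likelihood,
                         sample_mixture)


# ------------------------------------------------------------- closed forms
def test_topic_distributions_match_manual_softmax():
    rho = np.array([[1.0, 0.0, 2.0],
                    [0.0, 1.0, 1.0]])          # L=2, V=3
    alpha = np.array([[1.0], [2.0]])           # L=2, K=1
    beta = compute_topic_distributions(rho, alpha)
    logits = np.array([1.0, 2.0, 4.0])         # alpha_k . rho_v
    expected = np.exp(logits) / np.exp(logits).sum()
    assert beta.shape == (1, 3)
    assert np.allclose(beta[0], expected)
    assert np.allclose(beta.sum(axis=1), 1.0)


def test_topic_distributions_reject_non_finite():
    with pytest.raises(ValueError):
        compute_topic_distributions(np.array([[np.nan]]), np.array([[1.0]]))


def test_kl_divergence_closed_forms():
    # standard normal posterior: zero divergence
    assert kl_divergence(np.zeros(4), np.zeros(4)) == pytest.approx(0.0)
    # K=1, mu=1, sigma=1: KL = mu^2 / 2 = 0.5
    assert kl_divergence(np.array([1.0]), np.array([0.0])) == \
        pytest.approx(0.5)
    # always non-negative
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert kl_divergence(rng.standard_normal(3),
                             rng.standard_normal(3)) >= 0.0


def test_log_likelihood_uniform_beta_is_minus_n_log_v():
    V = 7
    beta = np.full((2, V), 1.0 / V)
    v = np.array([3, 0, 1, 0, 0, 2, 0], dtype=float)   # 6 tokens
    ll = log_likelihood(v, np.zeros(V), np.array([0.4, 0.6]), beta, beta)
    assert ll == pytest.approx(-6 * np.log(V))


def test_log_likelihood_hand_mixture():
    # theta = (0.5, 0.5), column mix for code 0 = 0.5*0.9 + 0.5*0.2 = 0.55
    beta = np.array([[0.9, 0.1], [0.2, 0.8]])
    ll = log_likelihood(np.array([1.0, 0.0]), np.zeros(2),
                        np.array([0.5, 0.5]), beta, beta)
    assert ll == pytest.approx(np.log(0.55))


def test_log_likelihood_rejects_off_simplex_theta():
    beta = np.full((2, 3), 1 / 3)
    with pytest.raises(ValueError, match="simplex"):
        log_likelihood(np.ones(3), np.zeros(3), np.array([0.7, 0.7]),
                       beta, beta)


def test_sample_mixture_on_simplex_and_deterministic_limit():
    mix = sample_mixture(np.array([1.0, 2.0, 0.5]),
                         np.array([0.3, -0.2, 0.0]), seed=3)
    assert mix.theta.sum() == pytest.approx(1.0)
    assert np.all(mix.theta > 0)
    # sigma -> 0: delta == mu exactly up to floating noise
    mu = np.array([0.1, -0.4])
    mix0 = sample_mixture(mu, np.full(2, -40.0), seed=0)
    assert np.allclose(mix0.delta, mu, atol=1e-12)


def test_has_converged_hand_trace():
    trace = [-100.0, -99.0, -98.999, -98.9989, -98.9988]
    assert has_converged(trace, tol=1e-4, patience=3)
    assert not has_converged(trace[:4], tol=1e-4, patience=3)
    assert not has_converged([-100.0, -50.0, -25.0], tol=1e-4, patience=2)
    assert not has_converged([-100.0], tol=1e-4, patience=1)


def test_elbo_batch_breakdown_and_scaling():
    enc = Encoder(v_icd=4, v_atc=3, K=2, hidden=8, seed=0)
    beta_icd = np.full((2, 4), 0.25)
    beta_atc = np.full((2, 3), 1 / 3)
    xi = np.array([[2.0, 0, 1, 0], [0, 1, 0, 1]])
    xa = np.array([[1.0, 0, 0], [0, 2, 0]])
    elbo, parts = elbo_batch(xi, xa, enc, beta_icd, beta_atc, seed=0)
    assert elbo == pytest.approx(parts["log_likelihood"] - parts["kl"])
    # uniform beta: the likelihood is exactly -sum(n_t log V_t) per modality
    expected_ll = -(3 * np.log(4) + 1 * np.log(3)) \
        - (2 * np.log(4) + 2 * np.log(3))
    assert parts["log_likelihood"] == pytest.approx(expected_ll)
    assert parts["kl"] >= 0
    elbo2, _ = elbo_batch(xi, xa, enc, beta_icd, beta_atc, seed=0, scale=10.0)
    assert elbo2 == pytest.approx(10.0 * elbo)
    with pytest.raises(ValueError):
        elbo_batch(np.zeros((0, 4)), np.zeros((0, 3)), enc,
                   beta_icd, beta_atc)


# ----------------------------------------------------------------- encoder
def test_encoder_is_scale_invariant_and_shapes():
    enc = Encoder(v_icd=5, v_atc=4, K=3, hidden=8, seed=1)
    xi = np.array([[1.0, 0, 2, 0, 0]])
    xa = np.array([[0.0, 3, 0, 1]])
    mu1, ls1 = enc.encode_mean(xi, xa)
    mu2, ls2 = enc.encode_mean(5 * xi, 5 * xa)
    assert mu1.shape == ls1.shape == (1, 3)
    assert np.allclose(mu1, mu2) and np.allclose(ls1, ls2)


def test_encoder_rejects_empty_record():
    enc = Encoder(v_icd=2, v_atc=2, K=2)
    with pytest.raises(ValueError, match="no tokens"):
        enc.forward(np.zeros((1, 2)), np.zeros((1, 2)))


def test_encoder_gradient_matches_finite_differences():
    from conftest import check_gradient
    enc = Encoder(v_icd=3, v_atc=2, K=2, hidden=4, seed=2)
    xi = np.array([[1.0, 2, 0], [0, 1, 1]])
    xa = np.array([[1.0, 0], [2, 1]])

    def loss():
        mu, ls = enc.forward(xi, xa)
        return (mu * mu).sum() + (ls.exp()).sum()

    for p in enc.parameters():
        check_gradient(loss, p, rtol=1e-4)


# ---------------------------------------------------------------- training
def test_fit_improves_elbo_and_yields_simplex_outputs(tiny_results):
    res = tiny_results
    assert len(res.trace) >= 2
    first, last = res.trace[0]["train_elbo"], res.trace[-1]["train_elbo"]
    assert last > first
    assert np.allclose(res.beta_icd.sum(axis=1), 1.0, atol=1e-8)
    assert np.allclose(res.beta_atc.sum(axis=1), 1.0, atol=1e-8)
    theta = res.transform_corpus(res.model.corpus)
    assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-8)
    assert np.all(theta >= 0)


def test_fit_is_deterministic_under_seed(small_sim):
    corpus, _ = small_sim
    cfg = TrainConfig(batch_size=128, max_epochs=3, seed=9,
                      use_node2vec_init=False, use_gat=False)
    r1 = MultimodalETM(corpus, n_topics=3, embedding_dim=8).fit(cfg)
    r2 = MultimodalETM(corpus, n_topics=3, embedding_dim=8).fit(cfg)
    assert np.allclose(r1.beta_icd, r2.beta_icd)
    assert r1.trace[-1]["train_elbo"] == pytest.approx(
        r2.trace[-1]["train_elbo"])


def test_fit_validates_configuration(small_sim):
    corpus, _ = small_sim
    model = MultimodalETM(corpus, n_topics=3, embedding_dim=8)
    with pytest.raises(ValueError, match="knowledge graph"):
        model.fit(TrainConfig(use_node2vec_init=False, use_gat=True))
    with pytest.raises(ValueError, match="init_embedding"):
        model.fit(TrainConfig(use_node2vec_init=True, use_gat=False))
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(convergence_tol=0.0)


def test_summary_and_top_codes(tiny_results):
    res = tiny_results
    text = res.summary()
    assert "topics K" in text and "3" in text
    assert "topic  0" in text
    top = res.top_codes("icd", 0, n=4)
    assert len(top) == 4
    beta = res.beta_icd[0]
    vocab = res.model.corpus.vocab_icd
    assert beta[vocab.index(top[0])] == beta.max()


def test_results_save_load_round_trip(tmp_path, tiny_results):
    res = tiny_results
    res.save(tmp_path / "model")
    back = ETMResults.load(tmp_path / "model", res.model.corpus)
    assert np.allclose(back.beta_icd, res.beta_icd)
    xi = np.asarray(res.model.corpus.icd_counts[:5].todense(), dtype=float)
    xa = np.asarray(res.model.corpus.atc_counts[:5].todense(), dtype=float)
    assert np.allclose(back.transform(xi, xa), res.transform(xi, xa))
    assert back.config == res.config


def test_elbo_gradient_end_to_end(small_sim):
    """The training-loss gradient of the topic embedding matches central
    finite differences on a toy instance."""
    from conftest import check_gradient
    from kgetm.autodiff import Tensor
    corpus, _ = small_sim
    rng = np.random.default_rng(0)
    K, L = 2, 4
    rho_icd = rng.standard_normal((corpus.v_icd, L)) * 0.1
    rho_atc = rng.standard_normal((corpus.v_atc, L)) * 0.1
    alpha = Tensor(rng.standard_normal((L, K)) * 0.1, requires_grad=True)
    enc = Encoder(corpus.v_icd, corpus.v_atc, K, hidden=4, seed=0)
    xi = np.asarray(corpus.icd_counts[:4].todense(), dtype=float)
    xa = np.asarray(corpus.atc_counts[:4].todense(), dtype=float)
    eps = rng.standard_normal((4, K))

    def loss():
        mu, ls = enc.forward(xi, xa)
        b_i = (Tensor(rho_icd) @ alpha).log_softmax(axis=0).exp().T
        b_a = (Tensor(rho_atc) @ alpha).log_softmax(axis=0).exp().T
        ll, kl = MultimodalETM._batch_elbo(xi, xa, mu, ls, b_i, b_a, eps)
        return kl - ll

    check_gradient(loss, alpha, rtol=1e-4)
    for p in enc.parameters():
        check_gradient(loss, p, rtol=1e-4)
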