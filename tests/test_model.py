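"""Forward-pass correctness of the multi-view encoder, attention, discriminator
and ZINB decoder, checked against straight-line numpy oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from dmgcn import (
    DMGCN,
    DataError,
    ModelConfig,
    SpotGraph,
    avg_readout,
    build_knn_graph,
    discriminate,
    fuse_contrastive_labels,
    gcn_layer,
    normalize_adjacency,
)
from dmgcn.autodiff import Tensor


def graph_from_dense(a):
    return normalize_adjacency(
        SpotGraph(adjacency=sp.csr_matrix(np.asarray(a, float)), k=0, metric="euclidean")
    )


def empty_graph(n):
    return graph_from_dense(np.zeros((n, n)))


# -- gcn_layer ---------------------------------------------------------------


def test_gcn_identity_propagation(rng):
    h = np.abs(rng.normal(size=(4, 3)))
    out = gcn_layer(h, empty_graph(4), np.eye(3))
    np.testing.assert_allclose(out.data, h)


def test_gcn_relu_clamps_negative(rng):
    h = np.abs(rng.normal(size=(4, 3)))
    out = gcn_layer(h, empty_graph(4), -np.eye(3))
    np.testing.assert_array_equal(out.data, np.zeros((4, 3)))


def test_gcn_matches_dense_oracle(rng):
    g = build_knn_graph(rng.normal(size=(5, 2)), k=2)
    h, w = rng.normal(size=(5, 4)), rng.normal(size=(4, 3))
    expected = np.maximum(g.normalized.toarray() @ h @ w, 0.0)
    np.testing.assert_allclose(gcn_layer(h, g, w).data, expected, atol=1e-10)


def test_gcn_shape_mismatch_errors(rng):
    with pytest.raises(DataError):
        gcn_layer(rng.normal(size=(4, 3)), empty_graph(5), np.eye(3))
    with pytest.raises(DataError):
        gcn_layer(rng.normal(size=(4, 3)), empty_graph(4), np.eye(2))


# -- encode ------------------------------------------------------------------


def _identity_model(n_genes, n_layers=1):
    m = DMGCN(n_genes, ModelConfig(n_layers=n_layers, hidden_dims=[n_genes] * n_layers,
                                   latent_dim=2, seed=0))
    for wl in (m.w_s, m.w_f, m.w_c, m.w_cl):
        for w in wl:
            w.data[...] = np.eye(n_genes)
    return m


def test_encode_reduces_to_relu_x_on_empty_graphs(rng):
    x = rng.normal(size=(6, 4))
    m = _identity_model(4)
    emb = m.encode(x, x, empty_graph(6), empty_graph(6))
    for h in (emb.h_s, emb.h_f, emb.h_sc, emb.h_fc, emb.h_c, emb.h_cls, emb.h_clf):
        np.testing.assert_allclose(h.data, np.maximum(x, 0.0))


def test_encode_symmetric_views_coincide(rng):
    x = rng.normal(size=(5, 3))
    g = build_knn_graph(rng.normal(size=(5, 2)), k=2)
    m = _identity_model(3)
    emb = m.encode(x, x, g, g)
    np.testing.assert_allclose(emb.h_sc.data, emb.h_fc.data)
    np.testing.assert_allclose(emb.h_sc.data, emb.h_c.data)


def test_encode_matches_scripted_forward_oracle(rng):
    """4-spot toy, 2 layers, hand-set weights vs a straight-line reimplementation."""
    x = rng.normal(size=(4, 3))
    g_s = build_knn_graph(rng.normal(size=(4, 2)), k=1)
    g_f = build_knn_graph(rng.normal(size=(4, 2)) + 3, k=2)
    m = DMGCN(3, ModelConfig(n_layers=2, hidden_dims=[3, 2], latent_dim=2, seed=1))
    xc = x[rng.permutation(4)]
    emb = m.encode(x, xc, g_s, g_f)
    s, f = g_s.normalized.toarray(), g_f.normalized.toarray()

    def fwd(h0, op, ws):
        h = h0
        for w in ws:
            h = np.maximum(op @ h @ w.data, 0.0)
        return h

    np.testing.assert_allclose(emb.h_s.data, fwd(x, s, m.w_s), atol=1e-10)
    np.testing.assert_allclose(emb.h_f.data, fwd(x, f, m.w_f), atol=1e-10)
    np.testing.assert_allclose(emb.h_sc.data, fwd(x, s, m.w_c), atol=1e-10)
    np.testing.assert_allclose(emb.h_fc.data, fwd(x, f, m.w_c), atol=1e-10)
    np.testing.assert_allclose(
        emb.h_c.data, (fwd(x, s, m.w_c) + fwd(x, f, m.w_c)) / 2, atol=1e-10
    )
    np.testing.assert_allclose(emb.h_cls.data, fwd(xc, s, m.w_cl), atol=1e-10)
    np.testing.assert_allclose(emb.h_clf.data, fwd(xc, f, m.w_cl), atol=1e-10)


def test_corrupted_branch_differs_only_by_weights(rng):
    """With x_corrupt = x the corrupted stacks equal co-conv stacks under Wcl."""
    x = rng.normal(size=(5, 3))
    g = build_knn_graph(rng.normal(size=(5, 2)), k=2)
    m = DMGCN(3, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=2, seed=2))
    for wc, wcl in zip(m.w_c, m.w_cl):
        wcl.data[...] = wc.data
    emb = m.encode(x, x, g, g)
    np.testing.assert_allclose(emb.h_cls.data, emb.h_sc.data)


# -- attention ---------------------------------------------------------------


def test_attention_identity_on_equal_views(rng):
    m = DMGCN(3, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=2, seed=3))
    h = np.abs(rng.normal(size=(6, 4)))
    fused, w = m.attention_fuse(h, h, h)
    np.testing.assert_allclose(fused.data, h, atol=1e-12)
    np.testing.assert_allclose(w.phi_s + w.phi_f + w.phi_c, np.ones(6), atol=1e-12)


def test_attention_weights_on_simplex(rng):
    m = DMGCN(3, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=2, seed=4))
    hs, hf, hc = (np.abs(rng.normal(size=(7, 4))) for _ in range(3))
    _, w = m.attention_fuse(hs, hf, hc)
    for phi in (w.phi_s, w.phi_f, w.phi_c):
        assert np.all(phi >= 0)
    np.testing.assert_allclose(w.phi_s + w.phi_f + w.phi_c, np.ones(7), atol=1e-12)


def test_attention_matches_hand_computation():
    """2 spots, 2 dims, fixed tiny parameters: scalar arithmetic oracle."""
    m = DMGCN(2, ModelConfig(n_layers=1, hidden_dims=[2], latent_dim=2,
                             attention_dim=2, seed=0))
    w1 = np.array([[0.5, -0.2], [0.1, 0.3]])
    b1 = np.array([0.05, -0.1])
    w2 = np.array([[0.7], [-0.4]])
    m.att_w1.data[...] = w1
    m.att_b1.data[...] = b1
    m.att_w2.data[...] = w2
    hs = np.array([[1.0, 0.0], [0.0, 2.0]])
    hf = np.array([[0.5, 0.5], [1.0, 1.0]])
    hc = np.array([[0.0, 1.0], [2.0, 0.0]])
    fused, w = m.attention_fuse(hs, hf, hc)
    scores = [np.tanh(h @ w1 + b1) @ w2 for h in (hs, hf, hc)]
    e = np.exp(np.hstack(scores))
    phi = e / e.sum(axis=1, keepdims=True)
    expected = phi[:, [0]] * hs + phi[:, [1]] * hf + phi[:, [2]] * hc
    np.testing.assert_allclose(fused.data, expected, atol=1e-12)
    np.testing.assert_allclose(w.phi_s, phi[:, 0], atol=1e-12)


# -- readout / discriminator -------------------------------------------------


def test_readout_plain_column_means_without_edges(rng):
    h = rng.normal(size=(6, 3))
    np.testing.assert_allclose(avg_readout(h, empty_graph(6)).data, h.mean(axis=0))


def test_readout_constant_rows_closed_form(rng):
    r = rng.normal(size=4)
    h = np.tile(r, (5, 1))
    g = build_knn_graph(rng.normal(size=(5, 2)), k=2)
    scale = np.ravel(g.normalized.sum(axis=1)).mean()
    np.testing.assert_allclose(avg_readout(h, g).data, r * scale, atol=1e-9)


def test_readout_permutation_invariant(rng):
    h = rng.normal(size=(8, 3))
    g = build_knn_graph(rng.normal(size=(8, 2)), k=2)
    perm = rng.permutation(8)
    p = sp.csr_matrix((np.ones(8), (np.arange(8), perm)), shape=(8, 8))
    g2 = normalize_adjacency(
        SpotGraph(adjacency=(p @ g.adjacency @ p.T).tocsr(), k=2, metric="euclidean")
    )
    np.testing.assert_allclose(avg_readout(h, g).data, avg_readout(h[perm], g2).data, atol=1e-12)


def test_discriminator_orthogonal_gives_half():
    summary = np.array([1.0, 0.0])
    z = np.array([[0.0, 3.0], [0.0, -1.0]])
    s1, s2 = discriminate(Tensor(summary), Tensor(z), Tensor(z), Tensor(np.eye(2)))
    np.testing.assert_allclose(s1.data, np.full((2, 1), 0.5))


def test_discriminator_scores_in_open_unit_interval(rng):
    s = rng.normal(size=3)
    z1, z2 = rng.normal(size=(5, 3)) * 10, rng.normal(size=(5, 3)) * 10
    b = rng.normal(size=(3, 3))
    d1, d2 = discriminate(Tensor(s), Tensor(z1), Tensor(z2), Tensor(b))
    for d in (d1.data, d2.data):
        assert np.all((d > 0) & (d < 1))


def test_discriminator_matches_quadratic_form_oracle(rng):
    s = rng.normal(size=4)
    z1, z2 = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    b = rng.normal(size=(4, 4))
    d1, d2 = discriminate(Tensor(s), Tensor(z1), Tensor(z2), Tensor(b))
    exp1 = 1 / (1 + np.exp(-np.array([zi @ b @ s for zi in z1])))
    exp2 = 1 / (1 + np.exp(-np.array([zi @ b @ s for zi in z2])))
    np.testing.assert_allclose(d1.data.ravel(), exp1, atol=1e-10)
    np.testing.assert_allclose(d2.data.ravel(), exp2, atol=1e-10)


def test_label_fusion_identity_and_bounds(rng):
    d = Tensor(rng.uniform(0.1, 0.9, size=(6, 1)))
    out = fuse_contrastive_labels(d, d, Tensor(rng.normal(size=2)))
    np.testing.assert_allclose(out.data, d.data, atol=1e-12)
    d2 = Tensor(rng.uniform(0.1, 0.9, size=(6, 1)))
    out2 = fuse_contrastive_labels(d, d2, Tensor(rng.normal(size=2))).data
    lo, hi = np.minimum(d.data, d2.data), np.maximum(d.data, d2.data)
    assert np.all(out2 >= lo - 1e-12) and np.all(out2 <= hi + 1e-12)


def test_label_fusion_weighted_mean_oracle():
    logits = Tensor(np.log(np.array([0.3, 0.7])))
    a, b = Tensor(np.array([[0.2], [0.8]])), Tensor(np.array([[0.6], [0.4]]))
    out = fuse_contrastive_labels(a, b, logits)
    np.testing.assert_allclose(out.data, 0.3 * a.data + 0.7 * b.data, atol=1e-12)


# -- decoder ----------------------------------------------------------------


def test_zinb_head_link_ranges(rng):
    m = DMGCN(5, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=3, seed=6))
    h = rng.normal(size=(7, 4)) * 5
    sf = rng.uniform(0.5, 2.0, size=7)
    _, _, zinb = m.decode(h, sf)
    assert np.all((zinb.pi.data > 0) & (zinb.pi.data < 1))
    assert np.all(zinb.mu.data > 0)
    assert np.all(zinb.theta.data > 0)
    assert np.all(np.isfinite(zinb.mu.data))


def test_size_factors_scale_mu_only(rng):
    m = DMGCN(5, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=3, seed=7))
    h = rng.normal(size=(6, 4))
    sf = rng.uniform(0.5, 2.0, size=6)
    _, _, z1 = m.decode(h, sf)
    _, _, z2 = m.decode(h, 2 * sf)
    np.testing.assert_allclose(z2.mu.data, 2 * z1.mu.data, atol=1e-10)
    np.testing.assert_allclose(z2.pi.data, z1.pi.data)
    np.testing.assert_allclose(z2.theta.data, z1.theta.data)


def test_decoder_matches_hand_computed_links():
    """1 spot x 2 genes with fixed tiny weights: every head checked by hand."""
    m = DMGCN(2, ModelConfig(n_layers=1, hidden_dims=[2], latent_dim=1,
                             decoder_hidden=2, seed=8))
    m.dec_w1.data[...] = [[0.2, -0.1], [0.3, 0.4]]
    m.dec_b1.data[...] = [0.0, 0.1]
    m.dec_wz.data[...] = [[0.5], [-0.5]]
    m.dec_bz.data[...] = [0.05]
    m.dec_w2.data[...] = [[0.6, -0.2]]
    m.dec_b2.data[...] = [0.0, 0.0]
    m.head_pi_w.data[...] = [[1.0, 0.0], [0.0, 1.0]]
    m.head_pi_b.data[...] = [0.1, -0.1]
    m.head_mu_w.data[...] = [[0.5, 0.5], [0.2, -0.2]]
    m.head_mu_b.data[...] = [0.0, 0.2]
    m.head_theta.data[...] = [[0.3, -0.3]]
    h = np.array([[1.0, 2.0]])
    sf = np.array([1.5])
    z, x_recon, zinb = m.decode(h, sf)
    hid = np.tanh(h @ m.dec_w1.data + m.dec_b1.data)
    z_exp = hid @ m.dec_wz.data + m.dec_bz.data
    hid2 = np.tanh(z_exp @ m.dec_w2.data + m.dec_b2.data)
    pi_exp = 1 / (1 + np.exp(-(hid2 @ m.head_pi_w.data + m.head_pi_b.data)))
    mu_exp = np.exp(hid2 @ m.head_mu_w.data + m.head_mu_b.data) * sf[:, None]
    theta_exp = np.logaddexp(0.0, m.head_theta.data)
    np.testing.assert_allclose(z.data, z_exp, atol=1e-12)
    np.testing.assert_allclose(zinb.pi.data, pi_exp, atol=1e-12)
    np.testing.assert_allclose(zinb.mu.data, mu_exp, atol=1e-12)
    np.testing.assert_allclose(x_recon.data, mu_exp, atol=1e-12)
    np.testing.assert_allclose(zinb.theta.data, np.clip(theta_exp, 1e-4, 1e4), atol=1e-12)


def test_nonpositive_size_factor_errors(rng):
    m = DMGCN(3, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=2, seed=9))
    with pytest.raises(DataError, match="size_factors"):
        m.decode(rng.normal(size=(2, 4)), np.array([1.0, 0.0]))


# -- whole-forward invariants ------------------------------------------------


def test_forward_is_permutation_equivariant(rng):
    n, g = 10, 6
    x = np.abs(rng.normal(size=(n, g)))
    coords = rng.normal(size=(n, 2))
    xc = x[rng.permutation(n)]
    sf = rng.uniform(0.5, 2.0, size=n)
    m = DMGCN(g, ModelConfig(n_layers=2, hidden_dims=[5, 4], latent_dim=3, seed=10))
    g_s, g_f = build_knn_graph(coords, 3), build_knn_graph(x, 3, "cosine")
    out = m.forward(x, xc, g_s, g_f, sf)

    perm = rng.permutation(n)
    p = sp.csr_matrix((np.ones(n), (np.arange(n), perm)), shape=(n, n))

    def permuted(gr):
        return normalize_adjacency(
            SpotGraph(adjacency=(p @ gr.adjacency @ p.T).tocsr(), k=gr.k, metric=gr.metric)
        )

    # note: row i of permuted data is old row perm[i]
    out_p = m.forward(x[perm], xc[perm], permuted(g_s), permuted(g_f), sf[perm])
    np.testing.assert_allclose(out_p["fused"].data, out["fused"].data[perm], atol=1e-9)
    np.testing.assert_allclose(out_p["z"].data, out["z"].data[perm], atol=1e-9)
    np.testing.assert_allclose(
        out_p["zinb"].mu.data, out["zinb"].mu.data[perm], atol=1e-9
    )
    for key in ("pos_s", "neg_f"):
        np.testing.assert_allclose(
            out_p["scores"][key].data, out["scores"][key].data[perm], atol=1e-9
        )


def test_fresh_models_with_same_seed_are_bit_identical(rng):
    x = np.abs(rng.normal(size=(8, 5)))
    xc = x[rng.permutation(8)]
    sf = np.ones(8)
    g_s = build_knn_graph(rng.normal(size=(8, 2)), 2)
    g_f = build_knn_graph(x, 2, "cosine")
    cfg = ModelConfig(n_layers=2, hidden_dims=[4, 3], latent_dim=2, seed=21)
    o1 = DMGCN(5, cfg).forward(x, xc, g_s, g_f, sf)
    o2 = DMGCN(5, cfg).forward(x, xc, g_s, g_f, sf)
    np.testing.assert_array_equal(o1["z"].data, o2["z"].data)
    np.testing.assert_array_equal(o1["zinb"].mu.data, o2["zinb"].mu.data)


def test_model_checkpoint_round_trip(tmp_path, rng):
    cfg = ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=2, seed=11)
    m1 = DMGCN(6, cfg)
    m1.save(tmp_path / "ckpt.npz")
    m2 = DMGCN(6, ModelConfig(n_layers=1, hidden_dims=[4], latent_dim=2, seed=99))
    m2.load(tmp_path / "ckpt.npz")
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(p1.data, p2.data)
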