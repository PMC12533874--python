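"""The DMGCN network.

Three graph-convolutional branches encode the expression matrix X: a spatial
branch through the coordinate KNN graph (weights Ws), a feature branch through
the expression KNN graph (Wf), and a co-convolution branch that pushes X
through *both* graphs with shared weights (Wc), averaging the two results into
a joint embedding Hc.  Corrupted features Xc run through the same
co-convolution with their own shared weights (Wcl) to produce negatives for
contrastive learning.  An attention mechanism fuses the spatial, feature and
joint embeddings per spot; a fully connected decoder maps the fused embedding
to a clustering bottleneck Z and to the zero-inflation / mean / dispersion
heads of a ZINB reconstruction of the raw counts.

All layers use ReLU except the attention scorer (tanh) and the decoder hidden
layers (tanh).  The forward pass is deterministic and permutation-equivariant
over spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, glorot_uniform, spmm, tensor
from .errors import ConfigError, DataError
from .graphs import SpotGraph

__all__ = [
    "ModelConfig",
    "ViewEmbeddings",
    "AttentionWeights",
    "ZINBParams",
    "DMGCN",
    "gcn_layer",
    "avg_readout",
    "discriminate",
    "fuse_contrastive_labels",
]


@dataclass
class ModelConfig:
    n_layers: int = 2
    hidden_dims: list[int] = field(default_factory=lambda: [128, 64])
    latent_dim: int = 32
    attention_dim: int = 32
    decoder_hidden: int = 64
    theta_mode: str = "per_gene"  # or "per_entry"
    readout_source: str = "coconv"  # or "view": which embeddings feed AvgReadout
    cluster_on: str = "Z"  # or "H": what K-means sees downstream
    seed: int = 0

    def validate(self) -> None:
        if len(self.hidden_dims) != self.n_layers:
            raise ConfigError("hidden_dims: length must equal n_layers")
        if any(d < 1 for d in self.hidden_dims) or self.latent_dim < 1:
            raise ConfigError("hidden_dims/latent_dim: all widths must be >= 1")
        if self.theta_mode not in ("per_gene", "per_entry"):
            raise ConfigError(f"theta_mode: unknown mode {self.theta_mode!r}")
        if self.readout_source not in ("coconv", "view"):
            raise ConfigError(f"readout_source: must be 'coconv' or 'view'")
        if self.cluster_on not in ("Z", "H"):
            raise ConfigError("cluster_on: must be 'Z' or 'H'")


@dataclass
class ViewEmbeddings:
    """Final-layer hidden states of every branch (spots x hidden)."""

    h_s: Tensor
    h_f: Tensor
    h_sc: Tensor
    h_fc: Tensor
    h_c: Tensor
    h_cls: Tensor
    h_clf: Tensor


@dataclass
class AttentionWeights:
    """Per-spot view weights on the probability simplex."""

    phi_s: np.ndarray
    phi_f: np.ndarray
    phi_c: np.ndarray


@dataclass
class ZINBParams:
    """Decoder heads parameterising the reconstruction likelihood."""

    pi: Tensor  # dropout probability, spots x genes, in (0,1)
    mu: Tensor  # mean, spots x genes, > 0 (size-factor scaled)
    theta: Tensor  # dispersion, per-gene row or spots x genes, > 0
    bias: np.ndarray  # per-spot size factor (the bias b_i)


def _as_operator(g) -> sp.csr_matrix:
    if isinstance(g, SpotGraph):
        if g.normalized is None:
            raise DataError("SpotGraph has no normalised operator; run normalize_adjacency")
        return g.normalized
    return sp.csr_matrix(g)


def gcn_layer(h, g_norm, w) -> Tensor:
    """One graph-convolution layer: ReLU(g_norm @ h @ w)."""
    h, w = tensor(h), tensor(w)
    op = _as_operator(g_norm)
    if op.shape[1] != h.shape[0]:
        raise DataError(f"graph has {op.shape[1]} spots but features have {h.shape[0]}")
    if h.shape[1] != w.shape[0]:
        raise DataError(f"feature dim {h.shape[1]} does not match weight rows {w.shape[0]}")
    return (spmm(op, h) @ w).relu()


def avg_readout(h, g) -> Tensor:
    """Graph-smoothed global summary: mean over spots of (g.normalized @ h)."""
    h = tensor(h)
    return spmm(_as_operator(g), h).mean(axis=0)


def discriminate(summary: Tensor, z1: Tensor, z2: Tensor, bilinear: Tensor):
    """Score each spot of z1 and z2 against the graph summary.

    Per spot i the score is sigmoid(z_i^T B s) with B the learned bilinear
    form; returns one score vector in (0,1) per input matrix.
    """
    s = tensor(summary)
    s_col = s if s.ndim == 2 else _reshape_col(s)
    proj = tensor(bilinear) @ s_col  # (d, 1)
    return (
        (tensor(z1) @ proj).sigmoid(),
        (tensor(z2) @ proj).sigmoid(),
    )


def _reshape_col(v: Tensor) -> Tensor:
    out_data = v.data.reshape(-1, 1)
    out = Tensor(out_data)
    out.requires_grad = v.requires_grad
    out._parents = (v,) if v.requires_grad else ()
    out._backward = lambda g: v.requires_grad and v._accumulate(g.reshape(v.shape))
    return out


def fuse_contrastive_labels(d_fwd: Tensor, d_bwd: Tensor, logits: Tensor) -> Tensor:
    """Convex combination of the two discrimination directions.

    ``logits`` (length 2) pass through a softmax to give the pair of fusion
    weights; the output is bounded between the two inputs per spot.
    """
    d_fwd, d_bwd = tensor(d_fwd), tensor(d_bwd)
    if d_fwd.shape != d_bwd.shape:
        raise DataError("direction score vectors must have equal length")
    e = tensor(logits).exp()
    denom = e.sum()
    w0 = _pick(e, 0) / denom
    w1 = _pick(e, 1) / denom
    return d_fwd * w0 + d_bwd * w1


def _pick(v: Tensor, i: int) -> Tensor:
    out = Tensor(v.data[i])
    out.requires_grad = v.requires_grad
    out._parents = (v,) if v.requires_grad else ()

    def bw(g):
        if v.requires_grad:
            full = np.zeros_like(v.data)
            full[i] = g
            v._accumulate(full)

    out._backward = bw
    return out


class DMGCN(object):
    """Multi-view GCN encoder + attention fusion + discriminator + ZINB decoder."""

    def __init__(self, n_genes: int, cfg: ModelConfig | None = None):
        self.cfg = cfg or ModelConfig()
        self.cfg.validate()
        self.n_genes = n_genes
        rng = np.random.default_rng(self.cfg.seed)
        dims = [n_genes] + list(self.cfg.hidden_dims)
        d = dims[-1]
        c = self.cfg

        def mat(fi, fo):
            return glorot_uniform(rng, fi, fo)

        def vec(size):
            return Tensor(np.zeros(size), requires_grad=True)

        self.w_s = [mat(dims[i], dims[i + 1]) for i in range(c.n_layers)]
        self.w_f = [mat(dims[i], dims[i + 1]) for i in range(c.n_layers)]
        self.w_c = [mat(dims[i], dims[i + 1]) for i in range(c.n_layers)]
        self.w_cl = [mat(dims[i], dims[i + 1]) for i in range(c.n_layers)]
        # attention: inner transform (W1, b1) then scoring vector w2, shared by views
        self.att_w1 = mat(d, c.attention_dim)
        self.att_b1 = vec(c.attention_dim)
        self.att_w2 = mat(c.attention_dim, 1)
        # discriminator bilinear form and per-view direction-fusion logits
        self.disc_b = mat(d, d)
        self.fuse_s = vec(2)
        self.fuse_f = vec(2)
        # decoder: H -> tanh hidden -> Z -> tanh hidden -> ZINB heads
        self.dec_w1 = mat(d, c.decoder_hidden)
        self.dec_b1 = vec(c.decoder_hidden)
        self.dec_wz = mat(c.decoder_hidden, c.latent_dim)
        self.dec_bz = vec(c.latent_dim)
        self.dec_w2 = mat(c.latent_dim, c.decoder_hidden)
        self.dec_b2 = vec(c.decoder_hidden)
        self.head_pi_w = mat(c.decoder_hidden, n_genes)
        self.head_pi_b = vec(n_genes)
        self.head_mu_w = mat(c.decoder_hidden, n_genes)
        self.head_mu_b = vec(n_genes)
        if c.theta_mode == "per_gene":
            self.head_theta = Tensor(np.zeros((1, n_genes)), requires_grad=True)
            self.head_theta_w = self.head_theta_b = None
        else:
            self.head_theta_w = mat(c.decoder_hidden, n_genes)
            self.head_theta_b = vec(n_genes)
            self.head_theta = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = (
            self.w_s + self.w_f + self.w_c + self.w_cl
            + [self.att_w1, self.att_b1, self.att_w2, self.disc_b,
               self.fuse_s, self.fuse_f,
               self.dec_w1, self.dec_b1, self.dec_wz, self.dec_bz,
               self.dec_w2, self.dec_b2,
               self.head_pi_w, self.head_pi_b, self.head_mu_w, self.head_mu_b]
        )
        if self.head_theta is not None:
            params.append(self.head_theta)
        else:
            params.extend([self.head_theta_w, self.head_theta_b])
        return params

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(path) as npz:
            for i, p in enumerate(self.parameters()):
                p.data[...] = npz[f"p{i}"]

    # -- forward pieces -----------------------------------------------------

    def encode(self, x, x_corrupt, g_s: SpotGraph, g_f: SpotGraph) -> ViewEmbeddings:
        """Run all five propagation stacks; returns final-layer embeddings."""
        x, xc = tensor(x), tensor(x_corrupt)
        if x.shape != xc.shape:
            raise DataError("clean and corrupted features must share a shape")
        if g_s.n_spots != x.shape[0] or g_f.n_spots != x.shape[0]:
            raise DataError("graph spot count does not match feature rows")
        h_s, h_f = x, x
        h_sc, h_fc = x, x
        h_cls, h_clf = xc, xc
        for l in range(self.cfg.n_layers):
            h_s = gcn_layer(h_s, g_s, self.w_s[l])
            h_f = gcn_layer(h_f, g_f, self.w_f[l])
            h_sc = gcn_layer(h_sc, g_s, self.w_c[l])  # shared weights both graphs
            h_fc = gcn_layer(h_fc, g_f, self.w_c[l])
            h_cls = gcn_layer(h_cls, g_s, self.w_cl[l])
            h_clf = gcn_layer(h_clf, g_f, self.w_cl[l])
        h_c = (h_sc + h_fc) * 0.5
        return ViewEmbeddings(h_s, h_f, h_sc, h_fc, h_c, h_cls, h_clf)

    def _att_score(self, h: Tensor) -> Tensor:
        return ((h @ self.att_w1 + self.att_b1).tanh()) @ self.att_w2  # (n, 1)

    def attention_fuse(self, h_s, h_f, h_c):
        """Softmax-weighted fusion of the three views, per spot."""
        h_s, h_f, h_c = tensor(h_s), tensor(h_f), tensor(h_c)
        if not (h_s.shape == h_f.shape == h_c.shape):
            raise DataError("view embeddings must share a shape")
        e_s = self._att_score(h_s).exp()
        e_f = self._att_score(h_f).exp()
        e_c = self._att_score(h_c).exp()
        denom = e_s + e_f + e_c
        phi_s, phi_f, phi_c = e_s / denom, e_f / denom, e_c / denom
        fused = h_s * phi_s + h_f * phi_f + h_c * phi_c
        weights = AttentionWeights(
            phi_s.data.ravel().copy(), phi_f.data.ravel().copy(), phi_c.data.ravel().copy()
        )
        return fused, weights

    def decode(self, h_fused, size_factors):
        """Map the fused embedding to (Z, reconstruction, ZINB heads)."""
        sf = np.asarray(size_factors, dtype=np.float64).ravel()
        if np.any(sf <= 0):
            raise DataError("size_factors must be strictly positive")
        h_fused = tensor(h_fused)
        hid = (h_fused @ self.dec_w1 + self.dec_b1).tanh()
        z = hid @ self.dec_wz + self.dec_bz
        hid2 = (z @ self.dec_w2 + self.dec_b2).tanh()
        pi = (hid2 @ self.head_pi_w + self.head_pi_b).sigmoid()
        mu = (hid2 @ self.head_mu_w + self.head_mu_b).clip(-30.0, 30.0).exp()
        mu = mu * sf[:, None]
        if self.head_theta is not None:
            theta = self.head_theta.softplus().clip(1e-4, 1e4)
        else:
            theta = (hid2 @ self.head_theta_w + self.head_theta_b).softplus().clip(1e-4, 1e4)
        zinb = ZINBParams(pi=pi, mu=mu, theta=theta, bias=sf)
        return z, mu, zinb

    def forward(self, x, x_corrupt, g_s: SpotGraph, g_f: SpotGraph, size_factors):
        """Full pass: embeddings, attention fusion, contrastive scores, decoder.

        Returns a dict with every intermediate the losses need: the
        ViewEmbeddings, fused H and attention weights, per-view fused
        positive/negative discriminator scores (Rcls/Rclf halves), Z, the
        reconstruction and the ZINB parameter heads.
        """
        emb = self.encode(x, x_corrupt, g_s, g_f)
        fused, att = self.attention_fuse(emb.h_s, emb.h_f, emb.h_c)

        if self.cfg.readout_source == "coconv":
            src_s, src_f = emb.h_sc, emb.h_fc
        else:
            src_s, src_f = emb.h_s, emb.h_f
        summary_s = avg_readout(src_s, g_s)
        summary_f = avg_readout(src_f, g_f)

        scores = {}
        for view, summary, h_neg, fuse_logits in (
            ("s", summary_s, emb.h_cls, self.fuse_s),
            ("f", summary_f, emb.h_clf, self.fuse_f),
        ):
            d_pos, d_neg = discriminate(summary, emb.h_c, h_neg, self.disc_b)
            # the two directions swap the roles of clean and corrupted inputs
            scores[f"pos_{view}"] = fuse_contrastive_labels(d_pos, d_neg, fuse_logits)
            scores[f"neg_{view}"] = fuse_contrastive_labels(d_neg, d_pos, fuse_logits)

        z, x_recon, zinb = self.decode(fused, size_factors)
        return {
            "embeddings": emb,
            "fused": fused,
            "attention": att,
            "scores": scores,
            "z": z,
            "x_recon": x_recon,
            "zinb": zinb,
        }
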