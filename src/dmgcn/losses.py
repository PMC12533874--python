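"""Training objectives.

The total objective is  L = alpha * L_zinb + L_coconv  with

    L_coconv = ((L_positive + L_negative) / 2) * beta + L_con * gamma,

where L_con is a consistency penalty between the two co-convolution
embeddings (squared Frobenius distance of their row-normalised Gram
matrices), L_positive / L_negative are the contrastive binary cross-entropy
terms (clean spots scored toward 1, corrupted toward 0), and L_zinb is the
negative log-likelihood of the raw counts under the decoder's zero-inflated
negative binomial.  The default weight triple (alpha, beta, gamma) = (1, 1, 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln as sc_gammaln

from .autodiff import Tensor, tensor
from .errors import ConfigError, DataError
from .model import ZINBParams

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "consistency_loss",
    "contrastive_bce",
    "zinb_nll",
    "total_loss",
]

log = logging.getLogger(__name__)

_EPS = 1e-7  # probability clamp for the BCE logs


@dataclass
class LossWeights:
    alpha: float = 1.0  # ZINB reconstruction weight
    beta: float = 1.0  # contrastive (positive+negative) weight
    gamma: float = 10.0  # consistency weight

    def validate(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ConfigError("loss weights alpha/beta/gamma must be nonnegative")


@dataclass
class LossBreakdown:
    l_con: float
    l_pos: float
    l_neg: float
    l_coconv: float
    l_zinb: float
    total: float


def _row_normalize(h: Tensor) -> Tensor:
    """L2-normalise rows; all-zero rows map to zero vectors (logged)."""
    sq = (h * h).sum(axis=1, keepdims=True)
    zero_rows = sq.data.ravel() == 0
    if zero_rows.any():
        log.warning("consistency_loss: %d all-zero embedding rows", int(zero_rows.sum()))
    # the +mask keeps the sqrt differentiable at zero rows; those rows stay 0/1=0
    safe = sq + zero_rows.astype(np.float64)[:, None]
    return h / safe.sqrt()


def consistency_loss(h_sc, h_fc, normalize_rows: bool = True) -> Tensor:
    """Mean-square difference of the two views' cosine Gram matrices.

    Rows are L2-normalised so Gram entries are cosine similarities; the squared
    Frobenius norm of the difference is divided by N^2 (a plain mean over
    entries) to keep the scale independent of spot count.
    ``normalize_rows=False`` compares the raw Gram matrices instead.
    """
    h_sc, h_fc = tensor(h_sc), tensor(h_fc)
    if h_sc.shape != h_fc.shape:
        raise DataError("consistency_loss: embeddings must share a shape")
    if normalize_rows:
        a, b = _row_normalize(h_sc), _row_normalize(h_fc)
    else:
        a, b = h_sc, h_fc
    diff = a @ a.T - b @ b.T
    return (diff * diff).mean()


def contrastive_bce(scores_pos, scores_neg) -> tuple[Tensor, Tensor]:
    """Binary cross-entropy for one view's fused discriminator scores.

    Clean spots (``scores_pos``) are pushed toward 1, corrupted spots
    (``scores_neg``) toward 0.  Scores exactly at {0, 1} are clamped to
    [1e-7, 1-1e-7] before the log.
    """
    p = tensor(scores_pos)
    q = tensor(scores_neg)
    if np.any(p.data < 0) or np.any(p.data > 1) or np.any(q.data < 0) or np.any(q.data > 1):
        raise DataError("contrastive_bce: scores must lie in [0, 1]")
    if np.any(p.data <= 0) or np.any(p.data >= 1) or np.any(q.data <= 0) or np.any(q.data >= 1):
        log.warning("contrastive_bce: scores at {0,1} clamped to [%g, %g]", _EPS, 1 - _EPS)
    l_pos = -(p.clip(_EPS, 1 - _EPS).log()).mean()
    l_neg = -((1.0 - q).clip(_EPS, 1 - _EPS).log()).mean()
    return l_pos, l_neg


def zinb_nll(x, params: ZINBParams) -> Tensor:
    """Negative mean log-likelihood of counts under the ZINB mixture.

    Per entry the likelihood is  pi * [x = 0] + (1 - pi) * NB(x | mu, theta)
    with the NB pmf evaluated through log-gamma; the zero branch is computed
    as log(pi + (1 - pi) * exp(theta * log(theta / (theta + mu)))), which is
    stable because the inner exponent is nonpositive and pi > 0.
    The loss is the negative mean over all spots x genes entries.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise DataError("zinb_nll: counts must be nonnegative integers")
    pi, mu, theta = params.pi, params.mu, params.theta
    pi = tensor(pi).clip(1e-6, 1.0 - 1e-6)
    mu, theta = tensor(mu), tensor(theta)

    log_theta_frac = theta.log() - (theta + mu).log()
    log_p0 = theta * log_theta_frac  # NB log-probability of a zero
    # NB log pmf (the lgamma(x+1) term is constant in the parameters)
    nb_ll = (
        (theta + x).lgamma()
        - theta.lgamma()
        + log_p0
        + x * (mu.log() - (theta + mu).log())
    )
    nb_ll = nb_ll - Tensor(sc_gammaln(x + 1.0))
    zero_ll = (pi + (1.0 - pi) * log_p0.exp()).log()
    nonzero_ll = (1.0 - pi).log() + nb_ll
    mask0 = (x == 0).astype(np.float64)
    ll = zero_ll * mask0 + nonzero_ll * (1.0 - mask0)
    return -ll.mean()


def total_loss(
    l_con: Tensor,
    l_pos: Tensor,
    l_neg: Tensor,
    l_zinb: Tensor,
    weights: LossWeights | None = None,
    ablation: str = "full",
) -> tuple[Tensor, LossBreakdown]:
    """Assemble the weighted objective; returns the graph node and a record.

    ``ablation`` switches select the standard model variants: ``no_zinb``
    zeroes alpha, ``no_coconv`` zeroes beta and gamma.
    """
    w = weights or LossWeights()
    w.validate()
    alpha, beta, gamma = w.alpha, w.beta, w.gamma
    if ablation == "no_zinb":
        alpha = 0.0
    elif ablation == "no_coconv":
        beta = gamma = 0.0
    elif ablation != "full":
        raise ConfigError(f"ablation: unknown variant {ablation!r}")

    parts = {"l_con": l_con, "l_pos": l_pos, "l_neg": l_neg, "l_zinb": l_zinb}
    for name, t in parts.items():
        if not np.isfinite(tensor(t).data).all():
            raise DataError(f"non-finite loss component: {name}")
    l_con, l_pos, l_neg, l_zinb = (tensor(parts[k]) for k in parts)
    l_coconv = ((l_pos + l_neg) * 0.5) * beta + l_con * gamma
    total = l_zinb * alpha + l_coconv
    record = LossBreakdown(
        l_con=l_con.item(),
        l_pos=l_pos.item(),
        l_neg=l_neg.item(),
        l_coconv=l_coconv.item(),
        l_zinb=l_zinb.item(),
        total=total.item(),
    )
    return total, record
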