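"""Feature corruption for contrastive learning.

Negative samples are made by shuffling whole spot rows of the expression
matrix while both graphs stay fixed (the deep-graph-infomax convention): each
corrupted spot keeps a genuine expression profile but sits at the wrong
location in the neighbourhood structure.  The discriminator is then trained to
tell clean spots (label 1) from corrupted ones (label 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["ContrastiveBatch", "corrupt_features"]


@dataclass
class ContrastiveBatch:
    """Clean features, their row-permuted corruption, and contrastive labels."""

    x: np.ndarray
    x_corrupt: np.ndarray
    labels: np.ndarray  # length 2N: ones for clean spots, zeros for corrupted
    permutation: np.ndarray


def corrupt_features(x: np.ndarray, seed: int | np.random.Generator) -> ContrastiveBatch:
    """Row-shuffle ``x`` with a uniform random permutation.

    ``seed`` may be an integer (fresh generator) or a Generator whose stream is
    advanced, letting a training loop redraw the permutation every epoch while
    staying reproducible under the run seed.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise DataError("corruption needs at least 2 spots (it is the identity on 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    return ContrastiveBatch(x=x, x_corrupt=x[perm], labels=labels, permutation=perm)
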