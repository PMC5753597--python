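"""Replicate-consistency QC for differential-expression signatures.

An experiment's reliability is scored by the average cosine distance (ACD)
between its replicate signatures: tightly clustered replicates give an ACD
near 0, uncorrelated replicates near 1, anti-correlated replicates near 2.
Significance is assessed against an empirical null built by repeatedly
drawing same-sized replicate sets at random from the same batch, so the null
captures batch-level technical variation.  Small p-values therefore mark
experiments whose replicates agree more than random batch members do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["ReplicateSet", "NullModel", "compute_acd", "build_null", "acd_pvalue"]


@dataclass
class ReplicateSet:
    """Replicate signature vectors for one experiment."""

    experiment_id: str
    batch_id: str
    replicates: list[np.ndarray]

    def __post_init__(self) -> None:
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        if len(self.replicates) < 2:
            raise ValueError("a replicate set needs at least 2 replicates")
        lengths = {r.shape for r in self.replicates}
        if len(lengths) > 1:
            raise ValueError("replicates have inconsistent lengths")
        for r in self.replicates:
            if not np.all(np.isfinite(r)):
                raise ValueError("replicate contains non-finite values")


@dataclass
class NullModel:
    """Empirical batch null: ACD values of randomly drawn replicate sets."""

    batch_id: str
    sampled_acds: np.ndarray
    k: int
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.sampled_acds)


def compute_acd(rs: ReplicateSet) -> float:
    """Mean pairwise cosine distance (1 − cosine similarity) over all
    unordered replicate pairs; lies in [0, 2]."""
    X = np.vstack(rs.replicates)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(
            f"replicate {zero[0]} of experiment {rs.experiment_id!r} has zero norm"
        )
    return float(np.mean(pdist(X, metric="cosine")))


def build_null(
    batch_replicates: list[np.ndarray],
    k: int,
    n_samples: int = 10_000,
    seed: int = 0,
    batch_id: str = "",
) -> NullModel:
    """Monte-Carlo null distribution of the ACD for replicate sets of size
    ``k`` drawn from one batch.

    Each of the ``n_samples`` draws picks ``k`` distinct replicate vectors
    uniformly at random from the batch (without replacement within a draw,
    with replacement across draws) and records their ACD.
    """
    X = np.vstack([np.asarray(r, dtype=float) for r in batch_replicates])
    n = X.shape[0]
    if k < 2:
        raise ValueError("replicate-set size k must be >= 2")
    if n < k:
        raise ValueError(f"batch has {n} replicates, fewer than k={k}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("batch contains a zero-norm replicate")
    # precompute the unit rows once; each draw averages a submatrix of
    # pairwise distances
    U = X / norms[:, None]
    dist = 1.0 - U @ U.T
    iu = np.triu_indices(k, 1)
    rng = np.random.default_rng(seed)
    acds = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(n, size=k, replace=False)
        sub = dist[np.ix_(idx, idx)]
        acds[i] = sub[iu].mean()
    return NullModel(batch_id=batch_id, sampled_acds=acds, k=k, seed=seed)


def acd_pvalue(acd: float, null: NullModel) -> float:
    """Left-tail empirical p-value with an add-one pseudo-count:
    ``(1 + #{null <= acd}) / (1 + n_samples)``.

    Lower ACD (more consistent replicates) gives a smaller p-value; the
    pseudo-count keeps finite sampling from ever reporting p = 0.
    """
    n_le = int(np.sum(null.sampled_acds <= acd))
    return (1 + n_le) / (1 + null.n_samples)
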