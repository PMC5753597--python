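"""Synthetic data generators with the statistical structure the methods
assume: low-CP-rank drug/gene/cell factor tensors, unit-norm profiles,
profile-level (column-structured) missingness, and noisy replicate sets.

Every generator is a pure function of its arguments including the seed, so
fixtures are reproducible bit-for-bit.  Defaults are sized (D=60, G=50,
C=12) so that a full cross-validation over all completion methods runs in
seconds while still exhibiting the low-rank and neighborhood structure the
predictors exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .qc import ReplicateSet
from .tensor_build import DataTensor

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "gen_lowrank_tensor",
    "apply_missingness",
    "gen_paired_drug_tensor",
    "gen_replicate_sets",
]


@dataclass
class SyntheticTruth:
    """Ground-truth factors behind a generated tensor."""

    drug_factors: np.ndarray
    gene_factors: np.ndarray
    cell_factors: np.ndarray
    noise_sd: float
    seed: int
    full_tensor: np.ndarray


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _renormalize_profiles(values: np.ndarray) -> np.ndarray:
    """Scale every (drug, cell) profile to unit Euclidean norm."""
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return values / norms


def gen_lowrank_tensor(
    D: int = 60,
    G: int = 50,
    C: int = 12,
    rank: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SyntheticTruth, DataTensor]:
    """CP-rank-``rank`` tensor from unit-variance gaussian factor matrices,
    plus optional additive gaussian noise, with every (drug, cell) profile
    renormalized to unit norm afterwards.  Returned fully observed."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if min(D, G, C) < rank:
        raise ValueError("all dimensions must be >= rank")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((D, rank))
    B = rng.standard_normal((G, rank))
    Cc = rng.standard_normal((C, rank))
    full = np.einsum("dr,gr,cr->dgc", A, B, Cc)
    if noise_sd > 0.0:
        full = full + rng.normal(scale=noise_sd, size=full.shape)
    full = _renormalize_profiles(full)
    truth = SyntheticTruth(A, B, Cc, noise_sd, seed, full)
    t = DataTensor(
        _default_ids("drug", D),
        _default_ids("g", G),
        _default_ids("cell", C),
        full.copy(),
        np.ones((D, C), dtype=bool),
    )
    return truth, t


def apply_missingness(
    t: DataTensor,
    density: float,
    pattern: str = "profile_uniform",
    seed: int = 0,
) -> DataTensor:
    """Reduce the tensor to ``floor(density · D · C)`` observed profiles.

    Missingness is profile-level (whole columns of genes vanish at once),
    emulating real perturbation compendia where a (drug, cell) condition is
    either assayed or not.  ``profile_uniform`` samples profiles uniformly;
    ``drug_skewed`` gives drug ``i`` inclusion weight ∝ 1/(i+1), reproducing
    the staircase of heavily- vs sparsely-profiled drugs seen in real data.
    When feasible, every drug and every cell keeps at least one profile.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    if pattern not in ("profile_uniform", "drug_skewed"):
        raise ValueError(f"unknown missingness pattern {pattern!r}")
    D, _, C = t.shape
    n_keep = int(np.floor(density * D * C))
    observed = t.observed_pairs()
    if n_keep >= len(observed):
        return t.copy()
    rng = np.random.default_rng(seed)

    if pattern == "drug_skewed":
        weights = np.array([1.0 / (d + 1) for d, _ in observed])
    else:
        weights = np.ones(len(observed))
    weights = weights / weights.sum()

    keep: set[tuple[int, int]] = set()
    if n_keep < D + C:
        logger.warning(
            "density %.3f keeps %d profiles; cannot guarantee every drug and "
            "cell stays covered (best effort)", density, n_keep,
        )
    # coverage pass: one profile per drug, then per still-uncovered cell
    by_drug: dict[int, list[int]] = {}
    by_cell: dict[int, list[int]] = {}
    for i, (d, c) in enumerate(observed):
        by_drug.setdefault(d, []).append(i)
        by_cell.setdefault(c, []).append(i)
    for d in rng.permutation(sorted(by_drug)):
        if len(keep) >= n_keep:
            break
        idx = by_drug[d]
        keep.add(observed[idx[rng.integers(len(idx))]])
    covered_cells = {c for _, c in keep}
    for c in rng.permutation(sorted(by_cell)):
        if len(keep) >= n_keep:
            break
        if c in covered_cells:
            continue
        idx = by_cell[c]
        keep.add(observed[idx[rng.integers(len(idx))]])
    # fill the remainder by weighted sampling without replacement
    remaining = [i for i, pr in enumerate(observed) if pr not in keep]
    if len(keep) < n_keep and remaining:
        w = weights[remaining]
        w = w / w.sum()
        extra = rng.choice(
            len(remaining), size=min(n_keep - len(keep), len(remaining)),
            replace=False, p=w,
        )
        for i in extra:
            keep.add(observed[remaining[i]])

    out = t.copy()
    for pr in observed:
        if pr not in keep:
            d, c = pr
            out.mask[d, c] = False
            out.values[d, :, c] = 0.0
    return out


def gen_paired_drug_tensor(
    D: int = 60, G: int = 50, C: int = 12, seed: int = 0
) -> DataTensor:
    """Drugs generated in identical twin pairs: drugs 2p and 2p+1 share the
    same random unit profile in every cell, while profiles are independent
    across pairs and across cells.

    This is the neighbor-favorable fixture: for any held-out (drug, cell)
    profile the exact answer is the twin's measured profile in that cell,
    which a 1-nearest-neighbor DNPP recovers verbatim.
    """
    if D % 2 != 0:
        raise ValueError("D must be even for twin pairs")
    rng = np.random.default_rng(seed)
    values = np.empty((D, G, C))
    for p in range(D // 2):
        block = rng.standard_normal((C, G))
        block /= np.linalg.norm(block, axis=1, keepdims=True)
        values[2 * p] = block.T
        values[2 * p + 1] = block.T
    return DataTensor(
        _default_ids("drug", D),
        _default_ids("g", G),
        _default_ids("cell", C),
        values,
        np.ones((D, C), dtype=bool),
    )


def gen_replicate_sets(
    n_experiments: int = 20,
    replicates_per_experiment: int = 3,
    n_batches: int = 2,
    noise_sd: float = 0.1,
    G: int = 50,
    seed: int = 0,
) -> list[ReplicateSet]:
    """Replicate sets around latent unit directions: each experiment draws a
    random unit vector, and each replicate is that direction plus isotropic
    gaussian noise, renormalized.  Batch labels are assigned round-robin."""
    if replicates_per_experiment < 2:
        raise ValueError("need at least 2 replicates per experiment")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_experiments):
        direction = rng.standard_normal(G)
        direction /= np.linalg.norm(direction)
        reps = []
        for _ in range(replicates_per_experiment):
            r = direction + rng.normal(scale=noise_sd, size=G)
            r /= np.linalg.norm(r)
            reps.append(r)
        out.append(
            ReplicateSet(
                experiment_id=f"exp{i:04d}",
                batch_id=f"batch{i % n_batches}",
                replicates=reps,
            )
        )
    return out
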