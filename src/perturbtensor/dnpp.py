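"""Drug Neighbor Profile Prediction (DNPP).

A local, nearest-neighbor predictor adapted to the de-novo setting where the
target (drug, cell) condition has no measurements at all.  Similarity is
defined between *drugs* rather than profiles: for two drugs it is the mean
Pearson correlation of their profiles over the cells in which both were
measured.  The profile of drug ``d`` in cell ``c`` is then predicted as a
similarity-weighted average of up to K profiles measured in ``c`` from the
most similar drugs; because candidate neighbors must have data in ``c``, the
neighbor set can differ from cell to cell.

Only positively-similar drugs are eligible as neighbors, so the weights
(similarities normalized to sum to 1) form a convex combination.  When no
eligible neighbor exists the predictor abstains rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_build import DataTensor

__all__ = [
    "SimilarityMatrix",
    "DNPPConfig",
    "drug_similarity",
    "compute_similarity_matrix",
    "predict_profile_dnpp",
    "complete_tensor_dnpp",
]


@dataclass
class DNPPConfig:
    """Neighborhood parameters: K neighbors, the minimum number of shared
    cells for a similarity to be defined, and the minimum number of eligible
    neighbors below which the predictor abstains."""

    k: int = 10
    min_overlap: int = 1
    min_neighbors: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")


@dataclass
class SimilarityMatrix:
    """Drug–drug similarity S and shared-cell overlap counts.

    ``values[i, j]`` is the mean per-cell Pearson correlation between drugs i
    and j over their shared cells, or NaN where undefined (insufficient
    overlap, or a constant profile in a shared cell).  ``overlap[i, j]`` is
    the number of shared cells |C_i ∩ C_j|.
    """

    drug_ids: list[str]
    values: np.ndarray
    overlap: np.ndarray

    def defined(self, i: int, j: int) -> bool:
        return bool(np.isfinite(self.values[i, j]))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.dot(xc, yc) / (nx * ny))


def drug_similarity(
    t: DataTensor, d: int, d2: int, min_overlap: int = 1
) -> float:
    """Similarity S(d, d2): the mean Pearson correlation between the two
    drugs' profiles across their shared cells.

    Returns NaN (a sentinel, not an error) when the drugs share fewer than
    ``min_overlap`` cells or when any shared-cell profile is constant.
    """
    if d == d2:
        raise ValueError("drug_similarity requires two distinct drugs")
    shared = np.flatnonzero(t.mask[d, :] & t.mask[d2, :])
    if shared.size < min_overlap:
        return float("nan")
    corrs = [_pearson(t.values[d, :, c], t.values[d2, :, c]) for c in shared]
    if any(np.isnan(r) for r in corrs):
        return float("nan")
    return float(np.mean(corrs))


def compute_similarity_matrix(
    t: DataTensor, min_overlap: int = 1
) -> SimilarityMatrix:
    """All-pairs drug similarity, accumulated cell by cell.

    For each cell, the Pearson correlation matrix of the profiles observed in
    that cell is computed in one shot and added into per-pair running sums.
    A constant profile in a shared cell poisons every pair that shares that
    cell (their similarity becomes undefined).
    """
    D, G, C = t.shape
    ssum = np.zeros((D, D))
    count = np.zeros((D, D), dtype=int)
    poisoned = np.zeros((D, D), dtype=bool)
    for c in range(C):
        drugs = t.drugs_for_cell(c)
        if drugs.size < 2:
            continue
        X = t.values[drugs, :, c]
        sd = X.std(axis=1)
        const = sd == 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(X)
        ix = np.ix_(drugs, drugs)
        count[ix] += 1
        if const.any():
            bad = const[:, None] | const[None, :]
            poisoned[ix] |= bad
            R = np.where(bad, 0.0, R)
        ssum[ix] += R
    ssum = 0.5 * (ssum + ssum.T)  # BLAS matmuls are not exactly symmetric
    with np.errstate(invalid="ignore"):
        values = np.where(count >= max(min_overlap, 1), ssum / np.maximum(count, 1), np.nan)
    values[poisoned] = np.nan
    values[count < min_overlap] = np.nan
    # diagonal: a drug is perfectly similar to itself wherever it has data
    has_data = t.mask.any(axis=1)
    np.fill_diagonal(values, np.nan)
    diag = np.where(has_data, 1.0, np.nan)
    values[np.arange(D), np.arange(D)] = diag
    np.fill_diagonal(count, t.mask.sum(axis=1))
    return SimilarityMatrix(list(t.drug_ids), values, count)


def predict_profile_dnpp(
    t: DataTensor,
    s: SimilarityMatrix,
    d: int,
    c: int,
    cfg: DNPPConfig | None = None,
) -> np.ndarray | None:
    """Predict the profile of drug ``d`` in cell ``c`` as a convex combination
    of the top-K positively-similar drugs measured in ``c``.

    Ties at the K-th neighbor are broken lexicographically by drug id for
    determinism.  Returns ``None`` (abstention) when fewer than
    ``cfg.min_neighbors`` eligible neighbors exist.
    """
    if cfg is None:
        cfg = DNPPConfig()
    D, G, C = t.shape
    if not (0 <= d < D) or not (0 <= c < C):
        raise IndexError(f"(d={d}, c={c}) outside tensor of shape {t.shape}")
    candidates = [
        int(d2)
        for d2 in t.drugs_for_cell(c)
        if d2 != d and np.isfinite(s.values[d, d2]) and s.values[d, d2] > 0.0
    ]
    if len(candidates) < cfg.min_neighbors:
        return None
    candidates.sort(key=lambda d2: (-s.values[d, d2], t.drug_ids[d2]))
    chosen = candidates[: cfg.k]
    sims = s.values[d, chosen]
    weights = sims / sims.sum()
    return np.einsum("i,ig->g", weights, t.values[chosen, :, c])


def complete_tensor_dnpp(
    t: DataTensor,
    cfg: DNPPConfig | None = None,
    sim: SimilarityMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict every unobserved (drug, cell) profile with DNPP.

    Returns ``(pred, abstained)`` where ``pred`` is a (D, G, C) array with
    observed profiles copied through unchanged, predictions filled in where
    possible and NaN where the predictor abstained, and ``abstained`` is the
    (D, C) boolean abstention mask.
    """
    if cfg is None:
        cfg = DNPPConfig()
    if sim is None:
        sim = compute_similarity_matrix(t, min_overlap=cfg.min_overlap)
    D, G, C = t.shape
    pred = t.values.copy()
    abstained = np.zeros((D, C), dtype=bool)
    for d in range(D):
        for c in range(C):
            if t.mask[d, c]:
                continue
            p = predict_profile_dnpp(t, sim, d, c, cfg)
            if p is None:
                pred[d, :, c] = np.nan
                abstained[d, c] = True
            else:
                pred[d, :, c] = p
    return pred, abstained
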