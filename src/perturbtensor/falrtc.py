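"""Global low-rank tensor completion by iterated singular-value shrinkage.

The tensor of signatures is assumed to be approximately low-rank: a small
number of latent factors (e.g. shared drug targets or pathway programs)
explain most of the variation across drugs, genes and cells.  Since tensor
rank itself is hard to compute, the algorithm works with the three mode
unfoldings (matricizations) of the D×G×C array — D×(GC), G×(DC) and C×(DG)
matrices — and shrinks each one toward low rank with the proximal operator
of the trace norm (soft-thresholding of singular values).  The three
re-folded estimates are recombined with positive weights α that sum to one,
observed entries are reset to their measured values, and the cycle repeats
until the relative Frobenius-norm change falls below tolerance.

Because missing data are whole (drug, cell) columns, the gene-mode unfolding
— whose low-rank structure leans on gene–gene correlations alone — is far
less informative than the other two; its weight is therefore down-weighted
by a factor of 100 by default, i.e. α ∝ (100, 1, 100) over the
(drug, gene, cell) modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import BaselineConfig, complete_tensor_baseline
from .tensor_build import DataTensor

__all__ = [
    "FalrtcConfig",
    "CompletionReport",
    "MODES",
    "unfold",
    "fold",
    "shrink_lowrank",
    "complete_tensor_falrtc",
]

#: mode name → tensor axis, in the stored (drug, gene, cell) axis order
MODES: dict[str, int] = {"drug": 0, "gene": 1, "cell": 2}


@dataclass
class FalrtcConfig:
    """Completion hyperparameters.

    ``alpha`` holds the mode weights in (drug, gene, cell) axis order; they
    must be positive and sum to 1.  The default down-weights the gene mode
    by 100× relative to the drug and cell modes: (100, 1, 100)/201.
    ``shrinkage_tau`` gives the singular-value thresholds per mode in the
    same order; when None each τ defaults to ``tau_scale`` times the largest
    singular value of that mode's initial unfolding (a scale-free choice).
    ``init`` selects the fill for missing entries before the first
    iteration: a 2D-Mean warm start (default) or zeros.
    """

    alpha: tuple[float, float, float] = (100 / 201, 1 / 201, 100 / 201)
    shrinkage_tau: tuple[float, float, float] | None = None
    tau_scale: float = 0.1
    tol: float = 1e-5
    max_iter: int = 500
    init: str = "twod_mean"

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (3,) or np.any(a <= 0.0):
            raise ValueError("alpha must be 3 positive weights")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("alpha must sum to 1")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("zeros", "twod_mean"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class CompletionReport:
    iterations: int
    rel_change: float
    converged: bool
    trajectory: list[float] = field(default_factory=list)


def unfold(values: np.ndarray, mode: str) -> np.ndarray:
    """Mode-n matricization of a (D, G, C) array.

    The chosen mode's axis becomes the rows; the remaining axes index the
    columns with the earlier stored axis varying fastest.  drug-mode gives a
    D×(GC) matrix, gene-mode G×(DC), cell-mode C×(DG).
    """
    axis = MODES[mode]
    moved = np.moveaxis(values, axis, 0)
    return moved.reshape(moved.shape[0], -1, order="F")


def fold(m: np.ndarray, mode: str, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given (D, G, C) shape."""
    axis = MODES[mode]
    rest = [s for i, s in enumerate(shape) if i != axis]
    moved = m.reshape([shape[axis]] + rest, order="F")
    return np.moveaxis(moved, 0, axis)


def shrink_lowrank(m: np.ndarray, tau: float) -> np.ndarray:
    """Soft-threshold the singular values of ``m`` by ``tau`` — the proximal
    operator of the trace norm, the convex surrogate of matrix rank."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    try:
        U, s, Vt = np.linalg.svd(m, full_matrices=False)
    except np.linalg.LinAlgError as e:  # pragma: no cover - numerical edge
        raise np.linalg.LinAlgError(
            f"SVD failed on a {m.shape[0]}x{m.shape[1]} unfolding: {e}"
        ) from e
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def _initial_fill(t: DataTensor, cfg: FalrtcConfig) -> np.ndarray:
    if cfg.init == "zeros":
        return t.values.copy()
    pred, abstained = complete_tensor_baseline(t, "mean2d", BaselineConfig(0.5))
    if abstained.any():
        pred = np.where(np.isnan(pred), 0.0, pred)
    return pred


def complete_tensor_falrtc(
    t: DataTensor, cfg: FalrtcConfig | None = None
) -> tuple[np.ndarray, CompletionReport]:
    """Complete the tensor by iterated α-weighted spectral shrinkage.

    Each iteration replaces the working tensor X with

        X ← Σ_m α_m · fold_m( shrink(unfold_m(X), τ_m) )

    and then resets the observed profiles to their measured values, so the
    data are honored exactly at every step.  Iteration stops when the
    relative Frobenius change drops below ``cfg.tol`` or after
    ``cfg.max_iter`` sweeps; non-convergence is reported, never raised.

    Returns the completed (D, G, C) array (observed entries bit-identical to
    the input) and a :class:`CompletionReport`.
    """
    if cfg is None:
        cfg = FalrtcConfig()
    if t.n_observed == 0:
        raise ValueError("cannot complete a tensor with no observed profiles")
    shape = t.shape
    obs3 = np.broadcast_to(t.mask[:, None, :], shape)
    truth = t.values

    X = _initial_fill(t, cfg)
    X[obs3] = truth[obs3]

    if cfg.shrinkage_tau is not None:
        taus = dict(zip(MODES, cfg.shrinkage_tau))
    else:
        taus = {
            mode: cfg.tau_scale * np.linalg.svd(unfold(X, mode), compute_uv=False)[0]
            for mode in MODES
        }
    alphas = dict(zip(MODES, cfg.alpha))

    trajectory: list[float] = []
    converged = False
    rel = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        X_new = np.zeros_like(X)
        for mode in MODES:
            X_new += alphas[mode] * fold(
                shrink_lowrank(unfold(X, mode), taus[mode]), mode, shape
            )
        X_new[obs3] = truth[obs3]
        denom = max(np.linalg.norm(X), np.finfo(float).tiny)
        rel = float(np.linalg.norm(X_new - X) / denom)
        trajectory.append(rel)
        X = X_new
        if rel < cfg.tol:
            converged = True
            break
    return X, CompletionReport(
        iterations=it, rel_change=rel, converged=converged, trajectory=trajectory
    )
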