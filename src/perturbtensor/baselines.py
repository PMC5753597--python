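"""Averaging baselines for profile prediction.

1D-Mean predicts a drug's missing profile in a cell as the mean of that
drug's profiles across the cells where it was measured.  2D-Mean blends that
within-drug average with the within-cell average over drugs:

    2DMean(d, g, c; λ) = λ · mean_{d' ∈ D_c} T[d', g, c]
                       + (1 − λ) · mean_{c' ∈ C_d} T[d, g, c']

with λ = ½ by default.  When one of the two index sets is empty the other
term is used with full weight; when both are empty the predictor abstains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_build import DataTensor

__all__ = ["BaselineConfig", "mean_1d", "mean_2d", "complete_tensor_baseline"]


@dataclass
class BaselineConfig:
    lam: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")


def mean_1d(t: DataTensor, d: int, c: int) -> np.ndarray | None:
    """Within-drug average: mean profile of drug ``d`` over its observed
    cells.  ``c`` identifies the target but does not enter the average
    (held-out exclusion is the caller's masking responsibility).  Abstains
    (returns None) when the drug has no observations."""
    cells = t.cells_for_drug(d)
    if cells.size == 0:
        return None
    return t.values[d, :, cells].mean(axis=0)


def _cell_average(t: DataTensor, c: int) -> np.ndarray | None:
    drugs = t.drugs_for_cell(c)
    if drugs.size == 0:
        return None
    return t.values[drugs, :, c].mean(axis=0)


def mean_2d(
    t: DataTensor, d: int, c: int, cfg: BaselineConfig | None = None
) -> np.ndarray | None:
    """λ-blend of the within-cell drug average and the within-drug cell
    average; falls back to whichever term exists when the other is empty."""
    if cfg is None:
        cfg = BaselineConfig()
    across_drugs = _cell_average(t, c)
    across_cells = mean_1d(t, d, c)
    if across_drugs is None and across_cells is None:
        return None
    if across_drugs is None:
        return across_cells
    if across_cells is None:
        return across_drugs
    return cfg.lam * across_drugs + (1.0 - cfg.lam) * across_cells


def complete_tensor_baseline(
    t: DataTensor,
    method: str = "mean2d",
    cfg: BaselineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill every unobserved profile with the chosen baseline.

    Returns ``(pred, abstained)`` in the same convention as the other
    completion routines: observed entries copied through, abstentions NaN
    with the (D, C) abstention mask set.
    """
    if method not in ("mean1d", "mean2d"):
        raise ValueError(f"unknown baseline method {method!r}")
    D, G, C = t.shape
    pred = t.values.copy()
    abstained = np.zeros((D, C), dtype=bool)
    for d in range(D):
        for c in range(C):
            if t.mask[d, c]:
                continue
            if method == "mean1d":
                p = mean_1d(t, d, c)
            else:
                p = mean_2d(t, d, c, cfg)
            if p is None:
                pred[d, :, c] = np.nan
                abstained[d, c] = True
            else:
                pred[d, :, c] = p
    return pred, abstained
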