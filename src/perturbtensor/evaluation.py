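"""Evaluation machinery: profile-holdout cross-validation, correlation with
truth, differentially-expressed-gene ROC analysis, density experiments, winner
maps and per-drug cell-specificity.

Cross-validation holds out *entire* (drug, cell) profiles — never individual
genes — mirroring the real prediction task, where an unmeasured condition is
missing all of its genes at once.  Accuracy is summarized as the Pearson
correlation with truth (PCT): the element-wise correlation between measured
and predicted values pooled over any subset Ω of tensor entries, be that one
profile, one fold, or the whole tensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .baselines import BaselineConfig, complete_tensor_baseline
from .dnpp import DNPPConfig, complete_tensor_dnpp
from .falrtc import FalrtcConfig, complete_tensor_falrtc
from .tensor_build import DataTensor

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "EvalReport",
    "CompletionFn",
    "standard_methods",
    "withhold",
    "make_cv_folds",
    "pct",
    "profile_pct",
    "cross_validate",
    "deg_labels",
    "deg_roc",
    "winner_map",
    "density_experiment",
    "cell_specificity",
]

#: a completion routine: masked tensor → (prediction array, abstention mask)
CompletionFn = Callable[[DataTensor], tuple[np.ndarray, np.ndarray]]

Pair = tuple[int, int]


def standard_methods(
    dnpp_cfg: DNPPConfig | None = None,
    falrtc_cfg: FalrtcConfig | None = None,
    baseline_cfg: BaselineConfig | None = None,
) -> dict[str, CompletionFn]:
    """The four predictors under their canonical names (this ordering is
    also the documented tie-break order in :func:`winner_map`)."""
    return {
        "falrtc": lambda t: complete_falrtc_pair(t, falrtc_cfg),
        "dnpp": lambda t: complete_tensor_dnpp(t, dnpp_cfg),
        "mean2d": lambda t: complete_tensor_baseline(t, "mean2d", baseline_cfg),
        "mean1d": lambda t: complete_tensor_baseline(t, "mean1d", baseline_cfg),
    }


def complete_falrtc_pair(
    t: DataTensor, cfg: FalrtcConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Adapter giving FaLRTC the common (prediction, abstention) signature;
    the spectral method always predicts, so the abstention mask is empty."""
    pred, _report = complete_tensor_falrtc(t, cfg)
    return pred, np.zeros(t.mask.shape, dtype=bool)


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Disjoint folds of observed (drug, cell) pairs partitioning the mask."""

    folds: list[list[Pair]]
    k: int
    seed: int


def _fold_is_safe(t: DataTensor, fold: Sequence[Pair]) -> bool:
    """A fold is safe if masking it leaves every drug and cell that could
    keep an observation (i.e. has >= 2 in total) with at least one."""
    drug_total = t.mask.sum(axis=1)
    cell_total = t.mask.sum(axis=0)
    drug_held = np.zeros(len(t.drug_ids), dtype=int)
    cell_held = np.zeros(len(t.cell_ids), dtype=int)
    for d, c in fold:
        drug_held[d] += 1
        cell_held[c] += 1
    bad_drug = (drug_total >= 2) & (drug_held == drug_total)
    bad_cell = (cell_total >= 2) & (cell_held == cell_total)
    return not bad_drug.any() and not bad_cell.any()


def make_cv_folds(
    t: DataTensor, k: int = 10, seed: int = 0, max_redraws: int = 50
) -> CVPlan:
    """Randomly partition the observed profiles into ``k`` folds whose sizes
    differ by at most one.

    Re-draw rule: a candidate partition is rejected and redrawn (up to
    ``max_redraws`` times, advancing the generator) if any fold would strip a
    drug or cell of *all* its observations while it had two or more — losing
    every anchor point makes its held-out profiles unpredictable for every
    method.  Singleton drugs/cells are exempt (emptying them is unavoidable).
    The last draw is kept if no safe partition is found.
    """
    pairs = t.observed_pairs()
    n = len(pairs)
    if n < k:
        raise ValueError(f"{n} observed profiles cannot form {k} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[Pair]] = []
    for _ in range(max_redraws):
        perm = rng.permutation(n)
        folds = [
            [pairs[i] for i in perm[j::k]]
            for j in range(k)
        ]
        if all(_fold_is_safe(t, f) for f in folds):
            break
    else:
        logger.warning("no fully safe CV partition found in %d draws", max_redraws)
    return CVPlan(folds=folds, k=k, seed=seed)


def withhold(t: DataTensor, pairs: Sequence[Pair]) -> DataTensor:
    """A copy of ``t`` with the given profiles masked out (and zeroed), as
    presented to a prediction method during cross-validation."""
    out = t.copy()
    for d, c in pairs:
        if not out.mask[d, c]:
            raise ValueError(f"cannot withhold unobserved pair {(d, c)}")
        out.mask[d, c] = False
        out.values[d, :, c] = 0.0
    return out


# ---------------------------------------------------------------------------
# Pearson correlation with truth
# ---------------------------------------------------------------------------

def _pooled_entries(
    truth: DataTensor,
    pred: np.ndarray,
    pairs: Sequence[Pair],
    abstained: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    xs, ys = [], []
    skipped = 0
    for d, c in pairs:
        if abstained is not None and abstained[d, c]:
            skipped += 1
            continue
        p = pred[d, :, c]
        if np.any(np.isnan(p)):
            skipped += 1
            continue
        xs.append(truth.values[d, :, c])
        ys.append(p)
    if skipped:
        logger.info("PCT pooling skipped %d abstained/undefined profiles", skipped)
    if not xs:
        return np.empty(0), np.empty(0), skipped
    return np.concatenate(xs), np.concatenate(ys), skipped


def pct(
    truth: DataTensor,
    pred: np.ndarray,
    pairs: Sequence[Pair],
    abstained: np.ndarray | None = None,
) -> float:
    """PCT_Ω: element-wise Pearson correlation between truth and prediction
    pooled over all genes of the profiles in Ω.

    Abstained or NaN profiles are skipped (with a logged count); a constant
    pooled vector makes the correlation undefined and returns NaN.
    """
    if len(pairs) == 0:
        raise ValueError("omega must be non-empty")
    x, y, _ = _pooled_entries(truth, pred, pairs, abstained)
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def profile_pct(
    truth: DataTensor,
    pred: np.ndarray,
    pairs: Sequence[Pair],
    abstained: np.ndarray | None = None,
) -> dict[Pair, float]:
    """Per-profile PCT for each pair in Ω (NaN for abstained/undefined)."""
    out: dict[Pair, float] = {}
    for d, c in pairs:
        if abstained is not None and abstained[d, c]:
            out[(d, c)] = float("nan")
            continue
        out[(d, c)] = pct(truth, pred, [(d, c)])
    return out


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Cross-validated accuracy for one or more methods.

    ``predictions[m]`` is a (D, G, C) tensor holding method ``m``'s held-out
    predictions compiled across folds (NaN where unpredicted/abstained),
    matching the observed pattern of the input tensor.
    """

    pct_overall: dict[str, float]
    pct_per_fold: dict[str, list[float]]
    pct_per_profile: dict[str, dict[Pair, float]]
    predictions: dict[str, np.ndarray]
    abstained: dict[str, np.ndarray]
    plan: CVPlan


def cross_validate(
    t: DataTensor,
    methods: Mapping[str, CompletionFn],
    k: int = 10,
    seed: int = 0,
    plan: CVPlan | None = None,
) -> EvalReport:
    """Hold out each fold of whole profiles, predict it with every method,
    and compile the held-out predictions into one tensor per method."""
    if plan is None:
        plan = make_cv_folds(t, k=k, seed=seed)
    D, G, C = t.shape
    predictions = {m: np.full((D, G, C), np.nan) for m in methods}
    abstained = {m: np.zeros((D, C), dtype=bool) for m in methods}
    pct_per_fold: dict[str, list[float]] = {m: [] for m in methods}

    for fold in plan.folds:
        masked = withhold(t, fold)
        for name, fn in methods.items():
            pred, abst = fn(masked)
            for d, c in fold:
                predictions[name][d, :, c] = pred[d, :, c]
                abstained[name][d, c] = abst[d, c]
            pct_per_fold[name].append(pct(t, pred, fold, abst))

    all_pairs = [p for fold in plan.folds for p in fold]
    pct_overall = {
        m: pct(t, predictions[m], all_pairs, abstained[m]) for m in methods
    }
    pct_per_profile = {
        m: profile_pct(t, predictions[m], all_pairs, abstained[m]) for m in methods
    }
    return EvalReport(
        pct_overall=pct_overall,
        pct_per_fold=pct_per_fold,
        pct_per_profile=pct_per_profile,
        predictions=predictions,
        abstained=abstained,
        plan=plan,
    )


# ---------------------------------------------------------------------------
# Differentially-expressed-gene ROC
# ---------------------------------------------------------------------------

def deg_labels(profile: np.ndarray, p: float) -> np.ndarray:
    """Boolean DEG labels: a gene is differentially expressed when its
    absolute signature value is at or above the (100 − p)-th percentile of
    the profile's absolute values (linear-interpolation percentile), so that
    roughly p% of genes are flagged."""
    if not (0.0 < p < 100.0):
        raise ValueError("percentile p must lie in (0, 100)")
    a = np.abs(np.asarray(profile, dtype=float))
    thresh = np.percentile(a, 100.0 - p)
    return a >= thresh


def _percentile_scores(profile: np.ndarray) -> np.ndarray:
    """Within-profile percentile rank of |value| — the score swept by the
    pooled ROC so one global threshold means the same percentile cut in
    every profile."""
    a = np.abs(np.asarray(profile, dtype=float))
    return 100.0 * rankdata(a, method="average") / a.size


def deg_roc(
    truth: DataTensor,
    pred: np.ndarray,
    pairs: Sequence[Pair],
    p: float,
    abstained: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled (micro-averaged) ROC for DEG recovery at truth percentile ``p``.

    For every evaluated profile, "true" DEGs come from :func:`deg_labels` on
    the measured profile; predictions are scored by their within-profile
    percentile of absolute value and a single threshold is swept from 0 to
    100, pooling TP/FP/TN/FN across profiles.  Returns (fpr, tpr, auc) with
    the trapezoidal area under the pooled curve.
    """
    labels, scores = [], []
    for d, c in pairs:
        if abstained is not None and abstained[d, c]:
            continue
        pr = pred[d, :, c]
        if np.any(np.isnan(pr)):
            continue
        labels.append(deg_labels(truth.values[d, :, c], p))
        scores.append(_percentile_scores(pr))
    if not labels:
        raise ValueError("no evaluable profiles for ROC")
    y = np.concatenate(labels)
    s = np.concatenate(scores)
    if not y.any():
        raise ValueError("no positive DEG labels in any profile")
    fpr, tpr, _ = _roc_curve(y, s)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# Winner map, density experiment, cell-specificity
# ---------------------------------------------------------------------------

def winner_map(
    truth: DataTensor,
    preds: Mapping[str, tuple[np.ndarray, np.ndarray]],
    pairs: Sequence[Pair],
) -> dict[Pair, str]:
    """Per held-out profile, the method with the highest per-profile PCT.

    Ties are broken by the iteration order of ``preds`` (document your
    ordering); abstained or undefined predictions rank below any finite PCT.
    """
    if len(preds) < 2:
        raise ValueError("winner_map needs at least 2 methods")
    winners: dict[Pair, str] = {}
    for pair in pairs:
        best_name, best_val = None, -np.inf
        for name, (pred, abst) in preds.items():
            v = float("nan")
            if abst is None or not abst[pair]:
                v = pct(truth, pred, [pair])
            score = v if np.isfinite(v) else -np.inf
            if score > best_val:
                best_name, best_val = name, score
        winners[pair] = best_name if best_name is not None else next(iter(preds))
    return winners


def density_experiment(
    t: DataTensor,
    densities: Sequence[float],
    methods: Mapping[str, CompletionFn],
    reps: int = 25,
    seed: int = 0,
    eval_fraction: float = 0.1,
) -> pd.DataFrame:
    """Accuracy as a function of observation density.

    For each repetition: hold out ``eval_fraction`` of the observed profiles
    as the evaluation set, then for each target density subsample the
    remaining observed profiles down to ``floor(density · D · C)`` training
    profiles, run every method, and record the held-out PCT.  Densities that
    exceed the available training pool are skipped with a warning.

    Returns a tidy DataFrame with columns (density, method, rep, pct) plus
    mean/sd obtainable by grouping.
    """
    rng = np.random.default_rng(seed)
    D, _, C = t.shape
    pairs = t.observed_pairs()
    n = len(pairs)
    n_eval = max(1, int(round(eval_fraction * n)))
    rows = []
    for rep in range(reps):
        perm = rng.permutation(n)
        eval_pairs = [pairs[i] for i in perm[:n_eval]]
        train_pool = [pairs[i] for i in perm[n_eval:]]
        for density in densities:
            n_train = int(np.floor(density * D * C))
            if n_train > len(train_pool):
                logger.warning(
                    "density %.2f needs %d training profiles, only %d available; skipped",
                    density, n_train, len(train_pool),
                )
                continue
            keep = set(
                tuple(train_pool[i])
                for i in rng.choice(len(train_pool), size=n_train, replace=False)
            )
            drop = [pr for pr in pairs if pr not in keep]
            masked = withhold(t, drop)
            for name, fn in methods.items():
                pred, abst = fn(masked)
                rows.append(
                    {
                        "density": density,
                        "method": name,
                        "rep": rep,
                        "pct": pct(t, pred, eval_pairs, abst),
                    }
                )
    return pd.DataFrame(rows)


def cell_specificity(t: DataTensor, d: int) -> float:
    """Mean pairwise cosine distance between a drug's profiles across its
    observed cells: 0 when the response is identical in every cell, up to 2
    for perfectly anti-correlated responses.  NaN when the drug is observed
    in fewer than two cells."""
    cells = t.cells_for_drug(d)
    if cells.size < 2:
        return float("nan")
    X = t.values[d, :, cells]
    norms = np.linalg.norm(X, axis=1)
    U = X / norms[:, None]
    sims = U @ U.T
    iu = np.triu_indices(len(cells), 1)
    return float(np.mean(1.0 - sims[iu]))
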