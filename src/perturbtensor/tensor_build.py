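"""Assemble a drugs × genes × cells signature tensor from per-experiment records.

The pipeline ingests one characteristic-direction (CD) signature per
(drug, cell, dose, time, batch) experiment together with a replicate-consistency
p-value (ACD p-value, see :mod:`perturbtensor.qc`), filters out unreliable or
sparsely sampled experiments, collapses doses and time points into one unit-norm
profile per (drug, cell) condition, and arranges the profiles into a 3-way
array ``T`` with ``T[d, g, c]`` the value of gene ``g`` for drug ``d`` in cell
``c``.  Missingness is column-structured: a (drug, cell) profile is either
fully observed or fully absent, recorded in a drugs × cells boolean mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentRecord",
    "CDProfile",
    "DataTensor",
    "FilterConfig",
    "AllDataFilteredError",
    "filter_experiments",
    "collapse_conditions",
    "build_tensor",
    "extract_profiles",
    "observation_density",
]

UNIT_NORM_TOL = 1e-8


class AllDataFilteredError(ValueError):
    """Raised when quality filtering leaves no experiments at all."""


@dataclass
class ExperimentRecord:
    """One replicate-averaged CD signature for a single experiment.

    ``values`` is the length-G signature vector; ``acd_pvalue`` is the
    empirical replicate-consistency p-value (smaller = more reproducible),
    or ``None`` when no replicate information was available.
    """

    drug_id: str
    cell_id: str
    values: np.ndarray
    acd_pvalue: float | None = None
    dose: str | None = None
    time: str | None = None
    batch_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signature values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-finite signature values for drug={self.drug_id!r} "
                f"cell={self.cell_id!r}"
            )
        if self.acd_pvalue is not None and not (0.0 <= self.acd_pvalue <= 1.0):
            raise ValueError(f"acd_pvalue {self.acd_pvalue} outside [0, 1]")


@dataclass
class CDProfile:
    """A unit-norm differential-expression profile for one (drug, cell) pair."""

    drug_id: str
    cell_id: str
    values: np.ndarray
    n_source_experiments: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        norm = float(np.linalg.norm(self.values))
        if abs(norm - 1.0) > UNIT_NORM_TOL:
            raise ValueError(
                f"profile ({self.drug_id}, {self.cell_id}) has norm {norm:.6g}, "
                "expected unit norm"
            )
        if self.n_source_experiments < 1:
            raise ValueError("n_source_experiments must be positive")


@dataclass
class FilterConfig:
    """Quality-filter thresholds: maximum ACD p-value and the minimum number
    of surviving experiments a drug or cell must retain."""

    acd_p_max: float = 0.1
    min_experiments: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.acd_p_max <= 1.0):
            raise ValueError("acd_p_max must lie in (0, 1]")
        if self.min_experiments < 1:
            raise ValueError("min_experiments must be >= 1")


@dataclass
class DataTensor:
    """Drugs × genes × cells signature tensor with a profile-level mask.

    ``values`` has shape (D, G, C); ``mask`` has shape (D, C) and is ``True``
    exactly where a (drug, cell) profile was measured.  Unobserved profiles
    are stored as zeros and must never be interpreted as data.
    """

    drug_ids: list[str]
    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        D, G, C = len(self.drug_ids), len(self.gene_ids), len(self.cell_ids)
        if self.values.shape != (D, G, C):
            raise ValueError(
                f"values shape {self.values.shape} != ({D}, {G}, {C})"
            )
        if self.mask.shape != (D, C):
            raise ValueError(f"mask shape {self.mask.shape} != ({D}, {C})")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def profile(self, d: int, c: int) -> np.ndarray:
        """The length-G profile for drug index ``d`` in cell index ``c``."""
        return self.values[d, :, c]

    def cells_for_drug(self, d: int) -> np.ndarray:
        """Indices of cells in which drug ``d`` was measured (C_d)."""
        return np.flatnonzero(self.mask[d, :])

    def drugs_for_cell(self, c: int) -> np.ndarray:
        """Indices of drugs measured in cell ``c`` (D_c)."""
        return np.flatnonzero(self.mask[:, c])

    def observed_pairs(self) -> list[tuple[int, int]]:
        """All observed (drug index, cell index) pairs in row-major order."""
        dd, cc = np.nonzero(self.mask)
        return list(zip(dd.tolist(), cc.tolist()))

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def cell_index(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)

    def copy(self) -> "DataTensor":
        return DataTensor(
            list(self.drug_ids),
            list(self.gene_ids),
            list(self.cell_ids),
            self.values.copy(),
            self.mask.copy(),
        )

    def validate(self) -> None:
        """Check the structural invariants: unit-norm observed profiles and
        zeroed unobserved profiles."""
        for d, c in self.observed_pairs():
            norm = float(np.linalg.norm(self.values[d, :, c]))
            if abs(norm - 1.0) > UNIT_NORM_TOL:
                raise ValueError(
                    f"observed profile ({self.drug_ids[d]}, {self.cell_ids[c]}) "
                    f"has norm {norm:.6g}"
                )
        if np.any(self.values[~self.mask[:, None, :].repeat(len(self.gene_ids), axis=1)]):
            raise ValueError("unobserved profiles must be stored as zeros")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _canonicalize(records: Iterable[ExperimentRecord],
                  synonyms: Mapping[str, str] | None) -> list[ExperimentRecord]:
    if not synonyms:
        return list(records)
    out = []
    for r in records:
        canon = synonyms.get(r.drug_id, r.drug_id)
        if canon != r.drug_id:
            r = ExperimentRecord(canon, r.cell_id, r.values, r.acd_pvalue,
                                 r.dose, r.time, r.batch_id)
        out.append(r)
    return out


def filter_experiments(
    records: Sequence[ExperimentRecord],
    cfg: FilterConfig | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[ExperimentRecord]:
    """Apply the reliability and coverage filters to experiment records.

    Steps, in order:

    1. map duplicate drug identifiers to one canonical id via ``synonyms``
       (default: exact-string identity, i.e. no merging);
    2. drop records whose ACD p-value is missing (logged) or exceeds
       ``cfg.acd_p_max``;
    3. iteratively remove every record belonging to a drug or a cell with
       fewer than ``cfg.min_experiments`` remaining records, until no further
       removal occurs (removing a drug can push a cell below threshold and
       vice versa, so the two prunes run jointly to a fixed point).

    Raises
    ------
    AllDataFilteredError
        if no record survives.
    """
    if not records:
        raise ValueError("no experiment records supplied")
    if cfg is None:
        cfg = FilterConfig()
    lengths = {len(r.values) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent signature lengths: {sorted(lengths)}")

    recs = _canonicalize(records, synonyms)

    n_missing_p = sum(1 for r in recs if r.acd_pvalue is None)
    if n_missing_p:
        logger.info("dropping %d records lacking an ACD p-value", n_missing_p)
    recs = [r for r in recs
            if r.acd_pvalue is not None and r.acd_pvalue <= cfg.acd_p_max]
    if not recs:
        raise AllDataFilteredError(
            f"no experiments with ACD p <= {cfg.acd_p_max}"
        )

    # joint drug/cell pruning to a fixed point
    while True:
        drug_counts: dict[str, int] = {}
        cell_counts: dict[str, int] = {}
        for r in recs:
            drug_counts[r.drug_id] = drug_counts.get(r.drug_id, 0) + 1
            cell_counts[r.cell_id] = cell_counts.get(r.cell_id, 0) + 1
        bad_drugs = {d for d, n in drug_counts.items() if n < cfg.min_experiments}
        bad_cells = {c for c, n in cell_counts.items() if n < cfg.min_experiments}
        if not bad_drugs and not bad_cells:
            break
        recs = [r for r in recs
                if r.drug_id not in bad_drugs and r.cell_id not in bad_cells]
        if not recs:
            raise AllDataFilteredError(
                "coverage pruning removed all experiments"
            )
    return recs


# ---------------------------------------------------------------------------
# Condition collapsing
# ---------------------------------------------------------------------------

def collapse_conditions(records: Sequence[ExperimentRecord]) -> list[CDProfile]:
    """Average each (drug, cell) pair's signatures over doses, time points and
    batches, then renormalize the mean to unit Euclidean norm.

    Pairs whose mean vector has zero norm (mutually cancelling signatures)
    cannot be renormalized and are dropped with a warning.
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    order: list[tuple[str, str]] = []
    for r in records:
        key = (r.drug_id, r.cell_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r.values)

    profiles: list[CDProfile] = []
    for key in order:
        vs = groups[key]
        mean = np.mean(vs, axis=0)
        norm = float(np.linalg.norm(mean))
        if norm == 0.0:
            logger.warning(
                "dropping (%s, %s): zero-norm mean of %d signatures",
                key[0], key[1], len(vs),
            )
            continue
        profiles.append(
            CDProfile(key[0], key[1], mean / norm, n_source_experiments=len(vs))
        )
    return profiles


# ---------------------------------------------------------------------------
# Tensor assembly
# ---------------------------------------------------------------------------

def build_tensor(
    profiles: Sequence[CDProfile],
    gene_ids: Sequence[str] | None = None,
) -> DataTensor:
    """Arrange (drug, cell) profiles into a drugs × genes × cells tensor.

    Drug and cell axes are ordered lexicographically by id for determinism.
    Gene ids default to ``g0000 .. g{G-1}`` when not supplied.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    seen: set[tuple[str, str]] = set()
    for p in profiles:
        key = (p.drug_id, p.cell_id)
        if key in seen:
            raise ValueError(f"duplicate profile for (drug={key[0]!r}, cell={key[1]!r})")
        seen.add(key)

    G = len(profiles[0].values)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(G)]
    elif len(gene_ids) != G:
        raise ValueError("gene_ids length does not match profile length")

    drug_ids = sorted({p.drug_id for p in profiles})
    cell_ids = sorted({p.cell_id for p in profiles})
    d_idx = {d: i for i, d in enumerate(drug_ids)}
    c_idx = {c: i for i, c in enumerate(cell_ids)}

    values = np.zeros((len(drug_ids), G, len(cell_ids)))
    mask = np.zeros((len(drug_ids), len(cell_ids)), dtype=bool)
    for p in profiles:
        values[d_idx[p.drug_id], :, c_idx[p.cell_id]] = p.values
        mask[d_idx[p.drug_id], c_idx[p.cell_id]] = True
    return DataTensor(drug_ids, list(gene_ids), cell_ids, values, mask)


def extract_profiles(t: DataTensor) -> list[CDProfile]:
    """Inverse of :func:`build_tensor`: recover the observed profiles."""
    return [
        CDProfile(t.drug_ids[d], t.cell_ids[c], t.values[d, :, c].copy())
        for d, c in t.observed_pairs()
    ]


def observation_density(t: DataTensor) -> float:
    """Fraction of (drug, cell) pairs with a measured profile."""
    D, _, C = t.shape
    return t.n_observed / (D * C)
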