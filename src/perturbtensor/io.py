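"""Text I/O: GCT-dialect signature matrices, experiment metadata tables, and
the on-disk tensor format (a genes × "drug::cell" GCT plus a 0/1 mask TSV).

Floats are written with 17 significant digits so that write → read
round-trips are bit-exact for IEEE double precision.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor_build import DataTensor, ExperimentRecord

__all__ = [
    "read_gct",
    "write_gct",
    "read_signature_matrix",
    "read_metadata",
    "load_experiment_records",
    "write_tensor",
    "read_tensor",
]

_FLOAT_FMT = "%.17g"


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a #1.2/#1.3 GCT text matrix into a genes × samples DataFrame
    (the Description column is dropped)."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: not a GCT file (header {version!r})")
        dims = fh.readline().split()
        nrow, ncol = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    df = df.drop(columns=[c for c in ("Description", "desc") if c in df.columns])
    if df.shape != (nrow, ncol):
        raise ValueError(
            f"{path}: declared {nrow}x{ncol}, found {df.shape[0]}x{df.shape[1]}"
        )
    return df.astype(float)


def write_gct(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes × samples DataFrame as a #1.2 GCT text matrix."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            vals = "\t".join(_FLOAT_FMT % v for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × experiments matrix: GCT dialect when the first line is
    a #1.x version tag, otherwise a plain TSV with a header of experiment
    ids and gene ids in the first column."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1."):
        return read_gct(path)
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip").astype(float)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the experiment metadata TSV (one row per experiment, indexed by
    the first column of experiment ids).  Required columns: drug_id,
    cell_id, acd_pvalue; optional: dose, time, batch_id."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    missing = {"drug_id", "cell_id", "acd_pvalue"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    return meta


def load_experiment_records(
    signatures: str | Path, metadata: str | Path
) -> list[ExperimentRecord]:
    """Join a signature matrix with its metadata into ExperimentRecords.

    Matrix columns and metadata rows are matched by experiment id; an
    experiment present in only one of the two files is an error.
    """
    sig = read_signature_matrix(signatures)
    meta = read_metadata(metadata)
    sig_ids = set(map(str, sig.columns))
    meta_ids = set(map(str, meta.index))
    if sig_ids != meta_ids:
        odd = sorted(sig_ids ^ meta_ids)[:5]
        raise ValueError(f"experiment ids disagree between files, e.g. {odd}")
    records = []
    for exp_id in map(str, sig.columns):
        row = meta.loc[exp_id]
        p = row["acd_pvalue"]
        records.append(
            ExperimentRecord(
                drug_id=str(row["drug_id"]),
                cell_id=str(row["cell_id"]),
                values=sig[exp_id].to_numpy(),
                acd_pvalue=None if (p is None or (isinstance(p, float) and math.isnan(p))) else float(p),
                dose=str(row["dose"]) if "dose" in meta.columns else None,
                time=str(row["time"]) if "time" in meta.columns else None,
                batch_id=str(row["batch_id"]) if "batch_id" in meta.columns else None,
            )
        )
    return records


def write_tensor(t: DataTensor, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a tensor as ``<prefix>.gct`` (genes × observed
    "drug_id::cell_id" profiles) and ``<prefix>.mask.tsv`` (drug rows, cell
    columns, 0/1).  Round-trips bit-exactly through :func:`read_tensor`."""
    prefix = Path(prefix)
    cols = {}
    for d, c in t.observed_pairs():
        cols[f"{t.drug_ids[d]}::{t.cell_ids[c]}"] = t.values[d, :, c]
    df = pd.DataFrame(cols, index=t.gene_ids)
    gct_path = prefix.with_suffix(".gct")
    write_gct(df, gct_path)
    mask_df = pd.DataFrame(
        t.mask.astype(int), index=t.drug_ids, columns=t.cell_ids
    )
    mask_path = Path(str(prefix) + ".mask.tsv")
    mask_df.to_csv(mask_path, sep="\t")
    return gct_path, mask_path


def read_tensor(prefix: str | Path) -> DataTensor:
    """Load a tensor written by :func:`write_tensor`."""
    prefix = Path(prefix)
    df = read_gct(prefix.with_suffix(".gct"))
    mask_df = pd.read_csv(Path(str(prefix) + ".mask.tsv"), sep="\t", index_col=0)
    drug_ids = [str(d) for d in mask_df.index]
    cell_ids = [str(c) for c in mask_df.columns]
    gene_ids = [str(g) for g in df.index]
    mask = mask_df.to_numpy().astype(bool)
    values = np.zeros((len(drug_ids), len(gene_ids), len(cell_ids)))
    d_idx = {d: i for i, d in enumerate(drug_ids)}
    c_idx = {c: i for i, c in enumerate(cell_ids)}
    for col in df.columns:
        drug, _, cell = str(col).partition("::")
        values[d_idx[drug], :, c_idx[cell]] = df[col].to_numpy()
    return DataTensor(drug_ids, gene_ids, cell_ids, values, mask)
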