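"""Core containers and file formats for the atlas pipeline.

Counts live in a genes x cells sparse matrix with a declared normalization
state; cell metadata is a plain pandas table; peaks are BED-style intervals
(0-based, half-open) everywhere internally.  All readers validate shape and
header agreement and raise a named error rather than silently truncating.
"""
from __future__ import annotations

import dataclasses
import enum
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

log = logging.getLogger("retina_atlas")

LOCATIONS = ("macula", "periphery", "whole")

CELL_TABLE_COLUMNS = ("cell_id", "age_days", "pcw_group", "location", "major_class")


class NormState(str, enum.Enum):
    """Normalization state of a count matrix."""

    RAW = "raw"
    CPM = "cpm"
    LOG1P_CPM = "log1p_cpm"
    SCALED = "scaled"


class FormatError(ValueError):
    """Raised when an on-disk input does not match its declared format."""


@dataclasses.dataclass
class CountMatrix:
    """Sparse genes x cells matrix with row/column names and a state tag.

    ``matrix`` is genes x cells; column order must match the cell table it is
    paired with.  ``state`` records how values are to be interpreted: raw
    integer counts, counts per million, natural-log CPM, or z-scaled.
    """

    matrix: sp.csr_matrix
    genes: list
    cells: list
    state: NormState = NormState.RAW

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        self.state = NormState(self.state)
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if (
            self.state in (NormState.RAW, NormState.CPM)
            and self.matrix.nnz
            and self.matrix.data.min() < 0
        ):
            raise FormatError("count matrix contains negative entries")

    @property
    def shape(self):
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.matrix[:, idx],
            self.genes,
            [self.cells[i] for i in idx],
            self.state,
        )


def read_counts(mtx_path, genes_path, cells_path) -> CountMatrix:
    """Read a MatrixMarket counts file with sidecar gene/cell name files.

    Raw entries must be integers; dimension mismatches between the matrix and
    the name files raise :class:`FormatError`.
    """
    try:
        m = mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    m = sp.csr_matrix(m)
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    if m.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx_path}: shape {m.shape} disagrees with "
            f"{len(genes)} genes / {len(cells)} cells"
        )
    if m.nnz and not np.allclose(m.data, np.round(m.data)):
        raise FormatError(f"{mtx_path}: raw counts must be integers")
    return CountMatrix(m, genes, cells, NormState.RAW)


def write_counts(cm: CountMatrix, mtx_path, genes_path, cells_path) -> None:
    mmwrite(str(mtx_path), sp.coo_matrix(cm.matrix))
    Path(genes_path).write_text("\n".join(map(str, cm.genes)) + "\n")
    Path(cells_path).write_text("\n".join(map(str, cm.cells)) + "\n")


def normalize(cm: CountMatrix, target: NormState | str = NormState.LOG1P_CPM) -> CountMatrix:
    """Normalize raw counts to CPM or natural-log CPM.

    CPM divides each column by its total and scales to 1e6.  All-zero columns
    are left all-zero and flagged with a warning rather than dropped.
    """
    target = NormState(target)
    if cm.state != NormState.RAW:
        raise ValueError(f"normalize expects raw counts, got state={cm.state.value}")
    if target == NormState.RAW:
        return cm
    m = sp.csc_matrix(cm.matrix, dtype=float)
    colsums = np.asarray(m.sum(axis=0)).ravel()
    zero = colsums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cells left unnormalized", stacklevel=2
        )
    scale = np.ones_like(colsums)
    nz = ~zero
    scale[nz] = 1e6 / colsums[nz]
    m = m.multiply(sp.csr_matrix(scale)).tocsr()
    if target == NormState.CPM:
        return CountMatrix(m, cm.genes, cm.cells, NormState.CPM)
    if target == NormState.LOG1P_CPM:
        m = m.copy()
        m.data = np.log1p(m.data)
        return CountMatrix(m, cm.genes, cm.cells, NormState.LOG1P_CPM)
    raise ValueError(f"unsupported normalization target {target}")


# ---------------------------------------------------------------------------
# Cell metadata table


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell metadata invariants and return the table.

    Required columns: cell_id (unique), age_days (positive int), pcw_group,
    location (macula/periphery/whole), major_class.  Optional: subclass,
    latent_time in [0, 1], sample_id, cluster, fate.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing columns {missing}")
    if df["cell_id"].duplicated().any():
        raise FormatError("cell_id values are not unique")
    if (df["age_days"] <= 0).any():
        raise FormatError("age_days must be positive")
    bad_loc = set(df["location"].unique()) - set(LOCATIONS)
    if bad_loc:
        raise FormatError(f"unknown locations {sorted(bad_loc)}")
    if "latent_time" in df.columns:
        lt = df["latent_time"].dropna()
        if len(lt) and ((lt < 0).any() or (lt > 1).any()):
            raise FormatError("latent_time outside [0, 1]")
    return df


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path) -> None:
    validate_cell_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peaks (BED6, 0-based half-open)


def validate_peaks(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("peak_id", "contig", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"peak set missing column {col!r}")
    if (df["start"] >= df["end"]).any():
        raise FormatError("peak intervals must satisfy start < end")
    if df["peak_id"].duplicated().any():
        raise FormatError("duplicate peak_ids")
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "peak_id", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    df = df[["peak_id", "contig", "start", "end", "score", "strand"]]
    return validate_peaks(df)


def write_bed(peaks: pd.DataFrame, path) -> None:
    validate_peaks(peaks)
    out = pd.DataFrame(
        {
            "contig": peaks["contig"],
            "start": peaks["start"],
            "end": peaks["end"],
            "peak_id": peaks["peak_id"],
            "score": peaks.get("score", pd.Series(0, index=peaks.index)),
            "strand": peaks.get("strand", pd.Series(".", index=peaks.index)),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Small config / result helpers


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} is not a YAML mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
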