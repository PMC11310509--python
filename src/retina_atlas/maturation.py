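"""Maturation scoring against an adult reference.

For one major class, developmental and adult cells are pooled, embedded with
the top principal components of the pooled expression matrix, and each
(location, PCW group) of developmental cells is scored by the Pearson
correlation between its mean embedding vector and the adult mean embedding
vector.  Scores live in [-1, 1]; 1 means the group's average transcriptome
sits where the adult average sits.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CountMatrix, NormState


@dataclasses.dataclass
class MaturationResult:
    major_class: str
    location: str
    pcw_group: int
    score: float  # NaN when the group is below the minimum cell count
    n_cells: int


def _pooled_embedding(dev_X, adult_X, n_pcs, n_hvg):
    """Center pooled matrix, select HVGs, project on top principal axes."""
    pooled = np.vstack([dev_X, adult_X])
    var = pooled.var(axis=0)
    if n_hvg and n_hvg < pooled.shape[1]:
        keep = np.argsort(var)[::-1][:n_hvg]
        pooled = pooled[:, keep]
        var = var[keep]
    informative = int((var > 0).sum())
    if informative < 2:
        raise ValueError("fewer than 2 informative components in pooled matrix")
    n_pcs = min(n_pcs, pooled.shape[0] - 1, informative)
    pooled = pooled - pooled.mean(axis=0, keepdims=True)
    # deterministic full SVD; matrices at this stage are modest
    _, _, vt = np.linalg.svd(pooled, full_matrices=False)
    comps = vt[:n_pcs]
    # canonical component signs (largest |loading| positive) so the score
    # does not depend on cell order via arbitrary SVD sign choices
    flips = np.sign(comps[np.arange(n_pcs), np.abs(comps).argmax(axis=1)])
    comps = comps * flips[:, None]
    emb = pooled @ comps.T
    return emb[: dev_X.shape[0]], emb[dev_X.shape[0]:]


def maturation_scores(
    dev_counts: CountMatrix,
    dev_cells: pd.DataFrame,
    adult_counts: CountMatrix,
    adult_labels,
    major_class: str,
    n_pcs: int = 50,
    n_hvg: int = 2000,
    min_cells: int = 100,
) -> list[MaturationResult]:
    """Score each (location, PCW group) of a class against the adult mean.

    Both count matrices must be log1p-CPM normalized and share the same gene
    order.  Groups below ``min_cells`` are emitted with a missing score.
    """
    if dev_counts.state != NormState.LOG1P_CPM or adult_counts.state != NormState.LOG1P_CPM:
        raise ValueError("maturation_scores expects log1p_cpm-normalized matrices")
    if dev_counts.genes != adult_counts.genes:
        raise ValueError("developmental and adult matrices must share gene order")
    adult_labels = np.asarray(adult_labels)
    adult_mask = adult_labels == major_class
    if not adult_mask.any():
        raise ValueError(f"class {major_class!r} absent from adult reference")
    dev_mask = (dev_cells["major_class"] == major_class).to_numpy()
    if not dev_mask.any():
        return []

    dev_X = dev_counts.dense().T[dev_mask]  # cells x genes
    adult_X = adult_counts.dense().T[adult_mask]
    dev_emb, adult_emb = _pooled_embedding(dev_X, adult_X, n_pcs, n_hvg)
    adult_mean = adult_emb.mean(axis=0)

    sub = dev_cells.loc[dev_mask, ["location", "pcw_group"]].reset_index(drop=True)
    results = []
    for (location, pcw), idx in sorted(sub.groupby(["location", "pcw_group"]).indices.items()):
        n = len(idx)
        if n < min_cells:
            score = float("nan")
        else:
            gmean = dev_emb[idx].mean(axis=0)
            score = float(np.corrcoef(adult_mean, gmean)[0, 1])
        results.append(MaturationResult(major_class, location, int(pcw), score, n))
    return results


def maturation_table(results: list[MaturationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
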