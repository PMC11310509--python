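"""Cell-fate inference on a combined velocity + connectivity kernel.

The transition kernel is a convex combination of (1) a velocity kernel in
which each cell's transition mass over its k nearest neighbors follows a
softmax of the cosine between its velocity vector and the neighbor
displacement, and (2) a similarity (connectivity) kernel from the symmetrized
kNN graph; the velocity kernel carries 0.8 of the weight by default.
Terminal fates are explicit cell sets; making them absorbing turns the chain
into an absorbing Markov chain whose fundamental-matrix solution
``B = (I - Q)^-1 R`` gives per-cell absorption (fate) probabilities.
Cluster-level fates are the argmax of mean fate probability when it clears a
threshold.  Transcription-factor fate specification is predicted by the fate
group with the highest mean normalized expression and validated against a
literature annotation table.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order
from scipy.sparse.linalg import spsolve
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, NormState

log = logging.getLogger("retina_atlas")


@dataclasses.dataclass
class TransitionModel:
    matrix: sp.csr_matrix  # row-stochastic
    terminal_sets: dict  # fate -> np.ndarray of cell indices
    k: int | None = None
    w_vel: float | None = None

    def __post_init__(self):
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.abs(rows - 1).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1 (tol 1e-9)")
        seen = set()
        for fate, idx in self.terminal_sets.items():
            idx = set(np.asarray(idx).tolist())
            if not idx:
                raise ValueError(f"terminal set {fate!r} is empty")
            if idx & seen:
                raise ValueError("terminal sets must be disjoint")
            seen |= idx


@dataclasses.dataclass
class FateProbabilities:
    probabilities: pd.DataFrame  # cells x fates; rows sum to 1 (NaN if unreachable)
    unreachable: np.ndarray  # indices of transient cells with no path to a terminal


def _knn_indices(embedding: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return idx[:, 1:]  # drop self


def velocity_kernel(
    embedding: np.ndarray,
    velocities: np.ndarray,
    k: int = 30,
    tau: float = 1.0,
) -> sp.csr_matrix:
    """Row-stochastic kernel: mass over kNN ∝ exp(cos(v_i, x_j - x_i) / tau).

    Cells with zero-length velocity get a uniform row over their neighbors
    (logged).
    """
    embedding = np.asarray(embedding, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if embedding.shape != velocities.shape:
        raise ValueError("embedding and velocities must have matching shapes")
    n = embedding.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    k = min(k, n - 1)
    nbrs = _knn_indices(embedding, k)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    disp = embedding[cols] - embedding[rows]  # (n*k, d)
    v = velocities[rows]
    vn = np.linalg.norm(v, axis=1)
    dn = np.linalg.norm(disp, axis=1)
    denom = vn * dn
    cos = np.zeros(len(rows))
    ok = denom > 0
    cos[ok] = np.einsum("ij,ij->i", v[ok], disp[ok]) / denom[ok]
    w = np.exp(cos / tau).reshape(n, k)
    zero_v = np.linalg.norm(velocities, axis=1) == 0
    if zero_v.any():
        log.info("velocity_kernel: %d zero-velocity cells get uniform rows", zero_v.sum())
        w[zero_v] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    T = sp.csr_matrix((w.ravel(), (rows, cols)), shape=(n, n))
    return T


def connectivity_kernel(embedding: np.ndarray, k: int = 30) -> sp.csr_matrix:
    """Row-normalized symmetrized kNN adjacency (similarity kernel)."""
    n = embedding.shape[0]
    k = min(k, n - 1)
    nbrs = _knn_indices(np.asarray(embedding, dtype=float), k)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n))
    A = ((A + A.T) > 0).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    Dinv = sp.diags(1.0 / np.maximum(deg, 1))
    return sp.csr_matrix(Dinv @ A)


def combine_kernels(
    T_vel: sp.spmatrix,
    T_conn: sp.spmatrix,
    terminal_sets: dict,
    w_vel: float = 0.8,
) -> TransitionModel:
    """Convex combination T = w_vel * T_vel + (1 - w_vel) * T_conn."""
    if T_vel.shape != T_conn.shape:
        raise ValueError("kernel shape mismatch")
    if not 0.0 <= w_vel <= 1.0:
        raise ValueError("w_vel must be in [0, 1]")
    T = sp.csr_matrix(w_vel * T_vel + (1.0 - w_vel) * T_conn)
    return TransitionModel(T, {f: np.asarray(v) for f, v in terminal_sets.items()},
                           w_vel=w_vel)


def terminal_sets_from_rule(
    cells: pd.DataFrame,
    classes=None,
    latent_quantile: float = 0.75,
) -> dict:
    """Terminal sets by rule: cells of class C whose latent time exceeds the
    class's ``latent_quantile`` quantile."""
    sets = {}
    for c, g in cells.groupby("major_class", sort=True):
        if classes is not None and c not in classes:
            continue
        lt = g["latent_time"]
        idx = g.index[lt >= lt.quantile(latent_quantile)].to_numpy()
        if len(idx):
            sets[c] = idx
    return sets


def absorption_probabilities(model: TransitionModel) -> FateProbabilities:
    """Absorbing-chain fate probabilities ``B = (I - Q)^-1 R``.

    Terminal cells are made absorbing (identity rows) and get probability 1
    for their own fate.  Transient cells with no path to any terminal set are
    reported in ``unreachable`` and carry NaN rows rather than being silently
    zeroed.
    """
    T = sp.csr_matrix(model.matrix, copy=True)
    n = T.shape[0]
    fates = sorted(model.terminal_sets)
    term_idx = np.concatenate([np.asarray(model.terminal_sets[f]) for f in fates])
    term_fate = np.concatenate(
        [np.full(len(model.terminal_sets[f]), i) for i, f in enumerate(fates)]
    )
    is_term = np.zeros(n, dtype=bool)
    is_term[term_idx] = True
    trans_idx = np.flatnonzero(~is_term)

    # reachability: on the reversed graph, which transient states can reach
    # a terminal state
    can_reach = np.zeros(n, dtype=bool)
    can_reach[term_idx] = True
    rev = (T.T > 0).astype(np.int8).tocsr()
    seen = np.zeros(n, dtype=bool)
    for s in term_idx:
        if seen[s]:
            continue
        order = breadth_first_order(rev, s, directed=True, return_predecessors=False)
        can_reach[order] = True
        seen[order] = True
    unreachable = trans_idx[~can_reach[trans_idx]]
    solve_idx = trans_idx[can_reach[trans_idx]]

    B = np.full((n, len(fates)), np.nan)
    B[term_idx, :] = 0.0
    B[term_idx, term_fate] = 1.0
    if len(solve_idx):
        Q = T[solve_idx][:, solve_idx]
        # aggregate transient->terminal mass per fate
        R_agg = np.zeros((len(solve_idx), len(fates)))
        Tt = T[solve_idx][:, term_idx].toarray()
        for i in range(len(fates)):
            R_agg[:, i] = Tt[:, term_fate == i].sum(axis=1)
        # mass leaking toward unreachable states would break row sums; by
        # construction reachable transients only leak into reachable states
        A = sp.eye(len(solve_idx), format="csc") - sp.csc_matrix(Q)
        sol = spsolve(A, R_agg)
        sol = np.atleast_2d(sol)
        if sol.shape != R_agg.shape:  # spsolve squeezes single-column results
            sol = sol.reshape(R_agg.shape)
        B[solve_idx] = sol
    probs = pd.DataFrame(B, columns=fates)
    ok = ~np.isnan(B).any(axis=1)
    rowsum = B[ok].sum(axis=1)
    if len(rowsum) and np.abs(rowsum - 1).max() > 1e-6:
        raise FloatingPointError("absorption probability rows deviate from 1 beyond 1e-6")
    if len(unreachable):
        log.warning("absorption_probabilities: %d unreachable cells", len(unreachable))
    return FateProbabilities(probs, unreachable)


def assign_cluster_fates(
    fate_probs: FateProbabilities | pd.DataFrame,
    clusters,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Cluster fate = argmax of mean fate probability when >= threshold.

    Returns a table with per-cluster fate (or 'undetermined') and the mean
    probabilities; member cells inherit the cluster fate.
    """
    B = fate_probs.probabilities if isinstance(fate_probs, FateProbabilities) else fate_probs
    clusters = np.asarray(clusters)
    if len(clusters) != len(B):
        raise ValueError("cluster labels must cover all cells")
    rows = []
    for cl in sorted(pd.unique(clusters)):
        mask = clusters == cl
        if not mask.any():
            raise ValueError(f"empty cluster {cl!r}")
        mean = B.loc[mask].mean(axis=0, skipna=True)
        if mean.isna().all():
            fate_label = "undetermined"
            best = float("nan")
        else:
            best = float(mean.max())
            fate_label = str(mean.idxmax()) if best >= threshold else "undetermined"
        rows.append({"cluster": cl, "fate": fate_label, "max_mean_prob": best,
                     "n_cells": int(mask.sum())})
    return pd.DataFrame(rows)


def cell_fates_from_clusters(cluster_fates: pd.DataFrame, clusters) -> np.ndarray:
    lookup = dict(zip(cluster_fates["cluster"], cluster_fates["fate"]))
    return np.array([lookup[c] for c in np.asarray(clusters)], dtype=object)


# ---------------------------------------------------------------------------
# TF fate-specification prediction and validation


def predict_tf_specification(
    expr: CountMatrix,
    fate_labels,
    tf_list,
) -> pd.DataFrame:
    """Predict the class each TF specifies: argmax of mean normalized
    expression across fate groups of neurogenic progenitors.

    Ties are broken lexicographically and flagged; all-zero TFs are flagged
    with no prediction.
    """
    if expr.state != NormState.LOG1P_CPM:
        raise ValueError("predict_tf_specification expects log1p_cpm expression")
    fate_labels = np.asarray(fate_labels)
    fates = sorted(f for f in pd.unique(fate_labels) if f not in ("", "undetermined"))
    if not fates:
        raise ValueError("no fate groups present")
    groups = {f: np.flatnonzero(fate_labels == f) for f in fates}
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every fate group must be non-empty")
    X = expr.dense()
    rows = []
    for tf in tf_list:
        g = expr.gene_index(tf)  # raises KeyError if absent
        means = {f: float(X[g, idx].mean()) for f, idx in groups.items()}
        vals = np.array([means[f] for f in fates])
        if np.all(vals == 0):
            rows.append({"tf": tf, "predicted_class": None, "flag": "all_zero", **means})
            continue
        best = vals.max()
        winners = [f for f, v in zip(fates, vals) if v == best]
        rows.append(
            {
                "tf": tf,
                "predicted_class": sorted(winners)[0],
                "flag": "tie" if len(winners) > 1 else "",
                **means,
            }
        )
    return pd.DataFrame(rows)


def validate_tf_predictions(predictions, annotation: pd.DataFrame) -> dict:
    """Compare predicted classes with literature annotation.

    ``predictions`` maps TF -> predicted class (or a DataFrame from
    :func:`predict_tf_specification`).  ``annotation`` needs columns ``tf``
    and ``literature_classes`` (empty tuple = unknown).  TFs with no
    literature record are excluded from the match-rate denominator.
    """
    if isinstance(predictions, pd.DataFrame):
        predictions = dict(zip(predictions["tf"], predictions["predicted_class"]))
    lit = dict(zip(annotation["tf"], annotation["literature_classes"]))
    n_matched = n_unmatched = n_unknown = 0
    for tf, pred in predictions.items():
        classes = lit.get(tf, ())
        if not classes:
            n_unknown += 1
        elif pred in classes:
            n_matched += 1
        else:
            n_unmatched += 1
    denom = n_matched + n_unmatched
    return {
        "n_matched": n_matched,
        "n_unmatched": n_unmatched,
        "n_unknown": n_unknown,
        "match_rate": (n_matched / denom) if denom else None,
    }
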