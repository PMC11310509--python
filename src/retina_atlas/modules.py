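"""Latent-time gene modules and timing statistics.

Genes whose expression varies with latent time are selected by Pearson
correlation with a Benjamini-Hochberg cutoff (a documented correlation-based
stand-in for graph-autocorrelation selection: the same null — no association
with the latent-time covariate — is tested).  Selected genes are grouped by
average-linkage hierarchical clustering of the gene-gene correlation matrix;
with ``core_only`` genes whose mean within-module correlation falls below a
floor remain unassigned.  Per-cell module scores are the cell loadings of a
single-component PCA on the neighbor-smoothed module submatrix, and each
gene can be timestamped by its expression-weighted sample age.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import beta as beta_dist
from scipy.stats import pearsonr, ttest_ind
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, NormState


def _check_log1p(expr: CountMatrix):
    if expr.state != NormState.LOG1P_CPM:
        raise ValueError("expected log1p_cpm-normalized expression")


def detect_correlated_genes(
    expr: CountMatrix,
    latent_time,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with latent time, BH-corrected.

    Constant genes have undefined correlation and are excluded (flagged in
    the output with selected=False and NaN statistics).  A gene is selected
    iff its BH q-value is below ``alpha``.
    """
    _check_log1p(expr)
    lt = np.asarray(latent_time, dtype=float)
    if len(lt) != expr.shape[1]:
        raise ValueError("latent_time must be present for all cells")
    X = expr.dense()
    n = len(lt)
    lt_c = lt - lt.mean()
    lt_ss = np.sqrt((lt_c**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    g_ss = np.sqrt((Xc**2).sum(axis=1))
    constant = g_ss == 0
    r = np.full(X.shape[0], np.nan)
    ok = ~constant & (lt_ss > 0)
    r[ok] = (Xc[ok] @ lt_c) / (g_ss[ok] * lt_ss)
    r = np.clip(r, -1, 1)
    # two-sided p via the exact null beta distribution of r^2
    p = np.full_like(r, np.nan)
    p[ok] = 2 * beta_dist.sf(np.abs(r[ok]), (n - 2) / 2, (n - 2) / 2, loc=-1, scale=2)
    p[ok] = np.minimum(p[ok], 1.0)
    q = np.full_like(r, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": expr.genes,
            "r": r,
            "p": p,
            "q": q,
            "selected": np.where(ok, q < alpha, False),
        }
    )


@dataclasses.dataclass
class ModuleResult:
    gene_table: pd.DataFrame  # gene, r, p, q, module (0 = unassigned)
    modules: dict  # module id -> list of genes
    scores: pd.DataFrame | None = None  # cells x modules


def group_modules(
    expr: CountMatrix,
    selected_genes,
    k: int = 3,
    min_gene_threshold: int = 160,
    core_only: bool = True,
    core_floor: float = 0.3,
    order_by_time=None,
) -> ModuleResult:
    """Cluster selected genes into k modules on their correlation matrix.

    Average-linkage hierarchical clustering on (1 - Pearson r) is
    deterministic given the data.  Modules smaller than
    ``min_gene_threshold`` are dropped with a warning; with ``core_only``,
    genes whose mean correlation with their module falls below
    ``core_floor`` stay unassigned.  When ``order_by_time`` (per-cell latent
    time) is given, module ids are relabeled 1..k by the expression-weighted
    latent time of their genes, so module 1 is the earliest program.
    """
    _check_log1p(expr)
    selected_genes = list(selected_genes)
    if len(selected_genes) < 2 * k:
        raise ValueError(f"need at least {2 * k} selected genes, got {len(selected_genes)}")
    idx = [expr.gene_index(g) for g in selected_genes]
    X = expr.dense()[idx]
    C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    # deepen the cut until k clusters clear the size floor (a plain k-cut
    # tends to shave off outlier genes and leave one giant cluster); keep
    # the k largest qualifying clusters as modules
    n_genes = len(selected_genes)
    raw = None
    for t in range(k, min(4 * k + 20, n_genes) + 1):
        labels = fcluster(Z, t=t, criterion="maxclust")
        sizes = pd.Series(labels).value_counts()
        if (sizes >= min_gene_threshold).sum() >= k:
            raw = labels
            break
    if raw is None:
        raw = fcluster(Z, t=k, criterion="maxclust")
        warnings.warn(
            f"fewer than {k} clusters reach min_gene_threshold="
            f"{min_gene_threshold}; emitting the qualifying ones"
        )
    sizes = pd.Series(raw).value_counts()
    keep = set(sizes[sizes >= min_gene_threshold].index[:k])
    assignment = np.zeros(len(selected_genes), dtype=int)
    next_id = 1
    for m in sorted(keep):
        members = np.flatnonzero(raw == m)
        assignment[members] = next_id
        next_id += 1
    if core_only:
        for m in range(1, next_id):
            members = np.flatnonzero(assignment == m)
            for g in members:
                others = members[members != g]
                if len(others) and C[g, others].mean() < core_floor:
                    assignment[g] = 0

    if order_by_time is not None and next_id > 1:
        lt = np.asarray(order_by_time, dtype=float)
        times = {}
        for m in range(1, next_id):
            members = np.flatnonzero(assignment == m)
            w = X[members].sum(axis=0)
            times[m] = float((w / w.sum()) @ lt) if w.sum() > 0 else np.inf
        order = sorted(times, key=times.get)
        remap = {old: new for new, old in enumerate(order, start=1)}
        assignment = np.array([remap.get(a, 0) for a in assignment])

    table = pd.DataFrame({"gene": selected_genes, "module": assignment})
    modules = {
        m: [selected_genes[i] for i in np.flatnonzero(assignment == m)]
        for m in sorted(set(assignment) - {0})
    }
    return ModuleResult(gene_table=table, modules=modules)


def _smooth(X: np.ndarray, embedding: np.ndarray | None, k: int) -> np.ndarray:
    """KNN-average smoothing of cells x genes values."""
    if embedding is None or k <= 1 or X.shape[0] <= k:
        return X
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return X[idx].mean(axis=1)


def module_score(
    expr: CountMatrix,
    module_genes,
    embedding: np.ndarray | None = None,
    k_smooth: int = 30,
) -> np.ndarray:
    """Per-cell score: first-PC cell loadings of the smoothed module submatrix.

    The sign is oriented so the score correlates positively with mean module
    expression.
    """
    _check_log1p(expr)
    if expr.shape[1] < 2:
        raise ValueError("module_score needs at least 2 cells")
    idx = [expr.gene_index(g) for g in module_genes]
    X = expr.dense()[idx].T  # cells x genes
    X = _smooth(X, embedding, k_smooth)
    mean_expr = X.mean(axis=1)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    score = u[:, 0] * s[0]
    if len(set(mean_expr)) > 1 and np.corrcoef(score, mean_expr)[0, 1] < 0:
        score = -score
    return score


def expression_weighted_time(expr_vector, age_days) -> float:
    """Expression-weighted sample age (days): weights normalized to sum 1."""
    x = np.asarray(expr_vector, dtype=float)
    ages = np.asarray(age_days, dtype=float)
    total = x.sum()
    if total <= 0:
        warnings.warn("all-zero gene: expression-weighted time undefined")
        return float("nan")
    return float((x / total) @ ages)


def latent_time_tests(
    cells: pd.DataFrame,
    correction: str = "bonferroni",
) -> dict:
    """Latent-time vs PCW correlation, and per-PCW macula/periphery tests.

    Pearson product-moment correlation (two-sided) of numeric PCW group with
    latent time, plus a two-sided Welch two-sample t-test of macula vs
    periphery latent times within each PCW group, corrected over PCW groups
    (Bonferroni by default).  PCW groups missing a location are skipped and
    reported.
    """
    if "latent_time" not in cells.columns or cells["latent_time"].isna().any():
        raise ValueError("latent_time must be present for all cells")
    r, p = pearsonr(cells["pcw_group"].astype(float), cells["latent_time"])
    rows, skipped = [], []
    for pcw, g in sorted(cells.groupby("pcw_group")):
        mac = g.loc[g["location"] == "macula", "latent_time"].to_numpy()
        per = g.loc[g["location"] == "periphery", "latent_time"].to_numpy()
        if len(mac) < 2 or len(per) < 2:
            skipped.append(int(pcw))
            continue
        t, pt = ttest_ind(mac, per, equal_var=False)
        rows.append(
            {
                "pcw_group": int(pcw),
                "mean_macula": float(mac.mean()),
                "mean_periphery": float(per.mean()),
                "t": float(t),
                "p": float(pt),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"], method=correction)[1]
    return {
        "pearson_r": float(r),
        "pearson_p": float(p),
        "per_pcw": table,
        "skipped_pcw": skipped,
    }
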