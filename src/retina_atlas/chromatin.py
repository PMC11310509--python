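"""Chromatin-side procedures: DARs, adult-overlap classification,
peak-to-gene linkage, and chromatin-expression phase segmentation.

Differentially accessible regions (DARs) are called per focal class against
the rest with a one-sided Wilcoxon rank-sum test on log2-normalized
pseudobulk accessibility, BH-corrected across peaks within the class, and
gated at FDR < 0.01 with log2 fold change strictly greater than 1.

Overlap classification follows the interval convention used throughout
(0-based, half-open): a query peak counts as overlapping a reference set
when at least 20% of its bases are covered by the union of reference peaks
(inclusive boundary), otherwise it is developmental-specific.

Peak-to-gene linkage pairs each gene's anchor (TSS) with peaks within
250 kb and keeps pairs whose accessibility/expression Pearson correlation
across pseudobulk units is at least 0.45 (both thresholds inclusive).

Phase segmentation classifies each point of a gene-time grid by the joint
behavior of chromatin accessibility c(t) and expression s(t): primed
(chromatin open, gene silent), coupled-on (both rising), coupled-off (both
falling), decoupled (discordant).  This is a descriptive classifier over
smoothed trajectories; no dynamical model is fitted.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .io import validate_peaks

PHASES = ("primed", "coupled_on", "coupled_off", "decoupled")


# ---------------------------------------------------------------------------
# Differential accessibility


def call_dars(
    acc: pd.DataFrame,
    unit_classes,
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum DAR test, each class vs the rest.

    ``acc`` is peaks x pseudobulk units on a log2-normalized scale;
    ``unit_classes`` labels each column.  log2FC is the mean difference of
    the log2 values.  A peak is a DAR for the focal class iff BH q <
    ``fdr_threshold`` and log2FC strictly greater than ``lfc_threshold``.
    """
    unit_classes = np.asarray(unit_classes)
    if len(unit_classes) != acc.shape[1]:
        raise ValueError("one class label per pseudobulk unit required")
    X = acc.to_numpy(dtype=float)
    rows = []
    for cls in sorted(pd.unique(unit_classes)):
        mask = unit_classes == cls
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"class {cls!r} needs >= 2 replicates on each side")
        focal, rest = X[:, mask], X[:, ~mask]
        _, p = mannwhitneyu(focal, rest, alternative="greater", axis=1)
        lfc = focal.mean(axis=1) - rest.mean(axis=1)
        q = multipletests(p, method="fdr_bh")[1]
        is_dar = (q < fdr_threshold) & (lfc > lfc_threshold)
        for j, pid in enumerate(acc.index):
            rows.append(
                {"peak_id": pid, "focal_class": cls, "log2_fold_change": lfc[j],
                 "p": p[j], "q": q[j], "is_dar": bool(is_dar[j])}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlap classification (developmental vs adult peak sets)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s), np.array(merged_e)


def overlap_fraction(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Fraction of each query peak covered by the union of reference peaks."""
    validate_peaks(query)
    validate_peaks(reference)
    frac = np.zeros(len(query))
    ref_by_contig = {
        c: _merge_intervals(g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for c, g in reference.groupby("contig")
    }
    for i, (_, row) in enumerate(query.iterrows()):
        length = int(row["end"]) - int(row["start"])
        if length <= 0:
            raise ValueError(f"zero-length peak {row['peak_id']!r}")
        if row["contig"] not in ref_by_contig:
            continue
        ms, me = ref_by_contig[row["contig"]]
        lo = np.clip(ms, int(row["start"]), int(row["end"]))
        hi = np.clip(me, int(row["start"]), int(row["end"]))
        frac[i] = (hi - lo).sum() / length
    return frac


def classify_overlap(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    min_frac: float = 0.2,
) -> pd.DataFrame:
    """Label each query peak 'overlapping' or 'specific'.

    A peak overlaps when the union of reference peaks covers at least
    ``min_frac`` of its bases (boundary inclusive: exactly 20% counts).
    """
    frac = overlap_fraction(query, reference)
    status = np.where(frac >= min_frac - 1e-12, "overlapping", "specific")
    return pd.DataFrame(
        {"peak_id": query["peak_id"].to_numpy(), "overlap_fraction": frac,
         "status": status}
    )


# ---------------------------------------------------------------------------
# Peak-to-gene linkage


@dataclasses.dataclass
class PeakGeneLink:
    peak_id: str
    gene: str
    distance_bp: int
    pearson_r: float


def _anchor_distance(anchor: int, start: int, end: int) -> int:
    """Distance in bp from an anchor position to a half-open interval."""
    if start <= anchor < end:
        return 0
    return int(start - anchor) if anchor < start else int(anchor - (end - 1))


def link_peaks_to_genes(
    peak_acc: pd.DataFrame,
    expr_pb: pd.DataFrame,
    peaks: pd.DataFrame,
    gene_anchors: pd.DataFrame,
    max_bp: int = 250_000,
    min_r: float = 0.45,
    genes=None,
) -> pd.DataFrame:
    """Correlated peak-gene pairs within the distance window.

    ``peak_acc`` (peaks x units) and ``expr_pb`` (genes x units) must share
    column order (matched pseudobulk units).  Candidate peaks lie within
    ``max_bp`` of the gene's anchor on the same contig; a pair is emitted
    iff Pearson r >= ``min_r`` (both thresholds inclusive).  Requesting a
    gene without an anchor raises KeyError.
    """
    if list(peak_acc.columns) != list(expr_pb.columns):
        raise ValueError("peak and expression pseudobulk units must match")
    validate_peaks(peaks)
    anchors = gene_anchors.set_index("gene")
    if genes is None:
        genes = [g for g in expr_pb.index if g in anchors.index]
    acc_X = peak_acc.to_numpy(dtype=float)
    peak_info = peaks.set_index("peak_id")
    peak_ids = [p for p in peak_acc.index if p in peak_info.index]
    rows = []
    for gene in genes:
        if gene not in anchors.index:
            raise KeyError(f"gene {gene!r} has no anchor")
        if gene not in expr_pb.index:
            continue
        contig = anchors.at[gene, "contig"]
        pos = int(anchors.at[gene, "position"])
        e = expr_pb.loc[gene].to_numpy(dtype=float)
        if e.std() == 0:
            continue
        for pid in peak_ids:
            if peak_info.at[pid, "contig"] != contig:
                continue
            d = _anchor_distance(pos, int(peak_info.at[pid, "start"]),
                                 int(peak_info.at[pid, "end"]))
            if d > max_bp:
                continue
            a = acc_X[peak_acc.index.get_loc(pid)]
            if a.std() == 0:
                continue
            r = float(np.corrcoef(a, e)[0, 1])
            if r >= min_r - 1e-12:
                rows.append(
                    {"peak_id": pid, "gene": gene, "distance_bp": d, "pearson_r": r}
                )
    return pd.DataFrame(rows, columns=["peak_id", "gene", "distance_bp", "pearson_r"])


# ---------------------------------------------------------------------------
# Phase segmentation


@dataclasses.dataclass
class PhaseSegmentation:
    gene: str
    grid: np.ndarray
    phases: np.ndarray  # per grid point, one of PHASES
    percentages: dict  # phase -> percent of grid points (sums to 100)


def segment_phases(
    grid,
    chromatin,
    unspliced,
    spliced,
    gene: str = "",
    silence_frac: float = 0.05,
    open_frac: float = 0.5,
) -> PhaseSegmentation:
    """Classify each grid point of a gene's trajectories into four phases.

    primed: chromatin above ``open_frac`` of its max while expression sits
    below ``silence_frac`` of its max; coupled-on / coupled-off: chromatin
    and expression change concordantly (both rising / both falling);
    decoupled: discordant changes.  Changes are forward differences; the
    last grid point inherits its predecessor's differences.  Percentages are
    grid-point shares and sum to 100.  The classification only uses signs
    and maxima-relative thresholds, so it is invariant to uniform rescaling
    of either trajectory.
    """
    t = np.asarray(grid, dtype=float)
    c = np.asarray(chromatin, dtype=float)
    s = np.asarray(spliced, dtype=float)
    if len(t) < 3:
        raise ValueError("grid must have at least 3 points")
    if not (len(t) == len(c) == len(s)):
        raise ValueError("trajectories must share the grid")
    dc = np.diff(c)
    ds = np.diff(s)
    dc = np.append(dc, dc[-1])
    ds = np.append(ds, ds[-1])
    c_open = open_frac * c.max() if c.max() > 0 else 0.0
    s_silent = silence_frac * s.max() if s.max() > 0 else 0.0
    phases = np.empty(len(t), dtype=object)
    for i in range(len(t)):
        if c[i] > c_open and s[i] <= s_silent:
            phases[i] = "primed"
        elif dc[i] > 0 and ds[i] > 0:
            phases[i] = "coupled_on"
        elif dc[i] < 0 and ds[i] < 0:
            phases[i] = "coupled_off"
        else:
            phases[i] = "decoupled"
    pct = {ph: 100.0 * float((phases == ph).mean()) for ph in PHASES}
    return PhaseSegmentation(gene=gene, grid=t, phases=phases, percentages=pct)


def gene_trajectories(
    values: np.ndarray,
    gene_time: np.ndarray,
    n_grid: int = 50,
    bandwidth: float = 0.1,
):
    """Gaussian-kernel smoothed trajectory of per-cell values on a gene-time
    grid in [0, 1]; support helper for building segment_phases inputs."""
    t = np.linspace(gene_time.min(), gene_time.max(), n_grid)
    w = np.exp(-((t[:, None] - gene_time[None, :]) ** 2) / (2 * bandwidth**2))
    return t, (w @ values) / np.maximum(w.sum(axis=1), 1e-12)


def phase_summaries(
    segmentations: dict,
    gene_classes: dict | None = None,
    compare_sets: tuple | None = None,
    compare_phase: str = "coupled_on",
) -> dict:
    """Average phase percentages per class, with an optional two-set Welch
    comparison of one phase's time shares.

    ``segmentations`` maps gene -> PhaseSegmentation; ``gene_classes`` maps
    gene -> class label (default: one pooled class).  ``compare_sets`` is a
    pair of gene lists whose ``compare_phase`` percentages are compared with
    a two-sided Welch t-test.
    """
    if not segmentations:
        raise ValueError("no segmentations given")
    gene_classes = gene_classes or {g: "all" for g in segmentations}
    per_class: dict = {}
    for g, seg in segmentations.items():
        per_class.setdefault(gene_classes.get(g, "all"), []).append(seg.percentages)
    summary_rows = []
    for cls, pcts in sorted(per_class.items()):
        row = {"major_class": cls, "n_genes": len(pcts)}
        for ph in PHASES:
            row[ph] = float(np.mean([p[ph] for p in pcts]))
        summary_rows.append(row)
    out = {"summary": pd.DataFrame(summary_rows)}
    if compare_sets is not None:
        a_genes, b_genes = compare_sets
        a = [segmentations[g].percentages[compare_phase] for g in a_genes]
        b = [segmentations[g].percentages[compare_phase] for g in b_genes]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each comparison set needs >= 2 genes")
        t, p = ttest_ind(a, b, equal_var=False)
        out["comparison"] = {
            "phase": compare_phase,
            "mean_a": float(np.mean(a)),
            "mean_b": float(np.mean(b)),
            "t": float(t),
            "p": float(p),
        }
    return out
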