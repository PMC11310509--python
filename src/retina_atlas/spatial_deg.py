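"""Differential expression: class markers and the two-stage location test.

Class markers use the overestimated-variance t-test: for focal group g vs
the rest, t = (m_g - m_rest) / sqrt(v_g/n_g + v_rest/n_g) — both variance
terms divided by the focal group's size, which inflates the rest-variance
term and makes the test conservative — with Welch-Satterthwaite degrees of
freedom on those same terms and BH correction within each group.

The macula-vs-periphery procedure is two-stage, per major class, on raw
counts with a log-total-count offset:

* stage 1: negative-binomial regression (log link) with Location as the sole
  covariate; Wald test on the Location coefficient; a gene passes with BH
  q < 0.01, |coefficient| > 1 (natural-log scale), and detection in more
  than 2,000 cells;
* stage 2: NB fits of Location + Age against Age alone, compared by a 1-df
  likelihood-ratio test, passing at BH q < 0.01.

The final DEG set is the intersection of the two stages.  NB fitting is
iteratively reweighted least squares, batched across genes, with a per-gene
method-of-moments dispersion; q-values are computed over the
post-abundance-filter gene set.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import ttest_ind_from_stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, NormState

_ETA_CLIP = 30.0


def rank_genes_overestim_t(expr: CountMatrix, group_labels) -> pd.DataFrame:
    """Overestimated-variance t-test of each group against the rest.

    Returns one row per (group, gene) with the statistic, two-sided p, and
    BH q within the group.
    """
    if expr.state != NormState.LOG1P_CPM:
        raise ValueError("rank_genes_overestim_t expects log1p_cpm expression")
    labels = np.asarray(group_labels)
    X = expr.dense()
    rows = []
    for g in sorted(pd.unique(labels)):
        mask = labels == g
        n_g = int(mask.sum())
        n_rest = int((~mask).sum())
        if n_g < 2 or n_rest < 2:
            raise ValueError(f"group {g!r} needs at least 2 cells on each side")
        m1 = X[:, mask].mean(axis=1)
        v1 = X[:, mask].var(axis=1, ddof=1)
        m2 = X[:, ~mask].mean(axis=1)
        v2 = X[:, ~mask].var(axis=1, ddof=1)
        # the rest's variance term is divided by the focal group's size
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = ttest_ind_from_stats(
                m1, np.sqrt(v1), n_g, m2, np.sqrt(v2), n_g, equal_var=False
            )
        t = np.asarray(t)
        p = np.asarray(p)
        zero = (v1 == 0) & (v2 == 0)
        t[zero & (m1 == m2)] = 0.0
        p[zero & (m1 == m2)] = 1.0
        q = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1]
        for j, gene in enumerate(expr.genes):
            rows.append(
                {"group": g, "gene": gene, "mean_diff": m1[j] - m2[j],
                 "t": t[j], "p": p[j], "q": q[j]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Batched negative-binomial GLM (log link, offset), IRLS


def _quasi_loglik(y, eta, mu, alpha):
    """Log-likelihood dropping per-gene terms constant in beta (they cancel
    in likelihood-ratio statistics and in convergence checks)."""
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        pois = y * eta - mu
        nb = y * (eta - np.log1p(a * mu)) - np.log1p(a * mu) / np.where(a > 0, a, 1.0)
    out = np.where(a > 0, nb, pois)
    # y*log(0) terms only arise for mu=0 with y=0 -> contribute 0
    return np.nan_to_num(out, nan=0.0, neginf=-1e30).sum(axis=1)


def _batched_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray | None,
    max_iter: int = 50,
    tol: float = 1e-6,
):
    """Fit y_g ~ NB(exp(X beta_g + offset), alpha_g) for all genes at once.

    Returns (beta (G,p), cov (G,p,p), converged (G,), qll (G,), mu (G,n))
    where qll omits additive terms constant in beta (valid for LRTs with a
    shared dispersion).  ``alpha=None`` fits Poisson (used to seed the
    dispersion estimate).
    """
    G, n = y.shape
    p = X.shape[1]
    if alpha is None:
        alpha = np.zeros(G)
    beta = np.zeros((G, p))
    # moment start: intercept at log(mean count / mean exposure)
    mean_y = np.maximum(y.mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean_y) - np.log(np.exp(offset).mean())
    converged = np.zeros(G, dtype=bool)
    P = np.einsum("ni,nj->nij", X, X).reshape(n, p * p)  # for batched X'WX
    eye = 1e-10 * np.eye(p)[None, :, :]
    active = np.arange(G)
    for _ in range(max_iter):
        ya = y[active]
        aa = alpha[active]
        eta = np.clip(beta[active] @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + aa[:, None] * mu)
        z = (eta - offset[None, :]) + (ya - mu) / mu
        A = (W @ P).reshape(len(active), p, p) + eye
        b = (W * z) @ X
        new = np.linalg.solve(A, b[..., None])[..., 0]
        # converge on the parameter update (quadratic near the optimum)
        done = np.abs(new - beta[active]).max(axis=1) < tol
        beta[active] = new
        converged[active[done]] = True
        active = active[~done]
        if len(active) == 0:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    A = (W @ P).reshape(G, p, p) + eye
    cov = np.linalg.inv(A)
    ll = _quasi_loglik(y, eta, mu, alpha)
    bad = ~np.isfinite(beta).all(axis=1) | ~np.isfinite(ll)
    converged = converged & ~bad
    return beta, cov, converged, ll, mu


def _mom_dispersion(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB2 dispersion alpha (var = mu + alpha mu^2)."""
    num = ((y - mu) ** 2 - mu).sum(axis=1)
    den = (mu**2).sum(axis=1)
    return np.clip(num / np.maximum(den, 1e-12), 1e-8, 100.0)


def location_deg(
    counts: CountMatrix,
    cells: pd.DataFrame,
    min_cells_detected: int = 2000,
    q_threshold: float = 0.01,
    effect_threshold: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Two-stage macula-vs-periphery DEG test for one major class.

    ``counts`` must be raw; ``cells`` must contain both locations and
    ``age_days``.  Returns a per-gene table with stage flags; ``final_deg``
    is true iff the abundance, Wald, and LRT criteria all hold.
    Non-converged fits are flagged and excluded from both stages.
    """
    if counts.state != NormState.RAW:
        raise ValueError("location_deg expects raw counts")
    locs = cells["location"].to_numpy()
    present = set(locs)
    if not {"macula", "periphery"} <= present:
        raise ValueError("both macula and periphery must be present")
    Y = counts.dense().astype(float)
    n_detected = (Y > 0).sum(axis=1)
    abundance_pass = n_detected > min_cells_detected
    out = pd.DataFrame(
        {
            "gene": counts.genes,
            "n_detected": n_detected,
            "abundance_pass": abundance_pass,
            "effect": np.nan,
            "p_wald": np.nan,
            "q_wald": np.nan,
            "wald_pass": False,
            "p_lrt": np.nan,
            "q_lrt": np.nan,
            "lrt_pass": False,
            "converged": False,
            "final_deg": False,
        }
    )
    keep = np.flatnonzero(abundance_pass)
    if len(keep) == 0:
        return out
    y = Y[keep]
    libsize = Y.sum(axis=0)
    offset = np.log(np.maximum(libsize, 1.0))
    loc_num = (locs == "periphery").astype(float)
    age = cells["age_days"].to_numpy(dtype=float)
    ones = np.ones_like(loc_num)

    # stage 1: Location-only model
    X1 = np.column_stack([ones, loc_num])
    _, _, _, _, mu_pois = _batched_irls(y, X1, offset, None, min(max_iter, 10), 1e-4)
    alpha1 = _mom_dispersion(y, mu_pois)
    beta1, cov1, conv1, _, _ = _batched_irls(y, X1, offset, alpha1, max_iter, tol)
    effect = beta1[:, 1]
    se = np.sqrt(np.maximum(cov1[:, 1, 1], 1e-30))
    z = effect / se
    p_wald = 2.0 * chi2.sf(z**2, df=1)

    # stage 2: Location + Age vs Age alone, same dispersion for both fits
    X_full = np.column_stack([ones, loc_num, age])
    X_red = np.column_stack([ones, age])
    _, _, _, _, mu_pois2 = _batched_irls(y, X_full, offset, None, min(max_iter, 10), 1e-4)
    alpha2 = _mom_dispersion(y, mu_pois2)
    _, _, conv_f, ll_full, _ = _batched_irls(y, X_full, offset, alpha2, max_iter, tol)
    _, _, conv_r, ll_red, _ = _batched_irls(y, X_red, offset, alpha2, max_iter, tol)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p_lrt = chi2.sf(lrt, df=1)

    converged = conv1 & conv_f & conv_r
    tested = converged  # non-converged genes excluded from both stages
    q_wald = np.full(len(keep), np.nan)
    q_lrt = np.full(len(keep), np.nan)
    if tested.any():
        q_wald[tested] = multipletests(p_wald[tested], method="fdr_bh")[1]
        q_lrt[tested] = multipletests(p_lrt[tested], method="fdr_bh")[1]
    wald_pass = tested & (q_wald < q_threshold) & (np.abs(effect) > effect_threshold)
    lrt_pass = tested & (q_lrt < q_threshold)

    out.loc[keep, "effect"] = effect
    out.loc[keep, "p_wald"] = p_wald
    out.loc[keep, "q_wald"] = q_wald
    out.loc[keep, "wald_pass"] = wald_pass
    out.loc[keep, "p_lrt"] = p_lrt
    out.loc[keep, "q_lrt"] = q_lrt
    out.loc[keep, "lrt_pass"] = lrt_pass
    out.loc[keep, "converged"] = converged
    out["final_deg"] = out["abundance_pass"] & out["wald_pass"] & out["lrt_pass"]
    return out


def deg_summary(results: dict) -> pd.DataFrame:
    """Per-class counts of macula- vs periphery-enriched final DEGs.

    ``results`` maps class name -> the table from :func:`location_deg`.
    A negative Location coefficient (periphery vs macula baseline) means
    macula-enriched.
    """
    rows = []
    for cls, table in results.items():
        final = table[table["final_deg"]]
        rows.append(
            {
                "major_class": cls,
                "n_deg": len(final),
                "macula_enriched": int((final["effect"] < 0).sum()),
                "periphery_enriched": int((final["effect"] > 0).sum()),
            }
        )
    return pd.DataFrame(rows)
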