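import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from retina_atlas.io import CountMatrix, NormState
from retina_atlas.modules import (
    detect_correlated_genes,
    expression_weighted_time,
    group_modules,
    latent_time_tests,
    module_score,
)


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return CountMatrix(
        sp.csr_matrix(values), genes,
        [f"c{j}" for j in range(values.shape[1])], NormState.LOG1P_CPM,
    )


class TestDetection:
    def test_latent_time_tracking_gene_selected(self, rng):
        n = 1000
        lt = rng.uniform(0, 1, n)
        tracking = lt + rng.normal(0, 0.1, n)
        noise = rng.normal(0, 1, n)
        out = detect_correlated_genes(_expr(np.vstack([tracking, noise])), lt)
        assert bool(out.loc[0, "selected"])

    def test_constant_gene_excluded(self, rng):
        lt = rng.uniform(0, 1, 100)
        out = detect_correlated_genes(_expr(np.vstack([np.ones(100)])), lt)
        assert not out.loc[0, "selected"]
        assert np.isnan(out.loc[0, "r"])

    def test_p_values_match_scipy_reference(self, rng):
        from scipy.stats import pearsonr

        lt = rng.uniform(0, 1, 60)
        X = rng.normal(size=(5, 60))
        out = detect_correlated_genes(_expr(X), lt)
        for i in range(5):
            r, p = pearsonr(X[i], lt)
            assert out.loc[i, "r"] == pytest.approx(r, abs=1e-12)
            assert out.loc[i, "p"] == pytest.approx(p, rel=1e-9)

    def test_null_selection_rate_bounded_by_alpha(self, rng):
        """Label-permuted genes are selected at no more than the FDR level."""
        n, G = 400, 80
        lt = rng.uniform(0, 1, n)
        rates = []
        for _ in range(25):
            X = rng.normal(size=(G, n))  # independent of latent time
            out = detect_correlated_genes(_expr(X), lt, alpha=0.05)
            rates.append(out["selected"].mean())
        assert np.mean(rates) <= 0.05


class TestGrouping:
    def test_planted_modules_recovered(self, small_atlas, small_log_expr):
        from sklearn.metrics import adjusted_rand_score

        a = small_atlas
        prpc = (a.cells["major_class"] == "PRPC").to_numpy()
        expr = small_log_expr.subset_cells(prpc)
        lt = a.cells.loc[prpc, "latent_time"].to_numpy()
        det = detect_correlated_genes(expr, lt)
        sel = det.loc[det["selected"], "gene"].tolist()
        res = group_modules(expr, sel, k=3, min_gene_threshold=10, order_by_time=lt)
        modgenes = [g for g in expr.genes if g.startswith("MOD")]
        gene_to_idx = {g: i for i, g in enumerate(expr.genes)}
        truth = [a.truth.module_label[gene_to_idx[g]] for g in modgenes]
        pred_map = dict(zip(res.gene_table["gene"], res.gene_table["module"]))
        pred = [pred_map.get(g, 0) for g in modgenes]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_modules_ordered_by_expression_weighted_time(self, small_atlas, small_log_expr):
        """Module 1 is the early (decreasing) program, module 3 the late one."""
        a = small_atlas
        prpc = (a.cells["major_class"] == "PRPC").to_numpy()
        expr = small_log_expr.subset_cells(prpc)
        lt = a.cells.loc[prpc, "latent_time"].to_numpy()
        det = detect_correlated_genes(expr, lt)
        sel = det.loc[det["selected"], "gene"].tolist()
        res = group_modules(expr, sel, k=3, min_gene_threshold=10, order_by_time=lt)
        for m, genes in res.modules.items():
            prefixes = pd.Series([g.split("_")[0] for g in genes])
            assert prefixes.mode()[0] == f"MOD{m}"

    def test_uncorrelated_gene_left_unassigned_under_core_only(self, rng):
        n = 400
        lt = rng.uniform(0, 1, n)
        up = np.vstack([lt + rng.normal(0, 0.2, n) for _ in range(6)])
        down = np.vstack([-lt + rng.normal(0, 0.2, n) for _ in range(6)])
        lone = rng.normal(size=(1, n))
        expr = _expr(np.vstack([up, down, lone]))
        res = group_modules(expr, list(expr.genes), k=2, min_gene_threshold=3)
        tab = res.gene_table.set_index("gene")
        assert tab.loc["g12", "module"] == 0

    def test_deterministic_across_calls(self, rng):
        n = 300
        lt = rng.uniform(0, 1, n)
        X = np.vstack(
            [lt + rng.normal(0, 0.3, n) for _ in range(8)]
            + [-lt + rng.normal(0, 0.3, n) for _ in range(8)]
        )
        expr = _expr(X)
        r1 = group_modules(expr, list(expr.genes), k=2, min_gene_threshold=3)
        r2 = group_modules(expr, list(expr.genes), k=2, min_gene_threshold=3)
        assert r1.gene_table.equals(r2.gene_table)


class TestModuleScore:
    def test_single_gene_module_is_standardized_expression(self, rng):
        n = 200
        x = rng.normal(5, 2, n)
        expr = _expr(x[None, :])
        score = module_score(expr, ["g0"])
        centered = x - x.mean()
        assert np.allclose(np.abs(score), np.abs(centered), atol=1e-8)
        assert np.corrcoef(score, x)[0, 1] > 0.99

    def test_matches_independent_svd(self, rng):
        X = rng.normal(size=(10, 150))
        expr = _expr(X)
        score = module_score(expr, list(expr.genes))
        Xc = X.T - X.T.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        ref = u[:, 0] * s[0]
        agree = min(np.abs(score - ref).max(), np.abs(score + ref).max())
        assert agree < 1e-8

    def test_invariant_to_gene_duplication(self, rng):
        X = rng.normal(size=(5, 100))
        base = module_score(_expr(X), [f"g{i}" for i in range(5)])
        dup = module_score(
            _expr(np.vstack([X, X]), genes=[f"g{i}" for i in range(10)]),
            [f"g{i}" for i in range(10)],
        )
        assert np.allclose(np.abs(base) * np.sqrt(2), np.abs(dup), atol=1e-8)

    def test_invariant_to_gene_order(self, rng):
        X = rng.normal(size=(6, 80))
        genes = [f"g{i}" for i in range(6)]
        s1 = module_score(_expr(X, genes), genes)
        s2 = module_score(_expr(X, genes), genes[::-1])
        assert np.allclose(s1, s2, atol=1e-10)


class TestWeightedTime:
    def test_point_mass(self):
        assert expression_weighted_time([0, 3, 0], [80, 100, 120]) == 100.0

    def test_midpoint_of_equal_expression(self):
        assert expression_weighted_time([1, 1], [80, 120]) == 100.0

    def test_matches_scalar_loop(self, rng):
        x = rng.uniform(0, 5, 10)
        ages = rng.integers(50, 160, 10)
        expected = sum(xi * a for xi, a in zip(x / x.sum(), ages))
        assert expression_weighted_time(x, ages) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_gene_reported_missing(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = expression_weighted_time([0.0, 0.0], [80, 120])
        assert np.isnan(out)


class TestLatentTimeTests:
    def _cells(self, lt, pcw, loc):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(lt))],
                "age_days": np.asarray(pcw) * 7,
                "pcw_group": pcw,
                "location": loc,
                "major_class": "PRPC",
                "latent_time": lt,
            }
        )

    def test_affine_latent_time_has_unit_correlation(self):
        pcw = np.repeat([8, 10, 12, 14], 10)
        lt = (pcw - 8) / 10
        loc = np.tile(["macula", "periphery"], 20)
        out = latent_time_tests(self._cells(lt, pcw, loc))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["pearson_p"] < 1e-30

    def test_welch_p_uniform_under_null(self, rng):
        """Calibration: identical location distributions give uniform p."""
        from scipy.stats import kstest

        pvals = []
        for _ in range(100):
            lt = rng.uniform(0, 1, 80)
            loc = np.array(["macula"] * 40 + ["periphery"] * 40)
            out = latent_time_tests(self._cells(lt, np.full(80, 10), loc))
            pvals.append(out["per_pcw"]["p"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_macula_lead_detected_in_every_group(self, rng):
        rows = []
        for pcw in (8, 10, 12):
            for loc, shift in (("macula", 0.1), ("periphery", 0.0)):
                lt = np.clip(rng.normal(0.4 + shift, 0.1, 2000), 0, 1)
                rows.append(self._cells(lt, np.full(2000, pcw), loc))
        cells = pd.concat(rows).reset_index(drop=True)
        cells["cell_id"] = [f"c{i}" for i in range(len(cells))]
        out = latent_time_tests(cells)
        tab = out["per_pcw"]
        assert (tab["mean_macula"] > tab["mean_periphery"]).all()
        assert (tab["p_adj"] < 0.05).all()

    def test_missing_location_skipped_and_reported(self, rng):
        lt = rng.uniform(0, 1, 40)
        cells = self._cells(lt, np.r_[np.full(20, 8), np.full(20, 10)],
                            np.r_[["macula"] * 20, ["periphery"] * 20])
        out = latent_time_tests(cells)
        assert out["skipped_pcw"] == [8, 10]
        assert len(out["per_pcw"]) == 0


class TestTrajectoryShapes:
    def test_module_means_reproduce_planted_shapes(self, small_atlas, small_log_expr):
        """Smoothed module means: 1 decreasing, 3 increasing, 2 interior peak."""
        a = small_atlas
        prpc = (a.cells["major_class"] == "PRPC").to_numpy()
        X = small_log_expr.subset_cells(prpc).dense()
        lt = a.cells.loc[prpc, "latent_time"].to_numpy()
        bins = np.quantile(lt, np.linspace(0, 1, 9))
        which = np.clip(np.searchsorted(bins, lt) - 1, 0, 7)
        means = {}
        for k in (1, 2, 3):
            idx = [i for i, g in enumerate(small_log_expr.genes) if g.startswith(f"MOD{k}_")]
            prof = np.array([X[idx][:, which == b].mean() for b in range(8)])
            means[k] = prof
        assert np.all(np.diff(means[1]) < 0)
        assert np.all(np.diff(means[3]) > 0)
        interior = np.argmax(means[2])
        assert 0 < interior < 7
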