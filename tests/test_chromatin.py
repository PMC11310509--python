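import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retina_atlas.chromatin import (
    call_dars,
    classify_overlap,
    gene_trajectories,
    link_peaks_to_genes,
    overlap_fraction,
    phase_summaries,
    segment_phases,
)
from retina_atlas.synthetic import (
    planted_phase_trajectories,
    simulate_marker_accessibility,
)


class TestDARs:
    def test_identical_accessibility_gives_no_dars(self, rng):
        acc = pd.DataFrame(
            np.tile(rng.uniform(1, 4, 20)[:, None], (1, 12)),
            index=[f"p{i}" for i in range(20)],
        )
        out = call_dars(acc, np.repeat(["a", "b", "c"], 4))
        assert not out["is_dar"].any()

    def test_planted_markers_recovered_exactly(self):
        acc, unit_class, truth = simulate_marker_accessibility(
            n_classes=4, n_replicates=5, effect_log2=2.0, seed=3
        )
        out = call_dars(acc, unit_class)
        called = out[out["is_dar"]]
        assert len(called) == len(truth)
        for row in called.itertuples():
            assert truth[row.peak_id] == row.focal_class

    def test_exact_wilcoxon_enumeration_oracle(self):
        """p-values match brute-force enumeration of rank-sum permutations."""
        from itertools import combinations

        focal = np.array([3.2, 3.4, 3.1, 3.9, 3.3])
        rest = np.array([1.0, 1.5, 0.9, 1.2, 1.1, 1.4, 0.8])
        acc = pd.DataFrame([np.r_[focal, rest]], index=["p0"])
        classes = np.array(["f"] * 5 + ["r"] * 7)
        out = call_dars(acc, classes)
        row = out[(out["focal_class"] == "f")].iloc[0]
        pooled = np.r_[focal, rest]
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:5].sum()
        count = sum(
            1 for comb in combinations(range(12), 5) if ranks[list(comb)].sum() >= obs
        )
        p_exact = count / 792  # C(12,5)
        assert row["p"] == pytest.approx(p_exact, rel=1e-9)

    def test_fold_change_gate_blocks_small_effects(self, rng):
        base = rng.uniform(2, 3, 12)
        acc = pd.DataFrame([base], index=["p0"]).copy()
        acc.iloc[0, :6] = 5.0
        acc.iloc[0, 6:] = 4.5  # log2FC = 0.5, clearly separated groups
        out = call_dars(acc, np.array(["a"] * 6 + ["b"] * 6))
        row = out[out["focal_class"] == "a"].iloc[0]
        assert row["p"] < 0.01
        assert not row["is_dar"]

    def test_single_replicate_rejected(self):
        acc = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"])
        with pytest.raises(ValueError):
            call_dars(acc, np.array(["a", "b", "b"]))


def _peaks(rows):
    return pd.DataFrame(rows, columns=["peak_id", "contig", "start", "end"])


def brute_force_fraction(query, reference):
    """Per-base counting oracle for covered fraction."""
    out = []
    for q in query.itertuples():
        covered = 0
        for pos in range(q.start, q.end):
            for r in reference.itertuples():
                if r.contig == q.contig and r.start <= pos < r.end:
                    covered += 1
                    break
        out.append(covered / (q.end - q.start))
    return np.array(out)


class TestOverlap:
    def test_identical_intervals_overlap(self):
        q = _peaks([("q", "c1", 10, 60)])
        r = _peaks([("r", "c1", 10, 60)])
        assert classify_overlap(q, r)["status"].iloc[0] == "overlapping"

    def test_disjoint_intervals_specific(self):
        q = _peaks([("q", "c1", 10, 60)])
        r = _peaks([("r", "c1", 100, 200)])
        assert classify_overlap(q, r)["status"].iloc[0] == "specific"

    def test_exact_twenty_percent_boundary_is_inclusive(self):
        q = _peaks([("q", "c1", 0, 100)])
        r = _peaks([("r", "c1", 80, 300)])
        out = classify_overlap(q, r)
        assert out["overlap_fraction"].iloc[0] == pytest.approx(0.2)
        assert out["status"].iloc[0] == "overlapping"

    def test_just_below_boundary_is_specific(self):
        q = _peaks([("q", "c1", 0, 100)])
        r = _peaks([("r", "c1", 81, 300)])
        assert classify_overlap(q, r)["status"].iloc[0] == "specific"

    def test_union_not_double_counted(self):
        q = _peaks([("q", "c1", 0, 100)])
        r = _peaks([("r1", "c1", 0, 30), ("r2", "c1", 10, 40)])
        assert overlap_fraction(q, r)[0] == pytest.approx(0.4)

    def test_zero_length_peak_rejected(self):
        q = pd.DataFrame(
            {"peak_id": ["q"], "contig": ["c1"], "start": [5], "end": [6]}
        )
        r = _peaks([("r", "c1", 0, 10)])
        q.loc[0, "end"] = 5
        from retina_atlas.io import FormatError

        with pytest.raises((ValueError, FormatError)):
            classify_overlap(q, r)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_base_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        contigs = ["c1", "c2"]
        q = _peaks(
            [
                (f"q{i}", rng.choice(contigs), s := int(rng.integers(0, 300)),
                 s + int(rng.integers(1, 60)))
                for i in range(8)
            ]
        )
        r = _peaks(
            [
                (f"r{i}", rng.choice(contigs), s := int(rng.integers(0, 300)),
                 s + int(rng.integers(1, 60)))
                for i in range(8)
            ]
        )
        assert np.allclose(overlap_fraction(q, r), brute_force_fraction(q, r))


class TestLinkage:
    def _inputs(self, rng, r_target=0.9, distance=1000):
        n_units = 24
        e = rng.normal(0, 1, n_units)
        ec = e - e.mean()
        noise = rng.normal(0, 1, n_units)
        nc = noise - noise.mean()
        nc -= nc @ ec / (ec @ ec) * ec  # orthogonal to centered expression
        # exact sample correlation r_target by construction
        a = r_target * ec / np.linalg.norm(ec) + np.sqrt(1 - r_target**2) * nc / np.linalg.norm(nc)
        units = [f"u{i}" for i in range(n_units)]
        acc = pd.DataFrame([a], index=["p0"], columns=units)
        expr = pd.DataFrame([e], index=["g0"], columns=units)
        peaks = _peaks([("p0", "c1", 10_000 + distance, 10_500 + distance)])
        anchors = pd.DataFrame({"gene": ["g0"], "contig": ["c1"], "position": [10_000]})
        return acc, expr, peaks, anchors

    def test_distant_peak_not_linked_despite_high_r(self, rng):
        acc, expr, peaks, anchors = self._inputs(rng, r_target=0.99, distance=300_000)
        out = link_peaks_to_genes(acc, expr, peaks, anchors)
        assert out.empty

    def test_correlated_nearby_peak_linked(self, rng):
        acc, expr, peaks, anchors = self._inputs(rng, r_target=0.9)
        out = link_peaks_to_genes(acc, expr, peaks, anchors)
        assert len(out) == 1
        assert out.iloc[0]["pearson_r"] > 0.8

    def test_threshold_boundary_inclusive(self, rng):
        acc, expr, peaks, anchors = self._inputs(rng, r_target=0.45)
        out = link_peaks_to_genes(acc, expr, peaks, anchors)
        assert len(out) == 1  # sample r constructed to be exactly 0.45
        acc2, expr2, peaks2, anchors2 = self._inputs(rng, r_target=0.449)
        assert link_peaks_to_genes(acc2, expr2, peaks2, anchors2).empty

    def test_missing_anchor_raises(self, rng):
        acc, expr, peaks, anchors = self._inputs(rng)
        with pytest.raises(KeyError, match="anchor"):
            link_peaks_to_genes(acc, expr, peaks, anchors.iloc[:0], genes=["g0"])

    def test_emitted_pairs_respect_both_thresholds(self, small_atlas):
        from retina_atlas.io import NormState, normalize

        a = small_atlas
        log_expr = normalize(a.counts, NormState.LOG1P_CPM).dense()
        cols = []
        for u in a.peak_acc.columns:
            s_, c_ = u.split("|")
            mask = (
                (a.cells["sample_id"] == s_) & (a.cells["major_class"] == c_)
            ).to_numpy()
            cols.append(log_expr[:, mask].mean(axis=1))
        expr_pb = pd.DataFrame(
            np.column_stack(cols), index=a.counts.genes, columns=a.peak_acc.columns
        )
        out = link_peaks_to_genes(a.peak_acc, expr_pb, a.peaks, a.gene_anchors)
        assert len(out) > 0
        assert (out["distance_bp"] <= 250_000).all()
        assert (out["pearson_r"] >= 0.45 - 1e-12).all()


class TestPhases:
    def test_all_increasing_is_pure_coupled_on(self):
        t = np.linspace(0, 1, 20)
        c = 1 + t
        s = 0.5 + t
        seg = segment_phases(t, c, s, s)
        assert seg.percentages["coupled_on"] == 100.0

    def test_open_chromatin_with_silent_gene_is_primed(self):
        t = np.linspace(0, 1, 20)
        c = 1 + 0.5 * t
        s = np.zeros_like(t)
        seg = segment_phases(t, c, s, s)
        assert seg.percentages["primed"] == 100.0

    def test_planted_boundaries_recovered_within_one_step(self):
        t, c, u, s, truth, bounds = planted_phase_trajectories(101)
        seg = segment_phases(t, c, u, s)
        mismatch = np.flatnonzero(seg.phases != truth)
        for i in mismatch:  # disagreements may only hug a planted switch
            assert min(abs(i - b) for b in bounds) <= 1
        assert sum(seg.percentages.values()) == pytest.approx(100.0)

    def test_scale_invariance(self):
        t, c, u, s, _, _ = planted_phase_trajectories(81)
        a = segment_phases(t, c, u, s)
        b = segment_phases(t, 7.3 * c, 0.2 * u, 0.2 * s)
        assert list(a.phases) == list(b.phases)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            segment_phases([0, 1], [1, 2], [1, 2], [1, 2])


class TestPhaseSummaries:
    def _seg(self, pct):
        t = np.linspace(0, 1, 10)
        seg = segment_phases(t, 1 + t, 0.5 + t, 0.5 + t)
        seg.percentages = pct
        return seg

    def test_pure_coupled_on_summary(self):
        pct = {"primed": 0.0, "coupled_on": 100.0, "coupled_off": 0.0, "decoupled": 0.0}
        segs = {f"g{i}": self._seg(dict(pct)) for i in range(3)}
        out = phase_summaries(segs)
        row = out["summary"].iloc[0]
        assert row["coupled_on"] == 100.0 and row["primed"] == 0.0

    def test_single_gene_class_equals_its_percentages(self):
        pct = {"primed": 10.0, "coupled_on": 60.0, "coupled_off": 30.0, "decoupled": 0.0}
        out = phase_summaries({"g": self._seg(pct)}, {"g": "Rod"})
        row = out["summary"].set_index("major_class").loc["Rod"]
        assert row["coupled_on"] == 60.0

    def test_planted_share_difference_detected(self, rng):
        def seg_with(share):
            pct = {
                "primed": 0.0,
                "coupled_on": share,
                "coupled_off": 100.0 - share,
                "decoupled": 0.0,
            }
            return self._seg(pct)

        segs = {}
        set_a, set_b = [], []
        for i in range(100):
            segs[f"a{i}"] = seg_with(30 + rng.normal(0, 5))
            segs[f"b{i}"] = seg_with(70 + rng.normal(0, 5))
            set_a.append(f"a{i}")
            set_b.append(f"b{i}")
        out = phase_summaries(segs, compare_sets=(set_a, set_b))
        assert out["comparison"]["p"] < 1e-6
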