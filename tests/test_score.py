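"""Scarcity filter, fold change, consistency, ranking, gene summary, 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gcscreen.errors import (
    ConfigurationError,
    EmptySampleError,
    InsufficientReplicationError,
)
from gcscreen.score import (
    CATEGORY_EXCLUDED,
    FilterPolicy,
    QpcrMeasurement,
    ScreenAbundance,
    apply_filter,
    consistency,
    ddct_fold,
    filter_threshold,
    fold_change,
    gene_summary,
    rank_hits,
    score_screens,
)


def make_screen(name, medians_gc, medians_nongc, genes=None, reps_gc=None, reps_ngc=None):
    """Build a ScreenAbundance from per-construct medians (and optional
    replicate percentage rows, each a list per replicate)."""
    ids = [f"c{i + 1}" for i in range(len(medians_gc))]
    genes = genes or ["g1"] * len(ids)

    def frame(medians, reps):
        data = {"gene": genes}
        reps = reps if reps is not None else [list(medians)] * 2
        for r, values in enumerate(reps, start=1):
            data[f"rep{r}_pct"] = values
        data["median_pct"] = medians
        return pd.DataFrame(data, index=pd.Index(ids, name="construct_id"))

    return ScreenAbundance(name=name, gc=frame(medians_gc, reps_gc),
                           nongc=frame(medians_nongc, reps_ngc))


class TestFilterThreshold:
    @pytest.mark.parametrize(
        "size,factor,expected",
        [(400, 10, 0.025), (1, 1, 100.0), (200, 10, 0.05)],
    )
    def test_values(self, size, factor, expected):
        assert filter_threshold(size, factor) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            filter_threshold(0)
        with pytest.raises(ConfigurationError):
            filter_threshold(400, 0.0)


class TestApplyFilter:
    def test_toy_pass_set(self):
        screen = make_screen(
            "s1",
            medians_gc=[0.5, 0.0, 0.01, 0.5],
            medians_nongc=[0.0, 0.5, 0.01, 0.5],
            genes=["gA", "gB", "gC", "gD"],
        )
        policy = FilterPolicy(library_size=400)  # threshold 0.025
        flags = apply_filter([screen], policy)
        assert flags["pass_screen1"].to_list() == [True, True, False, True]
        assert flags["consistent"].to_list() == [True, True, False, True]

    def test_exceeding_is_strict(self):
        screen = make_screen("s1", [0.025], [0.025])
        flags = apply_filter([screen], FilterPolicy(library_size=400))
        assert not flags["pass_screen1"].iloc[0]

    def test_two_screen_consistency(self):
        s1 = make_screen("s1", [0.5, 0.5], [0.5, 0.5])
        s2 = make_screen("s2", [0.5, 0.0], [0.5, 0.0])
        flags = apply_filter([s1, s2], FilterPolicy(library_size=400))
        assert flags["consistent"].to_list() == [True, False]

    def test_mismatched_manifests_rejected(self):
        s1 = make_screen("s1", [0.5], [0.5])
        s2 = make_screen("s2", [0.5, 0.5], [0.5, 0.5])
        with pytest.raises(ConfigurationError):
            apply_filter([s1, s2], FilterPolicy(library_size=400))


class TestFoldChange:
    def test_equal_medians_unit_fc(self):
        fc, l2 = fold_change(0.3, 0.3, pseudocount=0.0)
        assert fc == pytest.approx(1.0)
        assert l2 == pytest.approx(0.0)

    def test_quarter_fold(self):
        fc, l2 = fold_change(0.05, 0.20, pseudocount=1e-12)
        assert fc == pytest.approx(0.25, rel=1e-6)
        assert l2 == pytest.approx(-2.0, abs=1e-6)

    def test_absent_in_gc_stays_finite(self):
        fc, l2 = fold_change(0.0, 0.4, pseudocount=0.01)
        assert fc == pytest.approx(0.01 / 0.41)
        assert l2 == pytest.approx(np.log2(0.01 / 0.41))
        assert np.isfinite(l2)

    def test_default_pseudocount_is_half_min_nonzero(self):
        gc = np.array([0.0, 0.2])
        ngc = np.array([0.4, 0.1])
        fc, _ = fold_change(gc, ngc)  # delta = 0.05
        assert fc[0] == pytest.approx(0.05 / 0.45)

    def test_both_zero_without_pseudocount_raises(self):
        with pytest.raises(EmptySampleError):
            fold_change(0.0, 0.0, pseudocount=0.0)

    @given(
        st.lists(st.floats(0.001, 50.0), min_size=1, max_size=20),
        st.lists(st.floats(0.001, 50.0), min_size=1, max_size=20),
    )
    def test_antisymmetry_under_compartment_swap(self, a, b):
        n = min(len(a), len(b))
        gc, ngc = np.array(a[:n]), np.array(b[:n])
        delta = 0.01
        _, forward = fold_change(gc, ngc, pseudocount=delta)
        _, backward = fold_change(ngc, gc, pseudocount=delta)
        assert np.allclose(forward, -backward, atol=1e-12)


class TestConsistency:
    def test_hand_arithmetic(self):
        sd, inv = consistency([-2.0, -1.0])
        assert sd == pytest.approx(np.sqrt(0.5))
        assert inv == pytest.approx(np.sqrt(2.0))

    def test_identical_estimates_hit_cap(self):
        sd, inv = consistency([0.7, 0.7, 0.7], cap=100.0)
        assert sd == 0.0
        assert inv == 100.0

    def test_permutation_invariance(self):
        assert consistency([1.0, -3.0, 0.5]) == consistency([0.5, 1.0, -3.0])

    def test_single_estimate_raises(self):
        with pytest.raises(InsufficientReplicationError):
            consistency([1.0])


class TestScoreScreens:
    def _screens(self):
        reps_gc = [[4.0, 0.1, 1.0], [4.2, 0.12, 1.1]]
        reps_ngc = [[1.0, 1.6, 1.0], [1.1, 1.55, 0.9]]
        s1 = make_screen(
            "s1", [4.1, 0.11, 1.05], [1.05, 1.57, 0.95],
            genes=["gA", "gB", "gC"], reps_gc=reps_gc, reps_ngc=reps_ngc,
        )
        s2 = make_screen(
            "s2", [3.9, 0.1, 1.0], [1.0, 1.5, 1.0],
            genes=["gA", "gB", "gC"], reps_gc=reps_gc, reps_ngc=reps_ngc,
        )
        return [s1, s2]

    def test_structure_and_categories(self):
        scores = score_screens(self._screens(), FilterPolicy(library_size=400),
                               fc_cut=1.5)
        assert list(scores.index) == ["c1", "c2", "c3"]
        assert scores.loc["c1", "log2_fc"] > 1.5
        assert scores.loc["c2", "log2_fc"] < -1.5
        assert abs(scores.loc["c3", "log2_fc"]) < 0.3
        assert np.allclose(scores["fold_change"], 2.0 ** scores["log2_fc"])

    def test_excluded_category(self):
        s1 = make_screen("s1", [0.5, 0.0], [0.5, 0.0])
        scores = score_screens([s1], FilterPolicy(library_size=400))
        assert scores.loc["c2", "category"] == CATEGORY_EXCLUDED

    def test_screen_medians_mode_needs_two_screens(self):
        s1 = make_screen("s1", [0.5], [0.5])
        with pytest.raises(InsufficientReplicationError):
            score_screens([s1], FilterPolicy(library_size=400),
                          consistency_mode="screen_medians")
        scores = score_screens(self._screens(), FilterPolicy(library_size=400),
                               consistency_mode="screen_medians")
        assert np.isfinite(scores["fc_sd"]).all()

    def test_scale_invariance(self, small_manifest, rng):
        """Multiplying all counts of one replicate by a constant changes
        nothing: percentages normalize the depth away."""
        from gcscreen.pipeline import screen_abundance_from_counts
        from gcscreen.quantify import counts_from_array

        counts = rng.integers(1, 400, size=(5, len(small_manifest)))
        scaled = counts.copy()
        scaled[2] *= 13
        screens = []
        for variant in (counts, scaled):
            gc = counts_from_array(variant, small_manifest)
            ngc = counts_from_array(variant[::-1].copy(), small_manifest)
            screens.append(screen_abundance_from_counts("s", gc, ngc))
        a = score_screens([screens[0]], FilterPolicy(library_size=len(small_manifest)))
        b = score_screens([screens[1]], FilterPolicy(library_size=len(small_manifest)))
        pd.testing.assert_frame_equal(a, b)


class TestRankHits:
    def _scores(self):
        return pd.DataFrame(
            {
                "gene": ["gA", "gB", "gC", "gD", "gE"],
                "consistent": [True, True, True, True, False],
                "log2_fc": [-3.0, -2.0, 0.1, 2.5, -9.0],
                "inv_sd": [5.0, 5.0, 5.0, 5.0, 5.0],
            },
            index=pd.Index([f"c{i}" for i in range(1, 6)], name="construct_id"),
        )

    def test_boundary_inclusive_and_excluded_dropped(self):
        depleted, enriched = rank_hits(self._scores(), fc_cut=2.0,
                                       consistency_quantile=0.0)
        assert list(depleted.index) == ["c1", "c2"]  # c2 exactly at the cut
        assert list(enriched.index) == ["c4"]
        assert "c5" not in depleted.index  # not consistently recovered

    def test_tie_break_by_inv_sd_then_id(self):
        scores = self._scores()
        scores.loc["c2", "log2_fc"] = -3.0
        scores.loc["c2", "inv_sd"] = 9.0
        depleted, _ = rank_hits(scores, fc_cut=2.0, consistency_quantile=0.0)
        assert list(depleted.index) == ["c2", "c1"]

    def test_consistency_quantile_gate(self):
        scores = self._scores()
        scores.loc["c1", "inv_sd"] = 0.1  # extreme but inconsistent
        depleted, _ = rank_hits(scores, fc_cut=2.0, consistency_quantile=0.5)
        assert "c1" not in depleted.index

    def test_empty_consistent_set_warns(self):
        scores = self._scores()
        scores["consistent"] = False
        with pytest.warns(UserWarning):
            depleted, enriched = rank_hits(scores)
        assert depleted.empty and enriched.empty


class TestGeneSummary:
    def _scores(self):
        # gene gX mirrors the described recovery pattern: of 5 hairpins one is
        # recovered in both screens, two in exactly one, two in none
        frame = pd.DataFrame(
            {
                "gene": ["gX"] * 5 + ["gY"] * 2,
                "pass_screen1": [True, True, False, False, False, True, True],
                "pass_screen2": [True, False, True, False, False, True, True],
                "log2_fc": [-4.0, -1.0, -2.0, 0.0, 0.0, 0.5, 0.7],
            },
            index=pd.Index([f"c{i}" for i in range(7)], name="construct_id"),
        )
        frame["consistent"] = frame["pass_screen1"] & frame["pass_screen2"]
        return frame

    def test_recovery_partition(self):
        summary = gene_summary(self._scores())
        row = summary.loc["gX"]
        assert (
            row["n_recovered_all_screens"],
            row["n_recovered_one_screen"],
            row["n_lost_all_screens"],
        ) == (1, 2, 2)
        assert row[["n_recovered_all_screens", "n_recovered_one_screen",
                    "n_lost_all_screens"]].sum() == row["n_constructs"]
        assert summary.loc["gX", "median_log2_fc"] == pytest.approx(-4.0)

    def test_fully_recovered_gene(self):
        summary = gene_summary(self._scores())
        row = summary.loc["gY"]
        assert (row["n_recovered_all_screens"], row["n_recovered_one_screen"],
                row["n_lost_all_screens"]) == (2, 0, 0)
        assert summary.loc["gY", "median_log2_fc"] == pytest.approx(0.6)


def test_plot_scatter_writes_figure(tmp_path):
    from gcscreen.score import plot_scatter

    scores = pd.DataFrame(
        {
            "gene": ["gA", "gB", "gC"],
            "consistent": [True, True, True],
            "log2_fc": [-3.0, 0.1, 2.5],
            "inv_sd": [4.0, 2.0, 3.0],
            "category": ["positive_regulator_candidate", "neutral",
                         "negative_regulator_candidate"],
        },
        index=pd.Index(["c1", "c2", "c3"], name="construct_id"),
    )
    out = tmp_path / "scatter.png"
    plot_scatter(scores, out)
    assert out.stat().st_size > 0


class TestDdct:
    def test_identity(self):
        assert ddct_fold(20.0, 20.0, 20.0, 20.0) == pytest.approx(1.0)

    def test_minus_two_gives_four(self):
        # ddCt = -2  ->  2^2 = 4
        assert ddct_fold(18.0, 20.0, 20.0, 20.0) == pytest.approx(4.0)

    def test_hand_arithmetic(self):
        m = QpcrMeasurement(20.0, 15.0, 24.0, 15.0)
        assert m.fold_difference == pytest.approx(16.0)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ConfigurationError):
            ddct_fold(float("nan"), 20.0, 20.0, 20.0)
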