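"""Signature selection, survival cut-point search, scoring and alpha."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hypoxiscore.differential import GroupComparison
from hypoxiscore.io import published_score_thresholds
from hypoxiscore.quantify import ExpressionMatrix
from hypoxiscore.score import (
    SignatureEmptyError,
    ThresholdTable,
    build_threshold_table,
    compute_scores,
    cronbach_alpha,
    evaluate_risk_groups,
    optimal_cutpoint,
    select_score_threshold,
    select_signature,
)

from _oracles import cronbach_brute, cutpoint_brute
from conftest import make_clinical


def fake_comparison(genes, pvals, folds, grouping="relapse"):
    table = pd.DataFrame({"p": pvals, "fold": folds}, index=genes)
    return GroupComparison(
        grouping=grouping,
        case_label="recurrent",
        control_label="non-recurrent",
        case_samples=[],
        control_samples=[],
        table=table,
        mean_overexpression_pct=0.0,
        mean_fold=0.0,
    )


class TestSelectSignature:
    def test_filters_on_p_and_direction(self):
        comp = fake_comparison(
            ["A", "B", "C", "D"], [0.01, 0.2, 0.04, 0.01], [0.5, 0.9, 1.2, -0.8]
        )
        assert select_signature(comp) == ["A", "C"]  # D excluded: negative fold

    def test_empty_selection_raises(self):
        comp = fake_comparison(["A"], [0.5], [1.0])
        with pytest.raises(SignatureEmptyError, match="relax"):
            select_signature(comp)

    def test_requires_relapse_grouping(self):
        comp = fake_comparison(["A"], [0.01], [1.0], grouping="her2")
        with pytest.raises(ValueError):
            select_signature(comp)


class TestOptimalCutpoint:
    def test_separating_toy(self):
        """Events only above the gap between 2 and 3: the optimum threshold
        falls in (2, 3) and matches exhaustive search."""
        values = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([100.0, 100.0, 10.0, 12.0])
        events = np.array([0, 0, 1, 1])
        res = optimal_cutpoint(values, times, events, min_frac=0.1)
        assert 2.0 < res.threshold < 3.0
        tau, stat = cutpoint_brute(values, times, events, min_frac=0.1)
        assert res.threshold == pytest.approx(tau)
        assert res.statistic == pytest.approx(stat, abs=1e-10)

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="no cut"):
            optimal_cutpoint([2.0, 2.0, 2.0], [5.0, 6.0, 7.0], [1, 1, 0])

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(0)
        n = 25
        values = rng.lognormal(0, 1, n)
        times = rng.exponential(50, n) + 1
        events = rng.integers(0, 2, n)
        events[0] = 1
        r1 = optimal_cutpoint(values, times, events)
        perm = rng.permutation(n)
        r2 = optimal_cutpoint(values[perm], times[perm], events[perm])
        assert r1.threshold == pytest.approx(r2.threshold)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_min_frac_constrains_candidates(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        times = np.linspace(10, 100, 10)
        events = np.ones(10, dtype=int)
        res = optimal_cutpoint(values, times, events, min_frac=0.3)
        n_high = (values > res.threshold).sum()
        assert 3 <= n_high <= 7

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(10, 40))
            values = rng.lognormal(0, 1, n).round(2)
            times = rng.exponential(60, n).round(1) + 1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            res = optimal_cutpoint(values, times, events)
            oracle = cutpoint_brute(values, times, events)
            assert oracle is not None
            assert res.threshold == pytest.approx(oracle[0])
            assert res.statistic == pytest.approx(oracle[1], abs=1e-10)


def rq_matrix(frame: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(values=frame, calibrator="cohort_mean")


class TestThresholdTableAndScores:
    def test_published_mode_returns_fixture(self):
        rq = rq_matrix(
            pd.DataFrame(
                np.ones((6, 4)),
                index=["EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI"],
                columns=list("abcd"),
            )
        )
        clin = make_clinical(n=4)
        table = build_threshold_table(rq, list(rq.genes), clin, mode="published")
        pub = published_score_thresholds()
        np.testing.assert_allclose(table.thresholds.loc[pub.index], pub)
        assert table.mode == "published"

    def test_search_and_published_share_schema(self, quantified32, cohort32):
        cohort, _ = cohort32
        _, rq = quantified32
        genes = ["EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI"]
        searched = build_threshold_table(rq, genes, cohort.clinical, mode="search")
        published = build_threshold_table(rq, genes, cohort.clinical, mode="published")
        assert list(searched.table.columns) == list(published.table.columns)
        assert searched.genes == published.genes
        # searched thresholds sit strictly inside the observed RQ range
        for g in genes:
            lo = rq.values.loc[g].min()
            hi = rq.values.loc[g].max()
            assert lo < searched.thresholds[g] < hi

    def test_worked_example_score_is_four(self):
        """The published thresholds applied to the worked RQ vector give
        indicators (1,1,0,1,0,1) and a score of 4."""
        rq_vals = {"EPO": 8.0, "ETS1": 2.0, "ENO1": 0.5, "PGK1": 1.5, "LDHA": 1.0, "TPI": 1.2}
        frame = pd.DataFrame({"pat": rq_vals}).loc[
            ["EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI"]
        ]
        table = ThresholdTable(
            table=pd.DataFrame(
                {
                    "threshold": published_score_thresholds(),
                    "statistic": np.nan,
                    "n_candidates": 0,
                    "min_frac": np.nan,
                }
            ),
            mode="published",
        )
        scores = compute_scores(rq_matrix(frame), table)
        assert list(scores.loc["pat", ["EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI"]]) == [
            1, 1, 0, 1, 0, 1,
        ]
        assert scores.loc["pat", "score"] == 4

    def test_all_below_thresholds_scores_zero(self):
        frame = pd.DataFrame(
            {"pat": {"EPO": 0.1, "ETS1": 0.1, "ENO1": 0.1, "PGK1": 0.1, "LDHA": 0.1, "TPI": 0.1}}
        )
        table = build_threshold_table(
            rq_matrix(frame), list(frame.index), make_clinical(n=1), mode="published"
        )
        assert compute_scores(rq_matrix(frame), table).loc["pat", "score"] == 0

    def test_boundary_equality_scores_zero(self):
        """Expression exactly at the threshold does not count (strict >)."""
        pub = published_score_thresholds()
        frame = pd.DataFrame({"pat": pub})
        table = build_threshold_table(
            rq_matrix(frame), list(pub.index), make_clinical(n=1), mode="published"
        )
        assert compute_scores(rq_matrix(frame), table).loc["pat", "score"] == 0

    def test_score_monotone_in_rq(self):
        rng = np.random.default_rng(2)
        genes = ["EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI"]
        frame = pd.DataFrame(
            rng.lognormal(0, 1, size=(6, 10)), index=genes,
            columns=[f"P{i:02d}" for i in range(10)],
        )
        table = build_threshold_table(
            rq_matrix(frame), genes, make_clinical(n=10), mode="published"
        )
        s0 = compute_scores(rq_matrix(frame), table)["score"]
        boosted = frame * 1.5
        s1 = compute_scores(rq_matrix(boosted), table)["score"]
        assert (s1 >= s0).all()

    def test_masked_gene_flags_incomplete(self):
        genes = ["EPO", "ETS1", "ENO1", "PGK1", "LDHA", "TPI"]
        frame = pd.DataFrame(
            np.full((6, 2), 10.0), index=genes, columns=["a", "b"]
        )
        frame.loc["EPO", "a"] = np.nan
        table = build_threshold_table(
            rq_matrix(frame), genes, make_clinical(n=2), mode="published"
        )
        scores = compute_scores(rq_matrix(frame), table)
        assert not scores.loc["a", "complete"]
        assert scores.loc["b", "complete"]
        assert scores.loc["a", "score"] == 5  # masked gene contributes 0


class TestScoreThreshold:
    def test_profile_tie_range_contains_selection(self):
        """Scores (0,0,3,3) with events only among the 3s: every s in
        {0,1,2} gives the same split; the selected s lies in that range and
        the profile is constant over it."""
        scores = np.array([0, 0, 3, 3])
        times = np.array([100.0, 90.0, 10.0, 15.0])
        events = np.array([0, 0, 1, 1])
        res = select_score_threshold(scores, times, events)
        assert res.s_star in {0, 1, 2}
        stats = res.profile["statistic"]
        assert stats.loc[0] == pytest.approx(stats.loc[1], abs=1e-9)
        assert stats.loc[1] == pytest.approx(stats.loc[2], abs=1e-9)

    def test_single_score_value_rejected(self):
        with pytest.raises(ValueError, match="single value"):
            select_score_threshold([2, 2, 2], [5.0, 6.0, 7.0], [1, 0, 1])

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(3)
        n = 30
        scores = rng.integers(0, 7, n)
        times = rng.exponential(50, n) + 1
        events = rng.integers(0, 2, n)
        events[0] = 1
        r1 = select_score_threshold(scores, times, events)
        r2 = select_score_threshold(scores, np.sqrt(times), events)
        assert r1.s_star == r2.s_star
        np.testing.assert_allclose(
            r1.profile["statistic"], r2.profile["statistic"], atol=1e-9
        )


class TestEvaluateRiskGroups:
    def test_high_group_holds_all_events(self):
        scores = pd.Series([1, 1, 1, 4, 4, 4], index=[f"P{i:02d}" for i in range(6)])
        clin = make_clinical(
            n=6, relapse=[0, 0, 0, 1, 1, 1], rfs_months=[100.0, 90.0, 80.0, 20.0, 30.0, 40.0]
        )
        res = evaluate_risk_groups(scores, 2, clin)
        assert res.n_low == 3 and res.n_high == 3
        assert res.events_low == 0 and res.events_high == 3
        assert res.incidence_low[60] == pytest.approx(0.0)
        assert res.incidence_high[60] == pytest.approx(1.0)
        assert res.hazard_ratio == np.inf or res.hazard_ratio > 10

    def test_identical_outcomes_null(self):
        scores = pd.Series([1, 1, 4, 4], index=[f"P{i:02d}" for i in range(4)])
        clin = make_clinical(n=4, relapse=[1, 0, 1, 0], rfs_months=[30.0, 90.0, 30.0, 90.0])
        res = evaluate_risk_groups(scores, 2, clin)
        assert res.logrank.p_value == pytest.approx(1.0)

    def test_incidence_is_curve_complement(self):
        scores = pd.Series([0, 0, 3, 3, 3], index=[f"P{i:02d}" for i in range(5)])
        clin = make_clinical(
            n=5, relapse=[0, 1, 1, 1, 0], rfs_months=[100.0, 50.0, 20.0, 70.0, 130.0]
        )
        res = evaluate_risk_groups(scores, 1, clin)
        from hypoxiscore.survival import survival_at

        assert res.incidence_high[60] == pytest.approx(
            1.0 - survival_at(res.curve_high, 60).survival
        )


class TestCronbachAlpha:
    def test_two_perfectly_correlated_items(self):
        x = np.arange(10, dtype=float)
        items = pd.DataFrame({"a": x, "b": 2 * x + 3})
        assert cronbach_alpha(items) == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        items = pd.DataFrame(rng.normal(0, 1, size=(1000, 6)))
        assert abs(cronbach_alpha(items)) < 0.1

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 50)
        items = pd.DataFrame(
            {f"i{k}": base + rng.normal(0, 0.8, 50) for k in range(4)}
        )
        assert cronbach_alpha(items, standardized=False) == pytest.approx(
            cronbach_brute(items.to_numpy()), rel=1e-12
        )

    def test_affine_rescaling_invariance_when_standardized(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 40)
        items = pd.DataFrame({f"i{k}": base + rng.normal(0, 0.5, 40) for k in range(3)})
        rescaled = items * [2.0, 0.1, 7.0] + [5.0, -3.0, 0.0]
        assert cronbach_alpha(items) == pytest.approx(cronbach_alpha(rescaled), rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestSelectionOptimism:
    """The in-sample p of the optimized procedure is anticonservative; the
    permutation extra re-optimizes per permutation and is calibrated."""

    def _end_to_end_p(self, cohort):
        from hypoxiscore.differential import compare_groups
        from hypoxiscore.quantify import (
            apply_detection_cutoff,
            compute_delta_ct,
            compute_rq,
            select_references,
        )

        ct = apply_detection_cutoff(cohort.ct)
        dct = compute_delta_ct(
            ct, select_references("housekeeping", available_genes=ct.genes)
        )
        rq = compute_rq(dct)
        comp = compare_groups(rq, dct, cohort.clinical, "relapse")
        try:
            sig = select_signature(comp)
        except SignatureEmptyError:
            return np.nan, None, None
        table = build_threshold_table(rq, sig, cohort.clinical)
        scores = compute_scores(rq, table)["score"]
        cut = select_score_threshold(
            scores.to_numpy(), cohort.clinical.times, cohort.clinical.events
        )
        res = evaluate_risk_groups(scores, cut.s_star, cohort.clinical)
        return res.logrank.p_value, rq, sig

    def test_null_in_sample_p_is_anticonservative(self):
        """Zero planted effect: the optimized in-sample p rejects far more
        often than the nominal 5% (threshold search optimism)."""
        from hypoxiscore.simulate import null_config, simulate_cohort

        ps = []
        for rep in range(12):
            cohort, _ = simulate_cohort(null_config(n_patients=150, seed=7000 + rep))
            p, _, _ = self._end_to_end_p(cohort)
            if np.isfinite(p):
                ps.append(p)
        assert len(ps) >= 4
        assert np.mean(np.asarray(ps) < 0.05) > 0.2

    def test_permutation_extra_corrects_null_p(self):
        """On a null cohort the selection-corrected permutation p is
        substantially larger than the optimistic in-sample p."""
        from hypoxiscore.score import permutation_p_extra
        from hypoxiscore.simulate import null_config, simulate_cohort

        for rep in range(10):
            cohort, _ = simulate_cohort(null_config(n_patients=150, seed=7100 + rep))
            p, rq, sig = self._end_to_end_p(cohort)
            if np.isfinite(p) and p < 0.05:
                p_corr = permutation_p_extra(
                    rq, sig, cohort.clinical, n_perm=60, seed=1
                )
                assert p_corr > p
                return
        pytest.skip("no optimistic null rejection found in 10 seeds")
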