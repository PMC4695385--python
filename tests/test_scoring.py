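"""ROC/FDR calibration, q-values, gene t-tests and the hit conjunction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from screenscore.errors import CalibrationError, DomainError, InsufficientDataError
from screenscore.qc_normalization import RelativeGrowthRecord
from screenscore.scoring import (
    GeneScore,
    call_hits,
    estimate_qvalues,
    roc_calibration,
    score_genes,
)


def brute_force_calibration(positives, negatives, target):
    """Independent oracle: try every admissible cutoff, keep the largest.

    Cutoffs are the observed values plus one above the maximum; a well is
    called iff value < cutoff; FDR = FP/(FP+TP).
    """
    cutoffs = sorted(set(positives) | set(negatives))
    cutoffs.append(max(cutoffs) + 1.0)
    best = None
    for t in cutoffs:
        tp = sum(1 for v in positives if v < t)
        fp = sum(1 for v in negatives if v < t)
        if tp >= 1 and fp / (fp + tp) <= target:
            best = t
    return best


class TestROCCalibration:
    def test_perfect_separation(self):
        # two positives: a single false positive would give FDR 1/3 > 0.3,
        # so the chosen cutoff admits none and its FDR is exactly 0
        cal = roc_calibration([10, 20], [90, 100, 110], 0.30)
        assert cal.auc == pytest.approx(1.0)
        assert cal.chosen_threshold_pct == 90
        idx = np.searchsorted(cal.thresholds, cal.chosen_threshold_pct)
        assert cal.fdr[idx] == 0.0

    def test_hand_enumerated_example(self):
        # positives {10,20,30,80}, negatives {50,90,100,110}: at cutoff 90
        # FDR = 1/5 = 0.2; the next observed cutoff (100) gives 2/6 = 1/3
        cal = roc_calibration([10, 20, 30, 80], [50, 90, 100, 110], 0.30)
        assert cal.chosen_threshold_pct == 90
        idx = np.searchsorted(cal.thresholds, 90)
        assert cal.fdr[idx] == pytest.approx(0.2)

    def test_calibration_failure_carries_the_curve(self):
        # all positives at/above all negatives: every cutoff is FP-heavy
        with pytest.raises(CalibrationError) as err:
            roc_calibration([100, 110], [10, 20, 30, 40, 50, 60, 70], 0.10)
        assert err.value.calibration is not None
        assert len(err.value.calibration.fdr) > 0

    def test_empty_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_calibration([], [1.0], 0.3)

    def test_tpr_fpr_nondecreasing_and_fdr_bound_holds(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(40, 15, 30)
        neg = rng.normal(100, 15, 30)
        cal = roc_calibration(pos, neg, 0.30)
        assert np.all(np.diff(cal.tpr) >= 0)
        assert np.all(np.diff(cal.fpr) >= 0)
        idx = np.searchsorted(cal.thresholds, cal.chosen_threshold_pct)
        assert cal.fdr[idx] <= 0.30

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_on_small_control_sets(self, data):
        # exhaustive-enumeration equivalence on <= 12-well control sets
        values = st.integers(0, 120).map(float)
        pos = data.draw(st.lists(values, min_size=1, max_size=6))
        neg = data.draw(st.lists(values, min_size=1, max_size=6))
        target = data.draw(st.sampled_from([0.1, 0.3, 0.5]))
        expected = brute_force_calibration(pos, neg, target)
        if expected is None:
            with pytest.raises(CalibrationError):
                roc_calibration(pos, neg, target)
        else:
            cal = roc_calibration(pos, neg, target)
            assert cal.chosen_threshold_pct == expected

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(5, 90, 12)
        neg = rng.uniform(40, 140, 12)
        base = roc_calibration(pos, neg, 0.99).auc
        for f in (np.log, np.sqrt, lambda x: x ** 3, lambda x: x / 7 + 2):
            assert roc_calibration(f(pos), f(neg), 0.99).auc == pytest.approx(base)


class TestQValues:
    def test_single_p_is_its_own_q(self):
        assert estimate_qvalues([0.05]) == pytest.approx([0.05])

    def test_bh_step_up_hand_examples(self):
        np.testing.assert_allclose(estimate_qvalues([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(estimate_qvalues([0.001, 0.5]),
                                   [0.002, 0.5])

    def test_output_order_matches_input_order(self):
        q = estimate_qvalues([0.5, 0.001])
        np.testing.assert_allclose(q, [0.5, 0.002])

    def test_out_of_domain_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.1]):
            with pytest.raises(DomainError):
                estimate_qvalues(bad)

    def test_storey_scales_bh_by_pi0(self):
        p = [0.001, 0.002, 0.8, 0.9]
        q_bh = estimate_qvalues(p, method="bh")
        q_st = estimate_qvalues(p, method="storey")
        # pi0 = #{p > 0.5} / (m * 0.5) = 2 / 2 = 1 here -> identical
        np.testing.assert_allclose(q_st, q_bh)
        p2 = [0.001, 0.002, 0.003, 0.8]
        # pi0 = 1/2; Storey q halves the BH values
        np.testing.assert_allclose(estimate_qvalues(p2, method="storey"),
                                   0.5 * np.asarray(estimate_qvalues(p2)))

    def test_nan_passes_through_without_joining_the_family(self):
        q = estimate_qvalues([0.01, float("nan"), 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose([q[0], q[2]],
                                   estimate_qvalues([0.01, 0.04]))

    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1,
                    max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_bh_monotone_in_p_and_never_below_p(self, p):
        q = np.asarray(estimate_qvalues(p))
        p = np.asarray(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def records_for(gene_values):
    recs = []
    for gene, values in gene_values.items():
        for i, v in enumerate(values):
            recs.append(RelativeGrowthRecord(
                reagent_id=f"sh{gene}_{i+1}", target_gene=gene, plate_id="P1",
                control_class="candidate", n_replicates=3,
                relative_growth_pct=float(v)))
    return recs


class TestScoreGenes:
    CONTROLS = [100.0, 105.0, 110.0]

    def test_gene_identical_to_controls_scores_null(self):
        scores = score_genes(records_for({"G": self.CONTROLS}),
                             self.CONTROLS, calibration=50.0)
        (s,) = scores
        assert s.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert s.p_value == pytest.approx(1.0)
        assert not s.is_hit

    @pytest.mark.parametrize("equal_var", [False, True])
    def test_hand_worked_t_example(self, equal_var):
        # (50,55,60) vs (100,105,110): equal n and variance, so Welch and
        # Student agree: t = -50/sqrt(50/3) = -12.2474, df = 4
        scores = score_genes(records_for({"G": [50, 55, 60]}), self.CONTROLS,
                             calibration=52.0, equal_var=equal_var)
        (s,) = scores
        assert s.t_statistic == pytest.approx(-12.247449, abs=1e-5)
        expected_p = 2 * stats.t.sf(12.247449, df=4)
        assert s.p_value == pytest.approx(expected_p, rel=1e-4)
        assert s.p_value == pytest.approx(2.5e-4, rel=0.05)
        assert s.n_shrnas_below_cutoff == 1  # only the 50 sits below 52

    def test_single_value_gene_flagged_not_dropped(self):
        scores = score_genes(records_for({"G": [40.0], "H": [90.0, 95.0]}),
                             self.CONTROLS, calibration=52.0)
        by_gene = {s.target_gene: s for s in scores}
        assert set(by_gene) == {"G", "H"}
        assert np.isnan(by_gene["G"].p_value)
        assert np.isnan(by_gene["G"].q_value)
        assert not by_gene["G"].is_hit
        assert np.isfinite(by_gene["H"].p_value)

    def test_counts_below_cutoff_and_means(self):
        scores = score_genes(records_for({"G": [10, 20, 60, 70, 80]}),
                             self.CONTROLS, calibration=52.0)
        (s,) = scores
        assert s.n_shrnas_total == 5
        assert s.n_shrnas_below_cutoff == 2
        assert s.mean_relative_growth_pct == pytest.approx(48.0)


def score(gene="G", p=1e-5, q=0.005, n_below=5, n_total=5, growth=30.0):
    level = {5: 1, 4: 2, 3: 3}.get(n_below)
    return GeneScore(target_gene=gene, mean_relative_growth_pct=growth,
                     t_statistic=-10.0, p_value=p, q_value=q,
                     n_shrnas_total=n_total, n_shrnas_below_cutoff=n_below,
                     significance_level=level, is_hit=False)


class TestCallHits:
    def test_full_conjunction_level_1(self):
        table = call_hits([score(n_below=5)])
        assert list(table["target_gene"]) == ["G"]
        assert table.loc[0, "significance_level"] == 1

    def test_large_p_never_hits(self):
        assert call_hits([score(p=0.5, q=1e-4, n_below=5)]).empty

    def test_shrna_count_boundary_at_three(self):
        assert call_hits([score(n_below=2)]).empty
        table = call_hits([score(n_below=3)])
        assert len(table) == 1
        assert table.loc[0, "significance_level"] == 3

    def test_sorted_by_growth_with_gene_tiebreak(self):
        table = call_hits([score("B", growth=20.0), score("A", growth=20.0),
                           score("C", growth=10.0)])
        assert list(table["target_gene"]) == ["C", "A", "B"]

    @given(dp=st.floats(0, 1), dq=st.floats(0, 1), dn=st.integers(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_hit_calling_is_monotone(self, dp, dq, dn):
        # improving p, q or the hairpin count never un-hits a hit
        base = score(p=5e-5, q=0.008, n_below=3)
        if not call_hits([base]).empty:
            better = score(p=base.p_value * (1 - dp) + 1e-300,
                           q=base.q_value * (1 - dq) + 1e-300,
                           n_below=min(5, base.n_shrnas_below_cutoff + dn))
            assert not call_hits([better]).empty
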