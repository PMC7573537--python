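"""Per-ROI activation tables, condition differences and Holm adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgpathways.bayes_factors import DegenerateSampleError
from bgpathways.compound_contrasts import compound_estimates
from bgpathways.data_model import BayesResult, Condition, EvidenceCategory, RoiId
from bgpathways.roi_stats import (
    activation_table,
    active_rois,
    condition_difference_table,
    holm_adjust,
    is_active,
    RoiStatRow,
)
from bgpathways.synthetic_data import SyntheticParams, default_assignment, generate_dataset


def make_estimates(params, seed):
    table, _ = generate_dataset(params, seed=seed)
    return compound_estimates(table, default_assignment(params))


def small_counts():
    return {
        Condition.EXECUTION: 4,
        Condition.INHIBITION_PRO: 3,
        Condition.INHIBITION_REAC: 3,
    }


def result_with(p, bf10):
    category = (EvidenceCategory.SUBSTANTIAL_H1 if bf10 > 3
                else EvidenceCategory.INTERMEDIATE)
    return BayesResult(t=1.0, df=29, n_eff=30, p=p, bf10=bf10, category=category)


class TestActivation:
    def test_zero_variance_cells_raise_degenerate_error(self):
        params = SyntheticParams(
            n_participants=30,
            contrast_counts=small_counts(),
            roi_means={(RoiId.parse("L_THAL"), Condition.EXECUTION): 0.3},
            between_participant_sd=0.0,
            within_contrast_sd=0.0,
        )
        est = make_estimates(params, seed=0)
        with pytest.raises(DegenerateSampleError):
            activation_table(est, Condition.EXECUTION)

    def test_tiny_jitter_around_zero_activates_nothing(self):
        params = SyntheticParams(
            n_participants=30, contrast_counts=small_counts(),
            between_participant_sd=1e-6, within_contrast_sd=0.0,
        )
        est = make_estimates(params, seed=1)
        rows = activation_table(est, Condition.EXECUTION)
        assert len(rows) == 16
        assert active_rois(rows) == frozenset()
        assert all(abs(r.result.t) < 5 for r in rows)

    def test_null_false_active_rate_matches_or_criterion_level(self):
        """Under a true null the p<0.05-or-BF>3 rule fires at ~5% per ROI.

        At N=30 the BF>3 region is strictly inside the p<0.05 region, so the
        OR criterion's joint level equals the frequentist 0.05.  Over 100
        seeds x 16 ROIs the observed rate must sit inside the binomial 99%
        band around 0.05 ([0.036, 0.064] at 1600 trials).
        """
        params = SyntheticParams(n_participants=30, contrast_counts=small_counts())
        flags = []
        for seed in range(100):
            rows = activation_table(make_estimates(params, seed=seed), Condition.EXECUTION)
            flags.extend(row.active for row in rows)
        rate = np.mean(flags)
        assert 0.036 <= rate <= 0.064


class TestConditionDifference:
    def test_identical_cells_degenerate(self):
        params = SyntheticParams(
            n_participants=10, contrast_counts=small_counts(),
            between_participant_sd=0.2, within_contrast_sd=0.0,
        )
        est = make_estimates(params, seed=2)
        with pytest.raises(DegenerateSampleError):
            condition_difference_table(est, Condition.EXECUTION, Condition.EXECUTION)

    def test_swap_negates_t_preserves_bf(self):
        params = SyntheticParams(n_participants=12, contrast_counts=small_counts())
        est = make_estimates(params, seed=3)
        ab = condition_difference_table(est, Condition.EXECUTION, Condition.INHIBITION_ALL)
        ba = condition_difference_table(est, Condition.INHIBITION_ALL, Condition.EXECUTION)
        for r1, r2 in zip(ab, ba):
            assert r1.result.t == pytest.approx(-r2.result.t)
            assert r1.result.bf10 == pytest.approx(r2.result.bf10, rel=1e-9)

    def test_single_shifted_roi_dominates_difference_table(self):
        """A 0.3 %BOLD execution-vs-inhibition shift on one ROI tops |t|."""
        shifted = RoiId.parse("R_IFG")
        params = SyntheticParams(
            n_participants=30, contrast_counts=small_counts(),
            roi_means={(shifted, Condition.EXECUTION): 0.3},
        )
        hits = 0
        for seed in range(50):
            est = make_estimates(params, seed=seed)
            rows = condition_difference_table(est, Condition.EXECUTION,
                                              Condition.INHIBITION_ALL)
            top = max(rows, key=lambda r: abs(r.result.t))
            hits += top.roi == shifted
        assert hits >= 48  # >= 95% of 50 seeds


class TestHolm:
    def test_step_down_hand_examples(self):
        assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])
        assert holm_adjust([0.5]) == pytest.approx([0.5])
        assert holm_adjust([0.9, 0.8]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_matches_hand_formula_and_never_decreases(self, pvals):
        """Independent oracle: sort, multiply by (m-i), running max, cap at 1."""
        adjusted = holm_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[idx]))
            expected[idx] = running
        assert adjusted == pytest.approx(expected)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, derandomize=True)
    def test_permutation_equivariance(self, perm):
        pvals = np.array([0.003, 0.04, 0.2, 0.049, 0.51, 0.011])
        base = holm_adjust(pvals)
        permuted = holm_adjust(pvals[perm])
        assert permuted == pytest.approx(base[perm])


class TestActiveCriterion:
    @pytest.mark.parametrize(
        "p,bf,expected",
        [(0.04, 2.0, True), (0.20, 4.0, True), (0.20, 0.5, False), (0.05, 3.0, False)],
    )
    def test_or_rule(self, p, bf, expected):
        assert is_active(result_with(p, bf)) is expected

    def test_active_rois_filters_rows(self):
        rows = [
            RoiStatRow(RoiId.parse("L_STR"), "execution", result_with(0.04, 2.0), True),
            RoiStatRow(RoiId.parse("R_STR"), "execution", result_with(0.2, 0.5), False),
        ]
        assert active_rois(rows) == {RoiId.parse("L_STR")}
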