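"""Pathway membership maps and product-of-Bayes-factors evidence."""

import math

import pytest

from bgpathways.compound_contrasts import compound_estimates
from bgpathways.data_model import Condition, DataError, Hemisphere, RoiId, SUBCORTICAL_ROIS
from bgpathways.pathway_evidence import (
    EVIDENCE_CONDITIONS,
    PathwayModel,
    PathwayName,
    default_pathway_models,
    evidence_product,
    evidence_table,
    roi_bf_table,
)
from bgpathways.published import EXECUTION_BF, INHIBITION_BF, PUBLISHED_EVIDENCE
from bgpathways.synthetic_data import SyntheticParams, default_assignment, generate_dataset


def model_by_name(models, name):
    return next(m for m in models if m.name is name)


class TestMembership:
    def test_right_hand_defaults(self):
        models = default_pathway_models("right")
        direct = model_by_name(models, PathwayName.DIRECT)
        indirect = model_by_name(models, PathwayName.INDIRECT)
        hyper = model_by_name(models, PathwayName.HYPERDIRECT)
        assert {str(r) for r in direct.member_rois} == {"L_STR", "L_GPi", "L_SN", "L_THAL"}
        assert {str(r) for r in indirect.member_rois} == {
            "R_STR", "R_GPe", "R_GPi", "R_SN", "R_STN", "R_THAL"
        }
        assert {str(r) for r in hyper.member_rois} == {"R_GPi", "R_STN", "R_SN", "R_THAL"}

    def test_members_and_non_members_partition_subcortex(self):
        for model in default_pathway_models("right"):
            assert model.member_rois | model.non_member_rois == frozenset(SUBCORTICAL_ROIS)
            assert not model.member_rois & model.non_member_rois

    def test_left_hand_is_exact_mirror(self):
        right = default_pathway_models("right")
        left = default_pathway_models("left")
        for r_model, l_model in zip(right, left):
            assert {roi.mirrored() for roi in r_model.member_rois} == l_model.member_rois

    def test_cortical_members_rejected(self):
        from bgpathways.data_model import Structure
        with pytest.raises(ValueError):
            PathwayModel(PathwayName.DIRECT, Hemisphere.L, frozenset({Structure.IFG}))


class TestEvidenceProduct:
    def test_all_unit_bfs_give_unit_product(self):
        bfs = {roi: 1.0 for roi in SUBCORTICAL_ROIS}
        score = evidence_product(bfs, default_pathway_models("right")[0])
        assert score.bf_product == pytest.approx(1.0)
        assert score.log10_bf_product == pytest.approx(0.0)

    def test_toy_hand_arithmetic(self):
        """One member BF 4 and two non-member BFs 0.5: 4 x 2 x 2 = 16."""
        model = default_pathway_models("right")[0]  # direct, left
        bfs = {roi: 1.0 for roi in SUBCORTICAL_ROIS}
        bfs[RoiId.parse("L_STR")] = 4.0        # member
        bfs[RoiId.parse("R_STR")] = 0.5        # non-member
        bfs[RoiId.parse("R_GPe")] = 0.5        # non-member
        assert evidence_product(bfs, model).bf_product == pytest.approx(16.0)

    def test_ledger_log_additivity(self):
        model = default_pathway_models("right")[2]
        score = evidence_product(INHIBITION_BF, model)
        assert score.log10_bf_product == pytest.approx(
            sum(math.log10(f) for f in score.ledger.values()), abs=1e-9
        )
        assert score.bf_product == pytest.approx(
            math.prod(score.ledger.values()), rel=1e-9
        )

    def test_member_non_member_swap_inverts_product(self):
        for model in default_pathway_models("right"):
            score = evidence_product(EXECUTION_BF, model)
            inverted = evidence_product(EXECUTION_BF, model.swapped())
            assert score.bf_product * inverted.bf_product == pytest.approx(1.0, rel=1e-9)

    def test_missing_and_nonpositive_bfs_rejected(self):
        model = default_pathway_models("right")[0]
        partial = dict(EXECUTION_BF)
        partial.pop(RoiId.parse("R_THAL"))
        with pytest.raises(DataError, match="R_THAL"):
            evidence_product(partial, model)
        bad = dict(EXECUTION_BF)
        bad[RoiId.parse("R_THAL")] = 0.0
        with pytest.raises(DataError):
            evidence_product(bad, model)


class TestPublishedReproduction:
    """Injecting the published per-ROI BF columns reproduces the published grid.

    Inputs are printed at 2-decimal precision, hence the 5% tolerance.
    """

    @pytest.mark.parametrize("condition,pathway", sorted(PUBLISHED_EVIDENCE))
    def test_grid_cell(self, condition, pathway):
        models = default_pathway_models("right")
        bf_tables = {
            Condition.EXECUTION: EXECUTION_BF,
            Condition.INHIBITION_ALL: INHIBITION_BF,
        }
        scores = evidence_table(None, models, conditions=tuple(bf_tables),
                                bf_tables=bf_tables)
        cell = next(s for s in scores
                    if s.condition.value == condition and s.pathway_name.value == pathway)
        assert cell.bf_product == pytest.approx(PUBLISHED_EVIDENCE[(condition, pathway)],
                                                rel=0.05)


class TestGrid:
    def test_full_cross_with_matched_flags(self):
        bf_tables = {c: dict(EXECUTION_BF) for c in EVIDENCE_CONDITIONS}
        scores = evidence_table(None, default_pathway_models("right"),
                                bf_tables=bf_tables)
        assert len(scores) == len(EVIDENCE_CONDITIONS) * 3
        matched = {(s.condition.value, s.pathway_name.value) for s in scores if s.matched}
        assert ("execution", "direct") in matched
        assert ("inhibition_all", "hyperdirect") in matched
        assert ("execution", "indirect") not in matched
        assert ("inhibition_pro", "direct") not in matched

    def test_roi_bf_table_from_synthetic_null(self):
        params = SyntheticParams(
            contrast_counts={Condition.EXECUTION: 4,
                             Condition.INHIBITION_PRO: 3,
                             Condition.INHIBITION_REAC: 3},
        )
        table, _ = generate_dataset(params, seed=9)
        est = compound_estimates(table, default_assignment(params))
        bfs = roi_bf_table(est, Condition.EXECUTION)
        assert set(bfs) == set(SUBCORTICAL_ROIS)
        assert all(bf > 0 for bf in bfs.values())
        assert sum(bf < 3 for bf in bfs.values()) >= 9  # null data: most BFs small
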