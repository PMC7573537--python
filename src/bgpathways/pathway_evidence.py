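"""Product-of-Bayes-factors evidence for basal-ganglia pathway models.

Each pathway model names the subcortical structures it predicts to be active
in one hemisphere.  Given per-ROI activation Bayes factors under a condition,
the pathway's evidence score multiplies BF10 for every member ROI and 1/BF10
for every non-member subcortical ROI (the remaining same-hemisphere
structures plus all six contralateral ones) — the inverse BF quantifying
evidence of *zero* activity where the model predicts none.  Cortical ROIs
(pre-SMA, IFG) never enter the product.  Products are accumulated in log
space, with a per-ROI contribution ledger kept for audit.

Default memberships, for responses made with the right hand:

- direct (execution route): left STR, GPi, SN, THAL;
- indirect (tonic suppression): all six right subcortical structures;
- hyperdirect (fast cancellation): right GPi, STN, SN, THAL.

Activation sign is deliberately ignored — the per-ROI tests are two-sided —
so predicted down-regulation within a pathway is not encoded.  The full
evidence grid crosses every condition with every pathway, so behaviourally
mismatched (control) cells are always computed alongside matched ones.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .bayes_factors import jzs_one_sample
from .compound_contrasts import CompoundEstimates
from .data_model import (
    Condition,
    DataError,
    Hemisphere,
    PriorSpec,
    RoiId,
    SUBCORTICAL_ROIS,
    SUBCORTICAL_STRUCTURES,
    Structure,
)

__all__ = [
    "PathwayName",
    "PathwayModel",
    "EvidenceScore",
    "default_pathway_models",
    "roi_bf_table",
    "evidence_product",
    "evidence_table",
    "EVIDENCE_CONDITIONS",
]


class PathwayName(enum.Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"
    HYPERDIRECT = "hyperdirect"


#: Conditions scored in the evidence grid.
EVIDENCE_CONDITIONS = (
    Condition.EXECUTION,
    Condition.INHIBITION_ALL,
    Condition.INHIBITION_PRO,
    Condition.INHIBITION_REAC,
)

#: Behaviourally appropriate condition sets per pathway: the direct pathway
#: is an execution route; indirect and hyperdirect are inhibition routes.
MATCHED_CONDITIONS = {
    PathwayName.DIRECT: frozenset({Condition.EXECUTION}),
    PathwayName.INDIRECT: frozenset(
        {Condition.INHIBITION_ALL, Condition.INHIBITION_PRO, Condition.INHIBITION_REAC}
    ),
    PathwayName.HYPERDIRECT: frozenset(
        {Condition.INHIBITION_ALL, Condition.INHIBITION_PRO, Condition.INHIBITION_REAC}
    ),
}

_DEFAULT_MEMBERS = {
    PathwayName.DIRECT: frozenset(
        {Structure.STR, Structure.GPi, Structure.SN, Structure.THAL}
    ),
    PathwayName.INDIRECT: frozenset(SUBCORTICAL_STRUCTURES),
    PathwayName.HYPERDIRECT: frozenset(
        {Structure.GPi, Structure.STN, Structure.SN, Structure.THAL}
    ),
}


@dataclass(frozen=True)
class PathwayModel:
    """A named pathway with lateralized member/non-member subcortical sets."""

    name: PathwayName
    hemisphere: Hemisphere
    members: frozenset[Structure]

    def __post_init__(self) -> None:
        bad = self.members - SUBCORTICAL_STRUCTURES
        if bad:
            raise ValueError(f"pathway members must be subcortical; got {sorted(s.value for s in bad)}")
        if not self.members:
            raise ValueError("pathway must have at least one member structure")

    @property
    def member_rois(self) -> frozenset[RoiId]:
        return frozenset(RoiId(self.hemisphere, s) for s in self.members)

    @property
    def non_member_rois(self) -> frozenset[RoiId]:
        return frozenset(SUBCORTICAL_ROIS) - self.member_rois

    def swapped(self) -> "PathwayModel":
        """Model with members and non-members conceptually exchanged.

        Returned as the complementary same-name model whose member ROIs are
        this model's non-members; its evidence product is exactly the
        reciprocal of this model's (self-inverse control).
        """
        return _ComplementModel(self)


@dataclass(frozen=True)
class _ComplementModel:
    base: PathwayModel

    @property
    def name(self) -> PathwayName:
        return self.base.name

    @property
    def member_rois(self) -> frozenset[RoiId]:
        return self.base.non_member_rois

    @property
    def non_member_rois(self) -> frozenset[RoiId]:
        return self.base.member_rois


@dataclass(frozen=True)
class EvidenceScore:
    """A pathway × condition evidence product with its per-ROI ledger.

    ``ledger`` maps each subcortical ROI to the factor actually multiplied
    in: BF10 for members, 1/BF10 for non-members.
    """

    pathway_name: PathwayName
    condition: Condition | None
    bf_product: float
    log10_bf_product: float
    ledger: dict[RoiId, float]
    matched: bool


def default_pathway_models(response_hand: str = "right") -> list[PathwayModel]:
    """The three pathway models lateralized for the responding hand.

    For right-hand responses the execution (direct) route is left-lateralized
    and the inhibition (indirect, hyperdirect) routes right-lateralized;
    mirror-imaged for the left hand.
    """
    if response_hand not in ("left", "right"):
        raise ValueError(f"response_hand must be 'left' or 'right', got {response_hand!r}")
    exec_hemi = Hemisphere.L if response_hand == "right" else Hemisphere.R
    inhib_hemi = exec_hemi.opposite
    return [
        PathwayModel(PathwayName.DIRECT, exec_hemi, _DEFAULT_MEMBERS[PathwayName.DIRECT]),
        PathwayModel(PathwayName.INDIRECT, inhib_hemi, _DEFAULT_MEMBERS[PathwayName.INDIRECT]),
        PathwayModel(
            PathwayName.HYPERDIRECT, inhib_hemi, _DEFAULT_MEMBERS[PathwayName.HYPERDIRECT]
        ),
    ]


def roi_bf_table(
    est: CompoundEstimates,
    condition: Condition,
    prior: PriorSpec = PriorSpec(),
) -> dict[RoiId, float]:
    """One-sample activation BF10 per lateralized subcortical ROI.

    Externally computed BF maps (e.g. published per-ROI values) can be passed
    directly to :func:`evidence_product` / :func:`evidence_table` in place of
    this function's output.
    """
    return {
        roi: jzs_one_sample(est.vector(roi, condition), prior=prior).bf10
        for roi in SUBCORTICAL_ROIS
    }


def evidence_product(
    bfs: dict[RoiId, float], pathway, condition: Condition | None = None
) -> EvidenceScore:
    """BF product: member BF10s times non-member reciprocals, in log space."""
    missing = [str(r) for r in SUBCORTICAL_ROIS if r not in bfs]
    if missing:
        raise DataError(f"BF map is missing subcortical ROI(s): {missing}")
    for roi in SUBCORTICAL_ROIS:
        if not bfs[roi] > 0:
            raise DataError(f"BF for {roi} must be positive, got {bfs[roi]}")
    ledger: dict[RoiId, float] = {}
    log10_sum = 0.0
    for roi in SUBCORTICAL_ROIS:
        factor = bfs[roi] if roi in pathway.member_rois else 1.0 / bfs[roi]
        ledger[roi] = factor
        log10_sum += math.log10(factor)
    return EvidenceScore(
        pathway_name=pathway.name,
        condition=condition,
        bf_product=10.0 ** log10_sum,
        log10_bf_product=log10_sum,
        ledger=ledger,
        matched=False,
    )


def evidence_table(
    est: CompoundEstimates | None,
    models: list[PathwayModel],
    prior: PriorSpec = PriorSpec(),
    conditions: tuple[Condition, ...] = EVIDENCE_CONDITIONS,
    bf_tables: dict[Condition, dict[RoiId, float]] | None = None,
) -> list[EvidenceScore]:
    """Full condition × pathway evidence grid.

    Every cell is computed — matched and mismatched (over-fitting control)
    alike — with matched cells flagged.  ``bf_tables`` bypasses the per-ROI
    tests with externally supplied BF maps keyed by condition.
    """
    if bf_tables is None:
        if est is None:
            raise ValueError("either compound estimates or bf_tables must be supplied")
        bf_tables = {cond: roi_bf_table(est, cond, prior=prior) for cond in conditions}
    scores = []
    for cond in conditions:
        if cond not in bf_tables:
            raise DataError(f"no BF table for condition {cond.value}")
        for model in models:
            base = evidence_product(bf_tables[cond], model, condition=cond)
            scores.append(
                EvidenceScore(
                    pathway_name=base.pathway_name,
                    condition=cond,
                    bf_product=base.bf_product,
                    log10_bf_product=base.log10_bf_product,
                    ledger=base.ledger,
                    matched=cond in MATCHED_CONDITIONS[model.name],
                )
            )
    return scores


def scores_to_rows(scores: list[EvidenceScore]) -> list[dict]:
    """Flatten evidence scores for tabular output."""
    return [
        {
            "condition": s.condition.value,
            "pathway": s.pathway_name.value,
            "bf_product": s.bf_product,
            "log10_bf_product": s.log10_bf_product,
            "matched": s.matched,
        }
        for s in scores
    ]
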