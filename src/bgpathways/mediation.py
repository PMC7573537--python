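"""Moderator/mediator partial analyses between active ROIs.

For every ordered pair of ROIs that are both active under a condition, the
target ROI's compound values are regressed on the covariate ROI's values
(simple OLS, one covariate).  The intercept's t-statistic tests whether the
target remains active — different from zero — once the covariate is taken
into account; a JZS Bayes factor is derived from that t with nu = N - 2 and
effective sample size N.  Comparing the adjusted evidence with the target's
original one-sample evidence classifies the covariate's influence:

- ``mediated``:   the original activation is eliminated
  (adjusted BF10 < 1/3 *and* adjusted p > 0.05);
- ``moderated``:  evidence is reduced into the insensitive band
  (1/3 <= adjusted BF10 < 3, below the original BF10);
- ``unchanged``:  adjusted BF10 >= 3 or not below the original;
- ``inconsistent``: the frequentist and Bayesian indicators disagree
  (adjusted BF10 < 1/3 with adjusted p <= 0.05) — flagged explicitly
  because the two elimination rules do not partition the outcome space.

The analysis is correlational: direction labels follow the regression roles
(mediation of A by B does not imply mediation of B by A), and no causal
path model is fitted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .bayes_factors import DegenerateSampleError, InsufficientDataError, jzs_bf_from_t
from .compound_contrasts import CompoundEstimates
from .data_model import BayesResult, Condition, PriorSpec, RoiId
from .roi_stats import activation_table, active_rois

__all__ = [
    "Relation",
    "MediationRecord",
    "partial_intercept_test",
    "classify_relation",
    "mediation_matrix",
]

log = logging.getLogger(__name__)


class Relation(enum.Enum):
    MEDIATED = "mediated"
    MODERATED = "moderated"
    UNCHANGED = "unchanged"
    INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class MediationRecord:
    target: RoiId
    covariate: RoiId
    condition: Condition
    original: BayesResult
    adjusted: BayesResult
    relation: Relation


def partial_intercept_test(
    target_values,
    covariate_values,
    prior: PriorSpec = PriorSpec(),
) -> BayesResult:
    """Intercept test of ``target = b0 + b1*covariate + e`` via OLS.

    Returns the JZS result for t = b0 / SE(b0) with nu = N - 2, n_eff = N.
    """
    y = np.asarray(target_values, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise InsufficientDataError(f"shape mismatch: target {y.shape}, covariate {x.shape}")
    n = y.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 paired values, got {n}")
    if x.std(ddof=1) == 0:
        raise DegenerateSampleError("covariate has zero variance; regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    # perfect-fit limit (target collinear with covariate): the residual
    # variance vanishes and t = b0/SE(b0) degenerates to 0/0; a zero
    # intercept there means complete mediation, so t is 0 by convention
    scale = float(np.abs(y).max() or 1.0)
    if fit.ssr <= 1e-20 * scale**2 * n:
        if abs(fit.params[0]) <= 1e-10 * scale:
            return jzs_bf_from_t(0.0, df=n - 2, n_eff=n, prior=prior)
        raise DegenerateSampleError("exact fit with nonzero intercept; t is infinite")
    t_intercept = fit.params[0] / fit.bse[0]
    return jzs_bf_from_t(t_intercept, df=n - 2, n_eff=n, prior=prior)


def classify_relation(original: BayesResult, adjusted: BayesResult) -> Relation:
    """Classify the covariate's influence from original vs adjusted evidence."""
    if adjusted.bf10 < 1 / 3 and adjusted.p > 0.05:
        return Relation.MEDIATED
    if 1 / 3 <= adjusted.bf10 < 3 and adjusted.bf10 < original.bf10:
        return Relation.MODERATED
    if adjusted.bf10 >= 3 or adjusted.bf10 >= original.bf10:
        return Relation.UNCHANGED
    return Relation.INCONSISTENT


def mediation_matrix(
    est: CompoundEstimates,
    condition: Condition,
    prior: PriorSpec = PriorSpec(),
    rois=None,
) -> list[MediationRecord]:
    """All ordered (target, covariate) pairs of active ROIs under a condition.

    Returns an empty list (with a logged notice) when fewer than two ROIs
    are active — there is nothing to regress.
    """
    rows = activation_table(est, condition, prior=prior, rois=rois)
    active = sorted(active_rois(rows))
    if len(active) < 2:
        log.warning(
            "mediation analysis under %s skipped: %d active ROI(s), need >= 2",
            condition.value, len(active),
        )
        return []
    originals = {row.roi: row.result for row in rows}
    vectors = {roi: est.vector(roi, condition) for roi in active}
    records = []
    for target in active:
        for covariate in active:
            if covariate == target:
                continue
            adjusted = partial_intercept_test(vectors[target], vectors[covariate], prior=prior)
            records.append(
                MediationRecord(
                    target=target,
                    covariate=covariate,
                    condition=condition,
                    original=originals[target],
                    adjusted=adjusted,
                    relation=classify_relation(originals[target], adjusted),
                )
            )
    return records


def records_to_rows(records: list[MediationRecord]) -> list[dict]:
    """Flatten mediation records for tabular output."""
    return [
        {
            "target": str(r.target),
            "covariate": str(r.covariate),
            "condition": r.condition.value,
            "t_original": r.original.t,
            "p_original": r.original.p,
            "bf10_original": r.original.bf10,
            "t_adjusted": r.adjusted.t,
            "p_adjusted": r.adjusted.p,
            "bf10_adjusted": r.adjusted.bf10,
            "relation": r.relation.value,
        }
        for r in records
    ]
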