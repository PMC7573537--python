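"""Per-ROI activation tests and condition contrasts.

Each ROI's compound values across participants are tested against zero with
a one-sample JZS t-test; condition differences use the paired test.  An ROI
counts as "active" when the frequentist or the Bayesian criterion fires
(p < 0.05 or BF10 > 3) — a logical OR, as in the exploratory analyses the
pipeline models, which were reported uncorrected.  Holm-Bonferroni step-down
adjustment is available as an opt-in utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .bayes_factors import jzs_one_sample, jzs_paired
from .compound_contrasts import CompoundEstimates
from .data_model import BayesResult, Condition, PriorSpec, RoiId

__all__ = [
    "RoiStatRow",
    "activation_table",
    "condition_difference_table",
    "holm_adjust",
    "active_rois",
    "is_active",
]

ACTIVE_P = 0.05
ACTIVE_BF = 3.0


def is_active(result: BayesResult) -> bool:
    return result.p < ACTIVE_P or result.bf10 > ACTIVE_BF


@dataclass(frozen=True)
class RoiStatRow:
    roi: RoiId
    label: str  # condition or "a_vs_b" pair label
    result: BayesResult
    active: bool


def _sorted_rois(est: CompoundEstimates, rois) -> list[RoiId]:
    return sorted(rois if rois is not None else est.rois)


def activation_table(
    est: CompoundEstimates,
    condition: Condition,
    prior: PriorSpec = PriorSpec(),
    rois=None,
) -> list[RoiStatRow]:
    """One-sample test of each ROI's compound values against zero."""
    rows = []
    for roi in _sorted_rois(est, rois):
        result = jzs_one_sample(est.vector(roi, condition), prior=prior)
        rows.append(RoiStatRow(roi=roi, label=condition.value, result=result,
                               active=is_active(result)))
    return rows


def condition_difference_table(
    est: CompoundEstimates,
    a: Condition,
    b: Condition,
    prior: PriorSpec = PriorSpec(),
    rois=None,
) -> list[RoiStatRow]:
    """Paired test per ROI on (a - b); positive t means a > b."""
    label = f"{a.value}_vs_{b.value}"
    rows = []
    for roi in _sorted_rois(est, rois):
        result = jzs_paired(est.vector(roi, a), est.vector(roi, b), prior=prior)
        rows.append(RoiStatRow(roi=roi, label=label, result=result, active=is_active(result)))
    return rows


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def active_rois(rows: list[RoiStatRow]) -> frozenset[RoiId]:
    """ROIs flagged active in a list of rows from one condition."""
    return frozenset(row.roi for row in rows if row.active)


def rows_to_records(rows: list[RoiStatRow]) -> list[dict]:
    """Flatten stat rows for :func:`bgpathways.data_model.write_stats_table`."""
    return [
        {
            "roi": str(r.roi),
            "label": r.label,
            "t": r.result.t,
            "df": r.result.df,
            "p": r.result.p,
            "bf10": r.result.bf10,
            "category": r.result.category.value,
            "active": r.active,
        }
        for r in rows
    ]
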