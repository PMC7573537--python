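"""Compound-contrast averaging: one point estimate per participant × ROI × condition.

Many different fMRI contrasts can index the same behavioural state (response
execution, proactive inhibition, reactive inhibition).  Averaging %BOLD over
all contrasts assigned to a condition cancels contrast-specific baselines and
retains the commonality, yielding a single stable "compound" value per
participant and ROI.  The pooled ``inhibition_all`` cell is the mean over the
*union* of the proactive and reactive contrast observations — each contrast
weighted equally — not the mean of the two sub-means (a mean-of-means variant
is available via ``all_mode="submeans"`` for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    BoldTable,
    Condition,
    ContrastAssignment,
    DataError,
    RoiId,
)

__all__ = ["CompoundEstimates", "compound_estimates", "UnassignedContrastError", "EmptyCellError"]


class UnassignedContrastError(DataError):
    """A contrast in the BOLD table has no condition assignment."""


class EmptyCellError(DataError):
    """A required (participant, roi, condition) cell has no observations."""


@dataclass(frozen=True)
class CompoundEstimates:
    """Per-cell compound means with contrast counts.

    ``frame`` has columns participant, roi, condition, value, n_contrasts;
    ``participants`` fixes the ordering used by downstream per-ROI vectors.
    """

    frame: pd.DataFrame
    participants: tuple[str, ...]

    @property
    def conditions(self) -> tuple[Condition, ...]:
        present = set(self.frame["condition"])
        return tuple(c for c in Condition if c.value in present)

    @property
    def rois(self) -> frozenset[RoiId]:
        return frozenset(RoiId.parse(r) for r in self.frame["roi"].unique())

    def vector(self, roi: RoiId, condition: Condition) -> np.ndarray:
        """Compound values for one (roi, condition), ordered by participants."""
        sub = self.frame[
            (self.frame["roi"] == str(roi)) & (self.frame["condition"] == condition.value)
        ]
        if sub.empty:
            raise EmptyCellError(f"no compound estimates for ROI {roi} under {condition.value}")
        by_participant = dict(zip(sub["participant"], sub["value"]))
        missing = [p for p in self.participants if p not in by_participant]
        if missing:
            raise EmptyCellError(
                f"missing compound cell(s) for ROI {roi} under {condition.value}: "
                f"participants {missing}"
            )
        return np.array([by_participant[p] for p in self.participants], dtype=float)

    def count(self, participant: str, roi: RoiId, condition: Condition) -> int:
        sub = self.frame[
            (self.frame["participant"] == participant)
            & (self.frame["roi"] == str(roi))
            & (self.frame["condition"] == condition.value)
        ]
        if sub.empty:
            raise EmptyCellError(
                f"no compound cell for ({participant}, {roi}, {condition.value})"
            )
        return int(sub["n_contrasts"].iloc[0])


def compound_estimates(
    table: BoldTable,
    assignment: ContrastAssignment,
    all_mode: str = "union",
) -> CompoundEstimates:
    """Collapse per-contrast %BOLD into compound means per condition.

    Every contrast present in the table must be assigned; cells are the
    arithmetic means of whatever observations exist (unequal counts across
    participants are allowed).  ``all_mode`` controls the pooled inhibition
    cell: ``"union"`` (default) averages over all pro+reac observations,
    ``"submeans"`` averages the two sub-condition means.
    """
    if all_mode not in ("union", "submeans"):
        raise ValueError(f"all_mode must be 'union' or 'submeans', got {all_mode!r}")
    df = table.frame
    unassigned = sorted(set(df["contrast"]) - set(assignment.mapping))
    if unassigned:
        raise UnassignedContrastError(
            f"{len(unassigned)} contrast(s) lack a condition assignment: {unassigned[:5]}"
        )
    cond_map = {c: k.value for c, k in assignment.mapping.items()}
    df = df.assign(condition=df["contrast"].map(cond_map))

    grouped = (
        df.groupby(["participant", "roi", "condition"], as_index=False)
        .agg(value=("value", "mean"), n_contrasts=("value", "size"))
    )

    pooled_src = df[df["condition"].isin(
        (Condition.INHIBITION_PRO.value, Condition.INHIBITION_REAC.value)
    )]
    if not pooled_src.empty:
        if all_mode == "union":
            pooled = (
                pooled_src.groupby(["participant", "roi"], as_index=False)
                .agg(value=("value", "mean"), n_contrasts=("value", "size"))
            )
        else:
            sub = grouped[grouped["condition"].isin(
                (Condition.INHIBITION_PRO.value, Condition.INHIBITION_REAC.value)
            )]
            pooled = (
                sub.groupby(["participant", "roi"], as_index=False)
                .agg(value=("value", "mean"), n_contrasts=("n_contrasts", "sum"))
            )
        pooled["condition"] = Condition.INHIBITION_ALL.value
        grouped = pd.concat([grouped, pooled], ignore_index=True)

    grouped = grouped.loc[:, ["participant", "roi", "condition", "value", "n_contrasts"]]
    return CompoundEstimates(frame=grouped, participants=table.participants)
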