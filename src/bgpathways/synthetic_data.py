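"""Synthetic %BOLD data with known ground truth.

The generator emulates the structure of the ROI study the pipeline targets:
30 participants, 16 lateralized ROIs and 131 contrasts partitioned into
execution, proactive-inhibition and reactive-inhibition sets.  The model is
a two-level Gaussian hierarchy.  For participant i, ROI k and condition c
the latent participant mean is

    m[i,k,c] = mu[k,c] + b,        b ~ Normal(0, tau^2)

(independently per participant, ROI and condition), and each contrast j in
condition set c contributes one observation

    value[i,j,k] = m[i,k,c] + Normal(0, sigma^2).

Optional coupling directives replace a target ROI's latent mean with a
linear function of another ROI's latent mean under the same condition,

    m[i,target,c] = alpha + beta * m[i,covariate,c] + Normal(0, resid_sd^2),

which creates exact moderator/mediator structure on the participant level:
with alpha = 0 the target's activation is fully explained by the covariate,
so the downstream intercept test recovers full mediation in expectation.

Defaults: tau = 0.2 and sigma = 0.3 %BOLD with active-ROI effects of
0.3 %BOLD — magnitudes typical of event-related ROI analyses, giving
per-ROI one-sample t-statistics in the single digits at n = 30, like the
published tables this pipeline reproduces.  The 131 contrasts are split
44/44/43 across the three condition sets (the true split is not public;
equal thirds is the configurable stand-in).

All randomness comes from ``numpy.random.default_rng`` (PCG64) in a fixed
draw order, so a (params, seed) pair reproduces a table bit-for-bit.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    ALL_ROIS,
    ASSIGNABLE_CONDITIONS,
    BoldTable,
    Condition,
    ContrastAssignment,
    Hemisphere,
    RoiId,
    Structure,
)

__all__ = [
    "CouplingDirective",
    "SyntheticParams",
    "GroundTruth",
    "generate_dataset",
    "scenario_presets",
    "default_assignment",
]

_CONDITION_PREFIX = {
    Condition.EXECUTION: "exe",
    Condition.INHIBITION_PRO: "pro",
    Condition.INHIBITION_REAC: "reac",
}

#: Default effect size for "active" ROIs in the presets (%BOLD).
DEFAULT_EFFECT = 0.3


@dataclass(frozen=True)
class CouplingDirective:
    """Make ``target``'s latent mean a linear function of ``covariate``'s."""

    target: RoiId
    covariate: RoiId
    condition: Condition
    alpha: float
    beta: float
    resid_sd: float


@dataclass(frozen=True)
class SyntheticParams:
    n_participants: int = 30
    contrast_counts: dict[Condition, int] = field(
        default_factory=lambda: {
            Condition.EXECUTION: 44,
            Condition.INHIBITION_PRO: 44,
            Condition.INHIBITION_REAC: 43,
        }
    )
    roi_means: dict[tuple[RoiId, Condition], float] = field(default_factory=dict)
    between_participant_sd: float = 0.2
    within_contrast_sd: float = 0.3
    coupling: tuple[CouplingDirective, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.between_participant_sd < 0 or self.within_contrast_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for cond, count in self.contrast_counts.items():
            if cond not in ASSIGNABLE_CONDITIONS:
                raise ValueError(f"contrast_counts key {cond} is not an assignable condition")
            if count < 1:
                raise ValueError(f"contrast count for {cond.value} must be >= 1")
        for d in self.coupling:
            if d.resid_sd < 0:
                raise ValueError("coupling residual sd must be >= 0")
        self._coupling_order()  # raises on cycles

    def _coupling_order(self) -> list[tuple[RoiId, Condition]]:
        """Topological order of coupled (roi, condition) nodes; rejects cycles."""
        graph: dict[tuple[RoiId, Condition], set[tuple[RoiId, Condition]]] = {}
        for d in self.coupling:
            key = (d.target, d.condition)
            if key in graph:
                raise ValueError(f"ROI {d.target} is targeted twice under {d.condition.value}")
            graph[key] = {(d.covariate, d.condition)}
        try:
            return [n for n in graphlib.TopologicalSorter(graph).static_order() if n in graph]
        except graphlib.CycleError as exc:
            raise ValueError(f"coupling graph has a cycle: {exc.args[1]}") from exc


@dataclass(frozen=True)
class GroundTruth:
    """Realized latent participant means plus the generating parameters."""

    latent_means: pd.DataFrame  # columns participant, roi, condition, latent_mean
    params: SyntheticParams
    scenario: str | None = None


def default_assignment(params: SyntheticParams) -> ContrastAssignment:
    """The contrast → condition mapping implied by the generator's naming."""
    mapping: dict[str, Condition] = {}
    for cond in ASSIGNABLE_CONDITIONS:
        prefix = _CONDITION_PREFIX[cond]
        for j in range(params.contrast_counts.get(cond, 0)):
            mapping[f"{prefix}_{j + 1:03d}"] = cond
    return ContrastAssignment(mapping)


def generate_dataset(
    params: SyntheticParams,
    seed: int | None = None,
    scenario: str | None = None,
) -> tuple[BoldTable, GroundTruth]:
    """Draw a BoldTable from the hierarchical model; deterministic given seed.

    ``seed`` overrides ``params.seed`` when given.  Draw order is fixed:
    first all between-participant deviates (participant-major, then ROI in
    canonical order, then condition), then coupling residuals in topological
    order, then observation noise contrast-by-contrast.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    participants = [f"p{i + 1:02d}" for i in range(params.n_participants)]
    conditions = [c for c in ASSIGNABLE_CONDITIONS if params.contrast_counts.get(c, 0) > 0]
    tau = params.between_participant_sd
    sigma = params.within_contrast_sd

    latent: dict[tuple[str, RoiId, Condition], float] = {}
    for p in participants:
        for roi in ALL_ROIS:
            for cond in conditions:
                mu = params.roi_means.get((roi, cond), 0.0)
                latent[(p, roi, cond)] = mu + (tau * rng.standard_normal() if tau else 0.0)

    directives = {(d.target, d.condition): d for d in params.coupling}
    for roi, cond in params._coupling_order():
        if cond not in conditions:
            continue
        d = directives[(roi, cond)]
        for p in participants:
            noise = d.resid_sd * rng.standard_normal() if d.resid_sd else 0.0
            latent[(p, roi, cond)] = d.alpha + d.beta * latent[(p, d.covariate, cond)] + noise

    roi_names = [str(r) for r in ALL_ROIS]
    n_p, n_r = len(participants), len(ALL_ROIS)
    blocks = []
    for cond in conditions:
        prefix = _CONDITION_PREFIX[cond]
        base = np.array([[latent[(p, roi, cond)] for roi in ALL_ROIS] for p in participants])
        for j in range(params.contrast_counts[cond]):
            contrast = f"{prefix}_{j + 1:03d}"
            noise = sigma * rng.standard_normal((n_p, n_r)) if sigma else 0.0
            blocks.append(
                pd.DataFrame(
                    {
                        "participant": np.repeat(participants, n_r),
                        "contrast": contrast,
                        "roi": np.tile(roi_names, n_p),
                        "value": (base + noise).ravel(),
                    }
                )
            )
    table = BoldTable(pd.concat(blocks, ignore_index=True))

    truth = pd.DataFrame(
        [(p, str(roi), cond.value, m) for (p, roi, cond), m in latent.items()],
        columns=["participant", "roi", "condition", "latent_mean"],
    )
    return table, GroundTruth(latent_means=truth, params=params, scenario=scenario)


def _means_for(rois, conditions, effect: float) -> dict[tuple[RoiId, Condition], float]:
    return {(roi, cond): effect for roi in rois for cond in conditions}


def scenario_presets(effect: float = DEFAULT_EFFECT) -> dict[str, SyntheticParams]:
    """Named ground-truth scenarios for testing and demonstration.

    - ``null``: all ROI means zero.
    - ``direct_execution_left``: left direct-pathway members (STR, GPi, SN,
      THAL) active under execution.
    - ``indirect_inhibition_right``: all six right subcortical structures
      active under both inhibition conditions.
    - ``hyperdirect_inhibition_right``: right GPi, STN, SN and THAL active
      under both inhibition conditions.
    - ``full_mediation_pair``: left THAL active under execution with left GPe
      fully driven by it (alpha = 0), so GPe activity is mediated by THAL.
    - ``independent_pair``: left THAL and left GPe independently active
      (strong means, low between-participant noise), a no-mediation control.
    """
    inhibition = (Condition.INHIBITION_PRO, Condition.INHIBITION_REAC)
    L, R = Hemisphere.L, Hemisphere.R
    direct_left = [RoiId(L, s) for s in (Structure.STR, Structure.GPi, Structure.SN, Structure.THAL)]
    indirect_right = [RoiId(R, s) for s in (Structure.STR, Structure.GPe, Structure.GPi,
                                            Structure.SN, Structure.STN, Structure.THAL)]
    hyperdirect_right = [RoiId(R, s) for s in (Structure.GPi, Structure.STN,
                                               Structure.SN, Structure.THAL)]
    l_thal = RoiId(L, Structure.THAL)
    l_gpe = RoiId(L, Structure.GPe)

    return {
        "null": SyntheticParams(),
        "direct_execution_left": SyntheticParams(
            roi_means=_means_for(direct_left, (Condition.EXECUTION,), effect)
        ),
        "indirect_inhibition_right": SyntheticParams(
            roi_means=_means_for(indirect_right, inhibition, effect)
        ),
        "hyperdirect_inhibition_right": SyntheticParams(
            roi_means=_means_for(hyperdirect_right, inhibition, effect)
        ),
        "full_mediation_pair": SyntheticParams(
            roi_means={(l_thal, Condition.EXECUTION): 0.5},
            coupling=(
                CouplingDirective(
                    target=l_gpe, covariate=l_thal, condition=Condition.EXECUTION,
                    alpha=0.0, beta=0.8, resid_sd=0.05,
                ),
            ),
        ),
        "independent_pair": SyntheticParams(
            roi_means={
                (l_thal, Condition.EXECUTION): 0.5,
                (l_gpe, Condition.EXECUTION): 0.5,
            },
            between_participant_sd=0.1,
        ),
    }
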