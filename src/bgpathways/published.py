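"""Published per-ROI activation Bayes factors for desk reproduction.

These are the printed per-ROI one-sample Bayes factors (2-decimal precision)
from the fronto-basal-ganglia stop-signal ROI study whose exploratory
pathway analysis this package re-implements: 30 right-handed participants,
compound %BOLD per ROI under response execution and response inhibition
(all inhibitory contrasts pooled).  Feeding these maps through
:func:`bgpathways.pathway_evidence.evidence_product` with the default
membership maps reproduces the study's published pathway-evidence grid for
the execution and pooled-inhibition rows, which is how the default direct
and indirect memberships were fixed.

Because the inputs are rounded to two decimals, reproduced products agree
with the published values to a few percent, not exactly.
"""

from __future__ import annotations

from .data_model import RoiId

__all__ = [
    "EXECUTION_BF",
    "INHIBITION_BF",
    "PUBLISHED_EVIDENCE",
    "CALIBRATION_T_BF",
]


def _bf_map(**kwargs: float) -> dict[RoiId, float]:
    return {RoiId.parse(name): bf for name, bf in kwargs.items()}


#: Per-ROI BF10, response-execution compound contrasts (subcortical only).
EXECUTION_BF: dict[RoiId, float] = _bf_map(
    L_STR=0.66, L_GPe=7.68, L_GPi=0.21, L_SN=0.22, L_STN=0.63, L_THAL=20.87,
    R_STR=0.89, R_GPe=0.21, R_GPi=0.23, R_SN=0.56, R_STN=0.72, R_THAL=0.34,
)

#: Per-ROI BF10, pooled response-inhibition compound contrasts.
INHIBITION_BF: dict[RoiId, float] = _bf_map(
    L_STR=0.40, L_GPe=0.20, L_GPi=0.43, L_SN=0.40, L_STN=0.20, L_THAL=0.31,
    R_STR=3369.02, R_GPe=7.12, R_GPi=0.24, R_SN=21.07, R_STN=31.30, R_THAL=72.37,
)

#: Published pathway-evidence products, (condition row, pathway) → value.
PUBLISHED_EVIDENCE: dict[tuple[str, str], float] = {
    ("execution", "direct"): 21.945,
    ("execution", "indirect"): 0.002,
    ("execution", "hyperdirect"): 0.056,
    ("inhibition_all", "direct"): 1.917e-9,
    ("inhibition_all", "indirect"): 3.216e11,
    ("inhibition_all", "hyperdirect"): 558.224,
}

#: Published (t, BF10) pairs at df = 29, N = 30 used to calibrate the prior
#: scale (the fourth pair exercises the large-|t| log-space regime).
CALIBRATION_T_BF: tuple[tuple[float, float], ...] = (
    (3.01, 7.68),
    (3.46, 20.87),
    (3.22, 12.10),
    (7.96, 1454887.67),
)
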