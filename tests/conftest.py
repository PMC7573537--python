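"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bgpathways.data_model import BoldTable, Condition, ContrastAssignment


def mc_jzs_bf(
    t: float,
    df: float,
    n_eff: float,
    r: float = math.sqrt(0.5),
    n_draws: int = 10**7,
    seed: int = 20260920,
) -> float:
    """Monte-Carlo prior-integration oracle for the JZS Bayes factor.

    Averages the noncentral-t likelihood over ``n_draws`` Cauchy(0, r) draws
    of the effect size and divides by the central-t likelihood — a direct
    simulation of the defining integral, independent of the quadrature path.
    The noncentral density is tabulated on a dense noncentrality grid and
    linearly interpolated onto the draws (grid spacing ~1.5e-3 noncentrality
    units; interpolation error ~1e-7 relative, far below Monte-Carlo noise).
    """
    rng = np.random.default_rng(seed)
    nc_draws = r * rng.standard_cauchy(n_draws) * math.sqrt(n_eff)
    # density is negligible (< 1e-250 relative) outside |nc - t| < 50
    grid = np.linspace(t - 50.0, t + 50.0, 2**16 + 1)
    dens = stats.nct.pdf(t, df, grid)
    lik = np.interp(nc_draws, grid, dens, left=0.0, right=0.0)
    return float(lik.mean() / stats.t.pdf(t, df))


def bold_table_from_rows(rows) -> BoldTable:
    """Rows of (participant, contrast, roi, value) → validated BoldTable."""
    return BoldTable(pd.DataFrame(rows, columns=["participant", "contrast", "roi", "value"]))


@pytest.fixture
def tiny_assignment() -> ContrastAssignment:
    return ContrastAssignment(
        {
            "c_exe": Condition.EXECUTION,
            "c_pro1": Condition.INHIBITION_PRO,
            "c_pro2": Condition.INHIBITION_PRO,
            "c_pro3": Condition.INHIBITION_PRO,
            "c_reac": Condition.INHIBITION_REAC,
        }
    )
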