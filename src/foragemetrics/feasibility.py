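"""The attainable region of the MPM–PTM plane.

For a given proportion of time moving, the number of distinct move bouts an
animal can exhibit is capped by the minimal recognizable bout durations.
At low PTM only a few discrete moves fit into the moving time, so
MPM_max = PTM / M_min; at high PTM the animal moves almost continuously and
the number of distinct moves is capped by how many stops of at least S_min
fit into the non-moving time, MPM_max = ((1 − PTM)·OD/S_min + 1)/OD.  The
attainable region is the triangle-like area under the pointwise minimum of
the two branches.

These are smooth approximations valid when M_min and S_min are much
shorter than OD (the exact boundary is a staircase); a warning is issued
when that assumption is strained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FeasibilityBounds", "mpm_max", "is_feasible",
           "triangle_boundary", "am_as_from_summary"]


@dataclass
class FeasibilityBounds:
    """Minimal bout durations and observation duration, all in minutes."""

    m_min: float
    s_min: float
    od: float

    def __post_init__(self) -> None:
        if self.m_min <= 0 or self.s_min <= 0 or self.od <= 0:
            raise ValueError("m_min, s_min and od must all be positive")
        if self.m_min > self.od / 10 or self.s_min > self.od / 10:
            warnings.warn(
                "m_min or s_min is not much shorter than od; the smooth "
                "two-branch boundary approximation may be inaccurate",
                stacklevel=2)


def mpm_max(ptm, bounds: FeasibilityBounds):
    """Maximal attainable naive MPM at a given PTM (scalar or array).

    The minimum of the low-PTM branch PTM/M_min and the high-PTM branch
    ((1 − PTM)·OD/S_min + 1)/OD.
    """
    ptm_arr = np.asarray(ptm, dtype=float)
    if np.any((ptm_arr < 0) | (ptm_arr > 1)):
        raise ValueError("PTM must lie in [0, 1]")
    low = ptm_arr / bounds.m_min
    high = ((1.0 - ptm_arr) * bounds.od / bounds.s_min + 1.0) / bounds.od
    out = np.minimum(low, high)
    return float(out) if np.isscalar(ptm) or ptm_arr.ndim == 0 else out


def is_feasible(ptm: float, mpm: float, bounds: FeasibilityBounds,
                tol: float | None = None) -> bool:
    """Whether an (PTM, naive MPM) point lies in the attainable region.

    ``tol`` defaults to 1/OD: the naive estimator can exceed the asymptotic
    bound by one edge-truncated fragment.
    """
    if tol is None:
        tol = 1.0 / bounds.od
    return bool(mpm <= mpm_max(ptm, bounds) + tol)


def triangle_boundary(bounds: FeasibilityBounds,
                      ptm_grid=None) -> pd.DataFrame:
    """Pointwise MPM_max along a PTM grid (default 201 points on [0, 1]).

    Returns a DataFrame with columns ``ptm`` and ``mpm_max``; the curve
    rises on the low-PTM branch, falls on the high-PTM branch, with its
    apex where the branches cross.
    """
    if ptm_grid is None:
        ptm_grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(ptm_grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("PTM grid must lie within [0, 1]")
    return pd.DataFrame({"ptm": grid, "mpm_max": mpm_max(grid, bounds)})


def am_as_from_summary(mpm: float, ptm: float) -> tuple[float, float]:
    """Species-level average move/stop durations from reported summaries.

    With a movement frequency of ``mpm`` bouts per minute and a fraction
    ``ptm`` of time moving, the average move bout lasts AM = PTM/MPM
    minutes and the average stop bout AS = (1 − PTM)/MPM minutes.  These
    are rough derived estimates: published averages of MPM, PTM and OD
    carry the naive estimator's bias into them.  ``mpm`` may be either the
    naive or the corrected value; with per-window OD available the
    corrected one is the less biased input.
    """
    if not 0 <= ptm <= 1:
        raise ValueError("PTM must be a fraction in [0, 1]")
    if mpm <= 0:
        warnings.warn("AM/AS undefined for MPM <= 0", stacklevel=2)
        return math.nan, math.nan
    return ptm / mpm, (1.0 - ptm) / mpm
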