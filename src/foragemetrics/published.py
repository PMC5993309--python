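"""Bias correction of published study-level MPM summaries.

Most comparative datasets report only per-study averages of MPM, PTM and
observation duration.  Applying MPM′ = MPM − PTM/OD to those averages
removes part of the edge-fragment bias and never adds any, so corrected
values are safe to use even when per-observation data are gone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .indices import study_level_correction

__all__ = ["correct_table"]

REQUIRED_COLUMNS = ("label", "mpm", "ptm")


def correct_table(rows: pd.DataFrame,
                  ptm_percent: bool | None = None) -> pd.DataFrame:
    """Append bias-corrected MPM′ and the relative change to a summary table.

    Parameters
    ----------
    rows : DataFrame
        Columns ``label, mpm, ptm`` and either ``od_mean_min`` or the pair
        ``total_min, n_obs`` (mean OD is then total/n).
    ptm_percent : bool, optional
        Whether the ``ptm`` column is in percent (0–100) rather than a
        fraction.  If ``None``, percent is assumed when any value exceeds
        1, with a warning.

    Returns
    -------
    DataFrame
        A copy with columns ``mpm_prime``, ``rel_change`` (percent change
        (MPM − MPM′)/MPM × 100) and ``flag`` appended.  Rows with no
        derivable OD are flagged ``missing_od``, never dropped; the row
        count is always preserved.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = rows.copy()

    ptm = out["ptm"].astype(float)
    if ptm_percent is None:
        ptm_percent = bool((ptm > 1).any())
        if ptm_percent:
            warnings.warn("ptm values exceed 1; interpreting the column as "
                          "percent (pass ptm_percent explicitly to silence)",
                          stacklevel=2)
    if ptm_percent:
        ptm = ptm / 100.0

    od = out["od_mean_min"].astype(float) if "od_mean_min" in out.columns \
        else pd.Series(np.nan, index=out.index)
    if {"total_min", "n_obs"} <= set(out.columns):
        derived = out["total_min"].astype(float) / out["n_obs"].astype(float)
        od = od.fillna(derived)

    mpm_prime, rel_change, flags = [], [], []
    for mpm_i, ptm_i, od_i in zip(out["mpm"].astype(float), ptm, od):
        if not np.isfinite(od_i) or od_i <= 0:
            mpm_prime.append(np.nan)
            rel_change.append(np.nan)
            flags.append("missing_od")
            continue
        if not 0 <= ptm_i <= 1:
            mpm_prime.append(np.nan)
            rel_change.append(np.nan)
            flags.append("ptm_out_of_range")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = study_level_correction(mpm_i, ptm_i, od_i)
        mpm_prime.append(corr)
        rel_change.append(100.0 * (mpm_i - corr) / mpm_i if mpm_i > 0 else np.nan)
        flags.append("negative_mpm_prime" if corr < 0 else "")
    out["mpm_prime"] = mpm_prime
    out["rel_change"] = rel_change
    out["flag"] = flags
    return out
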