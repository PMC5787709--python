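"""Algebraic inference of dynamical traits from fitted per-root traits.

Root growth is linear in time once zonation is stationary, with speed
R_growth = R_prod * l_diff where l_diff = l_0EZ * r_EZ^{N_EZ} is the
mature-cell length predicted by the fitted profile.  Combining a measured
R_growth with the fitted traits therefore yields

    R_prod = R_growth / l_diff          (meristematic activity, cells/h)
    r_elong = R_prod * ln(r_EZ)         (relative elongation rate, 1/h)
    T_EZ   = N_EZ / R_prod              (time spent elongating, h)

R_growth itself comes from root-length-vs-day tables: either one slope on
the cohort-mean lengths (approach 1) or one slope per tracked root
(approach 2), in both cases restricted to days >= ``day_min`` where growth
has become linear.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MM_PER_DAY_TO_UM_PER_H = 1000.0 / 24.0


def _slope_um_per_h(days: np.ndarray, lengths_mm: np.ndarray) -> float:
    return float(np.polyfit(days, lengths_mm, 1)[0]) * MM_PER_DAY_TO_UM_PER_H


def root_growth_rate(lengths: pd.DataFrame, day_min: float = 4,
                     per_root: bool = True) -> pd.Series | float:
    """Least-squares root growth rate (um/h) from a root-length table.

    ``lengths`` has columns root_id, day, root_length_mm.  With
    ``per_root`` (approach 2) a slope is fit per root and a Series indexed
    by root_id is returned (NaN, with a log entry, for roots with fewer
    than 3 usable days).  Otherwise (approach 1) daily means are pooled
    into a single cohort slope.
    """
    sub = lengths[lengths["day"] >= day_min]
    if not per_root:
        daily = sub.groupby("day")["root_length_mm"].mean()
        if daily.size < 3:
            raise ValueError("fewer than 3 days at or after day_min")
        return _slope_um_per_h(daily.index.to_numpy(float),
                               daily.to_numpy(float))
    out = {}
    for rid, grp in sub.groupby("root_id"):
        if len(grp) < 3:
            log.warning("root %s: only %d days >= %s; R_growth missing",
                        rid, len(grp), day_min)
            out[rid] = math.nan
        else:
            out[rid] = _slope_um_per_h(grp["day"].to_numpy(float),
                                       grp["root_length_mm"].to_numpy(float))
    return pd.Series(out, name="R_growth")


def infer_dynamics(traits: pd.DataFrame, use_l_diff: bool = True,
                   phase_correction: bool = False) -> pd.DataFrame:
    """Complete a traits table with l_diff, R_prod, r_elong and T_EZ.

    Requires columns R_growth, l0_EZ, r_EZ, N_EZ (and l_max when
    ``use_l_diff`` is False).  Rows with r_EZ <= 1 or missing inputs are
    left incomplete with a logged reason.

    ``phase_correction`` divides l_diff by (r_EZ - 1)/(r_EZ ln r_EZ), the
    expected ratio between the length of the oldest still-elongating cell
    observed at a random time and the length at which it will actually stop
    (cells are caught mid-way through their last rank).  Off by default --
    the raw identity R_prod = R_growth / l_diff then holds verbatim -- but
    needed when comparing inferred rates against generative ground truth.
    """
    out = traits.copy()
    r_ez = out["r_EZ"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        l_diff = out["l0_EZ"].to_numpy(float) * r_ez ** out["N_EZ"].to_numpy(float)
        if phase_correction:
            l_diff = l_diff * r_ez * np.log(r_ez) / (r_ez - 1.0)
    out["l_diff"] = l_diff
    denom = out["l_diff"] if use_l_diff else out["l_max"]
    valid = (r_ez > 1.0) & np.isfinite(denom) & np.isfinite(
        out["R_growth"].to_numpy(float))
    n_skip = int((~valid).sum())
    if n_skip:
        log.info("infer_dynamics: %d roots skipped (r_EZ <= 1 or missing inputs)",
                 n_skip)
    r_prod = np.where(valid, out["R_growth"] / denom, math.nan)
    out["R_prod"] = r_prod
    out["r_elong"] = np.where(valid, r_prod * np.log(r_ez), math.nan)
    out["T_EZ"] = np.where(valid & (r_prod > 0), out["N_EZ"] / r_prod, math.nan)
    return out
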