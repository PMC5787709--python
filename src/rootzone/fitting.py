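"""Automated two-segment exponential fitting of single-root length profiles.

A measured profile is the ordered list of cell lengths from the quiescent
center to the first root-hair cell.  On a log10 scale the meristem (MZ) and
elongation zone (EZ) are two straight segments; the fitter scans every
admissible breakpoint k (last MZ cell), fits least-squares lines to
log10(length) vs cell index on [1..k] and [k+1..m], and keeps the k with
the smallest total residual sum of squares subject to:

* each segment at least its minimum size (``min_mz``, ``min_ez`` cells),
* the EZ slope strictly exceeds the MZ slope,
* the implied elongation factor r_EZ = 10^{slope_EZ} >= ``r_min``.

If no breakpoint is admissible the root is reported as having no
elongation zone (N_EZ = 0, L_EZ = 0, r_EZ and l_max undefined); such roots
are kept in the cohort but excluded from analyses that need those traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MeasuredProfile:
    """One root's observed cell-length profile (the Dataset-EV1-like unit).

    ``lengths`` are indexed 1..n from the first cell distal to the QC;
    ``first_hair_index`` is the 1-based position of the first root-hair /
    mature cell (exclusive end of the EZ); n+1 means no hair was observed
    within the measured span.
    """

    root_id: str
    lengths: np.ndarray
    first_hair_index: int
    genotype: str = "unknown"
    day: int | None = None
    tissue: str = "epidermis"

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.lengths.size
        if n < 4:
            raise ValueError(f"root {self.root_id}: need >= 4 cells, got {n}")
        if (self.lengths <= 0).any():
            raise ValueError(f"root {self.root_id}: non-positive cell length")
        if not 1 <= self.first_hair_index <= n + 1:
            raise ValueError(
                f"root {self.root_id}: first_hair_index {self.first_hair_index} "
                f"outside 1..{n + 1}"
            )

    @property
    def n_measured(self) -> int:
        """Number of cells before the first hair cell (MZ + EZ span)."""
        return self.first_hair_index - 1


@dataclass(frozen=True)
class FitConfig:
    min_mz: int = 4
    min_ez: int = 2
    r_min: float = 1.05
    #: minimum r_EZ / r_MZ ratio: a two-segment fit must steepen by at
    #: least this factor, otherwise the profile is a single exponential
    min_slope_ratio: float = 1.02
    l0ez_from_fit: bool = True   # evaluate the EZ line at index k, vs raw length


@dataclass
class FitResult:
    status: str                   # ok | no_EZ | rejected
    breakpoint: int | None = None # k, last MZ cell (1-based)
    slope_mz: float = math.nan
    intercept_mz: float = math.nan
    slope_ez: float = math.nan
    intercept_ez: float = math.nan
    sse_mz: float = math.nan
    sse_ez: float = math.nan
    reason: str = ""

    @property
    def r_mz(self) -> float:
        return 10.0 ** self.slope_mz

    @property
    def r_ez(self) -> float:
        return 10.0 ** self.slope_ez

    @property
    def l0_mz(self) -> float:
        return 10.0 ** self.intercept_mz

    def l0_ez(self, config: FitConfig | None = None) -> float:
        """Entry length of the EZ: the EZ line evaluated at the breakpoint."""
        if self.status != "ok":
            return math.nan
        return 10.0 ** (self.intercept_ez + self.slope_ez * self.breakpoint)


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line y = a + b x; returns (slope, intercept, sse)."""
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    return float(b), float(a), float(resid @ resid)


def fit_profile(profile: MeasuredProfile,
                config: FitConfig | None = None) -> FitResult:
    """Breakpoint scan over log10(length) vs cell index (module docstring)."""
    cfg = config or FitConfig()
    m = profile.n_measured
    if m < cfg.min_mz + cfg.min_ez:
        return FitResult(status="rejected",
                         reason=f"only {m} cells before the hair; need "
                                f">= {cfg.min_mz + cfg.min_ez}")
    idx = np.arange(1, m + 1, dtype=float)
    logl = np.log10(profile.lengths[:m])
    log_r_min = math.log10(cfg.r_min)
    log_gap = math.log10(cfg.min_slope_ratio)

    # descending scan: on an SSE tie the larger k wins, i.e. the junction
    # cell (which lies on both segments of an exact piecewise profile)
    # counts as the last meristem cell
    best: FitResult | None = None
    for k in range(m - cfg.min_ez, cfg.min_mz - 1, -1):
        s_mz, a_mz, sse_mz = _segment_fit(idx[:k], logl[:k])
        s_ez, a_ez, sse_ez = _segment_fit(idx[k:], logl[k:])
        if s_ez < s_mz + log_gap or s_ez < log_r_min:
            continue
        total = sse_mz + sse_ez
        if best is None or total < best.sse_mz + best.sse_ez - 1e-12:
            best = FitResult(status="ok", breakpoint=k,
                             slope_mz=s_mz, intercept_mz=a_mz,
                             slope_ez=s_ez, intercept_ez=a_ez,
                             sse_mz=sse_mz, sse_ez=sse_ez)
    if best is None:
        return FitResult(status="no_EZ",
                         reason="no admissible breakpoint (single-exponential "
                                "profile or EZ constraints unmet)")
    return best


#: trait columns emitted per root
TRAIT_COLUMNS = ["root_id", "genotype", "day", "tissue", "fit_status",
                 "r_MZ", "r_EZ", "l0_MZ", "l0_EZ", "N_MZ", "N_EZ",
                 "L_EZ", "l_max", "inv_r_EZ", "inv_ln_r_EZ"]


def extract_traits(fit: FitResult, profile: MeasuredProfile,
                   config: FitConfig | None = None) -> dict:
    """Per-root phenotypic traits from a fitted profile.

    EZ cells are counted from the cell after the breakpoint up to (not
    including) the first hair cell; l_max is the measured length of the EZ
    cell adjacent to the hair.  Undefined fields propagate as NaN.
    """
    cfg = config or FitConfig()
    m = profile.n_measured
    rec = {"root_id": profile.root_id, "genotype": profile.genotype,
           "day": profile.day, "tissue": profile.tissue,
           "fit_status": fit.status}
    nan = math.nan
    if fit.status == "rejected":
        rec.update({c: nan for c in TRAIT_COLUMNS[5:]})
        return rec
    if fit.status == "no_EZ":
        rec.update(r_MZ=nan, r_EZ=nan, l0_MZ=nan, l0_EZ=nan,
                   N_MZ=m, N_EZ=0, L_EZ=0.0, l_max=nan,
                   inv_r_EZ=nan, inv_ln_r_EZ=nan)
        return rec
    k = fit.breakpoint
    l0ez = fit.l0_ez(cfg) if cfg.l0ez_from_fit else float(profile.lengths[k - 1])
    r_ez = fit.r_ez
    rec.update(
        r_MZ=fit.r_mz, r_EZ=r_ez, l0_MZ=fit.l0_mz, l0_EZ=l0ez,
        N_MZ=k, N_EZ=m - k,
        L_EZ=float(profile.lengths[k:m].sum()),
        l_max=float(profile.lengths[m - 1]),
        inv_r_EZ=1.0 / r_ez,
        inv_ln_r_EZ=1.0 / math.log(r_ez) if r_ez > 1.0 else nan,
    )
    return rec


def fit_cohort(profiles: list[MeasuredProfile],
               config: FitConfig | None = None
               ) -> tuple[pd.DataFrame, dict]:
    """Fit every profile; returns the traits table and status counts."""
    cfg = config or FitConfig()
    rows, counts = [], {"ok": 0, "no_EZ": 0, "rejected": 0}
    for prof in profiles:
        fit = fit_profile(prof, cfg)
        counts[fit.status] += 1
        rows.append(extract_traits(fit, prof, cfg))
    table = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    return table, counts


def render_profile(r_mz: float, r_ez: float, l0_mz: float, n_mz: int,
                   n_ez: int) -> np.ndarray:
    """Noiseless two-segment profile l_i (inverse of the fitter's model).

    MZ cells i = 1..n_mz have length l0_mz * r_mz^i; EZ cells continue from
    the last MZ length with factor r_ez.
    """
    i = np.arange(1, n_mz + n_ez + 1, dtype=float)
    l_mz = l0_mz * r_mz ** i[:n_mz]
    l_break = l0_mz * r_mz ** n_mz
    l_ez = l_break * r_ez ** (i[n_mz:] - n_mz)
    return np.concatenate([l_mz, l_ez])
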