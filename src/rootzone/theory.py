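"""Closed-form stationary traits of the noiseless cell-file models.

In the stationary regime with no variability, cells enter the EZ every
1/R_prod hours with length l_0EZ and elongate as l(t) = l_0EZ e^{r_elong t}.
The cell at rank k from the meristem end (k = 1 the youngest) has length
l_0EZ * r_EZ^k with elongation factor r_EZ = exp(r_elong / R_prod).  Each
rule fixes the residence time tau in the EZ, and hence

    N_EZ = R_prod * tau,     l_max = l_0EZ * r_EZ^{N_EZ}  (= l_diff),
    L_EZ = l_0EZ * r_EZ * (r_EZ^{N_EZ} - 1) / (r_EZ - 1),
    T_EZ = N_EZ / R_prod,    R_growth = R_prod * l_max.

N_EZ is returned as the (possibly non-integer) time-average; the ruler rule
is intrinsically integer-valued because its criterion is evaluated on the
discrete set of elongating cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulator import MODELS


@dataclass(frozen=True)
class SteadyTraits:
    n_ez: float
    l_max: float
    l_ez: float
    r_ez: float
    r_growth: float
    t_ez: float

    @property
    def n_ez_int(self) -> int:
        """Integer-rounded (ceil) cell count for per-snapshot comparison."""
        return int(math.ceil(self.n_ez - 1e-9))


def elongation_factor_from_rates(r_elong: float, r_prod: float) -> float:
    """r_EZ = exp(r_elong / R_prod); the base of the exponential profile."""
    if r_prod <= 0:
        raise ValueError("R_prod must be > 0")
    if r_elong < 0:
        raise ValueError("r_elong must be >= 0")
    return math.exp(r_elong / r_prod)


def _geometric_l_ez(l0ez: float, r_ez: float, n_ez: float) -> float:
    if abs(r_ez - 1.0) < 1e-12:
        return l0ez * n_ez
    return l0ez * r_ez * (r_ez ** n_ez - 1.0) / (r_ez - 1.0)


def ruler_n_ez(l0ez: float, r_ez: float, threshold: float) -> int:
    """Smallest N whose oldest-cell center distance reaches the ruler length.

    The center of the rank-N cell sits at sum_{k=1}^{N-1} l0ez r^k plus half
    its own length; mirrors the simulator's entry-event test exactly.
    """
    if r_ez <= 1.0:
        raise ValueError("ruler closed form requires r_EZ > 1")
    n = 1
    below = 0.0   # cumulative length of cells younger than rank n
    while True:
        ln = l0ez * r_ez ** n
        if below + ln / 2.0 >= threshold:
            return n
        below += ln
        n += 1
        if n > 100_000:
            raise ValueError("ruler threshold unreachably large")


def steady_state_traits(model: str, l0ez: float, r_elong: float,
                        r_prod: float, threshold: float,
                        k_decay: float = 0.0) -> SteadyTraits:
    """Stationary traits of the noiseless model (see module docstring)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if min(l0ez, r_elong, r_prod, threshold) <= 0:
        raise ValueError("all parameters must be > 0")
    r_ez = elongation_factor_from_rates(r_elong, r_prod)

    if model == "sizer":
        if threshold <= l0ez:
            import warnings
            warnings.warn("sizer threshold <= entry length: degenerate N_EZ = 0")
            n_ez, l_max = 0.0, l0ez
        else:
            n_ez = math.log(threshold / l0ez) / math.log(r_ez)
            l_max = threshold
    elif model == "timer":
        n_ez = threshold * r_prod
        l_max = l0ez * math.exp(r_elong * threshold)
    elif model == "dilution":
        tau = math.log(threshold) / (r_elong + k_decay)
        n_ez = tau * r_prod
        l_max = l0ez * math.exp(r_elong * tau)
    else:  # ruler
        n_ez = float(ruler_n_ez(l0ez, r_ez, threshold))
        l_max = l0ez * r_ez ** n_ez

    l_ez = _geometric_l_ez(l0ez, r_ez, n_ez)
    t_ez = n_ez / r_prod
    return SteadyTraits(n_ez=n_ez, l_max=l_max, l_ez=l_ez, r_ez=r_ez,
                        r_growth=r_prod * l_max, t_ez=t_ez)


RELATIONS = ("LEZ_vs_NEZ", "lmax_vs_inv_rEZ", "NEZ_vs_inv_ln_rEZ")
SWEEPABLE = ("r_elong", "r_prod", "threshold")


def relation_curve(model: str, relation: str, swept: str,
                   base: dict, grid: np.ndarray) -> np.ndarray:
    """Theoretical (x, y) pairs for one trait-pair relation.

    ``base`` holds l0ez, r_elong, r_prod, threshold (and k_decay for the
    dilution rule); ``swept`` is replaced by each grid value in turn.  For
    the timer rule the curve genuinely depends on which of r_elong / R_prod
    is swept (two distinct theoretical lines).  Sweeping the threshold
    yields the shared fixed-profile dependence along which all models
    collapse.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    if swept not in SWEEPABLE:
        raise ValueError(f"cannot sweep {swept!r}")
    pts = np.empty((len(grid), 2))
    for i, v in enumerate(np.asarray(grid, dtype=float)):
        p = dict(base)
        p[swept] = v
        tr = steady_state_traits(model, p["l0ez"], p["r_elong"],
                                 p["r_prod"], p["threshold"],
                                 p.get("k_decay", 0.0))
        if relation == "LEZ_vs_NEZ":
            pts[i] = (tr.n_ez, tr.l_ez)
        elif relation == "lmax_vs_inv_rEZ":
            pts[i] = (1.0 / tr.r_ez, tr.l_max)
        else:
            pts[i] = (1.0 / math.log(tr.r_ez), tr.n_ez)
    return pts
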