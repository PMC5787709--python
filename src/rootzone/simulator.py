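"""Event-driven stochastic simulation of a single elongating root cell file.

Cells are created at the meristem/elongation-zone (EZ) boundary at random
intervals, elongate exponentially with a constant relative rate, and stop
elongating (differentiate) according to one of four rules:

``ruler``
    a cell stops when its center lies at a distance >= L0 from the end of
    the meristem; the test is applied only at cell-creation events.
``timer``
    a cell stops after a fixed residence time T0 in the EZ.
``sizer``
    a cell stops when its length reaches a threshold length l_diff0.
``dilution``
    a cell stops when an initially loaded signaling factor, diluted by
    expansion and degraded at rate k, falls below a threshold concentration;
    k = 0 reduces to a (relative) sizer, large k approaches a timer.

Two-level Gaussian variability: each root draws its parameter means from a
cohort-level Gaussian (sd Delta), each cell draws its own values from a
root-level Gaussian (sd sigma <= Delta).  Non-positive draws are rejected
and redrawn.  Units are micrometres and hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

MODELS = ("ruler", "timer", "sizer", "dilution")

#: parameters that receive two-level Gaussian variability
PARAM_NAMES = ("r_prod", "l0", "r_elong", "threshold")

_REJECTION_CAP = 1_000_000


class InfeasibleConfigError(ValueError):
    """Raised when positivity rejection exceeds the draw cap."""


@dataclass(frozen=True)
class PopulationParams:
    """Cohort-level configuration of a simulated root population.

    ``r_prod`` is the meristematic activity (cells/h); the inter-arrival
    interval between consecutive cell entries is 1/r_prod.  ``threshold``
    is the model-specific differentiation threshold: distance L0 (um) for
    ruler, residence time T0 (h) for timer, length l_diff0 (um) for sizer,
    and the dimensionless initial/threshold concentration ratio for the
    dilution rule (whose decay constant is ``k_decay``, 1/h).
    """

    model: str
    r_prod: float
    l0: float
    r_elong: float
    threshold: float
    delta: dict = field(default_factory=dict)   # between-root sd, absolute
    sigma: dict = field(default_factory=dict)   # within-root sd, absolute
    k_decay: float = 0.0
    n_roots: int = 122
    t_end: float = 240.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for name in PARAM_NAMES:
            if self.mean(name) <= 0:
                raise ValueError(f"mean of {name} must be > 0")
            d, s = self.delta.get(name, 0.0), self.sigma.get(name, 0.0)
            if d < 0 or s < 0:
                raise ValueError(f"spreads for {name} must be >= 0")
            if s > d + 1e-12:
                raise ValueError(
                    f"within-root sd of {name} ({s}) exceeds between-root sd ({d})"
                )
        if self.k_decay < 0:
            raise ValueError("k_decay must be >= 0")
        if self.n_roots < 1 or self.t_end <= 0:
            raise ValueError("n_roots >= 1 and t_end > 0 required")

    def mean(self, name: str) -> float:
        return getattr(self, name)

    @property
    def entry_interval(self) -> float:
        """Mean interval between successive cell entries (h)."""
        return 1.0 / self.r_prod

    def with_(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RootParams:
    """Realized per-root parameter means (one draw from the cohort level)."""

    root_id: int
    r_prod: float
    l0: float
    r_elong: float
    threshold: float


@dataclass
class RootFileTrajectory:
    """Full record of one simulated cell file.

    Arrays are aligned by cell creation order.  ``stop_time`` is +inf and
    ``stop_length`` is NaN for cells still elongating at ``t_end``.
    """

    root_id: int
    model: str
    params: RootParams
    entry_time: np.ndarray
    l0: np.ndarray
    r_elong: np.ndarray
    stop_time: np.ndarray
    stop_length: np.ndarray
    t_end: float

    @property
    def n_cells(self) -> int:
        return self.entry_time.size

    def first_stop_time(self) -> float:
        stops = self.stop_time[np.isfinite(self.stop_time)]
        return float(stops.min()) if stops.size else math.inf


@dataclass
class SimSnapshot:
    """State of the cell file at one observation time."""

    t_obs: float
    lengths: np.ndarray          # elongating cells, youngest (nearest MZ) first
    n_ez: int
    l_ez: float
    l_max: float                 # oldest elongating cell ("next to the hair")
    dz_length: float
    dz_count: int


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     size: int) -> np.ndarray:
    """Gaussian draws with rejection of values <= 0 (capped)."""
    if sd == 0.0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    drawn = size
    while bad.any():
        n_bad = int(bad.sum())
        drawn += n_bad
        if drawn > _REJECTION_CAP:
            raise InfeasibleConfigError(
                f"positivity rejection exceeded {_REJECTION_CAP} draws "
                f"(mean={mean}, sd={sd})"
            )
        out[bad] = rng.normal(mean, sd, n_bad)
        bad = out <= 0
    return out


def sample_population(params: PopulationParams,
                      seed: int | np.random.Generator | None = None
                      ) -> list[RootParams]:
    """Draw per-root parameter means from the cohort-level Gaussians."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    draws = {
        name: _positive_normal(rng, params.mean(name),
                               params.delta.get(name, 0.0), params.n_roots)
        for name in PARAM_NAMES
    }
    return [
        RootParams(root_id=j, r_prod=float(draws["r_prod"][j]),
                   l0=float(draws["l0"][j]), r_elong=float(draws["r_elong"][j]),
                   threshold=float(draws["threshold"][j]))
        for j in range(params.n_roots)
    ]


def _draw_cells(rng, root: RootParams, sigma: dict, t_end: float):
    """Entry times and per-cell (l0, r_elong, threshold) up to t_end."""
    entry = [0.0]
    rates, l0s, thr = [], [], []
    block = max(int(t_end * root.r_prod * 1.5) + 32, 64)
    t = 0.0
    while True:
        rp = _positive_normal(rng, root.r_prod, sigma.get("r_prod", 0.0), block)
        intervals = 1.0 / rp
        for dt in intervals:
            t += dt
            if t > t_end:
                break
            entry.append(t)
        if t > t_end:
            break
    n = len(entry)
    l0s = _positive_normal(rng, root.l0, sigma.get("l0", 0.0), n)
    rates = _positive_normal(rng, root.r_elong, sigma.get("r_elong", 0.0), n)
    thr = _positive_normal(rng, root.threshold, sigma.get("threshold", 0.0), n)
    return np.asarray(entry), l0s, rates, thr


def simulate_root_file(root: RootParams, model: str, t_end: float,
                       seed: int | np.random.Generator | None = None,
                       sigma: dict | None = None,
                       k_decay: float = 0.0) -> RootFileTrajectory:
    """Simulate one cell file from a single initial cell up to ``t_end``.

    Stop times for timer/sizer/dilution are closed-form per cell; the ruler
    criterion is evaluated only at cell-creation events, on the cells
    present before the new cell is inserted.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = sigma or {}
    entry, l0s, rates, thr = _draw_cells(rng, root, sigma, t_end)
    n = entry.size

    if model == "timer":
        tau = thr
    elif model == "sizer":
        tau = np.where(l0s >= thr, 0.0, np.log(np.maximum(thr / l0s, 1.0)) / rates)
    elif model == "dilution":
        tau = np.log(thr) / (rates + k_decay)
    else:  # ruler: sequential evaluation at entry events
        return _simulate_ruler(root, entry, l0s, rates, thr, t_end)

    stop_time = entry + tau
    stop_length = l0s * np.exp(rates * tau)
    open_mask = stop_time > t_end
    stop_time = np.where(open_mask, np.inf, stop_time)
    stop_length = np.where(open_mask, np.nan, stop_length)
    return RootFileTrajectory(root.root_id, model, root, entry, l0s, rates,
                              stop_time, stop_length, t_end)


def _simulate_ruler(root, entry, l0s, rates, thr, t_end):
    n = entry.size
    stop_time = np.full(n, np.inf)
    stop_length = np.full(n, np.nan)
    active: list[int] = []          # elongating cells, entry order (oldest first)
    for m in range(n):
        t = entry[m]
        if active:
            idx = np.array(active)
            lengths = l0s[idx] * np.exp(rates[idx] * (t - entry[idx]))
            # distance from the meristem end: younger cells sit between the
            # meristem and the tested cell; youngest = most recently created
            rev = lengths[::-1]
            centers = np.cumsum(rev) - rev / 2.0
            stop_rev = centers >= thr[idx[::-1]]
            if stop_rev.any():
                stopped = idx[::-1][stop_rev]
                stop_time[stopped] = t
                stop_length[stopped] = rev[stop_rev]
                active = [i for i in active if stop_time[i] == np.inf]
        active.append(m)
    return RootFileTrajectory(root.root_id, "ruler", root, entry, l0s, rates,
                              stop_time, stop_length, t_end)


def snapshot(traj: RootFileTrajectory, t_obs: float) -> SimSnapshot:
    """Observe the file at ``t_obs``.

    A cell belongs to the EZ on the half-open interval [entry, stop): a cell
    whose stop time equals ``t_obs`` is already counted in the DZ.
    """
    if t_obs > traj.t_end:
        raise ValueError(f"t_obs={t_obs} beyond simulated horizon {traj.t_end}")
    ez = (traj.entry_time <= t_obs) & (traj.stop_time > t_obs)
    lengths = traj.l0[ez] * np.exp(traj.r_elong[ez] * (t_obs - traj.entry_time[ez]))
    order = np.argsort(traj.entry_time[ez])[::-1]     # youngest first
    lengths = lengths[order]
    dz = traj.stop_time <= t_obs
    l_max = float(lengths[-1]) if lengths.size else math.nan
    return SimSnapshot(
        t_obs=t_obs, lengths=lengths, n_ez=int(ez.sum()),
        l_ez=float(lengths.sum()), l_max=l_max,
        dz_length=float(np.nansum(traj.stop_length[dz])), dz_count=int(dz.sum()),
    )


def n_ez_at_entries(traj: RootFileTrajectory) -> np.ndarray:
    """Number of elongating cells just after each cell-creation event."""
    stops = np.sort(traj.stop_time[np.isfinite(traj.stop_time)])
    created = np.arange(1, traj.n_cells + 1)
    gone = np.searchsorted(stops, traj.entry_time, side="right")
    return created - gone


def detect_stationary(traj: RootFileTrajectory, window: int = 20,
                      tol: float = 0.05) -> float | None:
    """Earliest time after which windowed mean N_EZ has settled.

    Consecutive non-overlapping windows of ``window`` entry events are
    compared; the onset is the start of the first window that (a) begins at
    or after the first differentiation event and (b) whose mean differs from
    the previous window's by less than ``tol`` (relative, with an absolute
    floor of half a cell -- N_EZ is a small count and its windowed mean
    cannot settle tighter than its discreteness).  Returns None if the file
    never reaches that criterion (non-stationary within t_end).
    """
    n_ez = n_ez_at_entries(traj)
    n_blocks = n_ez.size // window
    if n_blocks < 2:
        return None
    first_stop = traj.first_stop_time()
    if not math.isfinite(first_stop):
        return None
    means = n_ez[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    starts = traj.entry_time[np.arange(n_blocks) * window]
    for k in range(1, n_blocks):
        if starts[k] < first_stop or means[k] <= 0:
            continue
        if abs(means[k] - means[k - 1]) <= max(tol * means[k], 0.5):
            return float(starts[k])
    return None


def sim_root_growth_rate(traj: RootFileTrajectory, t_from: float,
                         n_grid: int = 50) -> float:
    """Least-squares slope of cumulative DZ length vs time (um/h)."""
    if n_grid < 3:
        raise ValueError("need at least 3 grid points for a slope")
    grid = np.linspace(t_from, traj.t_end, n_grid)
    stops = traj.stop_time[np.isfinite(traj.stop_time)]
    order = np.argsort(stops)
    stop_sorted = stops[order]
    cum = np.concatenate([[0.0], np.cumsum(
        traj.stop_length[np.isfinite(traj.stop_time)][order])])
    dz = cum[np.searchsorted(stop_sorted, grid, side="right")]
    return float(np.polyfit(grid, dz, 1)[0])
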