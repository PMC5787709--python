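"""Synthetic measured cohorts with known ground truth.

Emulates per-root cell-length datasets: each root is a stochastic cell-file
simulation observed once in the stationary regime, prefixed with a
geometric meristem segment (the models do not simulate the meristem; its
only role here is to exercise the breakpoint fitter), terminated with a
first-root-hair marker cell, and corrupted with multiplicative lognormal
measurement noise.  Every emitted root is joinable to a ground-truth
manifest of its generating parameters and noiseless stationary traits.

Preset parameter values are back-solved from published cohort statistics
(mean elongation factor 1.29, ~11.8 EZ cells, ~26 meristem cells, mature
cells near 160 um, elongation time near 6.7 h for a wild-type epidermal
file) through the closed forms in :mod:`rootzone.theory`; see
docs/methods.md for the derivation and for what the generator deliberately
does not emulate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import theory
from .simulator import (PopulationParams, RootParams, sample_population,
                        simulate_root_file, snapshot, detect_stationary,
                        sim_root_growth_rate)

log = logging.getLogger(__name__)

#: relative between-root spreads shared by all wild-type-like presets;
#: chosen once so that sd(r_EZ) matches the published 1.29 +/- 0.10
#: (most spread on the elongation rate, little on meristematic activity)
WT_REL_DELTA = {"r_prod": 0.08, "l0": 0.15, "r_elong": 0.28}

#: threshold relative variability per rule (ruler/timer/sizer as published;
#: dilution assumed equal to sizer)
THRESHOLD_REL_DELTA = {"ruler": 0.35, "timer": 0.07, "sizer": 0.26,
                       "dilution": 0.26}


@dataclass(frozen=True)
class CohortPreset:
    """Recipe for one synthetic cohort (simulation + rendering + noise)."""

    name: str
    model: str
    r_prod: float = 1.75          # cells/h
    l0: float = 8.0               # um, entry length into the EZ
    r_elong: float = 0.446        # 1/h
    threshold: float = 160.0      # rule-specific units (see PopulationParams)
    k_decay: float = 0.0          # 1/h, dilution rule only
    rel_delta: dict = field(default_factory=dict)
    rel_sigma: dict = field(default_factory=dict)
    n_mz_mean: float = 26.2       # meristem rendering
    n_mz_sd: float = 3.0
    r_mz: float = 1.03
    r_mz_sd: float = 0.01
    noise_cv: float = 0.05        # multiplicative lognormal measurement noise
    n_roots: int = 122
    t_end: float = 240.0          # h (10 days)

    def __post_init__(self) -> None:
        if not 0 <= self.noise_cv < 0.3:
            raise ValueError("noise CV must be in [0, 0.3)")

    def population(self) -> PopulationParams:
        delta = {p: self.rel_delta.get(p, 0.0) * getattr(self, p)
                 for p in ("r_prod", "l0", "r_elong", "threshold")}
        sigma = {p: self.rel_sigma.get(p, 0.0) * getattr(self, p)
                 for p in ("r_prod", "l0", "r_elong", "threshold")}
        return PopulationParams(model=self.model, r_prod=self.r_prod,
                                l0=self.l0, r_elong=self.r_elong,
                                threshold=self.threshold, delta=delta,
                                sigma=sigma, k_decay=self.k_decay,
                                n_roots=self.n_roots, t_end=self.t_end)

    def with_(self, **kwargs) -> "CohortPreset":
        return replace(self, **kwargs)


def _wt(name: str, model: str, threshold: float, **kw) -> CohortPreset:
    rel_delta = dict(WT_REL_DELTA, threshold=THRESHOLD_REL_DELTA[model])
    # within-root spread Delta/4: small enough that slow outlier cells do
    # not dominate the old end of the file (which would bias the fitted
    # mature length and the rates inferred from it), while still producing
    # visible cell-to-cell scatter
    rel_sigma = {p: v / 4.0 for p, v in WT_REL_DELTA.items()}
    rel_sigma["threshold"] = 0.0   # threshold is a per-root property
    return CohortPreset(name=name, model=model, threshold=threshold,
                        rel_delta=rel_delta, rel_sigma=rel_sigma, **kw)


# Matched wild-type-like presets: identical kinetic parameters, each rule's
# threshold solved to give ~11.8 EZ cells (see docs/methods.md).  The
# dilution preset uses k = r_elong: dilution and degradation contribute
# equally to the decay of the signal, the midpoint between the sizer (k=0)
# and timer (k >> r_elong) limits.
PRESETS: dict[str, CohortPreset] = {}
for _p in [
    _wt("wt_epidermis_sizer", "sizer", threshold=160.0),
    _wt("wt_epidermis_timer", "timer", threshold=6.74),
    _wt("wt_epidermis_ruler", "ruler", threshold=603.0),
    _wt("wt_epidermis_dilution", "dilution", threshold=420.0, k_decay=0.45),
    # short-root scenarios: a mixed dilution rule with reduced elongation
    # and degradation-dominated signal decay, and a sizer with a reduced
    # length threshold
    _wt("bri1_like", "dilution", threshold=148.0, k_decay=0.45,
        r_elong=0.30, r_prod=1.2, n_mz_mean=20.0),
    _wt("pac_like", "sizer", threshold=100.0, r_elong=0.35, r_prod=1.4,
        n_mz_mean=22.0),
]:
    PRESETS[_p.name] = _p


def _simulate_stationary_root(root: RootParams, pop: PopulationParams,
                              rng: np.random.Generator, max_retries: int = 5):
    """Simulate one root, retrying with fresh noise if never stationary.

    Returns (trajectory, t_star), or None after ``max_retries`` attempts;
    callers exclude such roots from the cohort with a logged reason.
    """
    for _ in range(max_retries):
        traj = simulate_root_file(root, pop.model, pop.t_end, rng,
                                  sigma=pop.sigma, k_decay=pop.k_decay)
        t_star = detect_stationary(traj)
        if t_star is not None:
            return traj, t_star
    log.warning("root %d never stationary within t_end=%.0f h; excluded",
                root.root_id, pop.t_end)
    return None


def _log_linear(lengths: np.ndarray) -> tuple[float, float]:
    """(r_ez, l0ez) from a log-linear fit to snapshot lengths, rank 1..N."""
    ranks = np.arange(1, lengths.size + 1, dtype=float)
    b, a = np.polyfit(ranks, np.log(lengths), 1)
    return float(np.exp(b)), float(np.exp(a))


def simulate_cohort_traits(pop: PopulationParams, seed: int) -> pd.DataFrame:
    """Simulate a cohort and observe stationary traits root by root.

    The per-root elongation factor is estimated from a log-linear fit to the
    snapshot's ordered EZ lengths (mirroring how it is measured on data);
    R_growth is the post-stationarity slope of differentiated length vs
    time.  True per-root parameters are carried alongside for validation.
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, *root_seeds = ss.spawn(pop.n_roots + 1)
    roots = sample_population(pop, np.random.default_rng(pop_seed))
    rows = []
    for root, rseed in zip(roots, root_seeds):
        rng = np.random.default_rng(rseed)
        sim = _simulate_stationary_root(root, pop, rng)
        if sim is None:
            continue
        traj, t_star = sim
        snap = snapshot(traj, pop.t_end)
        if snap.n_ez < 3:
            continue
        r_ez, l0ez = _log_linear(snap.lengths)
        rows.append({
            "root_id": root.root_id,
            "N_EZ": snap.n_ez, "L_EZ": snap.l_ez, "l_max": snap.l_max,
            "r_EZ": r_ez, "l0_EZ": l0ez,
            "inv_r_EZ": 1.0 / r_ez,
            "inv_ln_r_EZ": 1.0 / math.log(r_ez) if r_ez > 1 else math.nan,
            "R_growth": sim_root_growth_rate(traj, t_star),
            "t_star": t_star,
            "true_r_prod": root.r_prod, "true_l0": root.l0,
            "true_r_elong": root.r_elong, "true_threshold": root.threshold,
        })
    return pd.DataFrame(rows)


def generate_cohort(preset: CohortPreset | str, seed: int
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a Dataset-EV1-style cohort of measured profiles.

    Returns (profiles, manifest).  Profiles are long-format rows
    (root_id, genotype, day, tissue, cell_index, cell_length_um,
    is_first_hair); the manifest has one row per root with the generating
    parameters and noiseless stationary traits.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    pop = preset.population()
    ss = np.random.SeedSequence(seed)
    pop_seed, noise_seed, *root_seeds = ss.spawn(pop.n_roots + 2)
    roots = sample_population(pop, np.random.default_rng(pop_seed))
    noise_rng = np.random.default_rng(noise_seed)
    sigma_ln = math.sqrt(math.log(1.0 + preset.noise_cv ** 2))

    prof_rows, man_rows = [], []
    for root, rseed in zip(roots, root_seeds):
        rng = np.random.default_rng(rseed)
        sim = _simulate_stationary_root(root, pop, rng)
        if sim is None:
            continue
        traj, t_star = sim
        snap = snapshot(traj, pop.t_end)
        if snap.n_ez < 1:
            continue
        ez = snap.lengths                       # youngest first = nearest MZ
        n_mz = max(int(round(rng.normal(preset.n_mz_mean, preset.n_mz_sd))), 5)
        r_mz = max(rng.normal(preset.r_mz, preset.r_mz_sd), 1.001)
        # geometric meristem: the last MZ cell sits one elongation-factor
        # step below the youngest EZ cell, so the rendered profile is
        # continuous across the breakpoint
        l_join = ez[0] / math.exp(root.r_elong / root.r_prod)
        l0_mz = max(l_join, 1.0) / r_mz ** (n_mz - 1)
        mz = l0_mz * r_mz ** np.arange(1, n_mz + 1)
        hair = snap.l_max * rng.uniform(0.95, 1.1)
        lengths = np.concatenate([mz, ez, [hair]])
        if sigma_ln > 0:
            noise = noise_rng.lognormal(-sigma_ln ** 2 / 2.0, sigma_ln,
                                        lengths.size)
            lengths = lengths * noise
        rid = f"{preset.name}_{root.root_id:03d}"
        first_hair = n_mz + ez.size + 1
        for i, l in enumerate(lengths, start=1):
            prof_rows.append((rid, preset.name, 6, "epidermis", i, float(l),
                              int(i == first_hair)))
        tr = theory.steady_state_traits(pop.model, root.l0, root.r_elong,
                                        root.r_prod, root.threshold,
                                        pop.k_decay)
        man_rows.append({
            "root_id": rid, "preset": preset.name, "model": pop.model,
            "seed": seed, "true_r_prod": root.r_prod, "true_l0": root.l0,
            "true_r_elong": root.r_elong, "true_threshold": root.threshold,
            "k_decay": pop.k_decay, "n_mz": n_mz, "r_mz": r_mz,
            "true_N_EZ": tr.n_ez, "true_l_max": tr.l_max,
            "true_L_EZ": tr.l_ez, "true_r_EZ": tr.r_ez,
            "true_R_growth": tr.r_growth, "true_T_EZ": tr.t_ez,
            "snap_N_EZ": snap.n_ez, "t_star": t_star,
        })
    profiles = pd.DataFrame(prof_rows, columns=[
        "root_id", "genotype", "day", "tissue", "cell_index",
        "cell_length_um", "is_first_hair"])
    return profiles, pd.DataFrame(man_rows)


def generate_root_length_series(preset: CohortPreset | str, days=range(1, 11),
                                seed: int = 0,
                                manifest: pd.DataFrame | None = None,
                                noise_sd_mm: float = 0.15) -> pd.DataFrame:
    """Daily root-length table with a sub-linear transient before day 4.

    From day 4 on the noiseless length is exactly linear with the root's
    stationary growth speed; earlier days lie below that line (a quadratic
    ramp), so fitting from day 1 underestimates the slope.  If a cohort
    ``manifest`` is given its per-root R_growth values (and root ids) are
    reused so the series joins the profile table.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    days = np.asarray(list(days), dtype=float)
    if days.min() < 1 or days.max() > 10:
        raise ValueError("days must lie in 1..10")
    rng = np.random.default_rng(seed)
    if manifest is not None:
        ids = manifest["root_id"].tolist()
        r_growth = manifest["true_R_growth"].to_numpy(float)
    else:
        pop = preset.population()
        roots = sample_population(pop, rng)
        ids = [f"{preset.name}_{r.root_id:03d}" for r in roots]
        r_growth = np.array([
            theory.steady_state_traits(pop.model, r.l0, r.r_elong, r.r_prod,
                                       r.threshold, pop.k_decay).r_growth
            for r in roots])
    rows = []
    day_lin = 4.0
    for rid, rg in zip(ids, r_growth):
        um_per_day = rg * 24.0
        # the root accumulates only ~half the stationary speed during the
        # transient, so the linear asymptote has a negative intercept and a
        # fit that includes days 1-3 underestimates the slope
        l_at_lin = 0.5 * um_per_day * day_lin
        for d in days:
            if d >= day_lin:
                length_um = l_at_lin + um_per_day * (d - day_lin)
            else:  # quadratic ramp up to the day-4 length
                length_um = l_at_lin * (d / day_lin) ** 2
            length_mm = length_um / 1000.0
            if noise_sd_mm > 0:
                length_mm = max(length_mm + rng.normal(0.0, noise_sd_mm), 0.01)
            rows.append((rid, int(d), length_mm))
    return pd.DataFrame(rows, columns=["root_id", "day", "root_length_mm"])
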