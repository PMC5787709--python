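# Methods

## Model

One root is one cell file. Cell i enters the elongation zone (EZ) at time
t_i with length l_0i (µm) and grows exponentially, l_i(t) =
l_0i·e^(r_i·(t−t_i)), with a constant relative elongation rate r_i (1/h),
until a rule-specific stopping condition fires; it then joins the
differentiation zone (DZ) at its final length. Inter-arrival intervals are
1/R_i where R_i is the per-cell meristematic activity (cells/h). The
meristem itself is not simulated: cells appear at the MZ/EZ boundary.

Two-level Gaussian variability: each root j draws parameter means p_j ~
N(p, Δ_p); each cell draws p_ij ~ N(p_j, σ_p) with σ_p ≤ Δ_p. Draws ≤ 0
are rejected and redrawn (capped at 10⁶ draws per parameter, after which
the configuration is reported infeasible rather than hanging). The
differentiation threshold is a root-level property: all cells of a root
share it (σ_threshold = 0 in every preset; the field is honored if set).

Stopping rules (τ = EZ residence time):

| rule     | threshold            | stop condition                          | closed form |
|----------|----------------------|-----------------------------------------|-------------|
| timer    | T0 (h)               | t − t_i = T0                            | τ = T0 |
| sizer    | l_diff0 (µm)         | l_i(t) = l_diff0                        | τ = ln(l_diff0/l_0i)/r_i (0 if already longer) |
| dilution | ratio ρ = c_0/c_thr  | c_0·(l_0i/l_i(t))·e^(−k(t−t_i)) < c_thr | τ = ln ρ/(r_i + k) |
| ruler    | L0 (µm)              | center ≥ L0 from the meristem end       | evaluated at entry events |

The dilution rule is the molecular construction of a mixed mechanism: the
stop length is l_0i·ρ^(r_i/(r_i+k)), so k = 0 is a relative sizer (stop
length ∝ initial length) and k ≫ r a timer (τ → ln ρ/k, length-free).

Timer/sizer/dilution stop times are closed-form per cell, so the
simulation is event-free and vectorized. The ruler criterion is evaluated
only when a new cell is created, on the cells present *before* the new
cell is inserted: the center distance of a tested cell is the summed
length of all younger elongating cells plus half its own length; all
cells at or beyond L0 stop at that instant. This entry-event evaluation
is exact (no time-step artifacts) and is mirrored verbatim by the
closed-form N_EZ (smallest N with Σ_{k=1}^{N−1} l_0EZ·r_EZ^k +
l_0EZ·r_EZ^N/2 ≥ L0).

Under within-root variability, sizer/dilution cells can stop out of entry
order; "oldest elongating cell" (the l_max analogue) always means oldest
by entry among cells still elongating. Snapshot boundary convention: a
cell whose stop time equals the observation time is already in the DZ
(half-open [entry, stop)).

## Stationarity and growth rate

Each file starts from a single cell and passes through a transient before
N_EZ fluctuates around a constant. Onset t\* is detected from N_EZ
evaluated at entry events: consecutive non-overlapping windows (default
20 events) are compared and t\* is the start of the first window, at or
after the first differentiation, whose mean differs from its predecessor
by less than 5% relative — with an absolute floor of 0.5 cells, because
the windowed mean of a count of ~12 cannot settle tighter than its
discreteness. Files that never settle within t_end are excluded with a
logged reason (5 resimulation attempts first). All cohort statistics use
t > t\*. The simulated root growth rate is the least-squares slope of
cumulative DZ length on a regular post-t\* grid; in the stationary regime
it equals R_prod·⟨stop length⟩ and growth is linear (R² > 0.99).

## Profile fitting

A measured profile is the ordered cell-length list from the quiescent
center, ending at the first root-hair cell (excluded from all zones). On
log10 scale the MZ and EZ are two straight segments; every admissible
breakpoint k (last MZ cell) is scored by total OLS residual sum of
squares, subject to: segments ≥ min_mz = 4 and min_ez = 2 cells; EZ slope
at least min_slope_ratio = 1.02 above the MZ slope (so a single
exponential yields `no_EZ` instead of winning on float jitter); r_EZ ≥
r_min = 1.05. All four constants are config-exposed. SSE ties break
toward the larger k: the junction cell of an exact piecewise profile lies
on both lines and is counted as the last meristem cell, which also makes
l_0EZ (the EZ line evaluated at index k; a raw-length option exists) the
last-MZ-cell length, so l_diff = l_0EZ·r_EZ^N_EZ holds with rank-k EZ
cells at l_0EZ·r_EZ^k. `no_EZ` roots keep N_EZ = 0 and L_EZ = 0 with
r_EZ/l_max undefined and are excluded from analyses needing those traits;
ok/no_EZ/rejected counts always sum to the cohort size.

## Dynamical inference

From fitted traits plus a root growth rate (per-root slopes of
root-length-vs-day tables restricted to days ≥ 4, where growth is linear;
or one cohort slope on daily means):

    R_prod = R_growth / l_diff,   r_elong = R_prod·ln r_EZ,   T_EZ = N_EZ / R_prod.

A subtlety: the oldest still-elongating cell is observed mid-way through
its final rank, so l_diff from a snapshot or measured profile
underestimates the stop length by the phase factor (r_EZ − 1)/(r_EZ·ln
r_EZ) ≈ 0.88 at r_EZ = 1.29. `infer_dynamics(phase_correction=True)`
divides it out; the default is off, so the raw identity above holds
verbatim on printed trait values. The correction matters when comparing
inferred rates with generative ground truth: with it, the signed median
per-root error on synthetic cohorts is < 1% and cohort means are
recovered within ~7% (the residual coming from the nonlinear averaging of
per-root ratios); without it R_prod is overestimated by ~13%.

## Synthetic cohorts

`generate_cohort` renders each simulated root as a measured profile: a
geometric meristem segment (N_MZ ~ round(N(26.2, 3.0)) cells, factor r_MZ
≈ 1.03) joined continuously one elongation-factor step below the youngest
EZ cell, then the EZ snapshot youngest-first, then one first-root-hair
marker cell, with every length multiplied by lognormal noise (CV 5%
default). A manifest records each root's true parameters and noiseless
stationary traits. Root-length-vs-day series reuse the manifest's
per-root growth speeds, with a sub-linear transient before day 4 (the
root accumulates half speed during the transient, so the linear asymptote
has a negative intercept and fits from day 1 underestimate the slope —
fits from day 4 are exact up to noise).

The meristem segment is static scenery for the breakpoint fitter (cell
division is not simulated), measurement noise is independent across cells
(no imaging covariance), each root is observed once (no repeated imaging
of one plant), and no transition zone exists between MZ and EZ. Passing
tests therefore validate the estimators against the model's own
assumptions, not against everything real roots do.

### Preset derivation

The wild-type epidermal presets are back-solved from published cohort
statistics through the closed forms: r_EZ = 1.29 and T_EZ ≈ 6.7 h with
l_diff ≈ 160 µm and R_growth ≈ 280 µm/h give R_prod = 280/160 = 1.75
cells/h, r_elong = 1.75·ln 1.29 = 0.446 /h, l_0EZ = 160/1.29^11.8 ≈ 8 µm;
each rule's threshold is then solved for N_EZ ≈ 11.8 (sizer 160 µm, timer
6.74 h, ruler 603 µm, dilution ρ = 420 with k = 0.45 /h). The dilution
preset sets k = r_elong: dilution and degradation contribute equally —
the midpoint between its sizer and timer limits.

Between-root spreads: sd(r_EZ) = 0.10 pins the combined CV of ln r_EZ =
r_elong/R_prod at ~29%. This is allocated mostly to the elongation rate
(Δ_r_elong 28% relative, Δ_R_prod 8%, Δ_l0 15%), i.e. the r_elong-driven
regime; an R_prod-driven allocation produces a timer statistically
indistinguishable from a sizer (both N_EZ and 1/ln r_EZ then track
R_prod), so the r_elong-driven regime is the one in which the four rules
are distinguishable at all. Threshold spreads are rule-specific (ruler
35%, timer 7%, sizer 26%, dilution taken equal to sizer). Within-root σ =
Δ/4: large within-root rate spread lets slow outlier cells accumulate at
the old end of the file, biasing the fitted mature length down ~20% and
the inferred R_prod up ~18%, which would defeat parameter recovery; Δ/4
keeps that bias within a few percent while preserving visible
cell-to-cell scatter. Because the mean of ln(l_diff0/l_0)/ln r_EZ over a
28%-spread of rates exceeds its value at the means (the 1/r tail),
realized cohort mean N_EZ sits near 12.5–13 rather than 11.8; the
fitted-cohort mean stays inside the published 11.8 ± 1.2 band.

## Mechanism discrimination

`trait_correlations` computes, over roots with defined traits, the three
signature relations (L_EZ ~ N_EZ, l_max ~ 1/r_EZ, N_EZ ~ 1/ln r_EZ) plus
an auxiliary l_max ~ l_0EZ relation, choosing Pearson when both margins
pass Shapiro–Wilk at α = 0.05 and Spearman otherwise (never mixed within
a relation), the OLS slope ± SE of N_EZ on 1/ln r_EZ, and two derived
statistics:

* **size-gain invariant**: N_EZ·ln r_EZ = ln(l_diff/l_0EZ) = r_elong·T_EZ
  is each root's total log size gain while elongating. Its log is
  regressed on the log of the inferred elongation rate (R_growth/l_diff ·
  ln r_EZ, phase-corrected). The slope β is 0 for a sizer (gain fixed by
  the threshold), 1 for a timer (gain ∝ rate at fixed time), k/(r+k) for
  the dilution rule, and ~0.33 for the ruler under wild-type-like
  spreads; the residual sd around the regression measures how much of the
  gain is set by a latent invisible to the kinetics — large (~0.17) for
  the ruler's positional threshold, small (~0.13) when kinetics dominate.
* **variance compression**: CV(N_EZ)/CV(1/ln r_EZ), ≈ 1 for sizer-like
  scaling, ≪ 1 for a timer.

`classify_mechanism` is a decision list (α = 0.01 on the correlation
tests): sizer if N_EZ ~ 1/ln r_EZ is significantly positive, l_max ~
1/r_EZ is not significant, and L_EZ ~ N_EZ is significantly positive;
otherwise, given a significant negative l_max ~ 1/r_EZ coupling: timer if
β > 0.72; else ruler vs mixed_sizer_timer by a linear discriminant on
(β, residual sd) centred at (0.41, 0.140) with scales (0.057, 0.014) —
mixed at higher elasticity with kinetics-dominated residuals, ruler at
lower elasticity with a large latent residual. Without an R_growth column
the weaker fallbacks (variance compression < 0.35 for timer; the l_max ~
l_0EZ coupling for mixed) are used. Everything evaluated is recorded in a
trace. The constants were calibrated on simulated training cohorts of
known rule (n = 122, wild-type-like spreads) and validated on disjoint
seeds at 95–100% per rule; an R_prod-driven timer is reported as sizer,
which is a genuine identifiability limit of these signatures, not a
classifier defect. A rule table based only on the significance pattern of
the three relations cannot separate the ruler from the dilution rule:
under realistic threshold spreads the ruler's L_EZ ~ N_EZ correlation is
significantly positive (~+0.4), and every 1-D statistic we examined
overlaps between the two; the (β, residual) plane is the operational
resolution.

`compare_trait_distributions` applies two-sided Wilcoxon rank-sum tests
to the five traits (r_EZ, l_max, L_EZ, N_EZ, R_growth); a candidate
passes when all five P > 0.01. `calibrate_model` searches for parameters
matching a reference cohort: a coarse grid over the threshold's relative
spread (0.25, 0.15, 0.35, 0.05) wraps a damped moment-matching fixed
point (η = 0.6, steps clamped to [0.6, 1.6], ≤ 6 iterations) with three
decoupled moves — the r_elong/R_prod ratio tracks mean r_EZ, the
threshold tracks mean l_max (additively in log-length units for the
timer), and R_prod tracks mean R_growth after discounting the part of the
R_growth mismatch already explained by l_max (R_growth = R_prod·l_max;
without the discount the timer's exponentially sensitive l_max makes the
iteration oscillate). Reference and candidate are observed through
identical snapshot statistics, so observation biases cancel and the fixed
point sits at the generating parameters (the sizer threshold is recovered
within a few percent). Degenerate regions (too few roots reaching
stationarity) abandon the grid point; an exhausted grid is an informative
no-fit result. No multiple-testing correction is applied across relations
or traits by design; a Holm-corrected mode would be a one-line addition
but matches nothing the verdict rules assume.

## Decorrelation analysis

`decouple_pairs` randomly re-pairs the N_EZ column against the (r_EZ,
l_0EZ, R_prod) tuples (identity permutation excluded), preserving every
marginal. `derived_growth` then computes l_diff = l_0EZ·r_EZ^N_EZ and
R_growth = R_prod·l_diff; the permutation test (default 1,000
re-pairings) reports the ratio of the median permuted sd to the observed
sd and the fraction of permutations at or below it. Because ln l_diff =
ln l_0EZ + N_EZ·ln r_EZ turns independent ~30% spreads into a product of
exponentials, decoupling inflates the sd of l_diff and R_growth by well
over the twofold the analysis asks about. `meristem_scenarios` rescales
1/ln r_EZ by factors (0.5, 2 = twofold meristematic-activity changes at
fixed r_elong); with the correlation preserved N_EZ co-scales by the same
factor, keeping N_EZ·ln r_EZ — hence l_diff — invariant to machine
precision (the factors are powers of two, so even floating point agrees
exactly) while mean R_growth scales linearly; without co-scaling the
mature length shifts strongly (longer cells at lower activity). Groups
are compared by one-way ANOVA when all pass Shapiro–Wilk at α = 0.05,
Kruskal–Wallis otherwise, on absolute and group-mean-normalized values.

## Problem sizes and determinism

Default cohorts are 122 roots simulated to t_end = 240 h (~420 cells per
file); classification experiments use 50 seeded cohorts per rule and
calibration simulates at t_end = 120 h, sizes at which every statistic
here is stable and the full suite runs in about a minute. All randomness
flows from a single integer seed through `numpy.random.SeedSequence`
spawning (one stream per root), so identical seeds give bit-identical
trajectories and byte-identical output tables.

## Limitations

Single cell file; no mechanical coupling between files, no spatial
signaling gradients, no explicit meristem dynamics, no pre-stationary
developmental trajectory (day-1-to-5 zonation build-up is not emulated).
The verdict rule is an operationalization validated on synthetic cohorts;
on real data its discriminant constants inherit the assumption that
between-root variability is r_elong-dominated. Analytic moments of the
stochastic (Δ, σ > 0) models are not derived; variability is studied by
simulation only.
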