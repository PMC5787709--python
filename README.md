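# rootzone

Tools for asking how plant roots decide when a cell should stop growing.

In the *Arabidopsis thaliana* root, cells are born in the meristem (MZ),
elongate exponentially in the elongation zone (EZ), and mature into the
differentiation zone (DZ) at the first root-hair cell. What terminates
elongation? Three canonical rules are distinguishable:

* **Ruler** — a cell stops when its center reaches a threshold *distance*
  L0 from the meristem end (positional sensing);
* **Timer** — a cell stops after a threshold *time* T0 in the EZ;
* **Sizer** — a cell stops at a threshold *length* l_diff0;
* **dilution** — a fourth, molecularly explicit rule: a signaling factor
  loaded at EZ entry is diluted by expansion and degraded at rate k;
  elongation stops below a threshold concentration. k = 0 realizes a
  (relative) sizer, k ≫ r_elong a timer, intermediate k a mixed
  sizer–timer mechanism.

`rootzone` implements stochastic single-cell-file simulations of all four
rules, their closed-form stationary traits, the automated two-segment
exponential fitting that extracts per-root traits (r_MZ, r_EZ, l_0MZ,
l_0EZ, N_MZ, N_EZ, L_EZ, l_max) from measured cell-length profiles, the
algebraic inference of dynamical rates, and the statistical machinery that
discriminates the rules from trait-pair correlation signatures.

## The model

Cells enter the EZ at rate R_prod (one every 1/R_prod hours) with length
l_0 and grow as l(t) = l_0·e^(r_elong·t). Parameters carry two-level
Gaussian variability: between roots (sd Δ) and between cells of one root
(sd σ ≤ Δ), with non-positive draws rejected. In the stationary regime the
length profile along the file is exponential with elongation factor

    r_EZ = exp(r_elong / R_prod),

and each rule fixes the EZ residence time τ, giving

    N_EZ = R_prod·τ,   l_diff = l_0EZ·r_EZ^N_EZ,   R_growth = R_prod·l_diff.

The key discriminating signatures across a cohort: a sizer leaves the
mature cell length uncorrelated with 1/r_EZ while N_EZ is proportional to
1/ln(r_EZ) = R_prod/r_elong; a timer couples the mature length to the
kinetics and freezes N_EZ; a ruler and the dilution rule sit in between
and are separated by how the per-root size gain N_EZ·ln(r_EZ) responds to
the elongation rate (see `docs/methods.md`).

## Worked example

Generate a wild-type-like epidermal cohort (122 roots, 5% measurement
noise), fit every profile, infer the dynamical rates from per-root growth
curves, and ask which rule the cohort supports:

```python
import rootzone as rz

preset = rz.PRESETS["wt_epidermis_sizer"]
profiles, manifest = rz.generate_cohort(preset, seed=1)
traits, counts = rz.fit_cohort(rz.io.profiles_from_frame(profiles))

lengths = rz.generate_root_length_series(preset, seed=2, manifest=manifest)
growth = rz.root_growth_rate(lengths, day_min=4)          # um/h per root
traits = traits.merge(growth.rename("R_growth"),
                      left_on="root_id", right_index=True, how="left")
full = rz.infer_dynamics(traits, phase_correction=True)

print(f"fit status counts: {counts}")
print(f"r_EZ  = {full['r_EZ'].mean():.2f} +/- {full['r_EZ'].std():.2f}")
print(f"N_EZ  = {full['N_EZ'].mean():.1f} cells,  N_MZ = {full['N_MZ'].mean():.1f} cells")
print(f"R_prod = {full['R_prod'].mean():.2f} cells/h,  r_elong = {full['r_elong'].mean():.3f} /h")
print(f"T_EZ  = {full['T_EZ'].mean():.1f} h")

report = rz.classify_mechanism(rz.trait_correlations(full))
print(f"verdict: {report.verdict}")
```

prints

    fit status counts: {'ok': 122, 'no_EZ': 0, 'rejected': 0}
    r_EZ  = 1.27 +/- 0.09
    N_EZ  = 13.6 cells,  N_MZ = 25.8 cells
    R_prod = 1.83 cells/h,  r_elong = 0.431 /h
    T_EZ  = 7.6 h
    verdict: sizer

Every profile fit cleanly; the fitted elongation factor (1.27 ± 0.09) and
meristem size (~26 cells) sit at the values the preset was designed around;
the inferred meristematic activity (~1.8 cells/h) and elongation rate
(~0.43 /h) recover the generating parameters (1.75 cells/h, 0.446 /h)
within a few percent; cells spend ~7.6 h elongating; and the correlation
signatures correctly identify the generating sizer rule.

The same pipeline runs from a shell:

    rootzone synth --preset wt_epidermis_sizer --seed 1 -o profiles.csv \
        --manifest manifest.csv --lengths lengths.csv
    rootzone fit -i profiles.csv -o traits.csv
    rootzone infer -t traits.csv -l lengths.csv -o traits_full.csv
    rootzone discriminate -t traits_full.csv -o report.json
    rootzone decorrelate -t traits_full.csv --seed 1 -o scenarios.csv

`rootzone fit` accepts any long-format CSV/TSV with columns `root_id,
cell_index, cell_length_um` (optionally `genotype, day, tissue,
is_first_hair`), so measured datasets run through the identical code path
as synthetic ones.

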