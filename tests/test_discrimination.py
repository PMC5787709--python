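"""Correlation signatures, Wilcoxon comparison, calibration, verdicts."""

import numpy as np
import pandas as pd
import pytest

import rootzone as rz
from rootzone.discrimination import _size_gain_invariant


def _toy_traits(n=30, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(2.0, 6.0, n)          # 1/ln(r_EZ)
    r_ez = np.exp(1.0 / x)
    n_ez = 3.0 * x + rng.normal(0, 0.3, n)
    l0 = rng.normal(8.0, 0.5, n)
    l_max = l0 * r_ez ** n_ez
    return pd.DataFrame({
        "root_id": np.arange(n), "r_EZ": r_ez, "inv_r_EZ": 1 / r_ez,
        "inv_ln_r_EZ": x, "N_EZ": n_ez, "l0_EZ": l0, "l_max": l_max,
        "L_EZ": l_max * 3.0, "R_growth": 1.75 * l_max,
    })


class TestTraitCorrelations:
    def test_perfect_collinearity(self):
        df = _toy_traits(30)
        df["L_EZ"] = 2.0 * df["N_EZ"]     # exact line
        rep = rz.trait_correlations(df)
        assert rep.relations["LEZ_vs_NEZ"]["r"] == pytest.approx(1.0)

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            rz.trait_correlations(_toy_traits(8))

    def test_zero_variance_marked_undefined(self):
        df = _toy_traits(30)
        df["l_max"] = 100.0
        rep = rz.trait_correlations(df)
        assert rep.relations["lmax_vs_inv_rEZ"].get("undefined")

    def test_switch_is_function_of_normality(self):
        rng = np.random.default_rng(3)
        df = _toy_traits(80)
        # heavy-tailed margin forces Spearman
        df["l_max"] = np.exp(rng.normal(0, 1.5, len(df))) * 100
        rep = rz.trait_correlations(df)
        assert rep.relations["lmax_vs_inv_rEZ"]["method"] == "spearman"

    def test_shuffling_a_margin_destroys_significance(self, wt_sizer_cohort):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(60):
            df = wt_sizer_cohort.copy()
            df["N_EZ"] = rng.permutation(df["N_EZ"].to_numpy())
            rep = rz.trait_correlations(df)
            ps.append(rep.relations["NEZ_vs_inv_ln_rEZ"]["p"])
        assert np.median(ps) > 0.05

    def test_size_gain_invariant_slope_for_known_sizer(self):
        inv = _size_gain_invariant(_toy_traits(100, seed=5))
        # sizer-construction: gain independent of the rate
        assert abs(inv["slope"]) < 0.2


class TestCompareDistributions:
    def test_cohort_vs_itself_p_one(self, wt_sizer_cohort):
        ps, ok = rz.compare_trait_distributions(wt_sizer_cohort,
                                                wt_sizer_cohort)
        assert ok and all(p == pytest.approx(1.0) for p in ps.values())

    def test_null_calibration_same_parameters(self):
        pop = rz.PRESETS["wt_epidermis_sizer"].population()
        hits = 0
        for s in range(20):
            a = rz.simulate_cohort_traits(pop, seed=3000 + 2 * s)
            b = rz.simulate_cohort_traits(pop, seed=3001 + 2 * s)
            _, ok = rz.compare_trait_distributions(a, b, alpha=0.01)
            hits += ok
        assert hits >= 18  # matched cohorts pass in >= ~95% of repeats

    def test_halved_threshold_fails_on_l_max(self, wt_sizer_cohort):
        pop = rz.PRESETS["wt_epidermis_sizer"].population()
        pop2 = pop.with_(threshold=80.0,
                         delta=dict(pop.delta, threshold=0.26 * 80.0))
        other = rz.simulate_cohort_traits(pop2, seed=12)
        ps, ok = rz.compare_trait_distributions(other, wt_sizer_cohort)
        assert not ok and ps["l_max"] < 0.01

    def test_minimum_size(self, wt_sizer_cohort):
        with pytest.raises(ValueError):
            rz.compare_trait_distributions(wt_sizer_cohort.head(3),
                                           wt_sizer_cohort)


class TestClassifyMechanism:
    @pytest.mark.parametrize("model,expected", [
        ("sizer", "sizer"), ("timer", "timer"), ("ruler", "ruler"),
        ("dilution", "mixed_sizer_timer")])
    def test_self_classification(self, model, expected):
        pop = rz.PRESETS[f"wt_epidermis_{model}"].population()
        hits = 0
        n_rep = 8
        for s in range(n_rep):
            tr = rz.simulate_cohort_traits(pop, seed=5000 + s)
            rep = rz.classify_mechanism(rz.trait_correlations(tr))
            hits += rep.verdict == expected
        assert hits >= n_rep - 1

    def test_trace_records_every_rule(self, wt_sizer_cohort):
        rep = rz.classify_mechanism(rz.trait_correlations(wt_sizer_cohort))
        assert rep.verdict == "sizer"
        assert any("L_EZ~N_EZ" in t for t in rep.trace)
        assert any("->" in t for t in rep.trace)
        assert "verdict" in rep.summary()


@pytest.fixture(scope="module")
def reference():
    pop = rz.PRESETS["wt_epidermis_sizer"].population()
    return rz.simulate_cohort_traits(pop, seed=77)


class TestCalibration:
    def test_sizer_recovers_own_threshold(self, reference):
        res = rz.calibrate_model(reference, "sizer", seed=5)
        assert res.passed
        assert abs(res.params.threshold - 160.0) / 160.0 < 0.10
        assert all(p > 0.01 for p in res.wilcoxon.values())

    @pytest.mark.parametrize("model", ["timer", "ruler"])
    def test_other_rules_also_match_marginals(self, reference, model):
        # marginal trait distributions cannot discriminate the rules
        res = rz.calibrate_model(reference, model, seed=5)
        assert res.passed

    def test_degenerate_reference_refused(self, reference):
        with pytest.raises(ValueError):
            rz.calibrate_model(reference.head(3), "sizer")
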