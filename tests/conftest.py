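import logging

import numpy as np
import pytest

import rootzone as rz

logging.getLogger("rootzone").setLevel(logging.ERROR)
logging.getLogger("rootzone.synthetic").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def doubling_sizer():
    """Noiseless sizer: l0=10, l_diff0=160, r=ln2, one entry/h -> powers of 2."""
    root = rz.RootParams(0, r_prod=1.0, l0=10.0, r_elong=np.log(2.0),
                         threshold=160.0)
    return rz.simulate_root_file(root, "sizer", 240.0, seed=0)


@pytest.fixture(scope="session")
def wt_sizer_cohort():
    """Snapshot-trait cohort from the wild-type-like sizer preset."""
    pop = rz.PRESETS["wt_epidermis_sizer"].population()
    return rz.simulate_cohort_traits(pop, seed=20240)


@pytest.fixture(scope="session")
def wt_sizer_inferred(wt_sizer_cohort):
    """Same cohort with R_prod / r_elong / T_EZ completed."""
    return rz.infer_dynamics(wt_sizer_cohort, phase_correction=True)


@pytest.fixture(scope="session")
def wt_fitted_cohort():
    """Full generate -> fit -> infer pipeline on the wild-type sizer preset."""
    preset = rz.PRESETS["wt_epidermis_sizer"]
    profiles, manifest = rz.generate_cohort(preset, seed=42)
    traits, counts = rz.fit_cohort(rz.io.profiles_from_frame(profiles))
    lengths = rz.generate_root_length_series(preset, seed=43,
                                             manifest=manifest)
    rg = rz.root_growth_rate(lengths, day_min=4)
    traits = traits.merge(rg.rename("R_growth"), left_on="root_id",
                          right_index=True, how="left")
    full = rz.infer_dynamics(traits, phase_correction=True)
    return full.merge(manifest, on="root_id"), counts
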