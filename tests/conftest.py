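import warnings

import pytest

from commflux import synthetic_data as sd
from commflux.community_builder import apply_diet, build_community_model
from commflux.flux_profiler import (
    compute_exchange_flux_ranges,
    compute_metabolite_profile,
    compute_strain_contributions,
)


@pytest.fixture(scope="session")
def pan():
    return sd.generate_pan_reactome(seed=0)


@pytest.fixture(scope="session")
def strain_set(pan):
    return sd.generate_strain_set(pan, n_strains=40, seed=1)


@pytest.fixture(scope="session")
def strain_map(strain_set):
    return {s.strain_id: s for s in strain_set}


@pytest.fixture(scope="session")
def diet(pan):
    return sd.default_diet(pan)


@pytest.fixture(scope="session")
def small_design():
    """A reduced cohort for unit tests (not the full study conditions)."""
    return sd.CohortDesign(
        n_per_group={"healthy": 6, "IBD_nondysbiotic": 6, "IBD_dysbiotic": 6},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(strain_set, small_design):
    return sd.generate_cohort(strain_set, small_design)


@pytest.fixture(scope="session")
def profiled_small_cohort(strain_map, small_cohort, diet):
    """Models, flux ranges, profiles and contributions for the small cohort."""
    out = {}
    for sid in small_cohort.sample_ids:
        model = build_community_model(
            strain_map, small_cohort.sample(sid), sample_id=sid
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = apply_diet(model, diet)
        ranges = compute_exchange_flux_ranges(model)
        profile = compute_metabolite_profile(model, ranges)
        contrib = compute_strain_contributions(model, ranges)
        out[sid] = (model, ranges, profile, contrib)
    return out
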