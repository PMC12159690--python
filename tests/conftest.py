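import warnings

import numpy as np
import pytest

from netpert import (
    CohortSpec,
    NetworkPerturbationModel,
    PerturbationSpec,
    make_patient_group,
    make_reference_cohort,
)

# covariate extrapolation warnings are expected when synthetic patients sit
# at the edge of the reference age range
warnings.filterwarnings("ignore", message="subject age .* outside reference range")

AFFECTED = tuple(range(8))  # the striatal-like block of the default generator


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects x 8 regions with covariates; cheap enough for everything."""
    spec = CohortSpec(n_subjects=30, n_regions=8, seed=7)
    table, cov = make_reference_cohort(spec)
    return spec, table, cov


@pytest.fixture(scope="session")
def small_results(small_cohort):
    _, table, cov = small_cohort
    return NetworkPerturbationModel(table, cov).fit()


@pytest.fixture(scope="session")
def study():
    """Full-size synthetic study shared across the expensive tests:
    71 controls x 83 regions, two opposite-direction patient groups of 30."""
    spec = CohortSpec(n_subjects=71, n_regions=83, seed=20240)
    ref_table, ref_cov = make_reference_cohort(spec)
    results = NetworkPerturbationModel(ref_table, ref_cov).fit()
    pert_up = PerturbationSpec(AFFECTED, "strengthen")
    pert_down = PerturbationSpec(AFFECTED, "weaken")
    tab_up, cov_up = make_patient_group(spec, pert_up, 30, seed=20241, id_prefix="UP")
    tab_dn, cov_dn = make_patient_group(spec, pert_down, 30, seed=20242, id_prefix="DN")
    devs_up = results.perturb_cohort(tab_up, cov_up)
    devs_dn = results.perturb_cohort(tab_dn, cov_dn)
    return {
        "spec": spec,
        "results": results,
        "pert_up": pert_up,
        "pert_down": pert_down,
        "devs_up": devs_up,
        "devs_dn": devs_dn,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
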