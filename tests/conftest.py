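import pytest

from vdtsurv.cohort import (
    ATTRIBUTES,
    CLASS_LABELS,
    PopulationSpec,
    default_paper_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def paper_spec():
    return default_paper_spec()


@pytest.fixture(scope="session")
def calibration_cohort(paper_spec):
    """20,000 records from the calibrated spec; shared by recovery checks."""
    return generate_cohort(paper_spec, n=20_000, seed=20240)


@pytest.fixture(scope="session")
def small_cohort(paper_spec):
    return generate_cohort(paper_spec, n=2_000, seed=7)


def single_class_spec(**conditional_overrides) -> PopulationSpec:
    """Degenerate spec: everyone healthy, attribute parameters overridable."""
    prior = {c: 0.0 for c in CLASS_LABELS}
    prior["none"] = 1.0
    conds = {(c, a): 0.5 for c in CLASS_LABELS for a in ATTRIBUTES}
    for attr, p in conditional_overrides.items():
        for c in CLASS_LABELS:
            conds[(c, attr)] = p
    return PopulationSpec(n_records=10, class_prior=prior, conditionals=conds)
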