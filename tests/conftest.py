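import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    """The bundled 13-instrument study table as paired records."""
    from mrsurv import load_fixture_table1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # palindromic-allele advisory
        exposures, outcomes = load_fixture_table1()
    return exposures, outcomes


@pytest.fixture(scope="session")
def table1_model(table1):
    from mrsurv import MRModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MRModel(*table1)


def fit_cell(table1, phenotype, subgroup=None):
    """MR fit of one phenotype (optionally one subgroup cell)."""
    import warnings

    from mrsurv import MRModel

    exposures, outcomes = table1
    pairs = [
        (e, o)
        for e, o in zip(exposures, outcomes)
        if e.phenotype == phenotype and (subgroup is None or e.subgroup == subgroup)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MRModel([e for e, _ in pairs], [o for _, o in pairs]).fit()
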