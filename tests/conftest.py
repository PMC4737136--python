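import pytest

from starpap import AnalysisParams, CohortConfig, generate_cohort, run_analysis

EMBEDDED_7MER = "ACAUAUA"
EMBEDDED_5MERS = frozenset({"ACAUA", "AUAUA", "CAUAU"})


@pytest.fixture(scope="session")
def cohort7():
    """Default-condition cohort, fixed seed."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def result7(cohort7):
    """Full analysis of the default cohort."""
    return run_analysis(
        cohort7.sequences, cohort7.sites, cohort7.fold_changes, AnalysisParams()
    )
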