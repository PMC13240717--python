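import pathlib

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from amylatlas import pipeline, simulate  # noqa: E402


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> pathlib.Path:
    """A small packaged synthetic cohort exercising every stage."""
    d = tmp_path_factory.mktemp("cohort")
    pipeline.make_fixtures(seed=42, outdir=d, n_genomes=60)
    return d


@pytest.fixture(scope="session")
def small_cohort() -> simulate.SyntheticCohort:
    return simulate.generate_cohort(
        simulate.CohortParams(n_genomes=40, p_bgc=0.25, seed=11)
    )
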