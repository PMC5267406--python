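from pathlib import Path

import pytest

from msofa.pipeline import apply_eligibility, read_observations, score_cohort, scores_to_frame
from msofa.simulate import SimulationConfig, generate_cohort

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture_cohort"
#: configuration of the committed fixture cohort (regenerated byte-identically
#: by test_simulate.py)
FIXTURE_CONFIG = SimulationConfig(n_patients=24, seed=24001)


@pytest.fixture(scope="session")
def fixture_cohort():
    return generate_cohort(FIXTURE_CONFIG)


@pytest.fixture(scope="session")
def fixture_paths(fixture_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_cohort")
    return fixture_cohort.write(outdir)


@pytest.fixture(scope="session")
def default_cohort_frame(tmp_path_factory):
    """A defaults-sized (n=118) simulated cohort scored end to end."""
    cohort = generate_cohort(SimulationConfig(seed=11))
    outdir = tmp_path_factory.mktemp("default_cohort")
    paths = cohort.write(outdir)
    records = read_observations(paths["observations"], paths["patients"])
    included, _ = apply_eligibility(records)
    summaries, _ = score_cohort(included)
    return scores_to_frame(summaries, included)
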