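import pytest

from tmn.filters import CascadeConfig, run_cascade
from tmn.simulate import SimulationConfig, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size labelled synthetic cohort, fixed seed."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_cascade(default_cohort):
    cohort = default_cohort
    variants = cohort.consensus_annotated()
    return run_cascade(
        variants, cohort.normals_by_patient(), cohort.pon, CascadeConfig()
    )


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small cohort written to disk for pipeline/CLI round trips."""
    cfg = SimulationConfig(
        seed=7, n_patients=14, n_pediatric=2, n_matched_normals=5, n_longitudinal=1
    )
    cohort = simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(cohort, out)
    return out, cohort
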