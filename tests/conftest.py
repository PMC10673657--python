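import hypothesis
import pytest

from phasikit.pipeline import PipelineConfig, PipelineInputs, run_all
from phasikit.sim import SimConfig, simulate_dataset

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("deterministic")


RECOVERY_CONFIG = SimConfig(
    seed=1,
    n_phas_21=5,
    n_phas_24=0,
    n_tas3_like=0,
    cycles_per_locus=10,
    phased_read_abundance=20,
    background_read_density=50,
)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Five implanted 21-nt loci over 50 background reads/kb."""
    return simulate_dataset(RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def recovery_result(recovery_bundle):
    return run_all(
        PipelineInputs.from_bundle(recovery_bundle),
        PipelineConfig(seed=1, n_permutations=0, cycles=(21,)),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Full default study: 21- and 24-nt implants plus one TAS3-like locus."""
    return simulate_dataset(SimConfig(seed=5))
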