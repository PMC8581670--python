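import pytest

from scnkit.residualization import residualize
from scnkit.synthetic_cohort import SyntheticConfig, TopologySpec, generate_cohort


def small_config(seed: int = 42) -> SyntheticConfig:
    """A fast three-group cohort: 20 regions, 8/10/12 subjects."""
    return SyntheticConfig(
        group_sizes={"SHANK3": 8, "ASD": 10, "TD": 12},
        n_regions=20,
        topology={
            "SHANK3": TopologySpec("lattice", k=4),
            "ASD": TopologySpec("small_world", k=4, beta=0.2),
            "TD": TopologySpec("small_world", k=4, beta=0.3),
        },
        edge_coupling=0.1,
        noise_sd=0.3,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    cohort, _, _ = small_cohort
    return residualize(cohort)
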