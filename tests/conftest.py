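import dataclasses

import pytest

from dinchpbpk import params, synth


@pytest.fixture(scope="session")
def default_resolved():
    return params.resolve_parameters()


@pytest.fixture(scope="session")
def scheduled_bundle():
    """Default parameters with the standard 16-void collection schedule."""
    return dataclasses.replace(
        params.default_bundle(),
        urine=params.UrineParams(
            r_urine=0.104, creat=1.278, void_times=synth.DEFAULT_VOID_SCHEDULE
        ),
    )


@pytest.fixture(scope="session")
def volunteer_a_noiseless():
    scenario = synth.volunteer_preset("A", noise_sigma=0.0)
    dataset, truth = synth.generate_voids(scenario, seed=0)
    return dataset, truth


@pytest.fixture(scope="session")
def volunteer_a_noisy():
    scenario = synth.volunteer_preset("A", noise_sigma=0.28)
    dataset, truth = synth.generate_voids(scenario, seed=7)
    return dataset, truth
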