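import pytest

import twdiss as tw


@pytest.fixture(scope="session")
def formulation_c_psd():
    """Synthetic formulation-C-like PSD: MMAD 3.7 µm, GSD 1.8, 23 µg."""
    return tw.synthetic_psd(mmad=3.7, gsd=1.8, total_mass=23.0)


@pytest.fixture(scope="session")
def solution_config():
    """Solution diffusion run with the bench parameters and 9-point schedule."""
    return tw.ExperimentConfig(
        psd=None,
        donor_volume=0.58,
        receptor_volume=1.5,
        initial_amount=23.0,
        schedule=tw.SamplingSchedule(tw.DIFFUSION_TIMEPOINTS_MIN, sample_volume=0.5),
    )


@pytest.fixture(scope="session")
def particle_config(formulation_c_psd):
    """Particle dissolution run at the small-volume bench conditions."""
    return tw.ExperimentConfig(psd=formulation_c_psd)


@pytest.fixture(scope="session")
def solution_result(solution_config):
    return tw.simulate(solution_config)


@pytest.fixture(scope="session")
def particle_result(particle_config):
    return tw.simulate(particle_config)
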