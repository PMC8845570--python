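import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycotype import simulate

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_pangenome():
    """The default synthetic two-species pangenome (5+5 genomes, 200 core
    families, d_w=0.03, d_b=0.25, 10 transfer events, seed 1)."""
    spec = simulate.PangenomeSpec(seed=1)
    genomes, families, truth = simulate.simulate_pangenome_pair(spec)
    return spec, genomes, families, truth


@pytest.fixture(scope="session")
def zero_noise_panel():
    """4 species x 5 strains, zero noise/dropout, seed 1."""
    return simulate.simulate_phenotype_panel(
        n_species=4, strains_per_species=5, trait_dropout_p=0.0, noise_sd=0.0, seed=1
    )


def logistic_curve(baseline=0.1, plateau=0.9, rate=0.01, lag=600.0, timestep=15.0,
                   duration=5760.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + timestep / 2, timestep)
    a = baseline + (plateau - baseline) / (1 + np.exp(-rate * (t - lag)))
    if noise_sd:
        a = np.clip(a + rng.normal(0, noise_sd, t.shape), 0, None)
    return t, a
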