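import pytest

import homoeonet as hn


@pytest.fixture(scope="session")
def modular_dataset():
    """A mid-size dataset with planted modules, differentiation and bias,
    shared by tests that only read it."""
    cfg = hn.SimulationConfig(
        n_triplets=120, n_doublets=10, n_unique=10, n_other=5,
        n_samples=60, n_modules=4, frac_differentiated=0.1, frac_biased=0.1,
        frac_spatiotemporal=0.0, noise_sd=0.25, beta_min=1.0, beta_max=2.0,
        seed=42,
    )
    catalog, hits, matrix, truth = hn.simulate_dataset(cfg)
    return cfg, catalog, hits, matrix, truth


@pytest.fixture(scope="session")
def modular_pipeline(modular_dataset):
    """Groups, RPM and module assignment computed once on the shared dataset."""
    cfg, catalog, hits, matrix, truth = modular_dataset
    groups = hn.build_groups(hits, catalog)
    rpm = hn.compute_rpm(matrix)
    result = hn.build_modules(rpm)
    return cfg, catalog, truth, groups, rpm, result
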