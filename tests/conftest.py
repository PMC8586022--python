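import numpy as np
import pytest

import poregraph as pg


@pytest.fixture(scope="session")
def tiny_reference():
    """Noise-free synthetic additive model over DNA 2mers (16 kmers)."""
    spec = pg.SyntheticModelSpec(alphabet=pg.DNA, k=2, noise_sd=0.0, seed=5)
    model, truth = pg.generate(spec)
    return model, truth


@pytest.fixture(scope="session")
def tiny_trained(tiny_reference):
    """A small network trained to convergence on the 16 DNA 2mers."""
    reference, _ = tiny_reference
    kmers = pg.enumerate_kmers(pg.DNA, 2)
    P = pg.padding_size([pg.DNA], 2)
    config = pg.ArchitectureConfig(2, 1, 2, 8)
    tc = pg.TrainConfig(
        max_epochs=800, seed=1, validation_fraction=0.2,
        early_stop_patience=150, batch_size=8, learning_rate=5e-3,
        dropout_rate=0.0,
    )
    fitted = pg.train_on_kmers(kmers, reference, config, tc, P)
    return fitted, reference, kmers, P


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
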