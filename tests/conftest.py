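import numpy as np
import pytest

from strucfun.model import GCNConfig, GCNModel, TrainConfig, prepare_gcn_inputs, train_model
from strucfun.synthetic import MotifSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small noise-free planted-motif dataset shared across test modules."""
    cfg = SyntheticConfig(
        n_proteins=24, length_range=(60, 80), n_terms=2,
        label_noise_rate=0.0, seed=42, planting_probs=[0.5, 0.4],
        motif_library=[MotifSpec(motif_size=6), MotifSpec(motif_size=7)],
    )
    records, space = generate_dataset(cfg)
    return records, space


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A small GCN overfit on the tiny dataset (for saliency/predict tests)."""
    records, space = tiny_dataset
    inputs = prepare_gcn_inputs(records)
    labels = np.stack([r.labels for r in records])
    model = GCNModel(len(space), GCNConfig(channels=(16, 16, 16),
                                           input_channels=16, fc_hidden=32),
                     seed=0)
    state = train_model(model, inputs, labels, space.weight_vector,
                        TrainConfig(lr=3e-3, beta1=0.9, beta2=0.999,
                                    batch_size=16, max_epochs=120,
                                    patience=120, seed=0))
    return model, records, inputs, labels, space, state
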