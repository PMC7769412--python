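import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cxct.cx_core import LossWeights
from cxct.features import ExtractorConfig
from cxct.generator import GeneratorConfig, TrainConfig, train
from cxct.phantom_sim import ArtifactSpec, DeformationSpec, PhantomSpec, make_dataset
from cxct.presets import resolve_preset

SMOKE_SEED = 11
SMOKE_WIDTH = 32  # desk-scale generator channel width


@pytest.fixture(scope="session")
def smoke_dataset():
    """40 train / 8 val / 8 test synthetic 64x64 pairs, label misaligned <= 4 px."""
    return make_dataset(
        56,
        PhantomSpec(size=64),
        ArtifactSpec(),
        DeformationSpec(max_displacement=4.0),
        split=(40 / 56, 8 / 56, 8 / 56),
        master_seed=SMOKE_SEED,
    )


def train_smoke(dataset, preset: str, seed: int = SMOKE_SEED, epochs: int = 30):
    base = TrainConfig(epochs=epochs, seed=seed, loss_weights=LossWeights(sample_seed=seed))
    train_cfg, gen_cfg = resolve_preset(
        preset, base, GeneratorConfig(seed=seed), width_override=SMOKE_WIDTH
    )
    return train(dataset.train, gen_cfg, train_cfg, ExtractorConfig(seed=seed),
                 val_set=dataset.val)


@pytest.fixture(scope="session")
def cx_smoke(smoke_dataset):
    """CX-trained model + history under the 30-epoch smoke protocol."""
    return train_smoke(smoke_dataset, "cx")


@pytest.fixture(scope="session")
def l2_smoke(smoke_dataset):
    return train_smoke(smoke_dataset, "l2")


@pytest.fixture(scope="session")
def perceptual_smoke(smoke_dataset):
    return train_smoke(smoke_dataset, "perceptual")


def at_final_epoch(model, history):
    """Copy of a trained model carrying its last-epoch weights.

    When checkpoint selection rewound the model, the end of the
    optimisation trajectory — where each objective's bias is fully
    expressed — remains available through the history.
    """
    from cxct.generator import CorrectionNet

    m = CorrectionNet(model.config, model.side, model.hu_window)
    source = history.final_weights or [p.data for p in model.params]
    for p, w in zip(m.params, source):
        p.data = w.copy()
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
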