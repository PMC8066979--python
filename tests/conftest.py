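import numpy as np
import pytest

import tianet as tn
from tianet.transfer_pipeline import TrainSchedule


@pytest.fixture(scope="session")
def tiny_cfg():
    """32-px five-conv config small enough for sub-second training steps."""
    return tn.BackboneConfig(
        input_size=32,
        channels_per_conv=(4, 6, 8, 8, 8),
        kernel_sizes=(5, 3, 3, 3, 3),
        pool_after=(1, 2, 5),
        fc_widths=(16, 4),
    )


@pytest.fixture(scope="session")
def tiny_sched():
    return TrainSchedule(epochs=2, batch_size=8, lr=1e-2, lr_step_epochs=5, seed=0)


@pytest.fixture(scope="session")
def source_ds_small():
    return tn.generate_dataset(32, tn.SOURCE_TASK, seed=11, image_size=32)


@pytest.fixture(scope="session")
def target_ds_small():
    return tn.generate_dataset(24, tn.TARGET_TASK, seed=12, image_size=32)


@pytest.fixture(scope="session")
def source_model_small(source_ds_small, tiny_cfg, tiny_sched):
    model, history = tn.pretrain_source(source_ds_small, tiny_cfg, tiny_sched)
    return model, history


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
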