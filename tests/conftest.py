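import numpy as np
import pytest

from pneunet.data import SplitSpec, SyntheticSpec, generate_synthetic, stack_images, stratified_split
from pneunet.model import ArchitectureConfig, build_pneunet
from pneunet.training import TrainConfig, restore, train

#: resolution for desk-scale end-to-end runs (parameter counts are
#: spatial-size-independent, so audits still use the 224 configuration)
DESK_SIZE = 48


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default synthetic dataset: 200 images per class, seed 7."""
    return generate_synthetic(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def desk_run(synthetic_dataset):
    """One scaled-down end-to-end training run on the default synthetic
    dataset, shared by the end-to-end and interpretability checks."""
    records = synthetic_dataset
    labels = [r.label for r in records]
    tr, va, te = stratified_split(labels, SplitSpec(seed=42))
    x, y = stack_images(records, target=DESK_SIZE)
    net = build_pneunet(
        ArchitectureConfig(input_height=DESK_SIZE, input_width=DESK_SIZE), seed=42)
    ckpt, history = train(net, (x[tr], y[tr]), (x[va], y[va]),
                          TrainConfig(max_epochs=10, seed=42))
    restore(net, ckpt)
    return {
        "model": net, "checkpoint": ckpt, "history": history,
        "x": x, "y": y, "train": tr, "val": va, "test": te,
    }
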