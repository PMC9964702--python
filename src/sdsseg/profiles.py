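"""Named configuration profiles.

``desk`` is the scale at which everything in this package runs on one
CPU in minutes: small phantoms, 64x64 network inputs, base width 16,
SGD with momentum and a larger step size suited to the short schedules.
``paper`` records the reference hyperparameters of the original
training setup (224x224 inputs, base width 64, learning rate 0.001,
batch 8, up to 600 epochs with early-stopping patience 10); it is not
intended to be run on a desk machine.
"""

from __future__ import annotations

from .network import NetworkConfig
from .phantom import PhantomSpec
from .preprocess import PreprocessConfig
from .train import TrainConfig


def desk_profile(seed: int = 0) -> dict:
    return {
        "phantom": PhantomSpec(shape=(16, 64, 64), seed=seed),
        "preprocess": PreprocessConfig(crop_size=(56, 56), input_size=(64, 64)),
        "network": NetworkConfig(base_channels=16, in_plane=(64, 64), seed=seed),
        "train": TrainConfig(learning_rate=0.05, momentum=0.9, batch_size=8,
                             max_epochs=30, patience=10, seed=seed),
    }


def paper_profile(seed: int = 0) -> dict:
    return {
        "phantom": PhantomSpec(shape=(155, 240, 240), seed=seed),
        "preprocess": PreprocessConfig(crop_size=(160, 160), input_size=(224, 224)),
        "network": NetworkConfig(base_channels=64, in_plane=(224, 224), seed=seed),
        "train": TrainConfig(learning_rate=0.001, momentum=0.0, batch_size=8,
                             max_epochs=600, patience=10, seed=seed),
    }


PROFILES = {"desk": desk_profile, "paper": paper_profile}
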