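import numpy as np
import pytest

from fpolcyto import NetConfig, TrainConfig, build_network, generate_sample, train
from fpolcyto.phantom import PhantomSpec
from fpolcyto.segnet import AugmentConfig


def desk_phantom_spec(seed: int, noise_sd: float = 2.0, **overrides) -> PhantomSpec:
    """A 128x128 phantom matching the desk-scale training conditions."""
    kwargs = dict(
        image_size=128,
        n_cells=5,
        cell_radius_range=(6, 12),
        cluster_fraction=0.2,
        ambiguous_fraction=0.2,
        noise_sd=noise_sd,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def desk_training():
    """Train the 5-level, base-16 network once on 20 desk-scale phantoms.

    Shared between the training-progress check and the held-out Dice
    recovery check; held-out phantoms are noiseless and drawn from seeds
    disjoint from the training seeds.
    """
    samples = [
        (s.pair, s.masks)
        for s in (generate_sample(desk_phantom_spec(100 + i)) for i in range(20))
    ]
    held_out = [generate_sample(desk_phantom_spec(900 + i, noise_sd=0.0)) for i in range(4)]
    net = build_network(NetConfig(levels=5, base_channels=16, seed=0))
    cfg = TrainConfig(
        batch_size=4,
        learning_rate=1e-3,
        epochs=15,
        augment=AugmentConfig(
            rotation_deg=15.0, scale_range=(0.9, 1.1), shear_deg=5.0, random_crop=False
        ),
        seed=0,
    )
    history = train(net, samples, cfg)
    return {"net": net, "history": history, "held_out": held_out, "config": cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
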