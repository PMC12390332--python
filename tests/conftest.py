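import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small phantom dataset shared by I/O-level tests (2 per plane)."""
    from fbstrnet.phantom import generate_dataset

    root = tmp_path_factory.mktemp("phantoms")
    manifest = generate_dataset(n_per_plane=2, seed=11, out_dir=root,
                                image_size=128, val_fraction=0.5)
    return manifest
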