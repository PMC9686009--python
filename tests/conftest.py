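import numpy as np
import pytest

from mvmar.core import ImageVolume
from mvmar.phantom import MetalInsert, PhantomSpec, make_pair, make_phantom


@pytest.fixture(scope="session")
def steel_pair():
    """One seeded phantom pair with a single steel denture insert."""
    import mvmar.phantom as ph

    spec = PhantomSpec(
        seed=42,
        metal_inserts=(MetalInsert(position=(30.0, 64.0), radius=3.0, material="stainless_steel"),),
    )
    truth, masks = make_phantom(spec)
    ct = ph.simulate_kvct(truth, seed=43)
    mv = ph.simulate_mvcbct(truth, seed=44)
    return ph.PhantomPair(
        truth=truth, ct=ct, mv=mv, masks=masks, has_metal=True,
        mv_truth=ph.mv_truth_from_ct(truth), seed=42,
    )


@pytest.fixture(scope="session")
def clean_pair():
    """One seeded metal-free phantom pair."""
    return make_pair(seed=7, with_metal=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ct(rng):
    return ImageVolume(rng.uniform(-1000, 3000, (32, 32)), (1.0, 1.0), modality="ct")
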