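import numpy as np
import pytest

from ecbs import (
    FingerprintKind,
    ForestConfig,
    SynthConfig,
    generate_universe,
    make_retraining_scenario,
)


@pytest.fixture(scope="session")
def abstract_universe():
    """Small chemistry-free universe with planted scaffold signal."""
    return generate_universe(SynthConfig(seed=11, mode="abstract"))


@pytest.fixture(scope="session")
def smiles_universe():
    """Default-condition universe of real molecules."""
    return generate_universe(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def fast_forest():
    """Reduced tree count for unit tests where only behavior is probed."""
    return ForestConfig(n_trees=60)


@pytest.fixture(scope="session")
def abstract_scenario(abstract_universe):
    """Base pairs + pairing input for retraining tests."""
    base, pairing = make_retraining_scenario(
        abstract_universe, n_true_pos=4, n_false_pos=8, seed=5
    )
    return base, pairing


def random_fingerprint(rng, kind=FingerprintKind.MACCS166, p=0.3):
    from ecbs import Fingerprint, fingerprint_length

    n = fingerprint_length(kind)
    return Fingerprint(kind, (rng.random(n) < p).astype(np.uint8))
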