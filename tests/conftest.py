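import warnings

import numpy as np
import pytest

from habhet.io import SEQUENCES, VolumeStack
from habhet.phantom import PhantomSpec, generate_case

warnings.filterwarnings("ignore", category=RuntimeWarning)


#: compact phantom geometry used throughout the suite to keep runtimes short
SMALL_SPEC = dict(shape=(44, 44, 14), tumor_radius_mm=(5.5, 8.0))


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL_SPEC)


@pytest.fixture(scope="session")
def phantom_case(small_spec):
    """One deterministic high-heterogeneity phantom case."""
    return generate_case(small_spec, class_label=1, seed=42, case_id="fix01")


@pytest.fixture(scope="session")
def normalized_case(phantom_case):
    from habhet.io import normalize_stack

    stack = normalize_stack(phantom_case["stack"])
    return stack, phantom_case["masks"]["tumor_obs1"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_stack(shape=(12, 12, 6), spacing=(1.0, 1.0, 3.0), seed=0) -> VolumeStack:
    r = np.random.default_rng(seed)
    return VolumeStack(
        "toy", {s: r.standard_normal(shape) for s in SEQUENCES}, spacing
    )
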