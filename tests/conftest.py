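import numpy as np
import pytest

from doseret import (
    CohortSpec,
    EncoderSpec,
    PhantomSpec,
    VirtualizerSpec,
    generate_cohort,
    init_encoder,
)

#: desk-scale phantom for unit tests: 24^3 grid at 8 mm spacing
TINY_PHANTOM = PhantomSpec(grid_shape=(24, 24, 24), spacing_mm=(8.0, 8.0, 8.0))
TINY_ENCODER = EncoderSpec(input_shape=(16, 16, 16))


def tiny_cohort_spec(n_plans=6, n_classes=3, seed=123, **kw) -> CohortSpec:
    return CohortSpec(
        n_plans=n_plans,
        n_classes=n_classes,
        seed=seed,
        phantom=TINY_PHANTOM,
        **kw,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six plans in three beam classes on a 24^3 grid."""
    return generate_cohort(tiny_cohort_spec())


@pytest.fixture(scope="session")
def tiny_weights():
    return init_encoder(TINY_ENCODER, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
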