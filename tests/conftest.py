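import numpy as np
import pytest

from pdxms.synthdata import (
    CohortGenSpec,
    SynthMapSpec,
    TissueClass,
    generate_cohort,
    generate_label_map,
)


@pytest.fixture(scope="session")
def mixed_map():
    """A 200x200 map with a known intratumoral composition."""
    spec = SynthMapSpec(
        shape=(200, 200),
        target_composition={
            TissueClass.CARCINOMA: 0.45,
            TissueClass.NECROSIS: 0.15,
            TissueClass.STROMA: 0.25,
            TissueClass.TDLU: 0.05,
            TissueClass.ADIPOSE: 0.06,
            TissueClass.BACKGROUND: 0.04,
        },
        tumor_mass=0.30,
        seed=7,
    )
    return spec, generate_label_map(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """320-record synthetic cohort under the default outcome model."""
    return generate_cohort(CohortGenSpec(n=320, seed=11))


def random_label_map(seed: int, shape=(30, 30)):
    """Unstructured random map (every class equally likely) for stress
    tests of delineation and proportion book-keeping."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, 7, size=shape).astype(np.uint8)
    lymph = rng.uniform(size=shape)
    lymph[labels == TissueClass.BACKGROUND] = 0.0
    from pdxms.synthdata import TissueLabelMap

    return TissueLabelMap(labels=labels, lymph_fraction=lymph)
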