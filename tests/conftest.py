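import numpy as np
import pytest

from phytoqsar import SyntheticQsarSpec, gen_qsar_dataset


@pytest.fixture()
def planted_small():
    """50 compounds, 8 descriptors of which 3 informative, mild noise."""
    spec = SyntheticQsarSpec(
        n_compounds=50,
        m_descriptors=8,
        k_informative=3,
        true_coefficients=(1.5, -2.0, 0.8),
        noise_sd=0.2,
        seed=11,
    )
    return gen_qsar_dataset(spec)


@pytest.fixture()
def planted_noiseless():
    spec = SyntheticQsarSpec(
        n_compounds=40,
        m_descriptors=6,
        k_informative=2,
        true_coefficients=(2.0, -1.0),
        noise_sd=0.0,
        seed=5,
    )
    return gen_qsar_dataset(spec)
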