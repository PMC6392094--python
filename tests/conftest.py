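import math

import pytest

from picoflux.synthetic_data import (
    LabelingExperimentConfig,
    MetabolitePoolSpec,
)


@pytest.fixture
def small_panel():
    """Two metabolites spanning slow/fast turnover and short/long backbones."""
    return [
        MetabolitePoolSpec("glutamate", 5, 8.0, 0.03, 0.10),
        MetabolitePoolSpec("G3P", 3, 0.8, 0.12, 0.30),
    ]


@pytest.fixture
def noisefree_config():
    """Deterministic design: no noise, no natural abundance."""
    return LabelingExperimentConfig(
        noise_cv=0.0, natural_abundance=0.0, seed=7
    )


@pytest.fixture
def mono_exponential_spec():
    """Instantly equilibrated precursor: FC(t) is exactly mono-exponential."""
    return MetabolitePoolSpec("m", 5, 1.0, 0.03, math.inf)
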