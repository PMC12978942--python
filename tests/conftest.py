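import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from ommatid import ImagingConfig, MosaicSpec, generate_mosaic


@pytest.fixture
def base_spec():
    return MosaicSpec(
        n_rows=20,
        n_cols=20,
        class_proportions_ventral=(0.10, 0.50, 0.40),
        p_coexpress=0.25,
        seed=7,
    )


@pytest.fixture
def base_mosaic(base_spec):
    return generate_mosaic(base_spec)


@pytest.fixture
def noiseless_cfg():
    return ImagingConfig(noise_sd=0.0, fill_fraction_sd=0.0)
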