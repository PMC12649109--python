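import numpy as np
import pytest

from clinsegnet.dataprep import SampleRecord
from clinsegnet.network import ClinSegNet, NetworkConfig, OrganVocabulary
from clinsegnet.synthdata import SynthConfig, default_organ_styles, generate_sample

ORGANS3 = ["kidney", "liver", "lung"]


@pytest.fixture(scope="session")
def small_synth_config():
    """96-pixel patches keep the suite fast while preserving the
    generator's statistical structure."""
    return SynthConfig(image_size=96, lesion_radius=(10, 24),
                       organ_styles=default_organ_styles(ORGANS3), seed=7)


@pytest.fixture(scope="session")
def small_records(small_synth_config):
    records = []
    for organ in ORGANS3:
        for i in range(6):
            s = generate_sample(small_synth_config, organ, i)
            records.append(SampleRecord(filename=f"human_{organ}_{i}",
                                        image=s.he_image, mask=s.mask,
                                        organ=organ, id=i))
    return records


def tiny_network(seed=0, **overrides):
    """Narrow 7-stage model for fast tests; mirrors the full architecture."""
    defaults = dict(stage_channels=(4, 8, 16, 32, 16, 8, 4), embed_dim=8,
                    se_reduction=4, input_size=32, seed=seed)
    defaults.update(overrides)
    cfg = NetworkConfig(**defaults)
    return ClinSegNet(cfg, OrganVocabulary(ORGANS3))


@pytest.fixture
def tiny_model():
    return tiny_network()
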