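import numpy as np
import pytest

from codelcnn.ensemble import EnsembleConfig
from codelcnn.profile_io import CnBin, CnProfile
from codelcnn.vectorize import FeatureVector, SampleFeatures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_profile():
    """Two-chromosome toy profile with a deleted chr1 segment."""
    bins = []
    for i in range(6):
        bins.append(CnBin(chrom="1", start=i * 1000, end=(i + 1) * 1000,
                          log2=-1.0 if i < 3 else 0.0, label=f"g{i}"))
    for i in range(4):
        bins.append(CnBin(chrom="19", start=i * 500, end=(i + 1) * 500,
                          log2=0.1 * i))
    return CnProfile(sample_id="toy", bins=bins)


def make_features(sample_id, x1, x2, label=None):
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return SampleFeatures(
        sample_id=sample_id,
        x1=FeatureVector("1", x1, len(x1)),
        x2=FeatureVector("19", x2, len(x2)),
        label=label,
    )


@pytest.fixture
def tiny_model_config():
    """A miniature ensemble config for fast training tests."""
    return EnsembleConfig(
        branch1_pretrain=(("conv", 11, 8), ("pool", 2), ("conv", 5, 8),
                          ("pool", 2)),
        branch2_pretrain=(("conv", 7, 8), ("pool", 2)),
        residual_specs=((4, 16), (8, 32)),
        residual_iterations=2,
        branch_feature_len=16,
        input_lens=(120, 60),
        seed=7,
    )
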