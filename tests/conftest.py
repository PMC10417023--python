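import numpy as np
import pytest

from neqsel import SyntheticStudySpec, load_cdk_inhibition, sample_crooks_gaussian


@pytest.fixture(scope="session")
def cdk_records():
    """Packaged CDK inhibition table (compounds 1-4 x CDK1/2/5/9)."""
    return load_cdk_inhibition()


@pytest.fixture(scope="session")
def cdk_by_key(cdk_records):
    return {(r.compound, r.target): r for r in cdk_records}


@pytest.fixture
def gaussian_workset():
    """Crooks-consistent Gaussian works, dG=10, sigma=2, 200/direction."""
    return sample_crooks_gaussian(10.0, 2.0, 200, 200, temperature=298.15, seed=42)


@pytest.fixture
def small_spec():
    """4x4 synthetic study at modest size for pipeline tests."""
    return SyntheticStudySpec(n_forward=80, n_reverse=80, work_sigma=2.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
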