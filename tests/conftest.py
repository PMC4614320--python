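import numpy as np
import pytest

from lesionlab import EtaPolicy, HomeoParams, ThreeLayerParams


@pytest.fixture
def scaled_params() -> ThreeLayerParams:
    """Proportionally scaled three-layer model (N=100, n=20) used for fast
    simulation tests; per-connection arithmetic matches the full model."""
    return ThreeLayerParams().scaled()


@pytest.fixture
def fixed_eta() -> EtaPolicy:
    return EtaPolicy.fixed()


@pytest.fixture
def modified_eta() -> EtaPolicy:
    """Disability-dependent learning rate with knee/critical disability
    scaled to the N=100 model (H0=5, Hc=15)."""
    return EtaPolicy.modified(H0=5, Hc=15)


@pytest.fixture
def small_homeo() -> HomeoParams:
    """Miniature homeostasis ring for invariant tests (not the reference
    parameter set): everything shrunk so a trial takes milliseconds."""
    return HomeoParams(
        n_nodes=24,
        T=10,
        theta=20.0,
        beta=0.05,
        p_del=0.5,
        nu=0.02,
        lambda_ext=5.0,
        window=50,
        init_indegree=30,
        kernel_sigma=4.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
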