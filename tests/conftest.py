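import pytest

from mitokit import PipelineConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """One noise-free synthetic bundle shared across read-only tests."""
    return generate_bundle(seed=11)


@pytest.fixture()
def config():
    return PipelineConfig()
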