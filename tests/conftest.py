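import pytest

from c5nscreen import classifier, synthetic


@pytest.fixture(scope="session")
def panel():
    return classifier.load_default_panel()


@pytest.fixture(scope="session")
def ref_panel():
    return synthetic.synth_reference_panel(seed=0)


@pytest.fixture()
def cfg():
    return synthetic.SynthesisConfig(seed=1)
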