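import pytest

from pdpcr import Strand
from pdpcr.io import load_demo


@pytest.fixture(scope="session")
def demo():
    """The bundled worked-example strand set (template + four primers)."""
    return load_demo()


@pytest.fixture(scope="session")
def template(demo):
    return demo["template"]


@pytest.fixture(scope="session")
def template_strand(template):
    return Strand(template, label="template")


@pytest.fixture(scope="session")
def conventional_primers(demo):
    return demo["PCR-1"], demo["PCR-2"]


@pytest.fixture(scope="session")
def pdpcr_primers(demo):
    return demo["PD-PCR-1"], demo["PD-PCR-2"]
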