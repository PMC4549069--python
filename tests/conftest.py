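import pytest

from mtduplex.reference import packaged_annotation, packaged_reference
from mtduplex.simulate import make_toy_reference


@pytest.fixture(scope="session")
def rcrs():
    """Bundled mitochondrial reference (synthetic rCRS stand-in, 16569 bp)."""
    return packaged_reference()


@pytest.fixture(scope="session")
def rcrs_annotation(rcrs):
    return packaged_annotation(rcrs)


@pytest.fixture(scope="session")
def toy_genome():
    """Small circular genome: one 180-bp protein gene + tRNA + rRNA + noncoding."""
    return make_toy_reference(400, [("protein", 180), ("tRNA", 60), ("rRNA", 80)], seed=42)
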