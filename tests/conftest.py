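import pytest

from budmrna.synth import MINIMAL_ZIP
from budmrna.transcript import Transcript


@pytest.fixture(scope="session")
def minimal_zip() -> str:
    return MINIMAL_ZIP


@pytest.fixture(scope="session")
def mini_transcript(minimal_zip) -> Transcript:
    """The minimal zipcode element padded with unstructured flanks, with a
    CDS frame placing the element in frame."""
    seq = "A" * 20 + minimal_zip + "A" * 21
    return Transcript("mini", seq, 21, 59)
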