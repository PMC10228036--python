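import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make dp_oracle importable

from ampliquant.formats import Read, Reference
from ampliquant.quantify import EditEvent


def make_reference(length: int = 200, seed: int = 0, name: str = "amp1", cut_site=None) -> Reference:
    # seed 0 chosen so that the fixture edits (3-base deletion at 8, "GG"
    # insertion at 40) are already left-aligned against the sequence context
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list("ACGT"), size=length))
    return Reference(name=name, sequence=sequence, cut_site=cut_site)


@pytest.fixture
def reference() -> Reference:
    return make_reference()


@pytest.fixture
def del3_signature():
    """The canonical 3-base deletion at position 8 used across fixtures."""
    return (EditEvent(position=8, kind="deletion", length=3),)


def read_from(sequence: str, quality: int = 35, read_id: str = "r") -> Read:
    return Read(id=read_id, sequence=sequence, qualities=[quality] * len(sequence))
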