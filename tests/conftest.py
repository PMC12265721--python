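import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hapmerscan.sequence_io import HaplotypeAssembly, SequenceRecord


def make_assembly(label: str, seqs: dict[str, str]) -> HaplotypeAssembly:
    return HaplotypeAssembly(
        label=label,
        records=[SequenceRecord(id=sid, bases=bases) for sid, bases in seqs.items()],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pair():
    """The worked example pair: one substitution at the last base."""
    return (
        make_assembly("hap1", {"s": "ACGTACGT"}),
        make_assembly("hap2", {"s": "ACGTACGA"}),
    )
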