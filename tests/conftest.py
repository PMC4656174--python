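import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from vcfsieve.model import Role, SampleVariantSet, Variant, Zygosity

HET = Zygosity.HET
HOM = Zygosity.HOM_ALT


def V(chrom="chr1", pos=100, ref="A", alt="G"):
    return Variant(chrom, pos, ref, alt)


@pytest.fixture
def rng():
    return random.Random(20240915)


def case(sample_id, obs):
    return SampleVariantSet(sample_id, Role.CASE, dict(obs))


def control(sample_id, obs):
    return SampleVariantSet(sample_id, Role.CONTROL, dict(obs))


@pytest.fixture
def make_case():
    return case


@pytest.fixture
def make_control():
    return control
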