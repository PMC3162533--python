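from fractions import Fraction

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def make_nucleus(rreb1, ccnd1, myb, cep6, nucleus_id="n1", area_id="A1", qc=True):
    from melafish import NucleusSignal

    return NucleusSignal(
        nucleus_id=nucleus_id,
        area_id=area_id,
        rreb1=rreb1,
        ccnd1=ccnd1,
        myb=myb,
        cep6=cep6,
        qc_pass=qc,
    )


def make_nuclei(counts, area_id="A1", qc=True):
    """Build a list of nuclei from (rreb1, ccnd1, myb, cep6) tuples."""
    return [
        make_nucleus(*c, nucleus_id=f"n{i}", area_id=area_id, qc=qc)
        for i, c in enumerate(counts)
    ]


@pytest.fixture
def frac():
    return Fraction
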