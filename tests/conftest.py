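import pytest

from gedscreen import formats_io
from gedscreen.types import SampleCall, VariantRecord


@pytest.fixture(scope="session")
def panel():
    return formats_io.load_packaged_panel()


@pytest.fixture(scope="session")
def panel_frame():
    return formats_io.load_packaged_panel_frame()


@pytest.fixture(scope="session")
def inheritance_counts():
    return formats_io.load_packaged_inheritance_counts()


def make_record(chrom="chr1", pos=100, ref="A", alts=("T",), calls=None, **call_kw):
    """One-sample VariantRecord shorthand for tests."""
    if calls is None:
        calls = {"s1": SampleCall(**call_kw)} if call_kw else {}
    rec = VariantRecord(chrom, pos, ref, tuple(alts), calls)
    rec.validate()
    return rec
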