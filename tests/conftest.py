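import pytest

from germscreen.io_core import default_panel
from germscreen.models import Consequence, VariantCall


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_call(**kwargs) -> VariantCall:
    """A variant call that passes every filter unless overridden."""
    defaults = dict(
        patient_id="P1", gene="BRCA2", chrom="13", pos=32_900_000,
        ref="G", alt="A", hgvs_c="c.100G>A",
        consequence=Consequence.NONSENSE,
        call_quality=60.0, depth=50, vaf=0.5, pop_af=0.0,
    )
    defaults.update(kwargs)
    return VariantCall(**defaults)


@pytest.fixture
def clean_call():
    return make_call()
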