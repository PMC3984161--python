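import numpy as np
import pytest

from disorderome import synth


@pytest.fixture(scope="session")
def family():
    """One moderately sized splice-variant family shared across tests."""
    spec = synth.VariantFamilySpec(n_variants=8, parent_length=400,
                                   cterm_tags=(("DEC", 3), ("VYR", 3), ("ERL", 2)),
                                   elm_counts={"LIG": 6, "MOD": 4, "TRG": 2, "CLV": 2},
                                   n_domains=1, domain_len=(60, 90), n_morfs=2)
    return synth.gen_variant_family(spec, 20240)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
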