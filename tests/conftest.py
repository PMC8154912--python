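import logging

import numpy as np
import pytest

from codefidelity import (
    CodonUsageProfile,
    builtin_scales,
    standard_code,
    usage_from_counts,
)

logging.getLogger("codefidelity").setLevel(logging.ERROR)
logging.getLogger("codefidelity.synthetic").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def scales():
    return builtin_scales()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(p: dict[str, float], taxon_id: str = "toy") -> CodonUsageProfile:
    """Profile straight from a frequency dict (counts scaled to integers)."""
    code = standard_code()
    counts = {c: int(round(1_000_000 * f)) for c, f in p.items()}
    prof = usage_from_counts(counts, code=code, taxon_id=taxon_id)
    # overwrite with exact frequencies to avoid rounding in oracle comparisons
    object.__setattr__(prof, "p", {c: p.get(c, 0.0) for c in code.sense_codons})
    return prof


@pytest.fixture
def profile_factory():
    return make_profile
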