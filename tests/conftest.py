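import numpy as np
import pytest

from headdx.cbr import default_schema
from headdx.questionnaire import default_bank
from headdx.rules import default_rules
from headdx.vignettes import handcrafted_pm_ptth_casebase, make_record


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def pm_ptth_casebase():
    return handcrafted_pm_ptth_casebase()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def mo_record():
    """Textbook migraine-without-aura presentation."""
    return make_record(attacks=10, duration=1440, laterality="unilateral",
                       qualities={"pulsating"}, vas=7, nausea=True,
                       aggravated=True, days=2)
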