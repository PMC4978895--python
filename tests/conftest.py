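import pytest
from hypothesis import settings

import satscreen as ss

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design() -> ss.ScreenDesign:
    return ss.load_reference_design()


@pytest.fixture(scope="session")
def table(design) -> ss.AlleleTable:
    return ss.load_reference_allele_table(design)


@pytest.fixture(scope="session")
def ftable(design, table) -> ss.FrequencyTable:
    return ss.frequency_table(table, design)
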