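import pytest

from paleoxeno import load_cohort


@pytest.fixture(scope="session")
def builtin():
    """The packaged 47-individual cohort."""
    return load_cohort("builtin")
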