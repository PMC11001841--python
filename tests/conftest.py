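import logging

import pytest

from mammocdm.registry import default_registry

logging.getLogger("mammocdm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cdm():
    """The shipped 38-concept registry (read-only across the session)."""
    return default_registry()
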