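import matplotlib

matplotlib.use("Agg")

import pytest

from lignotherm import build_reference_chain


@pytest.fixture(scope="session")
def reference_chain():
    return build_reference_chain()
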