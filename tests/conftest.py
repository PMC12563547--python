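import pytest

import asymlung as al


@pytest.fixture(scope="session")
def preset_bundle():
    """Full pipeline run on the calibrated preset at seed 42 (shared)."""
    return al.run_all(config=al.published_preset(), seed=42)
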