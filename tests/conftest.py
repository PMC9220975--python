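import pytest

from scgdtw import BeatSpec, generate_beat_pair, load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def clean_beat():
    """Noise-free 966 ms beat: (ecg, scg, annotation, ground-truth fiducials)."""
    return generate_beat_pair(BeatSpec(rr_ms=966.0))
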