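"""Shared fixtures: synthetic records reused across test modules."""

import pytest

from ecgfusion.preprocess import normalized_record
from ecgfusion.synth import SynthParams, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """60 s noise-free NSR record at 250 Hz / 60 bpm, normalized."""
    return normalized_record(
        generate_record(SynthParams(duration=60, fs=250, heart_rate=60, seed=11)))


@pytest.fixture(scope="session")
def short_record():
    """10 s noise-free NSR record, raw (not normalized)."""
    return generate_record(SynthParams(duration=10, fs=250, heart_rate=60, seed=7))
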