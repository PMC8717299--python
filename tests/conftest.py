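import numpy as np
import pytest

from ugof import OnsetSequence, RhythmSpec, generate_isochronous


@pytest.fixture
def perfect_train() -> OnsetSequence:
    """Exact 10 Hz train, 20 beats, no jitter, no silent beats."""
    return generate_isochronous(RhythmSpec(frequency=10.0, n_beats=20),
                                id="perfect10")


@pytest.fixture
def jittered_train() -> OnsetSequence:
    """10 Hz train with 8 ms onset jitter (8% of the period)."""
    return generate_isochronous(
        RhythmSpec(frequency=10.0, n_beats=40, jitter_sd=0.008, seed=42),
        id="jittered10")


@pytest.fixture
def csv_file(tmp_path):
    """Write rows to a CSV file and return its path."""

    def _write(rows, name="onsets.csv"):
        path = tmp_path / name
        path.write_text("\n".join(str(r) for r in rows) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
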