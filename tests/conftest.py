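import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def maximal_inactive_runs_oracle(states):
    """Independent run-length scan: maximal inactive runs as half-open
    (start, end) frame intervals. Deliberately naive (frame-by-frame)."""
    runs = []
    start = None
    for i, active in enumerate(list(states) + [True]):  # sentinel closes a run
        if not active and start is None:
            start = i
        elif active and start is not None:
            runs.append((start, i))
            start = None
    return runs
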