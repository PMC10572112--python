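import numpy as np
import pytest

from pdkeys.io import KeystrokeEvent, TypingSession
from pdkeys.latency import LatencySeries


def make_session(press, release, keys=None, subject_id="s1", visit_index=1):
    press = np.asarray(press, dtype=float)
    release = np.asarray(release, dtype=float)
    if keys is None:
        keys = ["a"] * len(press)
    events = [
        KeystrokeEvent(str(k), float(p), float(r))
        for k, p, r in zip(keys, press, release)
    ]
    return TypingSession(subject_id=subject_id, visit_index=visit_index, events=events)


def make_series(values, kind="IL"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if kind == "HL":
        pairs = np.column_stack([np.arange(n), np.arange(n)])
    else:
        pairs = np.column_stack([np.arange(n), np.arange(n) + 1])
    return LatencySeries(kind, values, pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_session(rng, n):
    """Random but valid session: positive holds, gaps that may be negative."""
    holds = rng.uniform(0.01, 0.3, n)
    gaps = rng.uniform(-0.2, 0.5, n - 1)
    # keep press times strictly increasing
    incr = np.maximum(holds[:-1] + gaps, 1e-4)
    press = np.concatenate([[0.0], np.cumsum(incr)])
    release = press + holds
    return make_session(press, release)
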