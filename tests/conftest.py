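import numpy as np
import pytest

from foragemetrics import BoutSequence, parse_binary_string


def periodic_two_stop_sequence(minutes: int) -> BoutSequence:
    """An animal with a fixed rhythm: two 1-s stops every 5 minutes.

    Built from a 300-s period with stops at offsets 100 and 200 so that a
    5-min window holds 3 moves / 2 stops, 10 min holds 5 / 4, 20 min 9 / 8.
    """
    period = np.ones(300, dtype=np.uint8)
    period[100] = 0
    period[200] = 0
    reps = minutes * 60 // 300
    return BoutSequence(np.tile(period, reps), resolution=1.0)


def one_long_move_sequence() -> BoutSequence:
    """10-min observation: a single continuous 4-min move, then stopped."""
    return parse_binary_string("1" * 240 + "0" * 360)


def many_short_moves_sequence() -> BoutSequence:
    """10-min observation: 16 moves of 0.25 min separated by stops."""
    parts = []
    for i in range(16):
        parts.append("1" * 15)
        parts.append("0" * (22 if i % 2 else 23))
    return parse_binary_string("".join(parts))


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


def random_sequence(rng, n: int) -> BoutSequence:
    return BoutSequence(rng.integers(0, 2, size=n).astype(np.uint8))
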