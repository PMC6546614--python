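import numpy as np
import pytest

from termtide import bundled_taxonomy
from termtide.diary import DiaryDay


@pytest.fixture(scope="session")
def tax():
    return bundled_taxonomy()


def make_day(child_id="c1", day_type="school", events=None):
    if events is None:
        events = (
            ("sleep_night", 600),
            ("classroom_sitting", 360),
            ("watch_tv", 240),
            ("eat_meal", 60),
            ("playground_games", 120),
            ("clean_room", 60),
        )
    return DiaryDay(child_id, day_type, tuple(events))


@pytest.fixture
def toy_day():
    return make_day()


def random_valid_day(rng, tax, child_id="c1", day_type="school"):
    """A random diary day on the 5-min grid covering exactly 1440 min."""
    codes = list(tax.codes)
    n_events = int(rng.integers(3, 12))
    chosen = rng.choice(codes, size=n_events, replace=True)
    weights = rng.dirichlet(np.ones(n_events))
    units = np.floor(weights * 288).astype(int)
    units[0] += 288 - units.sum()
    events = tuple(
        (str(c), float(u * 5)) for c, u in zip(chosen, units) if u > 0
    )
    return DiaryDay(child_id, day_type, events)
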