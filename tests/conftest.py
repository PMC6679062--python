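import itertools

import pytest

from mtvntr.type1_model import ElongationEvent


def alternating_events(start_unit: str, kinds_len: int, spacers):
    """Build the unique alternating event-kind list of a given length for a
    start unit, with explicit spacer choices for the R events."""
    first = "R" if start_unit == "F" else "F"
    kinds = [first if i % 2 == 0 else ("F" if first == "R" else "R") for i in range(kinds_len)]
    it = iter(spacers)
    return [
        ElongationEvent("R", next(it)) if k == "R" else ElongationEvent("F")
        for k in kinds
    ]


def exhaustive_event_lists(max_events: int):
    """Every (start_unit, events) combination up to ``max_events`` with all
    spacer choices enumerated."""
    for start in ("F", "R"):
        first = "R" if start == "F" else "F"
        for k in range(max_events + 1):
            kinds = [
                first if i % 2 == 0 else ("F" if first == "R" else "R")
                for i in range(k)
            ]
            n_r = sum(1 for kd in kinds if kd == "R")
            for spacers in itertools.product("GC", repeat=n_r):
                yield start, alternating_events(start, k, spacers)


@pytest.fixture(scope="session")
def event_universe():
    """All alternating event lists up to 8 events, both starts and spacers."""
    return list(exhaustive_event_lists(8))
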