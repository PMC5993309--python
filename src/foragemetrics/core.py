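"""Bout-sequence representation and manipulation.

A behavioural observation is discretized at a fixed time resolution
(default 1 s) into a binary sequence: 1 = the animal is moving, 0 = it is
stopped.  A maximal run of one state is a *bout*.  The run-length encoded
form (:class:`BoutList`) carries the same information as the sequence and
round-trips losslessly.

Observers and analyses impose minimal recognizable bout durations
(``M_min`` for moves, ``S_min`` for stops); :func:`enforce_min_durations`
applies such a policy to a bout list by absorbing sub-threshold bouts into
their neighbours.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MOVE = 1
STOP = 0

_STATE_ALIASES = {
    "move": MOVE, "moving": MOVE, "m": MOVE, "1": MOVE,
    "stop": STOP, "stopped": STOP, "s": STOP, "0": STOP,
}


def _coerce_state(value) -> int:
    """Map a user-supplied state label (``move``/``stop``/1/0/...) to 0/1."""
    if isinstance(value, str):
        key = value.strip().lower()
        if key in _STATE_ALIASES:
            return _STATE_ALIASES[key]
        raise ValueError(f"unrecognized state label: {value!r}")
    iv = int(value)
    if iv not in (0, 1):
        raise ValueError(f"state must be 0 or 1, got {value!r}")
    return iv


@dataclass
class BoutSequence:
    """A discretized binary move/stop time series.

    Parameters
    ----------
    states : array-like of {0, 1}
        One value per time unit; 1 = moving, 0 = stopped.
    resolution : float
        Duration of one time unit in seconds (default 1).
    id : str, optional
        Free-text label carried through I/O.
    """

    states: np.ndarray
    resolution: float = 1.0
    id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.states)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("empty sequence")
        if not np.isin(arr, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(arr, (0, 1)))[0])
            raise ValueError(f"invalid state at position {bad + 1}")
        if not self.resolution > 0:
            raise ValueError("resolution must be > 0")
        self.states = arr.astype(np.uint8)

    def __len__(self) -> int:
        return self.states.size

    @property
    def duration_seconds(self) -> float:
        return len(self) * self.resolution

    @property
    def od_minutes(self) -> float:
        """Observation duration OD, in minutes."""
        return self.duration_seconds / 60.0

    def window(self, start_unit: int, n_units: int) -> "BoutSequence":
        """A contiguous sub-sequence (zero-copy view on the states)."""
        if start_unit < 0 or start_unit + n_units > len(self):
            raise ValueError("window out of range")
        return BoutSequence(self.states[start_unit:start_unit + n_units],
                            resolution=self.resolution, id=self.id)

    def to_string(self) -> str:
        return "".join("1" if s else "0" for s in self.states)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BoutSequence):
            return NotImplemented
        return (self.resolution == other.resolution
                and np.array_equal(self.states, other.states))


@dataclass
class BoutList:
    """Run-length encoding of a :class:`BoutSequence`.

    ``bouts`` is an ordered list of ``(state, duration_in_units)`` with
    alternating states and durations >= 1.
    """

    bouts: list[tuple[int, int]]
    resolution: float = 1.0
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError("empty bout list")
        for i, (state, dur) in enumerate(self.bouts):
            if state not in (0, 1):
                raise ValueError(f"bout {i}: state must be 0 or 1")
            if dur < 1:
                raise ValueError(f"bout {i}: duration must be >= 1 unit")
            if i and state == self.bouts[i - 1][0]:
                raise ValueError(f"bouts {i - 1} and {i} do not alternate")

    def __len__(self) -> int:
        return len(self.bouts)

    @property
    def total_units(self) -> int:
        return sum(d for _, d in self.bouts)

    def durations_seconds(self, state: int) -> np.ndarray:
        return np.array([d * self.resolution
                         for st, d in self.bouts if st == state])

    def decode(self) -> BoutSequence:
        states = np.repeat([st for st, _ in self.bouts],
                           [d for _, d in self.bouts]).astype(np.uint8)
        return BoutSequence(states, resolution=self.resolution, id=self.id)


@dataclass
class MinDurationPolicy:
    """Minimal recognizable bout durations and the sub-threshold merge rule.

    ``m_min`` / ``s_min`` are in seconds and must be positive integer
    multiples of the sequence resolution.  ``merge_rule``:

    - ``"absorb"`` (default): a left-to-right pass absorbs every bout
      shorter than its threshold into its preceding bout (the first bout
      absorbs into the following one), flipping its state; same-state
      neighbours then merge; passes repeat until stable.
    - ``"absorb_interior"``: the same rule but the first and last bouts are
      exempt (they may be genuine bouts truncated by the observation
      window).
    """

    m_min: float = 1.0
    s_min: float = 1.0
    merge_rule: str = "absorb"

    def __post_init__(self) -> None:
        if self.merge_rule not in ("absorb", "absorb_interior"):
            raise ValueError(f"unknown merge_rule: {self.merge_rule!r}")
        if self.m_min <= 0 or self.s_min <= 0:
            raise ValueError("thresholds must be positive")

    def threshold_units(self, resolution: float) -> dict[int, int]:
        out = {}
        for state, thr in ((MOVE, self.m_min), (STOP, self.s_min)):
            if thr < resolution:
                raise ValueError(
                    f"threshold {thr} s is below the resolution {resolution} s")
            units = thr / resolution
            if abs(units - round(units)) > 1e-9:
                raise ValueError(
                    f"threshold {thr} s is not a whole number of "
                    f"{resolution}-s time units")
            out[state] = int(round(units))
        return out


def parse_binary_string(text: str, resolution: float = 1.0,
                        id: str | None = None) -> BoutSequence:
    """Parse a 0/1 character string into a :class:`BoutSequence`.

    Raises ``ValueError`` for empty input or any character other than
    '0'/'1' (the message names the 1-based offending position).
    """
    if not text:
        raise ValueError("empty sequence")
    for pos, ch in enumerate(text, start=1):
        if ch not in "01":
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    return BoutSequence(np.frombuffer(text.encode(), dtype=np.uint8) - ord("0"),
                        resolution=resolution, id=id)


def read_event_log(rows: Iterable[tuple[float, object]],
                   total_duration_s: float,
                   resolution: float = 1.0,
                   id: str | None = None) -> BoutSequence:
    """Build a sequence from state-change events.

    ``rows`` are ``(time_s, state)`` records with strictly increasing times
    starting at 0 and alternating states; each state is held over the
    left-closed/right-open interval up to the next event (or to
    ``total_duration_s`` for the last).
    """
    rows = [(float(t), _coerce_state(s)) for t, s in rows]
    if not rows:
        raise ValueError("empty event log")
    if rows[0][0] != 0:
        raise ValueError("first event must be at time 0")
    times = [t for t, _ in rows]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("event times must be strictly increasing")
    states = [s for _, s in rows]
    if any(b == a for a, b in zip(states, states[1:])):
        raise ValueError("states do not alternate")
    if total_duration_s < times[-1]:
        raise ValueError("total duration is shorter than the last event time")
    n_units = int(round(total_duration_s / resolution))
    if n_units < 1:
        raise ValueError("total duration shorter than one time unit")
    edges = [int(round(t / resolution)) for t in times] + [n_units]
    seq = np.empty(n_units, dtype=np.uint8)
    for (start, end), state in zip(zip(edges, edges[1:]), states):
        seq[start:end] = state
    return BoutSequence(seq, resolution=resolution, id=id)


def run_length_encode(seq: BoutSequence) -> BoutList:
    """Encode a sequence into alternating ``(state, duration)`` bouts."""
    s = seq.states
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [s.size]])
    bouts = [(int(s[a]), int(b - a)) for a, b in zip(starts, ends)]
    return BoutList(bouts, resolution=seq.resolution, id=seq.id)


def enforce_min_durations(bouts: BoutList,
                          policy: MinDurationPolicy) -> BoutList:
    """Absorb bouts shorter than their minimal duration into a neighbour.

    The operation conserves the total duration, is idempotent, and leaves a
    single-bout list untouched.  See :class:`MinDurationPolicy` for the
    merge rule.
    """
    thr = policy.threshold_units(bouts.resolution)
    lst: list[list[int]] = [[st, d] for st, d in bouts.bouts]
    interior_only = policy.merge_rule == "absorb_interior"

    def first_violation() -> int | None:
        lo = 1 if interior_only else 0
        hi = len(lst) - 1 if interior_only else len(lst)
        for i in range(lo, hi):
            if lst[i][1] < thr[lst[i][0]]:
                return i
        return None

    while len(lst) > 1:
        i = first_violation()
        if i is None:
            break
        if i == 0:
            lst[1][1] += lst[0][1]
            del lst[0]
        else:
            lst[i - 1][1] += lst[i][1]
            del lst[i]
            # absorbing may bring two same-state bouts together
            if i < len(lst) and lst[i - 1][0] == lst[i][0]:
                lst[i - 1][1] += lst[i][1]
                del lst[i]
    return BoutList([(st, d) for st, d in lst],
                    resolution=bouts.resolution, id=bouts.id)


# ---------------------------------------------------------------------------
# file I/O

def read_sequences(path: str | Path, resolution: float = 1.0) -> list[BoutSequence]:
    """Read binary-string sequence files: one 0/1 string per line, optional
    preceding ``#id`` comment naming the next sequence."""
    out: list[BoutSequence] = []
    label: str | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            label = line[1:].strip() or None
            continue
        out.append(parse_binary_string(line, resolution=resolution, id=label))
        label = None
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_sequences(path: str | Path, seqs: Sequence[BoutSequence]) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            if seq.id:
                fh.write(f"#{seq.id}\n")
            fh.write(seq.to_string() + "\n")


def read_event_log_csv(path_or_buf, total_duration_s: float | None = None,
                       resolution: float = 1.0,
                       id: str | None = None) -> BoutSequence:
    """Read an event-log CSV with header ``time_s,state``.

    ``state`` is ``move``/``stop`` or 1/0.  The total observation duration
    must be supplied either as ``total_duration_s`` or as a trailing
    sentinel row whose state is ``end``.
    """
    import pandas as pd

    df = pd.read_csv(path_or_buf)
    cols = {c.strip().lower() for c in df.columns}
    if not {"time_s", "state"} <= cols:
        raise ValueError("event-log CSV must have columns time_s,state")
    df.columns = [c.strip().lower() for c in df.columns]
    rows = list(zip(df["time_s"], df["state"].astype(str)))
    if rows and rows[-1][1].strip().lower() == "end":
        total_duration_s = float(rows[-1][0])
        rows = rows[:-1]
    if total_duration_s is None:
        raise ValueError("total duration required (flag or 'end' sentinel row)")
    return read_event_log(rows, total_duration_s, resolution=resolution, id=id)
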