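"""Stationary alternating-renewal simulation of move/stop sequences.

The generator alternates move and stop bouts whose durations are drawn
independently from a chosen family (geometric by default: discrete,
memoryless, support >= 1 time unit — the natural discrete-time analogue of
the no-correlation assumption behind the bias model).  Initialization is
*stationary*: the starting state is drawn with the equilibrium probability
M/(M+S) of moving, and the first (edge) bout's remaining length from the
discrete forward-recurrence distribution P(R = r) = P(L >= r)/E[L], so that
every window of the output is statistically identical to a window of an
infinitely long sequence.  A burn-in initialization is available as a
fallback for cross-checking.

Under this model, with bout-duration means M and S in time units at 1-s
resolution, the long-run proportion of time moving is M/(M+S) and the true
movement frequency is 60/(M+S) bouts per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoutSequence

__all__ = ["SimulationParams", "simulate_sequence", "sample_windows"]

_FAMILIES = ("geometric", "fixed")


@dataclass
class SimulationParams:
    """Parameters of the alternating-renewal generator.

    mean_move_s, mean_stop_s : float
        Mean bout durations in seconds (>= resolution).
    length_units : int
        Output length in time units (>= 2).
    resolution : float
        Seconds per time unit (default 1).
    seed : int
        Mandatory for reproducibility.
    distribution : {"geometric", "fixed"}
        Bout-length family.  "fixed" draws every bout at exactly its mean
        (rounded to whole units), useful as an exact oracle.
    init : {"equilibrium", "burnin"}
        Stationary analytic start (default) or a discarded warm-up of
        10·(M+S) units starting from a fresh bout.
    """

    mean_move_s: float
    mean_stop_s: float
    length_units: int
    seed: int
    resolution: float = 1.0
    distribution: str = "geometric"
    init: str = "equilibrium"

    def __post_init__(self) -> None:
        if self.mean_move_s < self.resolution or self.mean_stop_s < self.resolution:
            raise ValueError("mean bout durations must be >= resolution")
        if self.length_units < 2:
            raise ValueError("length must be >= 2 time units")
        if self.distribution not in _FAMILIES:
            raise ValueError(f"unknown distribution: {self.distribution!r}")
        if self.init not in ("equilibrium", "burnin"):
            raise ValueError(f"unknown init: {self.init!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _draw_bouts(rng: np.random.Generator, mean_units: float,
                distribution: str, size: int) -> np.ndarray:
    if distribution == "geometric":
        return rng.geometric(1.0 / mean_units, size=size)
    # fixed: deterministic whole-unit durations
    return np.full(size, max(1, int(round(mean_units))), dtype=np.int64)


def _draw_forward_recurrence(rng: np.random.Generator, mean_units: float,
                             distribution: str) -> int:
    """Remaining length of the bout in progress at a stationary time point,
    P(R = r) = P(L >= r)/E[L] for r >= 1."""
    if distribution == "geometric":
        # memoryless: the residual is geometric with the same parameter
        return int(rng.geometric(1.0 / mean_units))
    length = max(1, int(round(mean_units)))
    return int(rng.integers(1, length + 1))


def simulate_sequence(params: SimulationParams) -> BoutSequence:
    """Generate one stationary move/stop sequence.

    Identical parameters (including the seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    m = params.mean_move_s / params.resolution
    s = params.mean_stop_s / params.resolution
    n = params.length_units
    means = {1: m, 0: s}

    if params.init == "equilibrium":
        state0 = 1 if rng.random() < m / (m + s) else 0
        first = _draw_forward_recurrence(rng, means[state0],
                                         params.distribution)
        extra = 0
    else:  # burn-in: fresh bout, discard a warm-up prefix
        state0 = 1 if rng.random() < 0.5 else 0
        first = int(_draw_bouts(rng, means[state0], params.distribution, 1)[0])
        extra = int(np.ceil(10 * (m + s)))

    target = n + extra
    durations = [np.array([first], dtype=np.int64)]
    states = [np.array([state0], dtype=np.uint8)]
    total = first
    state = state0
    while total < target:
        k = max(16, int(np.ceil(1.2 * (target - total) / (m + s) * 2)))
        pair_states = np.empty(k, dtype=np.uint8)
        pair_states[0::2] = 1 - state
        pair_states[1::2] = state
        durs = np.empty(k, dtype=np.int64)
        durs[0::2] = _draw_bouts(rng, means[1 - state], params.distribution,
                                 len(durs[0::2]))
        durs[1::2] = _draw_bouts(rng, means[state], params.distribution,
                                 len(durs[1::2]))
        durations.append(durs)
        states.append(pair_states)
        total += int(durs.sum())

    seq = np.repeat(np.concatenate(states), np.concatenate(durations))
    seq = seq[extra:extra + n]
    return BoutSequence(seq.astype(np.uint8), resolution=params.resolution,
                        id=f"sim-M{params.mean_move_s:g}-S{params.mean_stop_s:g}"
                           f"-seed{params.seed}")


def sample_windows(seq: BoutSequence, window_units: int,
                   step_units: int = 1) -> list[BoutSequence]:
    """All windows of ``window_units`` at offsets 0, step, 2·step, ...

    The number of windows is floor((length − window)/step) + 1.  Windows
    are zero-copy views of the parent sequence.
    """
    n = len(seq)
    if window_units < 1 or window_units > n:
        raise ValueError("window must be between 1 and the sequence length")
    if step_units < 1:
        raise ValueError("step must be >= 1")
    offsets = range(0, n - window_units + 1, step_units)
    return [seq.window(o, window_units) for o in offsets]
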