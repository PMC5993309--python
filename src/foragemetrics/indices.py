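"""Movement-based foraging indices and the MPM bias model.

Given a binary move/stop sequence observed for OD minutes:

- **PTM** — proportion of time moving, a fraction in [0, 1].
- **MPM (naive)** — move bouts per minute; every maximal run of 1s that
  intersects the window counts, including edge-truncated fragments.  This
  is the historical estimator; because partial bouts at the window edges
  count as whole moves, its expectation exceeds the true long-run movement
  frequency by PTM/OD (absolute) i.e. AM/OD (relative).
- **MPM′** — the bias-corrected estimator, MPM′ = MPM − PTM/OD.
- **CPM** — move/stop state changes per minute, with denominator OD minus
  one time unit (no change can be observed in the last unit).  Changes are
  instantaneous and cannot be partially sampled, so CPM/2 is an unbiased
  estimator of the movement frequency.
- **AM / AS** — mean durations of *complete* move / stop bouts, in
  minutes; the first and last bouts of a window are dropped because their
  full duration is not observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (MOVE, STOP, BoutList, BoutSequence, MinDurationPolicy,
                   enforce_min_durations, run_length_encode)

__all__ = [
    "ForagingIndices", "BiasEstimates", "compute_ptm", "compute_mpm_naive",
    "compute_cpm", "compute_am_as", "correct_mpm", "predicted_bias",
    "study_level_correction", "summarize",
]


@dataclass
class ForagingIndices:
    """The full index set computed from one observation window.

    ``am`` / ``as_`` are NaN when no interior bout of that state exists
    (a single bout spanning the whole window, for example).
    """

    ptm: float
    mpm_naive: float
    mpm_corrected: float
    cpm: float
    cpm_half: float
    am: float
    as_: float
    od: float
    n_moves: int
    n_stops: int
    n_changes: int
    id: str | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "id", "ptm", "mpm_naive", "mpm_corrected", "cpm", "cpm_half",
            "am", "as_", "od", "n_moves", "n_stops", "n_changes")}
        return d


@dataclass
class BiasEstimates:
    """Model-predicted bias of the naive MPM estimator.

    ``relative`` is dimensionless (AM/OD); ``absolute`` is in moves per
    minute (PTM/OD).  They satisfy absolute = relative × true MPM.
    """

    relative: float
    absolute: float


def compute_ptm(seq: BoutSequence) -> float:
    """Proportion of time moving: (time units moving) / (total units)."""
    return float(seq.states.mean())


def compute_mpm_naive(seq: BoutSequence) -> float:
    """Naive moves per minute: maximal runs of 1s (edge fragments included)
    divided by OD in minutes."""
    s = seq.states
    n_moves = int(s[0]) + int(np.count_nonzero((s[:-1] == 0) & (s[1:] == 1)))
    return n_moves / seq.od_minutes


def compute_cpm(seq: BoutSequence) -> float:
    """Changes per minute: state transitions divided by (OD − one time
    unit) in minutes."""
    if len(seq) < 2:
        raise ValueError("CPM requires a sequence of at least 2 time units")
    s = seq.states
    n_changes = int(np.count_nonzero(s[1:] != s[:-1]))
    denom_min = (len(seq) - 1) * seq.resolution / 60.0
    return n_changes / denom_min


def compute_am_as(bouts: BoutList) -> tuple[float, float]:
    """Mean durations (minutes) of interior move and stop bouts.

    The first and last bouts are edges — their full duration was not
    sampled — and are excluded.  A state with no interior bout yields NaN.
    """
    interior = bouts.bouts[1:-1]

    def mean_minutes(state: int) -> float:
        durs = [d for st, d in interior if st == state]
        if not durs:
            return math.nan
        return float(np.mean(durs)) * bouts.resolution / 60.0

    return mean_minutes(MOVE), mean_minutes(STOP)


def correct_mpm(mpm_naive: float, ptm: float, od: float) -> float:
    """Bias-corrected MPM′ = naive MPM − PTM/OD (PTM a fraction, OD in
    minutes).  A negative result is returned as-is with a warning rather
    than clamped, since clamping would re-introduce bias."""
    if od <= 0:
        raise ValueError("observation duration must be positive")
    if not 0 <= ptm <= 1:
        raise ValueError("PTM must be a fraction in [0, 1]")
    out = mpm_naive - ptm / od
    if out < 0:
        warnings.warn("corrected MPM is negative; returned unclamped",
                      stacklevel=2)
    return out


def study_level_correction(mean_mpm: float, mean_ptm: float,
                           mean_od: float) -> float:
    """Apply the MPM′ correction to study-level arithmetic means.

    When only per-study averages of MPM, PTM and OD are published, the same
    formula applied to the averages removes part of the bias and never adds
    any: the exact correction subtracts a term proportional to the
    reciprocal of the harmonic-mean OD, this one the reciprocal of the
    arithmetic mean, and the harmonic mean never exceeds the arithmetic
    mean.  If only total observation time is known, pass total/n as
    ``mean_od``.
    """
    return correct_mpm(mean_mpm, mean_ptm, mean_od)


def predicted_bias(am: float, ptm: float, od: float) -> BiasEstimates:
    """Model-predicted bias of naive MPM: relative AM/OD, absolute PTM/OD
    (AM, OD in minutes; PTM a fraction)."""
    if od <= 0:
        raise ValueError("observation duration must be positive")
    if am < 0:
        raise ValueError("AM must be non-negative")
    return BiasEstimates(relative=am / od, absolute=ptm / od)


def summarize(seq: BoutSequence,
              policy: MinDurationPolicy | None = None) -> ForagingIndices:
    """Compute every index for one observation window.

    If ``policy`` is given, sub-threshold bouts are merged first; all
    indices are then computed on the cleaned sequence.
    """
    bouts = run_length_encode(seq)
    if policy is not None:
        bouts = enforce_min_durations(bouts, policy)
        seq = bouts.decode()
    ptm = compute_ptm(seq)
    mpm = compute_mpm_naive(seq)
    od = seq.od_minutes
    cpm = compute_cpm(seq) if len(seq) >= 2 else 0.0
    am, as_ = compute_am_as(bouts)
    n_moves = sum(1 for st, _ in bouts.bouts if st == MOVE)
    n_stops = sum(1 for st, _ in bouts.bouts if st == STOP)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative MPM' surfaces in the value
        mpm_corr = correct_mpm(mpm, ptm, od)
    return ForagingIndices(
        ptm=ptm, mpm_naive=mpm, mpm_corrected=mpm_corr,
        cpm=cpm, cpm_half=cpm / 2.0, am=am, as_=as_, od=od,
        n_moves=n_moves, n_stops=n_stops, n_changes=len(bouts) - 1,
        id=seq.id)
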