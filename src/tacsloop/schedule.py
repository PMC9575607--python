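"""Timing skeleton of training and test runs.

A run is a sequence of stimulation blocks (20 s stimulation + 10 s rest by
default, 15 blocks per run), acquired at TR = 2 s, with a continuous 4-s
cognitive-task trial stream tiled over the whole run irrespective of block
boundaries.  Connectivity for a block is evaluated over a window the length
of the stimulation period, shifted 6 s to account for the hemodynamic
response delay (so the window for a block at onset t covers
[t + 6 s, t + 26 s), extending 6 s into the rest period).

All sample indexing is 0-based and half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .params import StimParams

__all__ = [
    "Block",
    "TrialEvent",
    "RunSchedule",
    "build_run_schedule",
    "tile_trials",
    "block_window_samples",
    "schedule_to_events",
]

HEMODYNAMIC_DELAY_S = 6.0


@dataclass(frozen=True)
class Block:
    """One stimulation block: ``stim_duration`` s of tACS then
    ``rest_duration`` s without stimulation."""

    index: int
    onset: float  # s
    stim_duration: float = 20.0  # s
    rest_duration: float = 10.0  # s
    params: StimParams | None = None  # filled in by the closed loop

    @property
    def duration(self) -> float:
        return self.stim_duration + self.rest_duration


@dataclass(frozen=True)
class TrialEvent:
    """One cognitive-task trial: stimulus/response phase then feedback."""

    onset: float  # s
    stim_phase: float = 2.5  # s, presentation + response
    feedback_phase: float = 1.5  # s

    @property
    def duration(self) -> float:
        return self.stim_phase + self.feedback_phase


@dataclass(frozen=True)
class RunSchedule:
    """Timing of one training or test run."""

    tr: float = 2.0  # s
    blocks: tuple[Block, ...] = ()
    trials: tuple[TrialEvent, ...] = ()

    @property
    def total_duration(self) -> float:
        return sum(b.duration for b in self.blocks)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.tr))


def build_run_schedule(
    n_blocks: int = 15,
    stim_s: float = 20.0,
    rest_s: float = 10.0,
    tr: float = 2.0,
) -> RunSchedule:
    """Lay out ``n_blocks`` contiguous stimulation blocks starting at 0 s.

    Warns (but still builds) if the TR does not evenly divide the block
    durations, since block windows then fall between samples.
    """
    if n_blocks <= 0:
        raise ValueError(f"n_blocks must be positive, got {n_blocks}")
    if stim_s <= 0 or rest_s <= 0 or tr <= 0:
        raise ValueError("durations and tr must be positive")
    for name, dur in (("stim", stim_s), ("rest", rest_s)):
        if abs(dur / tr - round(dur / tr)) > 1e-9:
            warnings.warn(
                f"tr = {tr} s does not divide the {name} duration {dur} s; "
                "window boundaries will be rounded to samples",
                stacklevel=2,
            )
    blocks = tuple(
        Block(index=i, onset=i * (stim_s + rest_s), stim_duration=stim_s, rest_duration=rest_s)
        for i in range(n_blocks)
    )
    return RunSchedule(tr=tr, blocks=blocks)


def tile_trials(run: RunSchedule, trial_s: float = 4.0) -> RunSchedule:
    """Tile the run contiguously with trials of ``trial_s`` seconds,
    keeping only trials that complete within the run."""
    if trial_s <= 0:
        raise ValueError(f"trial_s must be positive, got {trial_s}")
    total = run.total_duration
    n_trials = int(total / trial_s + 1e-9)
    frac = trial_s / 4.0
    trials = tuple(
        TrialEvent(onset=i * trial_s, stim_phase=2.5 * frac, feedback_phase=1.5 * frac)
        for i in range(n_trials)
    )
    return replace(run, trials=trials)


def block_window_samples(
    b: Block,
    tr: float,
    shift_s: float = HEMODYNAMIC_DELAY_S,
    window_s: float | None = None,
    run: RunSchedule | None = None,
) -> tuple[int, int]:
    """Half-open 0-based sample range of a block's evaluation window.

    The window starts ``shift_s`` after block onset (hemodynamic delay) and
    spans ``window_s`` seconds (the stimulation duration by default):
    start = round((onset + shift) / tr), length = round(window / tr).

    If ``run`` is given, a window extending past the end of the run raises
    a ValueError naming the block.
    """
    if shift_s < 0 or (window_s is not None and window_s < 0):
        raise ValueError("shift_s and window_s must be >= 0")
    if window_s is None:
        window_s = b.stim_duration
    start = int(round((b.onset + shift_s) / tr))
    length = int(round(window_s / tr))
    stop = start + length
    if run is not None and stop > run.n_samples:
        raise ValueError(
            f"window [{start}, {stop}) of block {b.index} extends past the run "
            f"({run.n_samples} samples)"
        )
    return start, stop


def schedule_to_events(run: RunSchedule) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, frequency,
    phase); one row per stimulation period, rest period, and task trial.
    Write with ``df.to_csv(path, sep="\\t", index=False, na_rep="n/a")``."""
    rows = []
    for b in run.blocks:
        freq = b.params.frequency if b.params else None
        phase = b.params.device_phase if b.params else None
        rows.append((b.onset, b.stim_duration, "stimulation", freq, phase))
        rows.append((b.onset + b.stim_duration, b.rest_duration, "rest", None, None))
    for t in run.trials:
        rows.append((t.onset, t.duration, "task_trial", None, None))
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "frequency", "phase"])
    return df.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)
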