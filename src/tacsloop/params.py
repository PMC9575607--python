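"""Stimulation parameters searched by the closed loop."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StimParams", "FREQ_MIN_HZ", "FREQ_MAX_HZ"]

FREQ_MIN_HZ = 1
FREQ_MAX_HZ = 150


@dataclass(frozen=True)
class StimParams:
    """One tACS setting: integer frequency (Hz) and inter-site phase
    difference (degrees).

    The stimulator accepts phases in [0, 359]; the optimizer works on an
    unwrapped phase axis (negative values allowed), so the stored
    ``phase_diff`` keeps the given value and :attr:`device_phase` reports it
    wrapped into the device range.
    """

    frequency: int  # Hz
    phase_diff: int  # degrees, possibly unwrapped

    def __post_init__(self) -> None:
        if not (FREQ_MIN_HZ <= self.frequency <= FREQ_MAX_HZ):
            raise ValueError(
                f"frequency {self.frequency} Hz outside [{FREQ_MIN_HZ}, {FREQ_MAX_HZ}]"
            )
        if self.frequency != int(self.frequency) or self.phase_diff != int(self.phase_diff):
            raise ValueError("stimulator parameters must be integers")

    @property
    def device_phase(self) -> int:
        """Phase wrapped into the stimulator's [0, 359] degree range."""
        return int(self.phase_diff) % 360
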