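"""Raw recording container: dual-wavelength intensities, events, behaviour."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .optics import WAVELENGTHS_NM

STIM_CONDITIONS = ("bimodal", "alternating")
CONDITIONS = STIM_CONDITIONS + ("baseline",)


@dataclass(frozen=True)
class Event:
    condition: str
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class RawRecording:
    """One participant's session.

    intensity has shape (n_channels, 2 wavelengths, n_samples), arbitrary
    units; ``looking`` holds one proportion-of-time-on-screen value in [0, 1]
    per stimulation trial, in trial order.
    """

    participant_id: str
    age_group: str  # "younger" | "older"
    sampling_rate: float
    intensity: np.ndarray
    events: list[Event]
    looking: np.ndarray
    channel_usable: Optional[np.ndarray] = None  # set by channel pruning
    wavelengths: tuple[float, float] = WAVELENGTHS_NM
    tested_during_pandemic: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.looking = np.asarray(self.looking, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def stim_events(self) -> list[Event]:
        return [e for e in self.events if e.condition in STIM_CONDITIONS]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.age_group not in ("younger", "older"):
            raise ValueError(f"bad age_group {self.age_group!r}")
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError(
                "intensity must be (n_channels, 2 wavelengths, n_samples); "
                f"got {self.intensity.shape}"
            )
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        last_end = -np.inf
        for e in self.events:
            if e.condition not in CONDITIONS:
                raise ValueError(f"unknown event condition {e.condition!r}")
            if e.duration_s <= 0:
                raise ValueError("event durations must be positive")
            if e.onset_s < last_end - 1e-9:
                raise ValueError(
                    f"events overlap or are unordered at onset {e.onset_s} s"
                )
            last_end = e.end_s
        n_stim = len(self.stim_events())
        if self.looking.shape != (n_stim,):
            raise ValueError(
                f"need one looking value per stimulation trial: "
                f"{self.looking.shape} vs {n_stim} trials"
            )
        if n_stim and (self.looking.min() < 0 or self.looking.max() > 1):
            raise ValueError("looking proportions must lie in [0, 1]")
        if self.channel_usable is not None:
            self.channel_usable = np.asarray(self.channel_usable, dtype=bool)
            if self.channel_usable.shape != (self.n_channels,):
                raise ValueError("channel_usable must have one flag per channel")
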