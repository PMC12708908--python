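"""Core containers shared across the pipeline.

The protocol records two participants over 12 two-minute intervals
(interval 0 = first baseline, 1..n_conv = conversation, n_conv+1 = second
baseline) on four autonomic channels: ECG, electrodermal activity (EDA,
microsiemens), respiration and skin temperature.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("ecg", "eda", "resp", "temp")

#: modalities on which inter-partner synchrony is computed
SYNC_MODALITIES = ("eda", "temp", "hr", "rr")


@dataclass(frozen=True)
class SignalInterval:
    """One channel of one participant in one 2-min interval."""

    dyad_id: int
    participant: int  # 1 | 2
    interval_index: int  # 0..11 with defaults
    channel: str
    sampling_rate: float  # Hz
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(
                f"non-finite samples in dyad {self.dyad_id} participant "
                f"{self.participant} interval {self.interval_index} {self.channel}"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class PeakTrain:
    """Detected events in one interval: R-peaks, breath peaks or SCRs.

    ``times`` are seconds from interval start and strictly increasing.  For
    skin-conductance responses ``valley_times`` and trough-to-peak
    ``amplitudes`` (microsiemens) are populated as well.
    """

    channel: str
    times: np.ndarray
    amplitudes: np.ndarray | None = None
    valley_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")
        for name in ("amplitudes", "valley_times"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RateSeries:
    """Evenly sampled instantaneous event-rate signal in events/minute."""

    kind: str  # "heart" | "respiration"
    sampling_rate: float  # output grid, Hz
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values <= 0):
            raise ValueError("rate values must be positive")


@dataclass
class DyadRecord:
    """One dyad's recording: signals, per-interval ratings, characteristics.

    ``signals`` maps (participant, interval_index, channel) to a
    :class:`SignalInterval`.  ``ratings`` has one row per
    (interval_index, participant, rater) with integer 1-9 ``valence`` /
    ``arousal`` plus the pre-rounding ``valence_raw`` / ``arousal_raw`` used
    by recoverability checks.  Observer rows use participant 0 (one rating
    per dyad-interval).  ``characteristics`` has one row per participant:
    age, gender, cognitive_empathy, affective_empathy, social_anxiety,
    depression.
    """

    dyad_id: int
    n_conversation_intervals: int
    signals: dict[tuple[int, int, str], SignalInterval] = field(default_factory=dict)
    ratings: pd.DataFrame | None = None
    characteristics: pd.DataFrame | None = None
    #: generative per-interval latent states (synthetic records only); columns
    #: interval_index, participant, valence, arousal, shared_valence,
    #: shared_arousal — used by oracle checks of coupling behaviour
    latents: pd.DataFrame | None = None

    @property
    def n_intervals(self) -> int:
        return self.n_conversation_intervals + 2

    @property
    def conversation_intervals(self) -> range:
        return range(1, self.n_conversation_intervals + 1)

    def interval(self, participant: int, interval_index: int, channel: str) -> SignalInterval:
        return self.signals[(participant, interval_index, channel)]
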