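"""In-memory containers for one participant's recording at each pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONDITIONS = ("preferred", "assigned", "preferred2")
CHROMOPHORES = ("HbO2", "HHb")


@dataclass(frozen=True)
class Annotation:
    """Condition block: half-open interval [onset, onset + duration) in seconds."""

    onset_s: float
    duration_s: float
    label: str

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def check_annotations(annotations: Sequence[Annotation]) -> None:
    ordered = sorted(annotations, key=lambda a: a.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset_s < a.end_s:
            raise ValueError(f"annotations overlap: {a.label} and {b.label}")


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str = "p00"
    gender: str = "female"
    age_years: float = 4.4


@dataclass
class RawRecording:
    """Raw dual-wavelength intensities plus accelerometer and condition blocks.

    intensity: (n_channels, 2, n_times), arbitrary units, strictly positive.
    accelerometer: (3, n_times) in g.
    """

    intensity: np.ndarray
    accelerometer: np.ndarray
    annotations: list[Annotation]
    sampling_rate_hz: float = 25.0
    meta: ParticipantMeta = field(default_factory=ParticipantMeta)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.accelerometer = np.asarray(self.accelerometer, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must have shape (n_channels, 2, n_times)")
        if self.accelerometer.shape != (3, self.intensity.shape[2]):
            raise ValueError("accelerometer must have shape (3, n_times)")
        check_annotations(self.annotations)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sampling_rate_hz

    def condition_slice(self, label: str) -> slice:
        for a in self.annotations:
            if a.label == label:
                fs = self.sampling_rate_hz
                return slice(int(round(a.onset_s * fs)), int(round(a.end_s * fs)))
        raise KeyError(f"no annotation labelled {label!r}")


@dataclass
class OdRecording:
    """Optical density change, (n_channels, 2, n_times); ``stage`` tracks pipeline order."""

    od: np.ndarray
    accelerometer: np.ndarray
    annotations: list[Annotation]
    sampling_rate_hz: float = 25.0
    meta: ParticipantMeta = field(default_factory=ParticipantMeta)
    stage: str = "od"

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]

    @property
    def n_times(self) -> int:
        return self.od.shape[2]

    def with_od(self, od: np.ndarray, stage: str) -> "OdRecording":
        return replace(self, od=od, stage=stage)

    def condition_slice(self, label: str) -> slice:
        return RawRecording.condition_slice(self, label)  # type: ignore[arg-type]


@dataclass
class ConcRecording:
    """Chromophore concentration changes in uM, (n_channels, 2, n_times).

    Axis 1 is (HbO2, HHb).  ``channel_mask`` marks channels that survived QC;
    non-surviving channels hold NaN.
    """

    conc: np.ndarray
    channel_mask: np.ndarray  # (n_channels,) bool
    accelerometer: np.ndarray
    annotations: list[Annotation]
    sampling_rate_hz: float = 25.0
    meta: ParticipantMeta = field(default_factory=ParticipantMeta)
    stage: str = "conc"

    @property
    def n_channels(self) -> int:
        return self.conc.shape[0]

    def condition_slice(self, label: str) -> slice:
        return RawRecording.condition_slice(self, label)  # type: ignore[arg-type]
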