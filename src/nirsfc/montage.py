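"""Physical array model: 48-channel dual-wavelength montage and its ROI assignment.

The array is two wearable continuous-wave units (763/841 nm, 25 Hz): one covering
the frontal lobe (channels 1-24), one the temporo-parietal regions bilaterally
(channels 25-48).  Source-detector separation is 25 mm except for the two
short-separation channels (12, frontal; 37, left temporal) at 10 mm, whose signal
is dominated by scalp/systemic physiology and serves as a nuisance regressor.

Channels are averaged into 10 cortical regions of interest (bilateral MPFC,
DLPFC, TPJ, M/STG, IPL).  The channel->ROI assignment ships as a static TSV
fixture (the pipeline default); :func:`build_roi_map` reproduces such an
assignment from anatomical labels plus per-channel placement overrides, and the
registration module recomputes labels geometrically when meshes are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

WAVELENGTHS_NM: tuple[float, float] = (763.0, 841.0)
SAMPLING_RATE_HZ: float = 25.0

N_CHANNELS = 48
SSC_CHANNELS: tuple[int, int] = (12, 37)
SD_DISTANCE_LONG_MM = 25.0
SD_DISTANCE_SHORT_MM = 10.0

ROI_LABELS: tuple[str, ...] = (
    "lMPFC", "rMPFC", "lDLPFC", "rDLPFC", "lTPJ", "rTPJ",
    "lM/STG", "rM/STG", "lIPL", "rIPL",
)
FRONTAL_ROIS: tuple[str, ...] = ("lMPFC", "rMPFC", "lDLPFC", "rDLPFC")
TEMPOROPARIETAL_ROIS: tuple[str, ...] = ("lTPJ", "rTPJ", "lM/STG", "rM/STG", "lIPL", "rIPL")
UNASSIGNED = "unassigned"


def fronto_temporoparietal_pairs() -> list[tuple[str, str]]:
    """The 24 frontal x temporo-parietal ROI pairs forming the FDR family."""
    return [(f, t) for f in FRONTAL_ROIS for t in TEMPOROPARIETAL_ROIS]


@dataclass(frozen=True)
class Channel:
    channel_id: int
    source_id: int
    detector_id: int
    sd_distance_mm: float
    is_short_separation: bool


@dataclass(frozen=True)
class Montage:
    """The physical array: channels, wavelengths, sampling rate."""

    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise ValueError(f"montage must have {N_CHANNELS} channels, got {len(self.channels)}")
        ssc = tuple(c.channel_id for c in self.channels if c.is_short_separation)
        if ssc != SSC_CHANNELS:
            raise ValueError(f"short-separation channels must be {SSC_CHANNELS}, got {ssc}")
        for c in self.channels:
            want = SD_DISTANCE_SHORT_MM if c.is_short_separation else SD_DISTANCE_LONG_MM
            if c.sd_distance_mm != want:
                raise ValueError(
                    f"channel {c.channel_id}: sd_distance {c.sd_distance_mm} mm, expected {want}"
                )

    @property
    def channel_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels]

    @property
    def ssc_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels if c.is_short_separation]

    @property
    def long_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels if not c.is_short_separation]

    def sd_distance_cm(self, channel_id: int) -> float:
        return self.channels[channel_id - 1].sd_distance_mm / 10.0


def default_montage() -> Montage:
    """The study's 48-channel array.

    Each unit carries 10 sources and 8 detectors; channel->optode wiring beyond the
    S-D distances is not used anywhere downstream, so a deterministic assignment
    (6 channels per source block) stands in for the vendor layout.
    """
    channels = []
    for cid in range(1, N_CHANNELS + 1):
        short = cid in SSC_CHANNELS
        channels.append(
            Channel(
                channel_id=cid,
                source_id=(cid - 1) // 6 + 1,
                detector_id=(cid - 1) % 8 + 1,
                sd_distance_mm=SD_DISTANCE_SHORT_MM if short else SD_DISTANCE_LONG_MM,
                is_short_separation=short,
            )
        )
    return Montage(channels=tuple(channels))


@dataclass(frozen=True)
class ChannelRoiMap:
    """channel_id -> ROI label (one of ROI_LABELS) or ``unassigned``."""

    assignment: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r for r in self.assignment.values()} - set(ROI_LABELS) - {UNASSIGNED}
        if bad:
            raise ValueError(f"unknown ROI labels: {sorted(bad)}")

    def roi_of(self, channel_id: int) -> str:
        return self.assignment.get(channel_id, UNASSIGNED)

    def channels_in_roi(self, roi: str) -> list[int]:
        return sorted(c for c, r in self.assignment.items() if r == roi)

    def present_rois(self) -> list[str]:
        return [r for r in ROI_LABELS if self.channels_in_roi(r)]


def _bundled_table() -> pd.DataFrame:
    with resources.as_file(resources.files("nirsfc.data") / "channel_roi_map.tsv") as p:
        return read_roi_table(p)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"channel_id", "anatomical_label", "roi"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table needs columns {sorted(required)}, got {list(df.columns)}")
    return df


def write_roi_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def default_roi_map() -> ChannelRoiMap:
    """The bundled channel->ROI assignment (the pipeline default)."""
    df = _bundled_table()
    return ChannelRoiMap(assignment=dict(zip(df["channel_id"], df["roi"])))


def default_anatomical_labels() -> dict[int, str]:
    df = _bundled_table()
    return dict(zip(df["channel_id"], df["anatomical_label"]))


# Anatomical-label -> ROI defaults.  Several gyri span two ROIs on this array
# (e.g. the right angular gyrus contributes to both rTPJ and rIPL); the bundled
# per-channel overrides below encode the placement-based disambiguation.
DEFAULT_LABEL_RULES: dict[str, str] = {
    "Right superior frontal gyrus": "rMPFC",
    "Right middle frontal gyrus": "rDLPFC",
    "Right inferior frontal gyrus": UNASSIGNED,
    "Left superior frontal gyrus": "lMPFC",
    "Left middle frontal gyrus": "lDLPFC",
    "Left inferior frontal gyrus": UNASSIGNED,
    "Right middle temporal gyrus": "rM/STG",
    "Right superior temporal gyrus": "rM/STG",
    "Right angular gyrus": "rTPJ",
    "Right supramarginal gyrus": "rIPL",
    "Left middle temporal gyrus": "lM/STG",
    "Left superior temporal gyrus": "lM/STG",
    "Left angular gyrus": "lTPJ",
    "Left supramarginal gyrus": "lIPL",
}

DEFAULT_CHANNEL_OVERRIDES: dict[int, str] = {
    4: "rMPFC", 6: "rMPFC",                      # medial-leaning middle frontal positions
    14: "lMPFC", 16: "lMPFC", 17: "lMPFC", 18: "lMPFC",
    33: "rTPJ",                                  # posterior superior temporal position
    35: "rIPL", 36: "rIPL",                      # ventral angular positions
    42: "lM/STG", 47: "lIPL",
    43: "lTPJ",                                  # anterior supramarginal position
}


def build_roi_map(
    labels: Mapping[int, str],
    rules: Mapping[str, str] | None = None,
    *,
    overrides: Mapping[int, str] | None = None,
    ssc_channels: tuple[int, ...] = SSC_CHANNELS,
) -> ChannelRoiMap:
    """Deterministically map anatomical labels to ROIs.

    ``rules`` maps anatomical label -> ROI; ``overrides`` maps channel_id -> ROI for
    channels whose gyrus spans two ROIs and whose assignment follows placement.
    Short-separation channels and unmatched labels map to ``unassigned``.
    Idempotent by construction.
    """
    if rules is None:
        rules = DEFAULT_LABEL_RULES
        if overrides is None:
            overrides = DEFAULT_CHANNEL_OVERRIDES
    overrides = overrides or {}
    assignment: dict[int, str] = {}
    for cid, label in labels.items():
        if cid in ssc_channels:
            assignment[cid] = UNASSIGNED
        elif cid in overrides:
            assignment[cid] = overrides[cid]
        else:
            assignment[cid] = rules.get(label, UNASSIGNED)
    return ChannelRoiMap(assignment=assignment)
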