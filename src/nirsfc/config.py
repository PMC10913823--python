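"""One configuration object holding every stage parameter, with the study defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # acquisition
    wavelengths_nm: tuple[float, float] = (763.0, 841.0)
    sampling_rate_hz: float = 25.0
    # wavelet motion correction
    wavelet_iqr: float = 0.8
    wavelet_family: str = "db2"
    # channel QC
    sci_threshold: float = 0.60
    psp_threshold: float = 0.06
    qc_window_s: float = 3.0
    bad_window_fraction: float = 0.60
    cardiac_band_hz: tuple[float, float] = (0.5, 2.5)
    saturation_check: bool = False
    saturation_ceiling: float | None = None
    # band-pass
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    # Beer-Lambert
    dpf: tuple[float, float] = (5.4, 4.6)
    # nuisance regression
    regress_per_condition: bool = True
    use_accelerometer: bool = True
    # connectivity
    min_window_s: float = 120.0
    # registration
    sphere_radius_mm: float = 12.5
    min_overlap_fraction: float = 0.25
    # group statistics
    fdr_q: float = 0.05
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
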