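"""Minimal SNIRF (HDF5) reader/writer for the study's recording layout.

Covers what the pipeline round-trips: dual-wavelength intensity time series
with a measurement list, 3-axis accelerometer as auxiliary channels, condition
blocks as stimulus groups, and participant metadata tags.  Follows the SNIRF
v1.0 group naming so files open in standard tools.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np

from .montage import Montage, default_montage
from .recording import Annotation, ParticipantMeta, RawRecording

logger = logging.getLogger(__name__)

_STR = h5py.string_dtype(encoding="utf-8")
_AUX_NAMES = ("ACCEL_X", "ACCEL_Y", "ACCEL_Z")


class SnirfFormatError(ValueError):
    pass


def write_snirf(raw: RawRecording, path: str | Path, montage: Montage | None = None) -> None:
    montage = montage or default_montage()
    n_ch, n_wl, n_t = raw.intensity.shape
    times = raw.times
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # columns ordered (channel, wavelength)
        flat = raw.intensity.reshape(n_ch * n_wl, n_t).T
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=times)
        for c in range(n_ch):
            ch = montage.channels[c]
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{c * n_wl + w + 1}")
                ml.create_dataset("sourceIndex", data=ch.source_id)
                ml.create_dataset("detectorIndex", data=ch.detector_id)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw_wavelengths(montage)))
        probe.create_dataset("sourcePos3D", data=np.zeros((10, 3)))
        probe.create_dataset("detectorPos3D", data=np.zeros((8, 3)))
        for i, ann in enumerate(raw.annotations):
            stim = nirs.create_group(f"stim{i + 1}")
            stim.create_dataset("name", data=ann.label, dtype=_STR)
            stim.create_dataset("data", data=np.array([[ann.onset_s, ann.duration_s, 1.0]]))
        for i, name in enumerate(_AUX_NAMES):
            aux = nirs.create_group(f"aux{i + 1}")
            aux.create_dataset("name", data=name, dtype=_STR)
            aux.create_dataset("dataTimeSeries", data=raw.accelerometer[i][:, None])
            aux.create_dataset("time", data=times)
        meta = nirs.create_group("metaDataTags")
        for key, val in {
            "SubjectID": raw.meta.participant_id,
            "MeasurementDate": "unknown",
            "MeasurementTime": "unknown",
            "LengthUnit": "mm",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
            "Gender": raw.meta.gender,
            "AgeYears": str(raw.meta.age_years),
        }.items():
            meta.create_dataset(key, data=val, dtype=_STR)


def raw_wavelengths(montage: Montage) -> tuple[float, float]:
    return montage.wavelengths_nm


def _require(f: h5py.File | h5py.Group, name: str):
    if name not in f:
        raise SnirfFormatError(f"SNIRF file is missing required group/dataset '{name}'")
    return f[name]


def read_snirf(path: str | Path, montage: Montage | None = None) -> RawRecording:
    """Load a recording; missing accelerometer auxiliaries degrade gracefully
    (zero traces plus a warning, so the nuisance design reduces downstream)."""
    montage = montage or default_montage()
    try:
        with h5py.File(path, "r") as f:
            _require(f, "formatVersion")
            nirs = _require(f, "nirs")
            data = _require(nirs, "data1")
            flat = np.asarray(_require(data, "dataTimeSeries"))
            times = np.asarray(_require(data, "time"))
            n_t = flat.shape[0]
            n_ch = flat.shape[1] // 2
            intensity = flat.T.reshape(n_ch, 2, n_t)
            fs = 1.0 / float(np.median(np.diff(times))) if n_t > 1 else 25.0

            annotations = []
            for key in sorted(k for k in nirs if k.startswith("stim")):
                stim = nirs[key]
                label = _as_str(_require(stim, "name")[()])
                for onset, dur, _amp in np.atleast_2d(np.asarray(_require(stim, "data"))):
                    annotations.append(Annotation(onset_s=float(onset),
                                                  duration_s=float(dur), label=label))

            accel = np.zeros((3, n_t))
            aux_found = 0
            for key in (k for k in nirs if k.startswith("aux")):
                aux = nirs[key]
                name = _as_str(_require(aux, "name")[()])
                if name in _AUX_NAMES:
                    accel[_AUX_NAMES.index(name)] = np.asarray(aux["dataTimeSeries"]).ravel()
                    aux_found += 1
            if aux_found < 3:
                logger.warning(
                    "%s: accelerometer auxiliaries missing (%d of 3 found); "
                    "nuisance design will be reduced", path, aux_found)

            meta_grp = nirs["metaDataTags"] if "metaDataTags" in nirs else None
            meta = ParticipantMeta(
                participant_id=_tag(meta_grp, "SubjectID", "unknown"),
                gender=_tag(meta_grp, "Gender", "unknown"),
                age_years=float(_tag(meta_grp, "AgeYears", "nan")),
            )
    except (OSError, KeyError) as exc:
        raise SnirfFormatError(f"cannot parse SNIRF file {path}: {exc}") from exc
    return RawRecording(
        intensity=intensity, accelerometer=accel,
        annotations=sorted(annotations, key=lambda a: a.onset_s),
        sampling_rate_hz=round(fs, 6), meta=meta,
    )


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def _tag(grp, key: str, default: str) -> str:
    if grp is not None and key in grp:
        return _as_str(grp[key][()])
    return default
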