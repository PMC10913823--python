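"""Per-participant signal chain, in fixed order:

    intensity -> optical density -> wavelet motion correction -> SCI/PSP channel
    pruning -> band-pass (0.009-0.08 Hz) -> modified Beer-Lambert conversion.

The order is enforced by stage tags on the records and asserted by the pipeline
runner.  Channel quality is scored on every channel (including short-separation
ones, which are exempt from ROI use but still pruned if decoupled from the
scalp); a channel is dropped when both the scalp-coupling index (SCI) and the
peak spectral power (PSP) fall below threshold in more than 60% of 3-s windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .montage import Montage, default_montage
from .recording import ConcRecording, OdRecording, RawRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# optical density

def intensity_to_od(raw: RawRecording) -> OdRecording:
    """OD(t) = -ln(I(t) / mean(I)) per channel and wavelength.

    Raises on non-positive intensity samples, identifying channel and sample.
    """
    I = raw.intensity
    bad = np.argwhere(I <= 0)
    if bad.size:
        ch, wl, t = bad[0]
        raise ValueError(
            f"non-positive intensity at channel {ch + 1}, wavelength index {wl}, sample {t}"
        )
    od = -np.log(I / I.mean(axis=2, keepdims=True))
    return OdRecording(
        od=od,
        accelerometer=raw.accelerometer,
        annotations=list(raw.annotations),
        sampling_rate_hz=raw.sampling_rate_hz,
        meta=raw.meta,
        stage="od",
    )


# ---------------------------------------------------------------------------
# wavelet motion correction

@dataclass(frozen=True)
class WaveletParams:
    """IQR-outlier wavelet correction parameters.

    ``max_level`` None selects the depth automatically so that the
    approximation band still contains everything below ``protect_hz``: motion
    transients are broadband and land in the detail levels, while the slow
    connectivity band is never touched by the outlier rule (zeroing in-band
    coefficients of clean data would bias FC estimates downward).
    """

    iqr_multiplier: float = 0.8
    wavelet_family: str = "db2"
    max_level: int | None = None  # None -> auto from protect_hz
    protect_hz: float = 0.09      # just above the 0.08 Hz analysis band edge

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")

    def level_for(self, n_samples: int, fs: float) -> int:
        wav = pywt.Wavelet(self.wavelet_family)
        data_max = pywt.dwt_max_level(n_samples, wav.dec_len)
        if self.max_level is not None:
            return min(self.max_level, data_max)
        # details after L levels cover (fs / 2**(L+1), fs/2); keep protect_hz below
        auto = int(np.floor(np.log2(fs / self.protect_hz))) - 1
        return max(min(auto, data_max), 0)


def _wavelet_correct_1d(x: np.ndarray, fs: float, params: WaveletParams) -> np.ndarray:
    wav = pywt.Wavelet(params.wavelet_family)
    level = params.level_for(len(x), fs)
    if level < 1:
        warnings.warn("series too short for one wavelet level; passing through")
        return x.copy()
    coeffs = pywt.wavedec(x, wav, mode="symmetric", level=level)
    k = params.iqr_multiplier
    for d in coeffs[1:]:  # approximation coefficients untouched
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        outlier = (d < q1 - k * iqr) | (d > q3 + k * iqr)
        d[outlier] = 0.0
    rec = pywt.waverec(coeffs, wav, mode="symmetric")
    return rec[: len(x)]


def wavelet_motion_correct(od: OdRecording, params: WaveletParams = WaveletParams()) -> OdRecording:
    """Zero outlying detail coefficients (quartile +- iqr_multiplier * IQR) per level.

    Motion spikes and baseline steps concentrate in few large detail
    coefficients; band-limited physiological content survives the thresholding
    nearly unchanged.
    """
    out = np.empty_like(od.od)
    for c in range(od.od.shape[0]):
        for w in range(od.od.shape[1]):
            out[c, w] = _wavelet_correct_1d(od.od[c, w], od.sampling_rate_hz, params)
    return od.with_od(out, stage="wavelet")


# ---------------------------------------------------------------------------
# channel quality (SCI / PSP)

@dataclass(frozen=True)
class QcParams:
    window_s: float = 3.0
    sci_threshold: float = 0.60
    psp_threshold: float = 0.06
    bad_window_fraction: float = 0.60
    cardiac_band_hz: tuple[float, float] = (0.5, 2.5)

    def __post_init__(self) -> None:
        if self.sci_threshold <= 0 or self.psp_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.bad_window_fraction <= 1:
            raise ValueError("bad_window_fraction must be in (0, 1]")


@dataclass
class ChannelQc:
    channel_id: int
    sci: np.ndarray
    psp: np.ndarray
    fraction_bad: float
    keep: bool
    is_short_separation: bool = False
    saturation_flag: bool = False


@dataclass
class QcReport:
    channels: dict[int, ChannelQc] = field(default_factory=dict)
    params: QcParams = QcParams()

    def kept_ids(self) -> list[int]:
        return sorted(c for c, q in self.channels.items() if q.keep)

    def dropped_ids(self) -> list[int]:
        return sorted(c for c, q in self.channels.items() if not q.keep)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel_id": q.channel_id,
                "n_windows": len(q.sci),
                "fraction_bad": q.fraction_bad,
                "verdict": "keep" if q.keep else "drop",
                "is_short_separation": q.is_short_separation,
                "saturation_flag": q.saturation_flag,
            }
            for q in self.channels.values()
        ]
        return pd.DataFrame(rows).sort_values("channel_id").reset_index(drop=True)


def _cardiac_filter(fs: float, band: tuple[float, float]) -> np.ndarray:
    return sps.butter(3, band, btype="bandpass", fs=fs, output="sos")


def sci_psp_windows(od: OdRecording, params: QcParams = QcParams()) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-channel (SCI, PSP) over non-overlapping windows.

    Both wavelengths are band-passed to the cardiac band over the whole series,
    then z-normalised within each window.  SCI is their Pearson correlation in
    the window; PSP is the peak of the power spectrum of their biased
    cross-correlation sequence, restricted to the cardiac band.  Zero-variance
    windows score (0, 0).
    """
    fs = od.sampling_rate_hz
    nwin = int(round(params.window_s * fs))
    n_times = od.n_times
    n_windows = n_times // nwin
    if n_windows < 1:
        raise ValueError("recording shorter than one QC window")
    sos = _cardiac_filter(fs, params.cardiac_band_hz)
    filtered = sps.sosfiltfilt(sos, od.od, axis=2)

    # frequency grid of the length-(2*nwin-1) cross-correlation sequence
    nxc = 2 * nwin - 1
    freqs = np.fft.rfftfreq(nxc, d=1.0 / fs)
    band_mask = (freqs >= params.cardiac_band_hz[0]) & (freqs <= params.cardiac_band_hz[1])

    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for c in range(od.n_channels):
        sci = np.zeros(n_windows)
        psp = np.zeros(n_windows)
        for w in range(n_windows):
            seg = filtered[c, :, w * nwin : (w + 1) * nwin]
            s0, s1 = seg[0].std(), seg[1].std()
            if s0 == 0 or s1 == 0:
                logger.debug("zero-variance QC window %d on channel %d", w, c + 1)
                continue
            z0 = (seg[0] - seg[0].mean()) / s0
            z1 = (seg[1] - seg[1].mean()) / s1
            sci[w] = float(np.dot(z0, z1) / nwin)
            xc = np.correlate(z0, z1, mode="full") / nwin
            # normalised so a perfectly coupled cardiac sinusoid scores ~0.25
            # and uncorrelated noise stays well under the 0.06 threshold
            spectrum = np.abs(np.fft.rfft(xc)) ** 2 / nwin**2
            psp[w] = float(spectrum[band_mask].max())
        out[c + 1] = (sci, psp)
    return out


def prune_channels(
    windows: dict[int, tuple[np.ndarray, np.ndarray]],
    params: QcParams = QcParams(),
    montage: Montage | None = None,
    saturation_flags: dict[int, bool] | None = None,
) -> QcReport:
    """Drop a channel iff strictly more than ``bad_window_fraction`` of windows are
    bad on BOTH measures (SCI < threshold AND PSP < threshold)."""
    montage = montage or default_montage()
    ssc = set(montage.ssc_ids) if montage else set()
    saturation_flags = saturation_flags or {}
    report = QcReport(params=params)
    for cid, (sci, psp) in windows.items():
        bad = (sci < params.sci_threshold) & (psp < params.psp_threshold)
        frac = float(bad.mean())
        keep = not (frac > params.bad_window_fraction)
        if saturation_flags.get(cid, False):
            keep = False
        report.channels[cid] = ChannelQc(
            channel_id=cid, sci=sci, psp=psp, fraction_bad=frac, keep=keep,
            is_short_separation=cid in ssc,
            saturation_flag=saturation_flags.get(cid, False),
        )
    return report


def flag_saturation(raw: RawRecording, ceiling: float, max_fraction: float = 0.05) -> dict[int, bool]:
    """Automated stand-in for manual visual inspection: flag channels whose
    intensity sits at the sensor ceiling in more than ``max_fraction`` of samples.
    Off by default in the pipeline."""
    at_ceiling = (raw.intensity >= ceiling).mean(axis=(1, 2))
    return {c + 1: bool(f > max_fraction) for c, f in enumerate(at_ceiling)}


# ---------------------------------------------------------------------------
# band-pass

def bandpass(
    od: OdRecording, low_hz: float = 0.009, high_hz: float = 0.08, order: int = 3
) -> OdRecording:
    """Zero-phase Butterworth band-pass isolating slow spontaneous fluctuations."""
    fs = od.sampling_rate_hz
    nyq = fs / 2
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band edges ({low_hz}, {high_hz}) outside (0, {nyq}) or inverted")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, od.od, axis=2)
    return od.with_od(out, stage="bandpass")


def bandpass_array(x: np.ndarray, fs: float, low_hz: float = 0.009, high_hz: float = 0.08,
                   order: int = 3, axis: int = -1) -> np.ndarray:
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


# ---------------------------------------------------------------------------
# modified Beer-Lambert law

def load_extinction_table() -> pd.DataFrame:
    """Bundled molar extinction coefficients, 1/(mM*cm), at 763 and 841 nm."""
    with resources.as_file(resources.files("nirsfc.data") / "extinction_coefficients.tsv") as p:
        return pd.read_csv(p, sep="\t", comment="#")


@dataclass(frozen=True)
class MbllParams:
    """Differential pathlength factors and the extinction system.

    ``dpf`` pairs with the wavelengths in order: 5.4 at 763 nm, 4.6 at 841 nm
    (higher DPF conventionally at the lower wavelength).  ``extinction`` is a
    (2, 2) array, rows = wavelengths, columns = (HbO2, HHb), in 1/(mM*cm).
    """

    dpf: tuple[float, float] = (5.4, 4.6)
    extinction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf must be > 0")
        if self.extinction is None:
            tab = load_extinction_table()
            object.__setattr__(self, "extinction", tab[["e_hbo2", "e_hhb"]].to_numpy())
        eps = np.asarray(self.extinction, dtype=float)
        if eps.shape != (2, 2) or abs(np.linalg.det(eps)) < 1e-12:
            raise ValueError("extinction matrix must be (2, 2) and invertible")

    def system_matrix(self, sd_distance_cm: float) -> np.ndarray:
        """M with dOD = M @ (dHbO2, dHHb) [mM]: M[l, k] = d * DPF_l * eps[l, k]."""
        return sd_distance_cm * np.diag(self.dpf) @ np.asarray(self.extinction)


def mbll(
    od: OdRecording,
    params: MbllParams = MbllParams(),
    montage: Montage | None = None,
    channel_mask: np.ndarray | None = None,
) -> ConcRecording:
    """Invert the modified Beer-Lambert system per channel and time point.

    Solves dOD_l = d * DPF_l * (e_HbO2,l * dHbO2 + e_HHb,l * dHHb) for the two
    chromophores; output in uM.  Channels outside ``channel_mask`` are NaN.
    """
    montage = montage or default_montage()
    n_ch, _, n_t = od.od.shape
    if channel_mask is None:
        channel_mask = np.ones(n_ch, dtype=bool)
    conc = np.full((n_ch, 2, n_t), np.nan)
    for c in range(n_ch):
        if not channel_mask[c]:
            continue
        M = params.system_matrix(montage.sd_distance_cm(c + 1))
        conc[c] = np.linalg.solve(M, od.od[c]) * 1000.0  # mM -> uM
    return ConcRecording(
        conc=conc,
        channel_mask=np.asarray(channel_mask, dtype=bool),
        accelerometer=od.accelerometer,
        annotations=list(od.annotations),
        sampling_rate_hz=od.sampling_rate_hz,
        meta=od.meta,
        stage="conc",
    )


def forward_mbll(
    conc_um: np.ndarray,
    params: MbllParams = MbllParams(),
    montage: Montage | None = None,
) -> np.ndarray:
    """Map concentrations (n_channels, 2, n_times; uM) to optical densities.

    The exact forward of :func:`mbll`; the synthetic generator uses this so the
    analysis-side inversion is a true round-trip.
    """
    montage = montage or default_montage()
    n_ch = conc_um.shape[0]
    od = np.empty_like(conc_um)
    for c in range(n_ch):
        M = params.system_matrix(montage.sd_distance_cm(c + 1))
        od[c] = M @ (conc_um[c] / 1000.0)
    return od
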