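"""Synthetic cohorts with known ground truth.

The generator is the forward model of the analysis chain run backwards: latent
band-limited (0.009-0.08 Hz) neural fluctuations with a prescribed inter-ROI
correlation structure are mixed into channel concentrations, shared systemic
oscillations (cardiac ~1.1 Hz, Mayer ~0.1 Hz, respiration ~0.3 Hz) are added to
every channel including the two short-separation ones (which carry no neural
content by construction), concentrations are mapped to optical density through
the same modified Beer-Lambert system the analysis inverts, and drift, motion
artifacts (accelerometer-coupled spikes and baseline shifts, added in OD
space) and optical gain/noise produce raw intensities.

Because the ground truth (target correlations, nuisance parameters, latent
series) is stored alongside each recording, every downstream stage is testable
by parameter recovery rather than against withheld human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import (ROI_LABELS, UNASSIGNED, ChannelRoiMap, Montage,
                      default_montage, default_roi_map)
from .preprocess import MbllParams, bandpass_array, forward_mbll
from .recording import Annotation, ParticipantMeta, RawRecording

AVATARS = ("girl", "boy", "woman", "man")
AVATAR_AGE = {"girl": "toddler", "boy": "toddler", "woman": "adult", "man": "adult"}
AVATAR_GENDER = {"girl": "female", "boy": "male", "woman": "female", "man": "male"}


# ---------------------------------------------------------------------------
# ground-truth specification

@dataclass(frozen=True)
class SystemicComponent:
    center_freq_hz: float
    amplitude_um: float
    freq_jitter: float  # phase-noise step SD, rad per sample


DEFAULT_SYSTEMIC = (
    SystemicComponent(1.1, 0.40, 0.02),   # cardiac (child heart rate ~66 bpm)
    SystemicComponent(0.10, 0.20, 0.01),  # Mayer waves
    SystemicComponent(0.30, 0.15, 0.01),  # respiration
)


@dataclass(frozen=True)
class MotionSpec:
    spike_rate_per_min: float = 2.0
    spike_amplitude_od: float = 0.05
    shift_rate_per_min: float = 0.5
    shift_amplitude_od: float = 0.02
    accel_coupling: float = 1.0


@dataclass(frozen=True)
class GroundTruthSpec:
    """Targets and nuisance parameters for one condition's recording segment.

    roi_correlation is the 10x10 target correlation of the latent neural series
    (order follows ROI_LABELS); amplitudes are uM unless noted.
    """

    roi_correlation: np.ndarray = None  # type: ignore[assignment]
    neural_band_hz: tuple[float, float] = (0.009, 0.08)
    neural_amplitude_um: float = 0.5
    hbo_hhb_ratio: float = -0.4
    hhb_noise_um: float = 0.05
    systemic: tuple[SystemicComponent, ...] = DEFAULT_SYSTEMIC
    systemic_hhb_ratio: float = 0.25
    drift_slope_od_per_s: float = 2e-5
    motion: MotionSpec = MotionSpec()
    channel_noise_sd_um: float = 0.10
    od_noise_sd: float = 3e-4
    optical_gain_sigma: float = 0.3
    baseline_intensity: float = 1.0
    condition_length_s: float = 180.0

    def __post_init__(self) -> None:
        C = np.eye(len(ROI_LABELS)) if self.roi_correlation is None else np.asarray(
            self.roi_correlation, dtype=float)
        object.__setattr__(self, "roi_correlation", C)
        validate_correlation(C, name="roi_correlation")
        for val, nm in [
            (self.neural_amplitude_um, "neural_amplitude_um"),
            (self.hhb_noise_um, "hhb_noise_um"),
            (self.channel_noise_sd_um, "channel_noise_sd_um"),
            (self.od_noise_sd, "od_noise_sd"),
            (self.motion.spike_rate_per_min, "spike_rate_per_min"),
            (self.motion.shift_rate_per_min, "shift_rate_per_min"),
        ]:
            if val < 0:
                raise ValueError(f"{nm} must be >= 0")

    def noise_free(self) -> "GroundTruthSpec":
        """Copy with every nuisance amplitude zeroed (the oracle configuration)."""
        return replace(
            self,
            systemic=tuple(replace(s, amplitude_um=0.0) for s in self.systemic),
            drift_slope_od_per_s=0.0,
            motion=MotionSpec(spike_rate_per_min=0.0, shift_rate_per_min=0.0),
            channel_noise_sd_um=0.0,
            hhb_noise_um=0.0,
            od_noise_sd=0.0,
            optical_gain_sigma=0.0,
        )


def validate_correlation(C: np.ndarray, name: str = "correlation") -> None:
    if C.shape != (len(ROI_LABELS), len(ROI_LABELS)):
        raise ValueError(f"{name} must be {len(ROI_LABELS)}x{len(ROI_LABELS)}")
    if not np.allclose(C, C.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError(f"{name} does not have a unit diagonal")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {w.min():.3e})"
        )


def correlation_with_pairs(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    """Identity correlation with the given ROI-pair entries set to r."""
    C = np.eye(len(ROI_LABELS))
    idx = {r: i for i, r in enumerate(ROI_LABELS)}
    for (a, b), r in pairs.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    validate_correlation(C)
    return C


# ---------------------------------------------------------------------------
# latent neural series

def latent_roi_series(
    C: np.ndarray, n_times: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """(10, n_times) jointly Gaussian series with correlation C, band-limited.

    Synthesised in the frequency domain: independent complex Gaussian Fourier
    coefficients are shaped by a third-order Butterworth band-pass magnitude and
    mixed across ROIs by a factor of C, so the target cross-correlation holds
    exactly at every frequency and the series are circularly stationary (no
    filter edge transients).  Each series is rescaled to unit sample variance;
    Pearson correlation is scale-free, so targets are unaffected.
    """
    w, V = np.linalg.eigh(C)
    factor = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    freqs = np.fft.rfftfreq(n_times, d=1.0 / fs)
    low, high = band
    with np.errstate(divide="ignore"):
        mag = np.sqrt(
            1.0 / (1.0 + (low / np.maximum(freqs, 1e-12)) ** 6)
            / (1.0 + (freqs / high) ** 6)
        )
    mag[0] = 0.0
    n_roi = C.shape[0]
    coeff = (rng.standard_normal((n_roi, freqs.size))
             + 1j * rng.standard_normal((n_roi, freqs.size))) * mag
    x = np.fft.irfft(factor @ coeff, n=n_times)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# participant-level forward model

@dataclass
class ParticipantTruth:
    """Ground truth stored beside a simulated recording."""

    spec_per_condition: dict[str, GroundTruthSpec]
    latents: np.ndarray          # (10, n_times); zero outside condition blocks
    seed: int
    meta: ParticipantMeta = field(default_factory=ParticipantMeta)


def _systemic_series(spec: GroundTruthSpec, n_times: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_times) / fs
    out = np.zeros(n_times)
    for comp in spec.systemic:
        phase0 = rng.uniform(0, 2 * np.pi)
        jitter = np.cumsum(rng.normal(0.0, comp.freq_jitter, n_times))
        out += comp.amplitude_um * np.sin(2 * np.pi * comp.center_freq_hz * t + phase0 + jitter)
    return out


def _motion_od(spec: GroundTruthSpec, n_channels: int, n_times: int, fs: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Motion artifacts in OD space plus the matched accelerometer transients."""
    minutes = n_times / fs / 60.0
    od = np.zeros((n_channels, n_times))
    accel = np.zeros((3, n_times))
    t = np.arange(n_times) / fs
    m = spec.motion

    n_spikes = rng.poisson(m.spike_rate_per_min * minutes)
    n_shifts = rng.poisson(m.shift_rate_per_min * minutes)
    for _ in range(n_spikes):
        center = rng.uniform(0, n_times / fs)
        sigma = rng.uniform(0.25, 0.75)            # 1-3 s Gaussian transient
        amp = m.spike_amplitude_od * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
        pulse = np.exp(-0.5 * ((t - center) / sigma) ** 2)
        per_ch = rng.uniform(0.5, 1.5, n_channels)
        od += amp * per_ch[:, None] * pulse[None, :]
        axis = rng.integers(0, 3)
        accel[axis] += m.accel_coupling * abs(amp) * 10.0 * pulse
    for _ in range(n_shifts):
        onset = rng.integers(0, n_times)
        amp = m.shift_amplitude_od * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
        per_ch = rng.uniform(0.5, 1.5, n_channels)
        od[:, onset:] += amp * per_ch[:, None]
        axis = rng.integers(0, 3)
        pulse = np.exp(-0.5 * ((t - onset / fs) / 0.3) ** 2)
        accel[axis] += m.accel_coupling * abs(amp) * 10.0 * pulse
    return od, accel


def default_condition_specs(conditions: tuple[str, ...] = ("preferred", "assigned"),
                            ) -> dict[str, GroundTruthSpec]:
    return {c: GroundTruthSpec() for c in conditions}


def simulate_participant(
    specs: dict[str, GroundTruthSpec] | GroundTruthSpec,
    montage: Montage | None = None,
    roi_map: ChannelRoiMap | None = None,
    seed: int = 0,
    meta: ParticipantMeta | None = None,
    gap_s: float = 10.0,
    pad_s: float = 5.0,
    mbll_params: MbllParams | None = None,
) -> tuple[RawRecording, ParticipantTruth]:
    """Simulate one participant's raw recording plus its latent ROI series.

    ``specs`` maps condition label -> GroundTruthSpec (a bare spec means a
    single 'preferred' block).  Condition blocks of ``condition_length_s`` are
    separated by ``gap_s`` of latent-free recording.  Bit-reproducible for a
    fixed seed.
    """
    if isinstance(specs, GroundTruthSpec):
        specs = {"preferred": specs}
    montage = montage or default_montage()
    roi_map = roi_map or default_roi_map()
    mbll_params = mbll_params or MbllParams()
    meta = meta or ParticipantMeta()
    rng = np.random.default_rng(seed)
    fs = montage.sampling_rate_hz
    n_ch = len(montage.channels)

    annotations = []
    cursor = pad_s
    for label, spec in specs.items():
        annotations.append(Annotation(onset_s=cursor, duration_s=spec.condition_length_s,
                                      label=label))
        cursor += spec.condition_length_s + gap_s
    total_s = cursor - gap_s + pad_s
    n_times = int(round(total_s * fs))

    first_spec = next(iter(specs.values()))
    latents = np.zeros((len(ROI_LABELS), n_times))
    conc = np.zeros((n_ch, 2, n_times))  # (channel, chromophore, time), uM

    roi_index = {r: i for i, r in enumerate(ROI_LABELS)}
    ssc = set(montage.ssc_ids)

    for ann in annotations:
        spec = specs[ann.label]
        sl = slice(int(round(ann.onset_s * fs)), int(round(ann.end_s * fs)))
        n_seg = sl.stop - sl.start
        lat = latent_roi_series(spec.roi_correlation, n_seg, fs, spec.neural_band_hz, rng)
        latents[:, sl] = lat
        for c in range(n_ch):
            cid = c + 1
            roi = roi_map.roi_of(cid)
            if cid in ssc or roi == UNASSIGNED:
                continue
            hbo = spec.neural_amplitude_um * lat[roi_index[roi]]
            conc[c, 0, sl] += hbo

    # channel noise, HHb coupling, shared systemic (whole recording)
    spec = first_spec
    systemic_hbo = _systemic_series(spec, n_times, fs, rng)
    for c in range(n_ch):
        noise = rng.normal(0.0, spec.channel_noise_sd_um, n_times)
        conc[c, 0] += noise + systemic_hbo
        conc[c, 1] = (
            spec.hbo_hhb_ratio * (conc[c, 0] - systemic_hbo)
            + spec.systemic_hhb_ratio * systemic_hbo
            + rng.normal(0.0, spec.hhb_noise_um, n_times)
        )

    od = forward_mbll(conc, mbll_params, montage)

    # drift and motion in OD space
    t = np.arange(n_times) / fs
    drift_slopes = rng.uniform(-spec.drift_slope_od_per_s, spec.drift_slope_od_per_s,
                               (n_ch, 2)) if spec.drift_slope_od_per_s > 0 else np.zeros((n_ch, 2))
    od += drift_slopes[:, :, None] * t[None, None, :]
    motion_od, motion_accel = _motion_od(spec, n_ch, n_times, fs, rng)
    od += motion_od[:, None, :]
    if spec.od_noise_sd > 0:
        od += rng.normal(0.0, spec.od_noise_sd, od.shape)

    gains = spec.baseline_intensity * np.exp(
        rng.normal(0.0, spec.optical_gain_sigma, (n_ch, 2))
    )
    intensity = gains[:, :, None] * np.exp(-od)

    accel = np.vstack([
        rng.normal(0.0, 0.005, (2, n_times)),
        1.0 + rng.normal(0.0, 0.005, (1, n_times)),
    ])
    accel += motion_accel

    raw = RawRecording(intensity=intensity, accelerometer=accel, annotations=annotations,
                       sampling_rate_hz=fs, meta=meta)
    truth = ParticipantTruth(spec_per_condition=dict(specs), latents=latents, seed=seed,
                             meta=meta)
    return raw, truth


# ---------------------------------------------------------------------------
# cohort level

@dataclass
class CohortDataset:
    recordings: list[RawRecording]
    truths: list[ParticipantTruth]
    master_seed: int


def participant_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-participant seeds derived from the master seed
    (SeedSequence spawning, i.e. a documented counter-based derivation)."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(master_seed).spawn(n)]


def apply_effect(base: np.ndarray, effect: list[tuple[tuple[str, str], float]]) -> np.ndarray:
    """Return a copy of ``base`` with Delta-r added on the listed ROI pairs."""
    C = base.copy()
    idx = {r: i for i, r in enumerate(ROI_LABELS)}
    for (a, b), dr in effect:
        C[idx[a], idx[b]] += dr
        C[idx[b], idx[a]] += dr
    validate_correlation(C, name="effect-adjusted correlation")
    return C


def simulate_cohort(
    n_participants: int = 32,
    specs: dict[str, GroundTruthSpec] | None = None,
    effect: list[tuple[tuple[str, str], float]] | None = None,
    seed: int = 0,
    montage: Montage | None = None,
    roi_map: ChannelRoiMap | None = None,
    female_fraction: float = 15 / 37,
) -> CohortDataset:
    """Simulate a two-condition cohort (default n=32, mirroring the study).

    ``effect`` lists (roi_pair, Delta-r) added to the 'preferred' condition's
    correlation relative to 'assigned'.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if specs is None:
        specs = default_condition_specs()
    if effect:
        pref = specs.get("preferred", GroundTruthSpec())
        specs = dict(specs)
        specs["preferred"] = replace(
            pref, roi_correlation=apply_effect(pref.roi_correlation, effect))
    seeds = participant_seeds(seed, n_participants)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    recordings, truths = [], []
    for i, s in enumerate(seeds):
        gender = "female" if rng.random() < female_fraction else "male"
        meta = ParticipantMeta(participant_id=f"p{i:02d}", gender=gender,
                               age_years=float(np.clip(rng.normal(4.4, 0.8), 3.0, 5.9)))
        rec, truth = simulate_participant(specs, montage, roi_map, seed=s, meta=meta)
        recordings.append(rec)
        truths.append(truth)
    return CohortDataset(recordings=recordings, truths=truths, master_seed=seed)


def simulate_roi_cohort(
    n_participants: int,
    correlations: dict[str, np.ndarray],
    seed: int = 0,
    duration_s: float = 180.0,
    fs: float = 25.0,
    band: tuple[float, float] = (0.009, 0.08),
) -> list[dict[str, np.ndarray]]:
    """ROI-level fast path: latent (10, T) series per condition per participant.

    Skips the optical forward model; used for large Monte-Carlo calibrations of
    the connectivity and group-statistics layers.
    """
    n_times = int(round(duration_s * fs))
    out = []
    for s in participant_seeds(seed, n_participants):
        rng = np.random.default_rng(s)
        out.append({
            cond: latent_roi_series(np.asarray(C, dtype=float), n_times, fs, band, rng)
            for cond, C in correlations.items()
        })
    return out


# ---------------------------------------------------------------------------
# behaviour

# Per-gender avatar-choice probabilities consistent with the printed margins
# (females: 13/15 toddler, 12/15 same-gender; males: 12/22 toddler, 11/22 same-gender).
DEFAULT_CHOICE_PROBS: dict[str, dict[str, float]] = {
    "female": {"girl": 11 / 15, "boy": 2 / 15, "woman": 1 / 15, "man": 1 / 15},
    "male": {"girl": 8 / 22, "boy": 4 / 22, "woman": 3 / 22, "man": 7 / 22},
}

DEFAULT_BUBBLE_RATE = {"preferred": 30.0, "assigned": 30.0}


def simulate_behaviour(
    n: int = 37,
    choice_probs: dict[str, dict[str, float]] | None = None,
    bubble_rate: dict[str, float] | None = None,
    seed: int = 0,
    female_fraction: float = 15 / 37,
) -> pd.DataFrame:
    """Behavioural table: one avatar choice per participant, Poisson bubble counts.

    Bubble counts are drawn for the participant and for the avatar in each
    condition; both default to equal rates across conditions (the study found
    no condition difference).
    """
    choice_probs = choice_probs or DEFAULT_CHOICE_PROBS
    bubble_rate = bubble_rate or DEFAULT_BUBBLE_RATE
    for g, probs in choice_probs.items():
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"choice probabilities for {g!r} sum to {total}, not 1")
        if any(p < 0 for p in probs.values()):
            raise ValueError(f"negative choice probability for {g!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        gender = "female" if rng.random() < female_fraction else "male"
        probs = choice_probs[gender]
        avatar = rng.choice(AVATARS, p=[probs[a] for a in AVATARS])
        age = float(np.clip(rng.normal(4.4, 0.8), 3.0, 5.9))
        row = {
            "participant_id": f"p{i:02d}",
            "gender": gender,
            "age_years": age,
            "chosen_avatar": str(avatar),
        }
        for cond, rate in bubble_rate.items():
            row[f"bubbles_{cond}"] = int(rng.poisson(rate))
            row[f"avatar_bubbles_{cond}"] = int(rng.poisson(rate / 6.0))
        rows.append(row)
    df = pd.DataFrame(rows)
    median_age = df["age_years"].median()
    df["age_group"] = np.where(df["age_years"] <= median_age, "younger", "older")
    return df
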