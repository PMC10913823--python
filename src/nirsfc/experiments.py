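"""Monte-Carlo experiments over synthetic cohorts.

The study's group-level connectivity results cannot be recomputed without the
participant recordings, so the pipeline is validated by parameter recovery,
null calibration and power analyses on cohorts whose ground truth is known.
Problem sizes default to the study's (n=32 participants, 3-minute conditions);
replicate counts are chosen so each experiment runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .connectivity import fc_from_series
from .montage import ROI_LABELS, fronto_temporoparietal_pairs
from .pipeline import participant_fc
from .simulate import (GroundTruthSpec, apply_effect, correlation_with_pairs,
                       simulate_participant, simulate_roi_cohort)
from .stats import FdrFamily, bh_fdr, paired_t

_IDX = {r: i for i, r in enumerate(ROI_LABELS)}
DEFAULT_PAIR = ("lMPFC", "rTPJ")


@dataclass
class RecoveryResult:
    target_r: float
    mean_r: float
    sd_r: float
    oracle_mean_r: float
    oracle_sd_r: float
    n_participants: int

    @property
    def oracle_band(self) -> tuple[float, float]:
        """95% Monte-Carlo band for the mean of n oracle-run estimates."""
        half = 1.96 * self.oracle_sd_r / np.sqrt(self.n_participants)
        return (self.oracle_mean_r - half, self.oracle_mean_r + half)

    @property
    def within_band(self) -> bool:
        # two-sample comparison: realistic mean vs oracle mean, both estimated
        se = 1.96 * np.sqrt(self.sd_r**2 + self.oracle_sd_r**2) / np.sqrt(self.n_participants)
        return abs(self.mean_r - self.oracle_mean_r) <= se


def parameter_recovery(
    target_r: float = 0.6,
    pair: tuple[str, str] = DEFAULT_PAIR,
    n_participants: int = 50,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> RecoveryResult:
    """Run the full optical pipeline on cohorts with a known inter-ROI target.

    The realistic cohort carries every nuisance source at its default
    amplitude; the oracle cohort is the same generator with all nuisance
    amplitudes zeroed.  Both are analysed by the identical pipeline, and the
    realistic mean estimate is compared with the oracle Monte-Carlo band.
    """
    config = config or PipelineConfig()
    C = correlation_with_pairs({pair: target_r})
    i, j = _IDX[pair[0]], _IDX[pair[1]]
    estimates = {"realistic": [], "oracle": []}
    base = GroundTruthSpec(roi_correlation=C)
    specs = {"realistic": base, "oracle": base.noise_free()}
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_participants)
    for kind, spec in specs.items():
        for s in seeds:
            raw, _ = simulate_participant({"preferred": spec}, seed=int(s))
            fc, _, _ = participant_fc(raw, config)
            estimates[kind].append(fc["preferred"].r[0, i, j])
    real = np.asarray(estimates["realistic"])
    oracle = np.asarray(estimates["oracle"])
    return RecoveryResult(
        target_r=target_r,
        mean_r=float(real.mean()), sd_r=float(real.std(ddof=1)),
        oracle_mean_r=float(oracle.mean()), oracle_sd_r=float(oracle.std(ddof=1)),
        n_participants=n_participants,
    )


@dataclass
class CalibrationResult:
    per_pair_rejection_rate: float
    rates_by_pair: dict[str, float]
    family_fdp_mean: float
    n_cohorts: int
    n_participants: int
    alpha: float = 0.05


def _cohort_paired_tests(
    effect_r: float, seed: int, n_participants: int, alpha: float, q: float,
    pair: tuple[str, str] = DEFAULT_PAIR,
) -> tuple[dict[str, bool], FdrFamily]:
    """One synthetic cohort on the ROI-level fast path: latent series ->
    correlation matrices -> per-pair paired t over the 24-pair family -> BH-FDR."""
    C0 = np.eye(len(ROI_LABELS))
    C1 = apply_effect(C0, [(pair, effect_r)]) if effect_r else C0
    parts = simulate_roi_cohort(n_participants, {"preferred": C1, "assigned": C0},
                                seed=seed)
    z = {cond: [fc_from_series(p[cond])[1] for p in parts]
         for cond in ("preferred", "assigned")}
    rejected, ps, ids = {}, [], []
    for a, b in fronto_temporoparietal_pairs():
        i, j = _IDX[a], _IDX[b]
        x = np.array([m[i, j] for m in z["preferred"]])
        y = np.array([m[i, j] for m in z["assigned"]])
        res = paired_t(x, y, f"{a}-{b}")
        rejected[f"{a}-{b}"] = res.p_value < alpha
        ps.append(res.p_value)
        ids.append(f"{a}-{b}")
    family = bh_fdr(FdrFamily(ids, np.array(ps), q=q))
    return rejected, family


def null_calibration(
    n_cohorts: int = 200,
    n_participants: int = 32,
    seed: int = 0,
    alpha: float = 0.05,
    q: float = 0.05,
) -> CalibrationResult:
    """Type-I calibration on cohorts with no condition effect anywhere.

    All 24 family pairs are true nulls, so any BH rejection is a false
    discovery; the family-level false-discovery proportion must stay at or
    below q in expectation.
    """
    rng = np.random.default_rng(seed)
    cohort_seeds = rng.integers(0, 2**31 - 1, n_cohorts)
    per_pair: dict[str, list[bool]] = {}
    fdps = []
    for s in cohort_seeds:
        rejected, family = _cohort_paired_tests(0.0, int(s), n_participants, alpha, q)
        for k, v in rejected.items():
            per_pair.setdefault(k, []).append(v)
        fdps.append(float(np.mean(family.rejected)))
    rates = {k: float(np.mean(v)) for k, v in per_pair.items()}
    return CalibrationResult(
        per_pair_rejection_rate=float(np.mean(list(rates.values()))),
        rates_by_pair=rates,
        family_fdp_mean=float(np.mean(fdps)),
        n_cohorts=n_cohorts,
        n_participants=n_participants,
        alpha=alpha,
    )


def power_curve(
    deltas: tuple[float, ...] = (0.0, 0.15, 0.3),
    n_cohorts: int = 60,
    n_participants: int = 32,
    seed: int = 0,
    alpha: float = 0.05,
    pair: tuple[str, str] = DEFAULT_PAIR,
) -> dict[float, float]:
    """Rejection rate on the affected pair as the condition effect grows.

    The same cohort seeds are reused across effect sizes, so the curve is a
    paired comparison and must be non-decreasing up to Monte-Carlo noise.
    """
    rng = np.random.default_rng(seed)
    cohort_seeds = rng.integers(0, 2**31 - 1, n_cohorts)
    key = f"{pair[0]}-{pair[1]}"
    out = {}
    for dr in deltas:
        hits = [
            _cohort_paired_tests(dr, int(s), n_participants, alpha, 0.05, pair)[0][key]
            for s in cohort_seeds
        ]
        out[dr] = float(np.mean(hits))
    return out
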