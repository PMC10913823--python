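"""Nuisance removal, ROI aggregation, and functional-connectivity matrices.

Systemic physiology and residual motion are removed by ordinary least squares
on the two short-separation channels (chromophore-matched) plus the band-passed
3-axis accelerometer, fitted within each condition segment.  Surviving channels
are averaged (unweighted) into the 10 ROIs, and the per-condition Pearson
correlation matrix is Fisher z-transformed for group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import ROI_LABELS, UNASSIGNED, ChannelRoiMap, Montage, default_montage
from .preprocess import QcReport, bandpass_array
from .recording import CHROMOPHORES, ConcRecording

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-12
MIN_WINDOW_S = 120.0  # FC stabilises after ~2 minutes in this age group


@dataclass
class NuisanceDesign:
    """time x k regressor matrix per chromophore (intercept, SSCs, accelerometer)."""

    regressors: dict[str, np.ndarray]
    names: list[str]


def build_nuisance_design(
    conc: ConcRecording,
    montage: Montage | None = None,
    use_accelerometer: bool = True,
    band_hz: tuple[float, float] = (0.009, 0.08),
) -> NuisanceDesign:
    """Assemble intercept + chromophore-matched SSC series + band-passed accelerometer.

    Short-separation channels pruned by QC are skipped with a log message; the
    regression proceeds with whatever regressors remain.
    """
    montage = montage or default_montage()
    n_t = conc.conc.shape[2]
    regressors: dict[str, np.ndarray] = {}
    for k, chrom in enumerate(CHROMOPHORES):
        cols = [np.ones(n_t)]
        names = ["intercept"]
        for cid in montage.ssc_ids:
            if conc.channel_mask[cid - 1]:
                cols.append(conc.conc[cid - 1, k])
                names.append(f"ssc{cid}")
            else:
                logger.warning("SSC channel %d pruned by QC; omitted from design", cid)
        if use_accelerometer:
            acc = bandpass_array(conc.accelerometer, conc.sampling_rate_hz,
                                 band_hz[0], band_hz[1])
            for ax, nm in zip(acc, ("accel_x", "accel_y", "accel_z")):
                cols.append(ax)
                names.append(nm)
        regressors[chrom] = np.column_stack(cols)
    return NuisanceDesign(regressors=regressors, names=names)


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Greedily drop columns until X has full column rank."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear nuisance regressor (column %d)", j)
    return X[:, keep]


def regress_nuisance(
    conc: ConcRecording,
    design: NuisanceDesign,
    per_condition: bool = True,
) -> ConcRecording:
    """OLS-residualise every surviving channel on the nuisance regressors.

    Fitted within each condition segment separately by default (whole-recording
    fit behind the flag), so condition differences cannot leak into the fit.
    Residuals are exactly orthogonal to every regressor up to numerical
    tolerance; this is asserted on every call.
    """
    out = conc.conc.copy()
    segments = (
        [conc.condition_slice(a.label) for a in conc.annotations]
        if per_condition
        else [slice(0, conc.conc.shape[2])]
    )
    for k, chrom in enumerate(CHROMOPHORES):
        X_full = design.regressors[chrom]
        for sl in segments:
            X = _drop_collinear(X_full[sl])
            Q, _ = np.linalg.qr(X)
            for c in range(conc.n_channels):
                if not conc.channel_mask[c]:
                    continue
                y = conc.conc[c, k, sl]
                resid = y - Q @ (Q.T @ y)
                # orthogonality is a hard invariant of the projection
                scale = np.linalg.norm(y) * np.linalg.norm(X, axis=0).max() + 1e-300
                assert np.abs(X.T @ resid).max() <= 1e-8 * scale
                out[c, k, sl] = resid
    res = ConcRecording(
        conc=out, channel_mask=conc.channel_mask.copy(),
        accelerometer=conc.accelerometer, annotations=list(conc.annotations),
        sampling_rate_hz=conc.sampling_rate_hz, meta=conc.meta, stage="residual",
    )
    return res


def roi_average(
    conc: ConcRecording,
    roi_map: ChannelRoiMap,
    qc: QcReport | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean of each ROI's surviving channels.

    Returns (roi_series, present): roi_series is (10, 2, n_times) with NaN rows
    for absent ROIs; present is a (10,) bool mask.  An ROI is absent when none
    of its channels survived QC — never silently zero.
    """
    n_t = conc.conc.shape[2]
    roi_series = np.full((len(ROI_LABELS), 2, n_t), np.nan)
    present = np.zeros(len(ROI_LABELS), dtype=bool)
    for i, roi in enumerate(ROI_LABELS):
        ids = [cid for cid in roi_map.channels_in_roi(roi) if conc.channel_mask[cid - 1]]
        if not ids:
            logger.warning("ROI %s has no surviving channels", roi)
            continue
        present[i] = True
        roi_series[i] = conc.conc[[cid - 1 for cid in ids]].mean(axis=0)
    return roi_series, present


@dataclass
class FcResult:
    """Per-participant, per-condition 10x10 correlation and Fisher-z matrices.

    r and z are (2, 10, 10) over (HbO2, HHb); rows/columns of absent ROIs are
    NaN and flagged in ``roi_present``.
    """

    r: np.ndarray
    z: np.ndarray
    roi_present: np.ndarray
    participant_id: str = ""
    condition: str = ""
    roi_labels: tuple[str, ...] = ROI_LABELS

    def pair_z(self, chrom: str, roi_a: str, roi_b: str) -> float:
        k = CHROMOPHORES.index(chrom)
        i, j = self.roi_labels.index(roi_a), self.roi_labels.index(roi_b)
        return float(self.z[k, i, j])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for k, chrom in enumerate(CHROMOPHORES):
            for i in range(len(self.roi_labels)):
                for j in range(i + 1, len(self.roi_labels)):
                    rows.append({
                        "participant": self.participant_id,
                        "condition": self.condition,
                        "chromophore": chrom,
                        "roi_a": self.roi_labels[i],
                        "roi_b": self.roi_labels[j],
                        "r": self.r[k, i, j],
                        "z": self.z[k, i, j],
                    })
        return pd.DataFrame(rows)


def fc_from_series(series: np.ndarray, present: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and clipped Fisher z among rows of a (10, T) array."""
    n = series.shape[0]
    if present is None:
        present = ~np.isnan(series).any(axis=1)
    r = np.full((n, n), np.nan)
    idx = np.flatnonzero(present)
    if idx.size:
        sub = np.corrcoef(series[idx])
        sub = np.atleast_2d(sub)
        for a, i in enumerate(idx):
            r[i, idx] = sub[a]
    clipped = np.clip(r, -R_CLIP, R_CLIP)
    if idx.size and np.nanmax(np.abs(r[np.ix_(idx, idx)])) > R_CLIP:
        logger.info("correlation clipped to +-%.1e before Fisher transform", R_CLIP)
    z = np.arctanh(clipped)  # diagonal r=1 clips to a finite z
    return r, z


def fc_matrix(
    roi_series: np.ndarray,
    present: np.ndarray,
    condition_slice: slice,
    sampling_rate_hz: float = 25.0,
    min_window_s: float = MIN_WINDOW_S,
    participant_id: str = "",
    condition: str = "",
) -> FcResult:
    """Correlation over the condition's samples for every present ROI pair.

    Raises if the window is shorter than ``min_window_s`` — short windows give
    unstable connectivity estimates and are refused rather than silently used.
    """
    n_samples = condition_slice.stop - condition_slice.start
    if n_samples < min_window_s * sampling_rate_hz:
        raise ValueError(
            f"condition window {n_samples / sampling_rate_hz:.0f} s shorter than "
            f"minimum {min_window_s:.0f} s"
        )
    n = roi_series.shape[0]
    r = np.full((2, n, n), np.nan)
    z = np.full((2, n, n), np.nan)
    for k in range(2):
        r[k], z[k] = fc_from_series(roi_series[:, k, condition_slice], present)
        if present.all():
            np.fill_diagonal(r[k], 1.0)
    return FcResult(r=r, z=z, roi_present=present.copy(),
                    participant_id=participant_id, condition=condition)


def fc_results_to_frame(results: list[FcResult]) -> pd.DataFrame:
    return pd.concat([res.to_long_frame() for res in results], ignore_index=True)
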