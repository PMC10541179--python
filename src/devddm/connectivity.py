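"""Resting-state visuomotor within-network connectivity scoring.

A participant's score is the mean Fisher-z (atanh) of the 21 pairwise Pearson
correlations among the 7 visuomotor-network ROI time series, computed on
motion-censored frames after zero-phase Butterworth high-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "VISUOMOTOR_ROIS",
    "TR_S",
    "N_VOLUMES",
    "CensorResult",
    "ConnectivityScore",
    "censor_frames",
    "highpass_filter",
    "connectivity_score",
]

#: The 7 nodes of the visuomotor network (4 visual + 3 sensorimotor).
VISUOMOTOR_ROIS = (
    "Visual.Medial",
    "Visual.Occipital",
    "Visual.Lateral.L",
    "Visual.Lateral.R",
    "SensoriMotor.Lateral.L",
    "SensoriMotor.Lateral.R",
    "SensoriMotor.Superior",
)

TR_S = 0.933  # sampling interval (s)
N_VOLUMES = 380


@dataclass(frozen=True)
class CensorResult:
    mask: np.ndarray  # True = frame retained
    frac_censored: float
    excluded: bool


@dataclass(frozen=True)
class ConnectivityScore:
    participant_id: str
    z: float
    n_pairs: int
    frac_censored: float


def censor_frames(
    fd: np.ndarray | pd.Series,
    fd_threshold: float = 2.0,
    max_frac: float = 0.05,
    n_frames: int | None = None,
) -> CensorResult:
    """Scrub high-motion frames and apply the participant exclusion rule.

    Frames with framewise displacement strictly above ``fd_threshold`` (mm)
    are removed; if strictly more than ``max_frac`` of frames are removed the
    participant is marked excluded (a removed fraction exactly at the
    threshold is retained).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1:
        raise ValueError("fd must be a 1-D per-frame trace")
    if n_frames is not None and fd.size != n_frames:
        raise ValueError(f"fd length {fd.size} does not match {n_frames} frames")
    mask = fd <= fd_threshold
    frac = float((~mask).sum()) / fd.size
    return CensorResult(mask=mask, frac_censored=frac, excluded=frac > max_frac)


def highpass_filter(
    series: np.ndarray, cutoff_hz: float = 0.01, tr: float = TR_S, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the last axis."""
    b, a = butter(order, cutoff_hz, btype="highpass", fs=1.0 / tr)
    return filtfilt(b, a, series, axis=-1)


def connectivity_score(
    ts: pd.DataFrame,
    fd: np.ndarray | pd.Series | None = None,
    highpass_hz: float | None = 0.01,
    tr: float = TR_S,
    fd_threshold: float = 2.0,
    max_frac: float = 0.05,
    min_frames: int = 30,
    confounds: pd.DataFrame | None = None,
    participant_id: str = "",
) -> ConnectivityScore:
    """Mean pairwise Fisher-z connectivity of the visuomotor network.

    ``ts`` holds one column per ROI (any subset order of
    :data:`VISUOMOTOR_ROIS`; labels are validated) and one row per frame.
    The pipeline is: optional nuisance regression (least squares on supplied
    ``confounds`` columns), high-pass filtering on the full time base, frame
    censoring from ``fd``, then Pearson r over the 21 ROI pairs on retained
    frames and ``z = atanh(r)`` averaged over pairs.

    Raises if the participant fails the censoring rule, if too few frames
    remain, or if any pair is degenerate (|r| = 1 or a constant series).
    """
    roi_cols = [c for c in ts.columns if c in VISUOMOTOR_ROIS]
    unknown = [c for c in ts.columns if c not in VISUOMOTOR_ROIS and c != "fd"]
    if unknown:
        raise ValueError(f"unknown ROI column(s): {unknown}")
    if len(roi_cols) != len(VISUOMOTOR_ROIS):
        missing = sorted(set(VISUOMOTOR_ROIS) - set(roi_cols))
        raise ValueError(f"missing ROI column(s): {missing}")
    data = ts[roi_cols].to_numpy(dtype=float).T  # rois x T

    if confounds is not None and confounds.shape[1] > 0:
        X = np.column_stack([np.ones(data.shape[1]), confounds.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
        data = (data.T - X @ beta).T

    if highpass_hz is not None:
        data = highpass_filter(data, cutoff_hz=highpass_hz, tr=tr)

    if fd is not None:
        cens = censor_frames(fd, fd_threshold, max_frac, n_frames=data.shape[1])
        if cens.excluded:
            raise ValueError(
                f"participant excluded: {cens.frac_censored:.1%} of frames censored"
            )
        data = data[:, cens.mask]
        frac = cens.frac_censored
    else:
        frac = 0.0

    if data.shape[1] < min_frames:
        raise ValueError(f"only {data.shape[1]} retained frames (< {min_frames})")
    sds = data.std(axis=1)
    if np.any(sds == 0):
        raise ValueError("constant ROI series")
    r = np.corrcoef(data)
    iu = np.triu_indices_from(r, k=1)
    pair_r = r[iu]
    if np.any(np.abs(pair_r) >= 1.0):
        raise ValueError("degenerate series: |r| = 1 for at least one pair")
    z = float(np.mean(np.arctanh(pair_r)))
    return ConnectivityScore(
        participant_id=participant_id,
        z=z,
        n_pairs=len(pair_r),
        frac_censored=frac,
    )
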