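"""Functional and individual structural covariance network construction.

Functional networks: pairwise Pearson correlation of ROI time series,
negatives masked to zero (their interpretation is ambiguous), positives
Fisher-z transformed.

Individual structural covariance networks (SCN): each subject's regional
GMV deviations from the healthy-period mean are turned into an
inter-regional effect-size difference (ESD), squashed through a tanh to a
correlation-like quantity R, inverted to a weight W = 1 - R, and the weight
matrix multiplies the group-level healthy covariance entrywise:

    ESD(i,j) = |(x_i - M_i) - (x_j - M_j)| / sqrt((SD_i^2 + SD_j^2) / 2)
    R(i,j)   = (exp(2 ESD) - 1) / (exp(2 ESD) + 1)   [= tanh(ESD)]
    W(i,j)   = 1 - R(i,j)
    M(i,j)   = W(i,j) * SCN_HC(i,j)

A subject sitting exactly at the healthy mean has W = 1 everywhere and
recovers the group network; large deviations drive W (hence the edge) to 0.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    BaselineReference,
    ConnectivityMatrix,
    MorphometryRecord,
    TimeSeriesRecord,
    WeightMatrix,
)

__all__ = [
    "residualize_morphometry",
    "build_group_covariance",
    "compute_esd",
    "weight_from_esd",
    "build_individual_scn",
    "build_functional_network",
    "AdjustmentModel",
]

FISHER_R_CAP = 1.0 - 1e-7


class AdjustmentModel:
    """Per-ROI OLS adjustment of GMV for total intracranial volume.

    Fitted on healthy-baseline records (GMV ~ intercept + TIV across
    subjects) and reapplied unchanged to later timepoints, so longitudinal
    deviations from the healthy state are preserved rather than re-centered.
    """

    def __init__(self, intercepts: np.ndarray, slopes: np.ndarray) -> None:
        self.intercepts = np.asarray(intercepts, dtype=float)
        self.slopes = np.asarray(slopes, dtype=float)

    def residuals(self, gmv: np.ndarray, tiv: float) -> np.ndarray:
        return np.asarray(gmv, dtype=float) - (self.intercepts + self.slopes * float(tiv))


def _gmv_matrix(records: Sequence[MorphometryRecord]) -> tuple[np.ndarray, np.ndarray]:
    gmv = np.stack([r.gmv for r in records])           # subjects x ROI
    tiv = np.array([r.tiv for r in records], dtype=float)
    return gmv, tiv


def residualize_morphometry(
    records: Sequence[MorphometryRecord],
) -> tuple[pd.DataFrame, AdjustmentModel]:
    """Regress each ROI's baseline GMV on intercept + TIV; return residuals.

    Returns a (subjects x ROI) residual table (per-ROI mean exactly zero)
    and the fitted :class:`AdjustmentModel` for reuse at later timepoints.
    Requires at least three baseline subjects and non-constant TIV.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 baseline subjects for residualization")
    gmv, tiv = _gmv_matrix(records)
    if np.ptp(tiv) == 0:
        raise ValueError("TIV is constant across subjects; design matrix is singular")
    x = np.column_stack([np.ones_like(tiv), tiv])
    coef, *_ = np.linalg.lstsq(x, gmv, rcond=None)     # 2 x ROI
    resid = gmv - x @ coef
    model = AdjustmentModel(intercepts=coef[0], slopes=coef[1])
    frame = pd.DataFrame(
        resid,
        index=[r.subject_id for r in records],
        columns=[f"roi_{i + 1}" for i in range(gmv.shape[1])],
    )
    return frame, model


def build_group_covariance(
    residuals: pd.DataFrame, records: Sequence[MorphometryRecord]
) -> tuple[ConnectivityMatrix, BaselineReference]:
    """Group-level healthy covariance matrix and baseline reference.

    ``scn_hc[i, j]`` is the Pearson correlation of the TIV-adjusted residuals
    of regions *i* and *j* across baseline subjects; the reference mean/SD
    are computed from the raw baseline GMV (sample SD, ddof=1).
    """
    if residuals.shape[0] < 3:
        raise ValueError("need >= 3 baseline subjects")
    resid = residuals.to_numpy(dtype=float)
    sds = resid.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(f"zero-variance ROI(s) in residuals: {list(residuals.columns[dead])}")
    scn = np.corrcoef(resid, rowvar=False)
    scn = np.clip((scn + scn.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(scn, 1.0)

    gmv, _ = _gmv_matrix(records)
    mean = gmv.mean(axis=0)
    sd = gmv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [f"roi_{i + 1}" for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI(s) in baseline GMV: {bad}")
    labels = tuple(residuals.columns)
    ref = BaselineReference(mean=mean, sd=sd, scn_hc=scn, roi_labels=labels)
    conn = ConnectivityMatrix(
        values=scn - np.eye(scn.shape[0]), kind="group_scn", roi_labels=labels
    )
    return conn, ref


def compute_esd(record: MorphometryRecord, reference: BaselineReference) -> np.ndarray:
    """Inter-regional effect-size difference of one subject's GMV deviations.

    ``ESD(i,j) = |(x_i - M_i) - (x_j - M_j)| / sqrt((SD_i^2 + SD_j^2)/2)``:
    the difference of the two regions' deviations from their healthy means,
    standardized by the pooled healthy SD.  Symmetric, zero diagonal.
    """
    x = np.asarray(record.gmv, dtype=float)
    if x.size != reference.n_roi:
        raise ValueError("record GMV length does not match reference")
    if np.any(reference.sd <= 0):
        raise ValueError("reference SDs must all be positive")
    dev = x - reference.mean
    num = np.abs(dev[:, None] - dev[None, :])
    var = reference.sd**2
    denom = np.sqrt((var[:, None] + var[None, :]) / 2.0)
    esd = num / denom
    np.fill_diagonal(esd, 0.0)
    return esd


def weight_from_esd(esd: np.ndarray) -> WeightMatrix:
    """Map ESD to the subject weighting matrix: R = tanh(ESD), W = 1 - R.

    ``tanh`` is the overflow-safe form of ``(exp(2 ESD)-1)/(exp(2 ESD)+1)``.
    """
    esd = np.asarray(esd, dtype=float)
    if np.any(esd < 0):
        raise ValueError("esd entries must be nonnegative")
    # w = 1 - tanh(esd) = 2 e^{-2 esd} / (1 + e^{-2 esd}); computed in this
    # form so saturated entries stay strictly positive instead of
    # underflowing to 0 (W lies in the open-closed interval (0, 1]).
    e = np.exp(-2.0 * esd)
    w = np.maximum(2.0 * e / (1.0 + e), np.finfo(float).tiny)
    r = np.minimum(1.0 - w, np.nextafter(1.0, 0.0))  # keep r < 1 despite rounding
    return WeightMatrix(esd=esd, r=r, w=w)


def build_individual_scn(
    w: WeightMatrix, reference: BaselineReference, *, subject_id: str | None = None,
    timepoint: float | None = None,
) -> ConnectivityMatrix:
    """Individual SCN: entrywise product of the subject weighting matrix
    with the group-level healthy covariance; diagonal forced to zero."""
    if w.w.shape != reference.scn_hc.shape:
        raise ValueError(
            f"shape mismatch: W {w.w.shape} vs SCN_HC {reference.scn_hc.shape}"
        )
    m = w.w * reference.scn_hc
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(
        values=m,
        kind="individual_scn",
        roi_labels=reference.roi_labels,
        subject_id=subject_id,
        timepoint=timepoint,
    )


def build_functional_network(record: TimeSeriesRecord) -> ConnectivityMatrix:
    """Positive-Pearson, Fisher-z functional network from one ROI time series.

    Pairwise Pearson correlation across time; entries with r <= 0 are set to
    zero, the rest are Fisher-z transformed (atanh) with r clipped at
    ``1 - 1e-7`` so perfectly correlated pairs keep a finite edge.
    """
    series = record.series
    if series.shape[0] < 30:
        raise ValueError(f"need >= 30 time samples, got {series.shape[0]}")
    sds = series.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        names = [f"roi_{i + 1}" for i in dead]
        raise ValueError(f"zero-variance time series column(s): {names}")
    r = np.corrcoef(series, rowvar=False)
    r = (r + r.T) / 2.0
    z = np.where(r > 0, np.arctanh(np.clip(r, None, FISHER_R_CAP)), 0.0)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z,
        kind="functional_z",
        subject_id=record.subject_id,
        timepoint=record.timepoint,
    )
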