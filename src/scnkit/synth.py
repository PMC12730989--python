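"""Seeded synthetic cohorts emulating a longitudinal two-group injury study.

The generator produces the three tabular inputs the analysis consumes:
regional morphometry (GMV + TIV), ROI time series, and per-assessment
locomotor / spinal-cord DTI outcomes.  Baseline draws share a modular
inter-regional correlation structure; injury and treatment act as per-group
mean shifts over time; locomotor outcomes carry planted metric-by-group
interactions so the downstream moderation models have a known truth to
recover.

Everything is deterministic given ``config.seed`` through the named
substream scheme in :mod:`scnkit.config`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import GROUPS, CohortConfig, substream
from .types import BaselineReference, MorphometryRecord, OutcomeRecord, TimeSeriesRecord

__all__ = [
    "generate_baseline_reference",
    "simulate_morphometry",
    "simulate_timeseries",
    "simulate_outcomes",
    "modular_correlation",
    "outcome_frame",
    "morphometry_frame",
]

_PSD_TOL = 1e-10


def modular_correlation(
    n_roi: int, n_modules: int, within_r: float, between_r: float
) -> np.ndarray:
    """Block correlation matrix: ``within_r`` inside modules, ``between_r``
    across, unit diagonal.

    Raises ``ValueError`` when the requested block pattern is not positive
    semi-definite (e.g. strongly negative between-module correlation with
    several modules).
    """
    if n_modules < 1 or n_roi < n_modules:
        raise ValueError("need 1 <= n_modules <= n_roi")
    sizes = np.full(n_modules, n_roi // n_modules)
    sizes[: n_roi % n_modules] += 1
    labels = np.repeat(np.arange(n_modules), sizes)
    corr = np.where(labels[:, None] == labels[None, :], within_r, between_r)
    np.fill_diagonal(corr, 1.0)
    min_eig = float(np.linalg.eigvalsh(corr)[0])
    if min_eig < -_PSD_TOL:
        raise ValueError(
            f"block parameters (within_r={within_r}, between_r={between_r}, "
            f"n_modules={n_modules}) give a non-PSD correlation matrix "
            f"(min eigenvalue {min_eig:.3g})"
        )
    return corr


def generate_baseline_reference(config: CohortConfig) -> BaselineReference:
    """Healthy-period reference: per-ROI means, SDs and the modular
    inter-regional correlation matrix the cohort is drawn from."""
    rng = substream(config.seed, "baseline_reference")
    corr = modular_correlation(
        config.n_roi, config.n_modules, config.within_r, config.between_r
    )
    # mild ROI-to-ROI heterogeneity so no two regions are statistically identical
    mean = config.gmv_mean * (1.0 + 0.10 * rng.standard_normal(config.n_roi))
    sd = config.gmv_sd * (1.0 + 0.10 * np.abs(rng.standard_normal(config.n_roi)))
    return BaselineReference(mean=mean, sd=sd, scn_hc=corr)


def _sqrt_psd(corr: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root, tolerant of tiny negative eigenvalues."""
    w, u = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return (u * np.sqrt(w)) @ u.T


def _effect_at(config: CohortConfig, group: str, t_index: int) -> float:
    return float(config.injury_effect[group][t_index])


def _reference_corr_at(config: CohortConfig, corr: np.ndarray, t_index: int) -> np.ndarray:
    """Correlation used at one timepoint; optionally shrunk after injury."""
    if not config.perturb_covariance or t_index == 0 or config.covariance_shrink == 0.0:
        return corr
    p = float(np.clip(config.covariance_shrink, 0.0, 1.0))
    shrunk = (1.0 - p) * corr
    np.fill_diagonal(shrunk, 1.0)
    return shrunk


def simulate_morphometry(
    config: CohortConfig, reference: BaselineReference
) -> list[MorphometryRecord]:
    """Draw per-subject, per-timepoint regional GMV plus TIV.

    At baseline each subject's GMV follows the reference multivariate
    distribution (mean, SD, modular correlation) with a TIV coupling term.
    Post-injury records shift each group's ROI means by
    ``config.injury_effect[group][t]``.  A fraction ``subject_frac`` of the
    GMV covariance is a stable per-subject deviation, so individual
    departures from the healthy mean persist across timepoints as they would
    in real longitudinal morphometry.
    """
    rng = substream(config.seed, "morphometry")
    n_roi = config.n_roi
    sqrt_c = _sqrt_psd(reference.scn_hc)
    scale = reference.sd
    records: list[MorphometryRecord] = []
    f_subj = np.sqrt(config.subject_frac)
    f_time = np.sqrt(1.0 - config.subject_frac)
    for sid in config.subject_ids:
        group = config.group_of(sid)
        tiv = float(config.tiv_mean + config.tiv_sd * rng.standard_normal())
        subj_dev = scale * (sqrt_c @ rng.standard_normal(n_roi))
        for ti, t in enumerate(config.timepoints):
            corr_t = _reference_corr_at(config, reference.scn_hc, ti)
            sq = sqrt_c if corr_t is reference.scn_hc else _sqrt_psd(corr_t)
            time_dev = scale * (sq @ rng.standard_normal(n_roi))
            gmv = (
                reference.mean
                + config.tiv_coupling * (tiv - config.tiv_mean)
                + _effect_at(config, group, ti)
                + f_subj * subj_dev
                + f_time * time_dev
            )
            records.append(
                MorphometryRecord(
                    subject_id=sid, group=group, timepoint=float(t), gmv=gmv, tiv=tiv
                )
            )
    return records


def simulate_timeseries(
    config: CohortConfig,
    reference: BaselineReference,
    n_samples: int | None = None,
) -> list[TimeSeriesRecord]:
    """ROI time series whose population zero-lag correlation equals the
    reference matrix.

    Each series is i.i.d. Gaussian noise mixed by the symmetric square root
    of the reference correlation — the analysis consumes only zero-lag
    correlations, so no temporal autocorrelation is modeled.
    """
    n_t = int(config.n_timepoints_ts if n_samples is None else n_samples)
    if n_t < 2:
        raise ValueError("need at least 2 time samples per series")
    rng = substream(config.seed, "timeseries")
    sqrt_c = _sqrt_psd(reference.scn_hc)
    records: list[TimeSeriesRecord] = []
    for sid in config.subject_ids:
        for ti, t in enumerate(config.timepoints):
            corr_t = _reference_corr_at(config, reference.scn_hc, ti)
            sq = sqrt_c if corr_t is reference.scn_hc else _sqrt_psd(corr_t)
            z = rng.standard_normal((n_t, config.n_roi))
            records.append(
                TimeSeriesRecord(subject_id=sid, timepoint=float(t), series=z @ sq.T)
            )
    return records


def simulate_outcomes(
    config: CohortConfig, metric_table: pd.DataFrame
) -> list[OutcomeRecord]:
    """Locomotor parameters and DTI scalars driven by a network metric.

    ``metric_table`` must contain columns ``subject_id``, ``timepoint`` and
    ``metric`` (a real or latent network metric, e.g. global efficiency) for
    every subject at every timepoint of the design.

    Each locomotor outcome follows a linear mixed model with fixed effects
    metric, group, metric-by-group (the planted ``interaction_effects``),
    linear time, a per-subject random intercept and Gaussian noise.  FA is
    generated so that, at low FA noise, regressing the metric on FA recovers
    the planted main-effect slope ``fa_effect``; FA is clipped to [0, 1].
    """
    required = {"subject_id", "timepoint", "metric"}
    missing_cols = required - set(metric_table.columns)
    if missing_cols:
        raise ValueError(f"metric_table missing columns: {sorted(missing_cols)}")
    table = metric_table.set_index(["subject_id", "timepoint"])["metric"]
    design = [(sid, float(t)) for sid in config.subject_ids for t in config.timepoints]
    missing = [key for key in design if key not in table.index]
    if missing:
        raise ValueError(f"metric_table missing subject x timepoint cells: {missing[:5]}")

    rng = substream(config.seed, "outcomes")
    metric_vals = np.array([table.loc[key] for key in design], dtype=float)
    metric_center = float(metric_vals.mean())

    outcomes = ("path_length", "step_height", "stride_length")
    u = {
        sid: {o: config.subject_sd * rng.standard_normal() for o in outcomes}
        for sid in config.subject_ids
    }
    records: list[OutcomeRecord] = []
    for (sid, t), m in zip(design, metric_vals):
        group = config.group_of(sid)
        g = float(GROUPS.index(group))  # sci_only is the reference level
        vals = {}
        for o in outcomes:
            vals[o] = (
                config.outcome_intercepts[o]
                + config.metric_slopes[o] * m
                + config.group_effects[o] * g
                + config.interaction_effects[o] * m * g
                + config.time_slopes[o] * t
                + u[sid][o]
                + config.noise_sd * rng.standard_normal()
            )
        # FA: slope of metric on FA -> fa_effect as fa noise -> 0
        fa = (
            config.fa_intercept
            + (m - metric_center) / config.fa_effect
            + config.fa_noise_sd * rng.standard_normal()
        )
        fa = float(np.clip(fa, 0.0, 1.0))
        diffs = {}
        for name, base in config.diffusivity_base.items():
            bump = 0.05 * base * (t > 0) * (1.0 if group == "sci_only" else 0.5)
            diffs[name] = float(
                max(base + bump + config.diffusivity_noise_sd * rng.standard_normal(), 1e-6)
            )
        records.append(
            OutcomeRecord(
                subject_id=sid,
                group=group,
                timepoint=t,
                path_length=float(vals["path_length"]),
                step_height=float(vals["step_height"]),
                stride_length=float(vals["stride_length"]),
                fa=fa,
                md=diffs["md"],
                rd=diffs["rd"],
                ad=diffs["ad"],
            )
        )
    return records


# -- tabular views -----------------------------------------------------------


def morphometry_frame(records: Sequence[MorphometryRecord]) -> pd.DataFrame:
    """Wide table: subject, group, timepoint, tiv, roi_1..roi_N."""
    n_roi = records[0].gmv.size
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "timepoint": r.timepoint, "tiv": r.tiv}
        row.update({f"roi_{i + 1}": v for i, v in enumerate(r.gmv)})
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_frame(records: Sequence[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "timepoint": [r.timepoint for r in records],
            "path_length": [r.path_length for r in records],
            "step_height": [r.step_height for r in records],
            "stride_length": [r.stride_length for r in records],
            "fa": [r.fa for r in records],
            "md": [r.md for r in records],
            "rd": [r.rd for r in records],
            "ad": [r.ad for r in records],
        }
    )
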