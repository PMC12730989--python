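"""End-to-end orchestration: simulate -> build networks -> metric sweep ->
statistics, with per-stage file outputs, structured logging and a run
manifest for reproducibility.

Each stage reads its inputs from the output directory written by the
previous stage, so stages can be re-run individually and any corrupted
intermediate is caught at the stage boundary with the stage name and the
offending file in the error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GROUPS, CohortConfig
from .graphmetrics import global_metrics, sweep_thresholds
from .io import read_matrix, sha256_of, write_manifest, write_matrix
from .longstats import fit_moderation_model, fit_trajectory, select_and_compare
from .netbuild import (
    build_functional_network,
    build_group_covariance,
    build_individual_scn,
    compute_esd,
    residualize_morphometry,
    weight_from_esd,
)
from .synth import (
    generate_baseline_reference,
    morphometry_frame,
    outcome_frame,
    simulate_morphometry,
    simulate_outcomes,
    simulate_timeseries,
)
from .types import MorphometryRecord, ThresholdGrid, TimeSeriesRecord

logger = logging.getLogger("scnkit.pipeline")

_version = "0.1.0"

__all__ = ["PipelineOptions", "PipelineError", "run_pipeline", "summarize_run"]

FIXED_SPARSITY = 0.1  # single-threshold metrics feeding the moderation models


class PipelineError(RuntimeError):
    """Stage failure; message carries the stage name and the offending input."""


@dataclass(frozen=True)
class PipelineOptions:
    """Runtime knobs of the orchestrated pipeline (not of the science).

    The sweep defaults here are coarser than the canonical analysis grid
    (0.05-0.50 step 0.01, 100 nulls) so a full end-to-end run stays
    interactive; pass ``grid=ThresholdGrid()`` and ``n_null=100`` for the
    canonical settings.
    """

    grid: ThresholdGrid = ThresholdGrid(0.05, 0.50, 0.05)
    n_null: int = 10
    network_kinds: tuple[str, ...] = ("functional_z", "individual_scn")
    moderation_outcomes: tuple[str, ...] = ("path_length", "step_height", "stride_length")
    moderation_metric: str = "Eg"
    trajectory_metric: str = "Cp"


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage=%s status=start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                logger.error("stage=%s status=error message=%s", name, exc)
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage=%s status=done elapsed=%.2fs", name, time.perf_counter() - t0)
            return out
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


@_stage("simulate")
def stage_simulate(config: CohortConfig, out: Path) -> list[Path]:
    ref = generate_baseline_reference(config)
    morpho = simulate_morphometry(config, ref)
    series = simulate_timeseries(config, ref)
    files: list[Path] = []
    mpath = out / "morphometry.tsv"
    morphometry_frame(morpho).to_csv(mpath, sep="\t", index=False)
    files.append(mpath)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for rec in series:
        p = ts_dir / f"ts_{rec.subject_id}_t{rec.timepoint:g}.csv"
        pd.DataFrame(rec.series, columns=[f"roi_{i+1}" for i in range(rec.series.shape[1])]).to_csv(
            p, index=False
        )
        files.append(p)
    mpath = out / "cohort_manifest.json"
    mpath.write_text(
        json.dumps(
            {"seed": config.seed, "config_hash": config.config_hash(),
             "n_records": len(morpho), "n_series": len(series)},
            indent=2,
        )
    )
    files.append(mpath)
    return files


def _load_morphometry(out: Path, config: CohortConfig) -> list[MorphometryRecord]:
    mpath = out / "morphometry.tsv"
    try:
        frame = pd.read_csv(mpath, sep="\t")
        roi_cols = [c for c in frame.columns if c.startswith("roi_")]
        records = [
            MorphometryRecord(
                subject_id=row["subject_id"], group=row["group"],
                timepoint=float(row["timepoint"]),
                gmv=row[roi_cols].to_numpy(dtype=float), tiv=float(row["tiv"]),
            )
            for _, row in frame.iterrows()
        ]
    except Exception as exc:
        raise PipelineError(f"stage 'build-networks' failed reading {mpath}: {exc}") from exc
    if len(records) != config.n_subjects * len(config.timepoints):
        raise PipelineError(
            f"stage 'build-networks' failed: {mpath} has {len(records)} records, "
            f"expected {config.n_subjects * len(config.timepoints)}"
        )
    return records


@_stage("build-networks")
def stage_networks(config: CohortConfig, out: Path) -> list[Path]:
    morpho = _load_morphometry(out, config)
    baseline = [r for r in morpho if r.timepoint == 0.0]
    residuals, adjust = residualize_morphometry(baseline)
    group_net, ref = build_group_covariance(residuals, baseline)
    files: list[Path] = []
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    p = net_dir / "group_scn.tsv"
    write_matrix(p, group_net)
    files += [p, p.with_suffix(".tsv.json")]
    for rec in morpho:
        esd = compute_esd(rec, ref)
        w = weight_from_esd(esd)
        scn = build_individual_scn(w, ref, subject_id=rec.subject_id, timepoint=rec.timepoint)
        p = net_dir / f"iscn_{rec.subject_id}_t{rec.timepoint:g}.tsv"
        write_matrix(p, scn)
        files += [p, p.with_suffix(".tsv.json")]
    ts_dir = out / "timeseries"
    for tsfile in sorted(ts_dir.glob("ts_*.csv")):
        try:
            series = pd.read_csv(tsfile).to_numpy(dtype=float)
            stem = tsfile.stem.split("_")  # ts_<subject>_t<timepoint>
            rec = TimeSeriesRecord(
                subject_id=stem[1], timepoint=float(stem[2][1:]), series=series
            )
            fnet = build_functional_network(rec)
        except Exception as exc:
            raise PipelineError(
                f"stage 'build-networks' failed on {tsfile}: {exc}"
            ) from exc
        p = net_dir / f"func_{rec.subject_id}_t{rec.timepoint:g}.tsv"
        write_matrix(p, fnet)
        files += [p, p.with_suffix(".tsv.json")]
    return files


@_stage("metrics")
def stage_metrics(config: CohortConfig, out: Path, opts: PipelineOptions) -> list[Path]:
    net_dir = out / "networks"
    prefix = {"functional_z": "func", "individual_scn": "iscn"}
    long_rows = []
    auc_rows = []
    fixed_rows = []
    for kind in opts.network_kinds:
        for path in sorted(net_dir.glob(f"{prefix[kind]}_*.tsv")):
            try:
                net = read_matrix(path)
            except Exception as exc:
                raise PipelineError(f"stage 'metrics' failed on {path}: {exc}") from exc
            sweep = sweep_thresholds(
                net, opts.grid, n_null=opts.n_null, seed=config.seed
            )
            for name, curve in sweep.curves.items():
                for s, v in zip(curve.sparsities, curve.values):
                    long_rows.append(
                        {"subject_id": net.subject_id, "timepoint": net.timepoint,
                         "network": kind, "metric": name, "sparsity": s, "value": v}
                    )
                auc_rows.append(
                    {"subject_id": net.subject_id, "timepoint": net.timepoint,
                     "network": kind, "metric": name, "auc": curve.auc}
                )
            try:
                ms = global_metrics(net, FIXED_SPARSITY, n_null=opts.n_null, seed=config.seed)
            except ValueError as exc:
                # e.g. gamma undefined because sparse nulls have no triangles:
                # keep the raw metrics, record NaN small-world indices
                logger.warning("small-world normalization failed for %s: %s", path, exc)
                ms = global_metrics(net, FIXED_SPARSITY, n_null=0, seed=config.seed)
            for name, v in ms.as_dict().items():
                fixed_rows.append(
                    {"subject_id": net.subject_id, "timepoint": net.timepoint,
                     "network": kind, "metric": name, "sparsity": FIXED_SPARSITY, "value": v}
                )
    files = []
    for fname, rows in (
        ("metrics_long.tsv", long_rows),
        ("metrics_auc.tsv", auc_rows),
        ("metrics_fixed.tsv", fixed_rows),
    ):
        p = out / fname
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        files.append(p)
    return files


@_stage("stats")
def stage_stats(config: CohortConfig, out: Path, opts: PipelineOptions) -> list[Path]:
    try:
        auc = pd.read_csv(out / "metrics_auc.tsv", sep="\t")
        fixed = pd.read_csv(out / "metrics_fixed.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage 'stats' failed reading metric tables: {exc}") from exc
    subj_group = {sid: config.group_of(sid) for sid in config.subject_ids}
    auc["group"] = auc["subject_id"].map(subj_group)
    fixed["group"] = fixed["subject_id"].map(subj_group)

    # between-group comparisons of metric AUCs at each timepoint, and paired
    # within-group contrasts of each follow-up against baseline
    comp_rows = []
    for (network, metric), sub in auc.groupby(["network", "metric"]):
        wide = sub.pivot_table(index="subject_id", columns="timepoint", values="auc")
        for t in config.timepoints:
            a = sub[(sub.timepoint == t) & (sub.group == GROUPS[0])]["auc"].to_numpy()
            b = sub[(sub.timepoint == t) & (sub.group == GROUPS[1])]["auc"].to_numpy()
            if len(a) >= 3 and len(b) >= 3 and np.isfinite(a).all() and np.isfinite(b).all():
                try:
                    res = select_and_compare(a, b)
                except ValueError:
                    continue
                comp_rows.append(
                    {"network": network, "metric": metric, "contrast": "between_groups",
                     "timepoint": t, "test": res.test_name, "statistic": res.statistic,
                     "p": res.p_value, "effect_size": res.effect_size}
                )
        for grp in GROUPS:
            sids = [s for s, g in subj_group.items() if g == grp]
            base = wide.loc[sids, 0.0].to_numpy()
            for t in config.timepoints[1:]:
                follow = wide.loc[sids, t].to_numpy()
                if np.isfinite(base).all() and np.isfinite(follow).all():
                    try:
                        res = select_and_compare(follow, base, paired=True)
                    except ValueError:
                        continue
                    comp_rows.append(
                        {"network": network, "metric": metric,
                         "contrast": f"within_{grp}_vs_baseline", "timepoint": t,
                         "test": res.test_name, "statistic": res.statistic,
                         "p": res.p_value, "effect_size": res.effect_size}
                    )

    # moderation models: locomotor outcome ~ metric * group + timepoint + (1|subject)
    metric_fixed = fixed[
        (fixed.metric == opts.moderation_metric) & (fixed.network == "individual_scn")
    ][["subject_id", "timepoint", "value"]].rename(columns={"value": "metric"})
    outcomes = simulate_outcomes(config, metric_fixed)
    oframe = outcome_frame(outcomes)
    joined = oframe.merge(metric_fixed, on=["subject_id", "timepoint"])
    mod_results = {}
    for outcome_name in opts.moderation_outcomes:
        fit = fit_moderation_model(
            joined[outcome_name], joined["metric"], joined["group"],
            joined["timepoint"], joined["subject_id"],
        )
        mod_results[outcome_name] = fit

    # longitudinal trajectories per group for the chosen metric
    traj_rows = []
    tmetric = fixed[
        (fixed.metric == opts.trajectory_metric) & (fixed.network == "individual_scn")
    ]
    for grp in GROUPS:
        sub = tmetric[tmetric.group == grp]
        try:
            tfit = fit_trajectory(sub["value"], sub["timepoint"], sub["subject_id"])
            traj_rows.append(
                {"group": grp, "metric": opts.trajectory_metric, "edf": tfit.edf,
                 "p_smooth": tfit.p_smooth, "k_selected": tfit.k_selected,
                 "slope": tfit.slope, "bic": tfit.bic}
            )
        except ValueError as exc:
            logger.warning("trajectory fit skipped for group=%s: %s", grp, exc)

    files = []
    p = out / "comparisons.tsv"
    pd.DataFrame(comp_rows).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "outcomes.tsv"
    oframe.to_csv(p, sep="\t", index=False)
    files.append(p)
    mod_json = {}
    for name, fit in mod_results.items():
        planted = config.interaction_effects.get(name, 0.0)
        ci = (
            float(fit.coefficients.loc["metric:group", "ci_low"]),
            float(fit.coefficients.loc["metric:group", "ci_high"]),
        )
        est = fit.beta("metric:group")
        recovered = bool(
            planted != 0.0 and (ci[0] > 0 or ci[1] < 0) and np.sign(est) == np.sign(planted)
        )
        mod_json[name] = {
            "coefficients": fit.coefficients.reset_index().to_dict(orient="records"),
            "df_method": fit.df_method,
            "simple_slopes": fit.simple_slopes.reset_index().to_dict(orient="records"),
            "slope_difference": fit.slope_difference,
            "r2_marginal": fit.r2_marginal,
            "r2_conditional": fit.r2_conditional,
            "f2_interaction": fit.f2_interaction,
            "planted_interaction": planted,
            "interaction_recovered": recovered,
        }
    p = out / "moderation.json"
    p.write_text(json.dumps(mod_json, indent=2, default=float))
    files.append(p)
    p = out / "trajectories.tsv"
    pd.DataFrame(traj_rows).to_csv(p, sep="\t", index=False)
    files.append(p)
    return files


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: str | Path,
    options: PipelineOptions | None = None,
    force: bool = False,
) -> dict:
    """Run all stages end to end and return the run manifest.

    Refuses to write into an existing non-empty output directory unless
    ``force`` is set.  The manifest lists every output file with its SHA-256
    checksum; deterministic stages reproduce identical checksums for the
    same (config, seed).
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_file(config)
    options = options or PipelineOptions()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise PipelineError(
                f"output directory {out} is not empty; pass force=True to overwrite"
            )
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    config.to_file(out / "config.json")
    files = [out / "config.json"]
    files += stage_simulate(config, out)
    files += stage_networks(config, out)
    files += stage_metrics(config, out, options)
    files += stage_stats(config, out, options)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": _version,
        "stage_versions": {s: _version for s in ("simulate", "build-networks", "metrics", "stats")},
        "options": {
            "grid": dataclasses.asdict(options.grid),
            "n_null": options.n_null,
            "network_kinds": list(options.network_kinds),
        },
        "files": {str(p.relative_to(out)): sha256_of(p) for p in sorted(set(files))},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    write_manifest(out / "manifest.json", manifest)
    return manifest


def summarize_run(out_dir: str | Path) -> str:
    """Render a human-readable report from a completed run directory."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.json in {out}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    required = ["comparisons.tsv", "moderation.json", "metrics_auc.tsv"]
    missing = [f for f in required if f not in manifest["files"]]
    if missing:
        raise ValueError(f"manifest incomplete; missing outputs: {missing}")

    lines = [
        "# scnkit run summary",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}",
        "",
    ]
    comp = pd.read_csv(out / "comparisons.tsv", sep="\t")
    if len(comp):
        sig = comp[comp.p < 0.05]
        lines.append(
            f"## Group comparisons: {len(comp)} contrasts, {len(sig)} with p < 0.05"
        )
        for _, row in sig.iterrows():
            lines.append(
                f"- {row['network']}/{row['metric']} {row['contrast']} at t={row['timepoint']:g}: "
                f"{row['test']} p={row['p']:.4f}"
            )
    mod = json.loads((out / "moderation.json").read_text())
    if not mod:
        raise ValueError("stats stage produced no moderation models")
    lines.append("")
    lines.append("## Moderation models (metric x group interaction)")
    for name, m in mod.items():
        diff = m["slope_difference"]
        tag = "recovered" if m["interaction_recovered"] else "not recovered"
        lines.append(
            f"- {name}: interaction beta={diff['estimate']:.3f} "
            f"(95% CI {diff['ci'][0]:.3f}..{diff['ci'][1]:.3f}, p={diff['p']:.4f}); "
            f"planted={m['planted_interaction']:.3f} -> {tag}; "
            f"R2m={m['r2_marginal']:.3f} R2c={m['r2_conditional']:.3f} "
            f"f2={m['f2_interaction']:.3f}"
        )
    traj_path = out / "trajectories.tsv"
    if traj_path.exists():
        traj = pd.read_csv(traj_path, sep="\t")
        if len(traj):
            lines.append("")
            lines.append("## Longitudinal trajectories")
            for _, row in traj.iterrows():
                lines.append(
                    f"- {row['metric']} in {row['group']}: edf={row['edf']:.2f}, "
                    f"p_smooth={row['p_smooth']:.4f}, k={row['k_selected']}"
                )
    return "\n".join(lines) + "\n"
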