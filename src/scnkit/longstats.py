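"""Statistical layer: test-selection decision tree, mixed-effects moderation
models with simple slopes and effect sizes, and longitudinal trajectories.

Group comparisons follow a fixed decision tree (normality by Shapiro-Wilk,
homogeneity by Levene, both at alpha = 0.05): Student t when both hold,
Welch t under unequal variances, Mann-Whitney U under non-normality; paired
contrasts use the paired t or the Wilcoxon signed-rank test on the
differences.  Every result carries the trace of which checks fired.

Moderation models are linear mixed models

    outcome ~ metric + group + metric:group + C(timepoint) + (1 | subject)

fitted by REML, with the injury-only group as the reference level.  Fixed
effects are tested with Satterthwaite-type small-sample degrees of freedom
(recorded in ``df_method``).  Simple slopes decompose a metric-by-group
interaction into per-group conditional slopes; effect sizes are Nakagawa
marginal/conditional R-squared and Cohen's f-squared of the interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from ._mixed import ClusteredData, SatterthwaiteEngine, gls_beta
from .trajectory import TrajectoryFit, fit_trajectory

__all__ = [
    "ComparisonResult",
    "ModerationResult",
    "TrajectoryFit",
    "select_and_compare",
    "fit_moderation_model",
    "simple_slopes",
    "model_effect_sizes",
    "cohens_f2",
    "fit_trajectory",
]

SCREEN_ALPHA = 0.05  # normality / variance-homogeneity screening level


# ---------------------------------------------------------------------------
# decision-tree group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    ci: tuple[float, float] | None
    effect_size: float
    effect_size_name: str
    decision_trace: tuple[str, ...]


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else float("nan")


def select_and_compare(
    group_a: Sequence[float], group_b: Sequence[float], paired: bool = False
) -> ComparisonResult:
    """Compare two samples with the test the screening checks select.

    Unpaired: Shapiro-Wilk on each group; non-normality in either sends the
    data to the Mann-Whitney U test, otherwise Levene's test decides between
    the Student and Welch t-tests.  Paired: Shapiro-Wilk on the differences
    decides between the paired t and the Wilcoxon signed-rank test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    trace: list[str] = []

    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length samples")
        d = a - b
        if np.ptp(d) == 0:
            raise ValueError("paired differences are constant; test undefined")
        p_norm = stats.shapiro(d).pvalue
        trace.append(f"shapiro_diff p={p_norm:.4g}")
        if p_norm < SCREEN_ALPHA:
            trace.append("differences non-normal -> wilcoxon_signed_rank")
            res = stats.wilcoxon(a, b)
            n = len(d)
            rb = 1.0 - 2.0 * res.statistic / (n * (n + 1) / 2)  # rank-biserial
            return ComparisonResult(
                "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue),
                None, float(rb), "rank_biserial", tuple(trace),
            )
        trace.append("differences normal -> paired_t")
        res = stats.ttest_rel(a, b)
        ci = res.confidence_interval(0.95)
        dz = float(d.mean() / d.std(ddof=1))
        return ComparisonResult(
            "paired_t", float(res.statistic), float(res.pvalue),
            (float(ci.low), float(ci.high)), dz, "cohens_dz", tuple(trace),
        )

    pa = stats.shapiro(a).pvalue
    pb = stats.shapiro(b).pvalue
    trace.append(f"shapiro_a p={pa:.4g}")
    trace.append(f"shapiro_b p={pb:.4g}")
    if min(pa, pb) < SCREEN_ALPHA:
        trace.append("non-normality detected -> mann_whitney_u")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rb = 1.0 - 2.0 * res.statistic / (len(a) * len(b))  # rank-biserial
        return ComparisonResult(
            "mann_whitney_u", float(res.statistic), float(res.pvalue),
            None, float(rb), "rank_biserial", tuple(trace),
        )
    p_lev = stats.levene(a, b).pvalue
    trace.append(f"levene p={p_lev:.4g}")
    equal_var = p_lev >= SCREEN_ALPHA
    trace.append("equal variances -> independent_t" if equal_var
                 else "unequal variances -> welch_t")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(
        "independent_t" if equal_var else "welch_t",
        float(res.statistic), float(res.pvalue),
        (float(ci.low), float(ci.high)), _cohens_d(a, b), "cohens_d", tuple(trace),
    )


# ---------------------------------------------------------------------------
# mixed-effects moderation models
# ---------------------------------------------------------------------------


@dataclass
class ModerationResult:
    """Fitted moderation model: coefficient table, variance components,
    simple slopes and effect sizes."""

    coefficients: pd.DataFrame          # index: term; beta, se, df, t, p, ci_low, ci_high
    df_method: str
    tau: float                          # random-intercept variance
    sigma2: float                       # residual variance
    reference_group: str
    other_group: str
    simple_slopes: pd.DataFrame | None = None
    slope_difference: dict | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    f2_interaction: float | None = None
    converged: bool = True
    # internal handles for refits / contrasts
    _data: ClusteredData | None = field(default=None, repr=False)
    _terms: tuple[str, ...] = field(default=(), repr=False)
    _engine: SatterthwaiteEngine | None = field(default=None, repr=False)
    _inputs: dict | None = field(default=None, repr=False)

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "beta"])


def _build_design(
    metric: np.ndarray,
    group: np.ndarray,
    timepoint: np.ndarray,
    include_interaction: bool,
) -> tuple[np.ndarray, list[str], str, str]:
    levels = sorted(set(group.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    # injury-only group is the reference when present, else lexicographic
    ref = "sci_only" if "sci_only" in levels else levels[0]
    other = next(l for l in levels if l != ref)
    g = (group == other).astype(float)
    tlevels = sorted(set(np.asarray(timepoint, dtype=float).tolist()))
    if len(tlevels) < 2:
        raise ValueError("need at least 2 timepoints")
    cols = [np.ones_like(metric, dtype=float), metric.astype(float), g]
    names = ["intercept", "metric", f"group[{other}]"]
    if include_interaction:
        cols.append(metric.astype(float) * g)
        names.append("metric:group")
    for t in tlevels[1:]:
        cols.append((np.asarray(timepoint, dtype=float) == t).astype(float))
        names.append(f"timepoint[{t:g}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular fixed-effect design (collinear columns)")
    return x, names, ref, other


def fit_moderation_model(
    outcome: Sequence[float],
    metric: Sequence[float],
    group: Sequence[str],
    timepoint: Sequence[float],
    subject: Sequence[str],
    include_interaction: bool = True,
    with_effect_sizes: bool = True,
) -> ModerationResult:
    """Fit ``outcome ~ metric * group + C(timepoint) + (1 | subject)`` by REML.

    Timepoint enters categorically; the injury-only group is the reference
    level, so the ``metric`` coefficient is the reference-group slope and
    ``metric:group`` is the slope difference.  Fixed effects are tested with
    Satterthwaite-type degrees of freedom.  Set
    ``include_interaction=False`` for the main-effects-only variant (also
    used internally as the reduced model for Cohen's f-squared).
    """
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(metric, dtype=float)
    grp = np.asarray(group)
    tp = np.asarray(timepoint, dtype=float)
    subj = np.asarray(subject)
    if not (len(y) == len(m) == len(grp) == len(tp) == len(subj)):
        raise ValueError("all input vectors must have equal length")
    for g in sorted(set(grp.tolist())):
        if len(set(subj[grp == g].tolist())) < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")

    x, names, ref, other = _build_design(m, grp, tp, include_interaction)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, x, groups=subj)
        try:
            fit = model.fit(reml=True)
        except Exception:  # noqa: BLE001 - retry with a derivative-free optimizer
            try:
                fit = model.fit(reml=True, method="powell")
            except Exception as exc:  # noqa: BLE001
                raise ValueError(f"mixed model failed to converge: {exc}") from exc
    tau = float(np.atleast_2d(fit.cov_re)[0, 0])
    sigma2 = float(fit.scale)
    if not (np.all(np.isfinite(fit.fe_params)) and np.isfinite(tau) and np.isfinite(sigma2)):
        raise ValueError(
            "mixed model did not converge to finite estimates "
            f"(tau={tau}, sigma2={sigma2})"
        )

    data = ClusteredData.from_arrays(x, y, subj)
    beta = gls_beta(data, tau, sigma2)
    engine = SatterthwaiteEngine(data, tau, sigma2)
    rows = []
    for j, name in enumerate(names):
        c = np.zeros(len(names))
        c[j] = 1.0
        se = float(np.sqrt(engine.cov_beta[j, j]))
        df = engine.df_for_contrast(c)
        t_val = beta[j] / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t_val), df)
        half = stats.t.ppf(0.975, df) * se
        rows.append(
            {"term": name, "beta": beta[j], "se": se, "df": df, "t": t_val,
             "p": p, "ci_low": beta[j] - half, "ci_high": beta[j] + half}
        )
    coef = pd.DataFrame(rows).set_index("term")

    result = ModerationResult(
        coefficients=coef,
        df_method="satterthwaite",
        tau=tau,
        sigma2=sigma2,
        reference_group=ref,
        other_group=other,
        _data=data,
        _terms=tuple(names),
        _engine=engine,
        _inputs={"outcome": y, "metric": m, "group": grp, "timepoint": tp, "subject": subj},
    )
    if include_interaction:
        result.simple_slopes, result.slope_difference = _compute_simple_slopes(result)
    if with_effect_sizes:
        r2m, r2c, f2 = model_effect_sizes(result)
        result.r2_marginal, result.r2_conditional, result.f2_interaction = r2m, r2c, f2
    return result


def _compute_simple_slopes(fit: ModerationResult) -> tuple[pd.DataFrame, dict]:
    names = list(fit._terms)
    if "metric:group" not in names:
        raise ValueError("model has no metric:group interaction term")
    j_m = names.index("metric")
    j_i = names.index("metric:group")
    engine = fit._engine
    beta = fit.coefficients["beta"].to_numpy()

    def contrast_row(label: str, c: np.ndarray) -> dict:
        est = float(c @ beta)
        se = float(np.sqrt(c @ engine.cov_beta @ c))
        df = engine.df_for_contrast(c)
        t_val = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t_val), df)
        half = stats.t.ppf(0.975, df) * se
        return {"group": label, "slope": est, "se": se, "df": df, "t": t_val,
                "p": p, "ci_low": est - half, "ci_high": est + half}

    c_ref = np.zeros(len(names)); c_ref[j_m] = 1.0
    c_oth = np.zeros(len(names)); c_oth[j_m] = 1.0; c_oth[j_i] = 1.0
    slopes = pd.DataFrame(
        [contrast_row(fit.reference_group, c_ref), contrast_row(fit.other_group, c_oth)]
    ).set_index("group")
    diff_row = fit.coefficients.loc["metric:group"]
    difference = {
        "estimate": float(diff_row["beta"]), "se": float(diff_row["se"]),
        "df": float(diff_row["df"]), "p": float(diff_row["p"]),
        "ci": (float(diff_row["ci_low"]), float(diff_row["ci_high"])),
    }
    return slopes, difference


def simple_slopes(fit: ModerationResult) -> tuple[pd.DataFrame, dict]:
    """Per-group conditional slopes of the metric, plus their difference.

    The reference-group slope is the ``metric`` coefficient; the other
    group's slope adds the interaction coefficient; the between-group
    difference *is* the interaction estimate with its test.
    """
    if fit.simple_slopes is not None and fit.slope_difference is not None:
        return fit.simple_slopes, fit.slope_difference
    return _compute_simple_slopes(fit)


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f-squared for the terms dropped in the reduced model."""
    if r2_full >= 1.0:
        raise ValueError("f-squared undefined when the full model explains all variance")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def _nakagawa_r2(fit: ModerationResult) -> tuple[float, float]:
    x = np.vstack(fit._data.xs)
    beta = fit.coefficients["beta"].to_numpy()
    var_f = float(np.var(x @ beta, ddof=0))
    total = var_f + fit.tau + fit.sigma2
    return var_f / total, (var_f + fit.tau) / total


def model_effect_sizes(
    fit: ModerationResult, reduced: ModerationResult | None = None
) -> tuple[float, float, float]:
    """Nakagawa marginal/conditional R-squared and the interaction's f-squared.

    Marginal R2 is the fixed-effect variance share; conditional R2 adds the
    random-intercept variance.  f-squared compares the full model with its
    interaction-free refit on the same data (computed here if not supplied).
    """
    r2m, r2c = _nakagawa_r2(fit)
    if "metric:group" not in fit._terms:
        return r2m, r2c, float("nan")
    if reduced is None:
        inp = fit._inputs
        reduced = fit_moderation_model(
            inp["outcome"], inp["metric"], inp["group"], inp["timepoint"], inp["subject"],
            include_interaction=False, with_effect_sizes=False,
        )
    r2m_red, _ = _nakagawa_r2(reduced)
    # sampling noise can put the reduced R2 above the full R2; the effect
    # size of the interaction is then indistinguishable from zero
    return r2m, r2c, max(0.0, cohens_f2(r2m, r2m_red))
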