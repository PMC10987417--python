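"""The five-question concussion analysis pipeline plus temporal trends.

Stages (all consuming synthetic or real cohorts through the same interface):

* temporal trends — ZINB mixed models of daily total severity and daily
  profile count against a natural spline of days post-injury, with percent
  decline day 0 -> 14 and a linear-time comparison;
* q1 — per-profile probability of initial presentation by sex (Bernoulli
  mixed models);
* q2 — initial severity within each profile by sex (NB2 mixed models);
* q3 — time-to-recovery within each profile by sex (NB2 mixed models);
* q4 — initial profile count predicted by initial severity (binomial(6)
  mixed model with spline(severity) x sex);
* q5 — recovery and RTP times predicted by profile count, with per-count sex
  contrasts.

Cross-sectional stages consume only the initial-evaluation table plus
outcomes; the repeated-measures table feeds temporal trends alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import (
    apply_inclusion_filter,
    build_daily_table,
    build_initial_table,
    summarize_assignment_table,
)
from .glmm import (
    MixedModelFit,
    ModelSpec,
    cohens_d,
    contrast_between,
    fit_glmm,
    predict_conditional,
    variance_explained,
    wald_term_test,
)
from .scat5 import PROFILE_NAMES, ProfileRegistry, default_registry

__all__ = [
    "SexContrast",
    "TemporalTrends",
    "Q4Result",
    "Q5Result",
    "AnalysisReport",
    "temporal_trends",
    "q1_profile_probability",
    "q2_severity_within_profile",
    "q3_recovery_within_profile",
    "q4_profiles_from_severity",
    "q5_outcomes_from_profile_count",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _pooled_sd(values: pd.Series, sex: pd.Series) -> float:
    """Pooled (across sexes) standard deviation of an outcome."""
    parts = []
    for s in ("female", "male"):
        v = values[sex == s].to_numpy(float)
        if len(v) > 1:
            parts.append((len(v) - 1, np.var(v, ddof=1)))
    if not parts:
        return float("nan")
    dof = sum(n for n, _ in parts)
    if dof <= 0:
        return float("nan")
    return float(np.sqrt(sum(n * v for n, v in parts) / dof))


def _mean_deriv(fit: MixedModelFit, eta: np.ndarray) -> np.ndarray:
    """d(mean response)/d(eta), by central difference (link-agnostic)."""
    from .glmm import _make_family

    fam = _make_family(fit.spec.family, fit.spec.k_trials)
    h = 1e-6
    return (fam.mean_response(eta + h, fit.extra) - fam.mean_response(eta - h, fit.extra)) / (2 * h)


@dataclass
class SexContrast:
    """One female-vs-male contrast: predicted means, CI, p-value, effect size."""

    label: str
    mean_female: float
    ci_female: tuple[float, float]
    mean_male: float
    ci_male: tuple[float, float]
    difference: float
    ci_difference: tuple[float, float]
    p: float
    d: float
    magnitude: str
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sex_contrast(
    fit: MixedModelFit,
    grid: pd.DataFrame,
    label: str,
    pooled_sd: float,
    n: int,
) -> SexContrast:
    """Female (row 0) vs male (row 1) contrast on a two-row grid."""
    eff = predict_conditional(fit, grid)
    base = contrast_between(fit, grid, 0, 1)
    X = fit.design.transform(grid)
    J = _mean_deriv(fit, eff.eta)
    g = J[0] * X[0] - J[1] * X[1]
    se_resp = float(np.sqrt(max(g @ fit.cov_fixed() @ g, 0.0)))
    diff = base["response_diff"]
    z = norm.ppf(0.975)
    if pooled_sd and np.isfinite(pooled_sd) and pooled_sd > 0:
        es = cohens_d(diff, pooled_sd)
        d_val, mag = es.value, es.magnitude
    else:
        d_val, mag = float("nan"), "undefined"
    return SexContrast(
        label=label,
        mean_female=float(eff.estimate[0]),
        ci_female=(float(eff.lower[0]), float(eff.upper[0])),
        mean_male=float(eff.estimate[1]),
        ci_male=(float(eff.lower[1]), float(eff.upper[1])),
        difference=float(diff),
        ci_difference=(float(diff - z * se_resp), float(diff + z * se_resp)),
        p=float(base["p"]),
        d=float(d_val),
        magnitude=mag,
        n=n,
    )


# ---------------------------------------------------------------------------
# Temporal trends
# ---------------------------------------------------------------------------


@dataclass
class TemporalTrends:
    severity_decline_pct: float
    severity_r2: dict[str, float]
    severity_fit: MixedModelFit
    profiles_decline_pct: Optional[float] = None
    profiles_r2: Optional[dict[str, float]] = None
    profiles_fit: Optional[MixedModelFit] = None
    severity_linear_r2: Optional[dict[str, float]] = None
    profiles_linear_r2: Optional[dict[str, float]] = None

    def to_dict(self) -> dict:
        return {
            "severity_decline_pct": self.severity_decline_pct,
            "severity_r2": self.severity_r2,
            "profiles_decline_pct": self.profiles_decline_pct,
            "profiles_r2": self.profiles_r2,
            "severity_linear_r2": self.severity_linear_r2,
            "profiles_linear_r2": self.profiles_linear_r2,
        }


def _decline_pct(fit: MixedModelFit, day_from: int = 0, day_to: int = 14) -> float:
    grid = pd.DataFrame({"day": [day_from, day_to]})
    eff = predict_conditional(fit, grid)
    if eff.estimate[0] <= 0:
        return float("nan")
    return float(100.0 * (1.0 - eff.estimate[1] / eff.estimate[0]))


def temporal_trends(
    daily: pd.DataFrame,
    spline_df: int = 3,
    include_profiles: bool = True,
    include_linear: bool = True,
    seed: int = 0,
) -> TemporalTrends:
    """Repeated-measures ZINB mixed models of severity and profile count vs day.

    Requires longitudinal data (>= 2 evaluations for a nontrivial share of
    athletes).  Reports the percent decline of the predicted population mean
    from day 0 to day 14 and, optionally, linear-time comparison fits.
    """
    n_multi = (daily.groupby("athlete_id").size() >= 2).mean()
    if len(daily) == 0 or n_multi < 0.1:
        raise ValueError(
            "temporal trends require repeated measures: fewer than 10% of "
            "athletes have >= 2 evaluations"
        )
    groups = ["sport_group", "athlete_id"]
    sev_fit = fit_glmm(
        ModelSpec("severity", "zinb", terms=[f"ns(day,{spline_df})"], groups=groups),
        daily,
        seed=seed,
    )
    result = TemporalTrends(
        severity_decline_pct=_decline_pct(sev_fit),
        severity_r2=variance_explained(sev_fit, daily),
        severity_fit=sev_fit,
    )
    if include_profiles:
        prof_fit = fit_glmm(
            ModelSpec("n_profiles", "zinb", terms=[f"ns(day,{spline_df})"], groups=groups),
            daily,
            seed=seed,
        )
        result.profiles_fit = prof_fit
        result.profiles_decline_pct = _decline_pct(prof_fit)
        result.profiles_r2 = variance_explained(prof_fit, daily)
    if include_linear:
        sev_lin = fit_glmm(
            ModelSpec("severity", "zinb", terms=["day"], groups=groups), daily, seed=seed
        )
        result.severity_linear_r2 = variance_explained(sev_lin, daily)
        if include_profiles:
            prof_lin = fit_glmm(
                ModelSpec("n_profiles", "zinb", terms=["day"], groups=groups),
                daily,
                seed=seed,
            )
            result.profiles_linear_r2 = variance_explained(prof_lin, daily)
    return result


# ---------------------------------------------------------------------------
# Q1-Q3: per-profile sex effects
# ---------------------------------------------------------------------------


_SEX_GRID = pd.DataFrame({"sex": ["female", "male"]})


def q1_profile_probability(
    initial: pd.DataFrame,
    profile_names: Sequence[str] = PROFILE_NAMES,
    seed: int = 0,
) -> dict[str, SexContrast]:
    """Per-profile Bernoulli mixed models: P(profile present) ~ sex + (1 | sport group)."""
    results: dict[str, SexContrast] = {}
    for profile in profile_names:
        y = initial[profile].astype(int)
        if y.nunique() < 2:
            warnings.warn(
                f"profile {profile!r} has prevalence {y.mean():.0%}; model skipped"
            )
            continue
        df = initial[["sex", "sport_group"]].copy()
        df[profile] = y.to_numpy()
        fit = fit_glmm(
            ModelSpec(profile, "bernoulli", terms=["sex"], groups=["sport_group"]),
            df,
            seed=seed,
        )
        sd = _pooled_sd(y.astype(float), initial["sex"])
        results[profile] = _sex_contrast(fit, _SEX_GRID, profile, sd, len(df))
    return results


def _per_profile_outcome(
    initial: pd.DataFrame,
    outcome: str,
    profile_names: Sequence[str],
    family: str,
    seed: int,
) -> dict[str, SexContrast]:
    results: dict[str, SexContrast] = {}
    for profile in profile_names:
        subset = initial[initial[profile].astype(bool)].copy()
        n_censored = int(subset[outcome].isna().sum())
        subset = subset.dropna(subset=[outcome])
        if n_censored:
            logger.info(
                "%s within %s: excluded %d censored/missing outcome(s)",
                outcome,
                profile,
                n_censored,
            )
        if subset.empty:
            warnings.warn(f"profile {profile!r}: no usable observations; skipped")
            continue
        if subset["sex"].nunique() < 2:
            warnings.warn(f"profile {profile!r}: single-sex subset; skipped")
            continue
        subset[outcome] = subset[outcome].astype(float)
        fit = fit_glmm(
            ModelSpec(outcome, family, terms=["sex"], groups=["sport_group"]),
            subset,
            seed=seed,
        )
        sd = _pooled_sd(subset[outcome], subset["sex"])
        results[profile] = _sex_contrast(fit, _SEX_GRID, profile, sd, len(subset))
    return results


def q2_severity_within_profile(
    initial: pd.DataFrame,
    profile_names: Sequence[str] = PROFILE_NAMES,
    seed: int = 0,
) -> dict[str, SexContrast]:
    """Initial severity within each profile: NB2 mixed model, severity0 ~ sex."""
    return _per_profile_outcome(initial, "severity0", profile_names, "nb2", seed)


def q3_recovery_within_profile(
    initial: pd.DataFrame,
    profile_names: Sequence[str] = PROFILE_NAMES,
    seed: int = 0,
) -> dict[str, SexContrast]:
    """Time-to-recovery within each profile: NB2 mixed model on observed recoveries."""
    if initial["recovery"].notna().sum() == 0:
        raise ValueError("all recoveries are censored; q3 is inestimable")
    return _per_profile_outcome(initial, "recovery", profile_names, "nb2", seed)


# ---------------------------------------------------------------------------
# Q4: profile count from severity
# ---------------------------------------------------------------------------


@dataclass
class Q4Result:
    grid_severity: list[float]
    curve_female: list[float]
    curve_male: list[float]
    lower_female: list[float]
    upper_female: list[float]
    lower_male: list[float]
    upper_male: list[float]
    band_0_1_max_severity: float
    band_all6_min_severity: Optional[float]
    interaction_p: float
    r2: dict[str, float]
    fit: MixedModelFit

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "fit"
        }
        return d


def q4_profiles_from_severity(
    initial: pd.DataFrame, spline_df: int = 3, seed: int = 0
) -> Q4Result:
    """Binomial(6) mixed model: n_profiles0 ~ ns(severity0, df) * sex + (1 | sport group).

    Outputs the predicted severity -> profile-count curve per sex, the joint
    Wald test of the spline-by-sex interaction, Nakagawa variance explained,
    and the severity band edges where the rounded predicted count leaves 0-1
    and reaches 6.
    """
    if initial["severity0"].nunique() < 2:
        raise ValueError("severity0 is constant; spline inestimable")
    spline = f"ns(severity0,{spline_df})"
    fit = fit_glmm(
        ModelSpec(
            "n_profiles0",
            "binomial_k",
            terms=[f"{spline}*sex"],
            groups=["sport_group"],
            k_trials=6,
        ),
        initial,
        seed=seed,
    )
    s_max = int(initial["severity0"].max())
    sev = np.arange(0, s_max + 1, dtype=float)
    grids = {}
    for sex in ("female", "male"):
        grid = pd.DataFrame({"severity0": sev, "sex": sex})
        grids[sex] = predict_conditional(fit, grid)
    mean_curve = (grids["female"].estimate + grids["male"].estimate) / 2
    rounded = np.round(mean_curve).astype(int)
    low_band = sev[rounded <= 1]
    high_band = sev[rounded >= 6]
    interaction = wald_term_test(fit, f"{spline}:sex")
    return Q4Result(
        grid_severity=sev.tolist(),
        curve_female=grids["female"].estimate.tolist(),
        curve_male=grids["male"].estimate.tolist(),
        lower_female=grids["female"].lower.tolist(),
        upper_female=grids["female"].upper.tolist(),
        lower_male=grids["male"].lower.tolist(),
        upper_male=grids["male"].upper.tolist(),
        band_0_1_max_severity=float(low_band.max()) if len(low_band) else float("nan"),
        band_all6_min_severity=float(high_band.min()) if len(high_band) else None,
        interaction_p=float(interaction["p"]),
        r2=variance_explained(fit, initial),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Q5: outcomes from profile count
# ---------------------------------------------------------------------------


@dataclass
class Q5Result:
    outcome: str
    grid_counts: list[int]
    curve_female: list[float]
    curve_male: list[float]
    lower_female: list[float]
    upper_female: list[float]
    lower_male: list[float]
    upper_male: list[float]
    per_count_contrasts: dict[int, SexContrast]
    marginal_mean_female: float
    marginal_ci_female: tuple[float, float]
    marginal_mean_male: float
    marginal_ci_male: tuple[float, float]
    r2: dict[str, float]
    fit: MixedModelFit

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("fit", "per_count_contrasts")
        }
        d["per_count_contrasts"] = {
            str(k): v.to_dict() for k, v in self.per_count_contrasts.items()
        }
        return d


def _marginal_mean(
    fit: MixedModelFit, counts: np.ndarray, weights: np.ndarray, sex: str
) -> tuple[float, tuple[float, float]]:
    """Weighted average of per-count predicted means with a delta-method CI."""
    grid = pd.DataFrame({"n_profiles0": counts.astype(float), "sex": sex})
    eff = predict_conditional(fit, grid)
    X = fit.design.transform(grid)
    J = _mean_deriv(fit, eff.eta)
    g = (weights[:, None] * J[:, None] * X).sum(axis=0)
    var = float(g @ fit.cov_fixed() @ g)
    m = float(np.sum(weights * eff.estimate))
    z = norm.ppf(0.975)
    half = z * np.sqrt(max(var, 0.0))
    return m, (m - half, m + half)


def q5_outcomes_from_profile_count(
    initial: pd.DataFrame,
    outcome: str = "recovery",
    spline_df: int = 3,
    family: str = "nb2",
    contrast_counts: Sequence[int] = tuple(range(7)),
    seed: int = 0,
) -> Q5Result:
    """Count-family mixed model: outcome ~ ns(n_profiles0, df) * sex + (1 | sport group).

    Per-count female-male contrasts are evaluated on the fitted curve at the
    requested integer profile counts (0-6); counts with no observations are
    skipped with a warning.  Marginal per-sex means average the fitted curve
    over the observed profile-count distribution.
    """
    for c in contrast_counts:
        if not 0 <= int(c) <= 6:
            raise ValueError(f"profile count {c} outside the domain 0-6")
    data = initial.dropna(subset=[outcome]).copy()
    if data.empty:
        raise ValueError(f"no observed values of {outcome!r}")
    data[outcome] = data[outcome].astype(float)
    spline = f"ns(n_profiles0,{spline_df})"
    fit = fit_glmm(
        ModelSpec(outcome, family, terms=[f"{spline}*sex"], groups=["sport_group"]),
        data,
        seed=seed,
    )
    observed_counts = np.sort(data["n_profiles0"].unique()).astype(int)
    grid_counts = observed_counts.astype(float)
    effs = {}
    for sex in ("female", "male"):
        grid = pd.DataFrame({"n_profiles0": grid_counts, "sex": sex})
        effs[sex] = predict_conditional(fit, grid)
    contrasts: dict[int, SexContrast] = {}
    for c in contrast_counts:
        c = int(c)
        subset = data[data["n_profiles0"] == c]
        if subset.empty:
            warnings.warn(f"{outcome}: no observations at profile count {c}; contrast skipped")
            continue
        grid = pd.DataFrame({"n_profiles0": [float(c)] * 2, "sex": ["female", "male"]})
        sd = _pooled_sd(data[outcome], data["sex"])
        contrasts[c] = _sex_contrast(fit, grid, f"{outcome}@count={c}", sd, len(subset))
    weights = (
        data["n_profiles0"].value_counts(normalize=True).reindex(observed_counts).to_numpy()
    )
    mf, cif = _marginal_mean(fit, grid_counts, weights, "female")
    mm, cim = _marginal_mean(fit, grid_counts, weights, "male")
    return Q5Result(
        outcome=outcome,
        grid_counts=observed_counts.tolist(),
        curve_female=effs["female"].estimate.tolist(),
        curve_male=effs["male"].estimate.tolist(),
        lower_female=effs["female"].lower.tolist(),
        upper_female=effs["female"].upper.tolist(),
        lower_male=effs["male"].lower.tolist(),
        upper_male=effs["male"].upper.tolist(),
        per_count_contrasts=contrasts,
        marginal_mean_female=mf,
        marginal_ci_female=cif,
        marginal_mean_male=mm,
        marginal_ci_male=cim,
        r2=variance_explained(fit, data),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Machine-readable results of a full pipeline run."""

    seed: int
    n_episodes_input: int
    n_episodes_analyzed: int
    cohort_summary: dict
    temporal: Optional[dict]
    q1: dict[str, dict]
    q2: dict[str, dict]
    q3: dict[str, dict]
    q4: dict
    q5_recovery: dict
    q5_rtp: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def run_pipeline(config, include_temporal: bool = True) -> AnalysisReport:
    """Execute cohort assembly -> classification -> filtering -> all analyses.

    ``config`` is a :class:`concussion_profiles.io.RunConfig`.  Deterministic
    given the config seed.  Stage failures halt with a stage-labeled error;
    stage timings go to the log, not the report (reports are byte-identical
    across runs with the same seed).
    """
    from .io import assemble_episodes, load_registry, read_metadata_csv, read_symptom_csv
    from .simulate import generate_cohort

    registry = (
        load_registry(config.registry_path) if config.registry_path else default_registry()
    )

    def stage(name, func, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = func(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
        return out

    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        episodes = stage("simulate", generate_cohort, sim)
    else:
        symptoms = stage(
            "read_symptoms", read_symptom_csv, config.symptom_csv, config.symptom_dialect
        )
        metadata = stage("read_metadata", read_metadata_csv, config.metadata_csv)
        episodes = stage(
            "assemble", assemble_episodes, symptoms, metadata, config.sport_mapping
        )

    n_input = len(episodes)
    analyzed = stage("inclusion_filter", apply_inclusion_filter, episodes)
    initial = stage("initial_table", build_initial_table, analyzed, registry)
    summary = summarize_assignment_table(
        initial, profile_names=registry.profile_names
    )

    temporal = None
    if include_temporal:
        daily = stage("daily_table", build_daily_table, analyzed, registry)
        temporal = stage(
            "temporal_trends",
            temporal_trends,
            daily,
            config.spline_df,
            seed=config.seed,
        )

    q1 = stage("q1", q1_profile_probability, initial, registry.profile_names, config.seed)
    q2 = stage("q2", q2_severity_within_profile, initial, registry.profile_names, config.seed)
    q3 = stage("q3", q3_recovery_within_profile, initial, registry.profile_names, config.seed)
    q4 = stage("q4", q4_profiles_from_severity, initial, config.spline_df, config.seed)
    q5r = stage(
        "q5_recovery",
        q5_outcomes_from_profile_count,
        initial,
        "recovery",
        config.spline_df,
        config.recovery_family,
        seed=config.seed,
    )
    q5p = stage(
        "q5_rtp",
        q5_outcomes_from_profile_count,
        initial,
        "rtp",
        config.spline_df,
        config.recovery_family,
        seed=config.seed,
    )

    return AnalysisReport(
        seed=config.seed,
        n_episodes_input=n_input,
        n_episodes_analyzed=len(analyzed),
        cohort_summary={
            "n_total": summary.n_total,
            "n_by_sex": summary.n_by_sex,
            "profiles": summary.profile_counts,
            "sex_chi2": summary.sex_chi2,
            "sex_chi2_p": summary.sex_chi2_p,
        },
        temporal=temporal.to_dict() if temporal is not None else None,
        q1={k: v.to_dict() for k, v in q1.items()},
        q2={k: v.to_dict() for k, v in q2.items()},
        q3={k: v.to_dict() for k, v in q3.items()},
        q4=q4.to_dict(),
        q5_recovery=q5r.to_dict(),
        q5_rtp=q5p.to_dict(),
    )
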