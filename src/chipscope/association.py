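"""Association statistics and evidence pooling for CHIP–Alzheimer's analyses.

Covers the epidemiological layer: logistic regression for case-control AD
status, proportional-odds ordinal regression for autopsy neuropathology grades
(CERAD neuritic plaque score, grouped Braak stage, and their composite),
Kaplan–Meier / log-rank survival comparisons, reconstruction of standard
errors from printed Wald P-values, and inverse-variance fixed-effects
meta-analysis — including runs stratified by APOE genotype bin, sex, or
mutated driver gene.

Model fitting delegates to statsmodels (logistic, proportional odds) and
lifelines (Kaplan–Meier, log-rank); this module owns the conventions: Wald
P-values against the standard normal throughout, strict APOE binning
(any ε4 allele → high risk), and inverse-variance pooling on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

APOE_GENOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

#: APOE risk bins: ε3ε3 neutral, ε2ε2/ε2ε3 low-risk, any ε4 allele high-risk.
APOE_BINS = {
    "e2e2": "low",
    "e2e3": "low",
    "e2e4": "high",  # carries an ε4 allele
    "e3e3": "neutral",
    "e3e4": "high",
    "e4e4": "high",
}

SEPARATION_THRESHOLD = 15.0  # |log-odds| beyond which we declare separation


class SeparationError(RuntimeError):
    """Quasi-complete separation: a coefficient diverged during fitting."""


# ---------------------------------------------------------------------------
# Effect estimates and fixed-effects pooling
# ---------------------------------------------------------------------------

def se_from_wald_p(estimate_log: float, p: float) -> float:
    """Reconstruct a standard error from a log-scale estimate and its
    two-sided Wald P-value: se = |estimate| / z_{p/2}.

    Lets printed per-cohort estimates (ratio + P) enter inverse-variance
    pooling when the original SEs are not published.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if estimate_log == 0:
        raise ValueError("estimate_log = 0: SE is not identifiable from P")
    z = stats.norm.isf(p / 2.0)
    return abs(estimate_log) / z


@dataclass(frozen=True)
class CohortEstimate:
    """A log-scale effect estimate (log OR or log SHR) from one cohort."""

    cohort: str
    effect_scale: Literal["log_or", "log_shr"]
    estimate: float
    se: float | None = None
    ci95: tuple[float, float] | None = None  # ratio scale
    p: float | None = None

    def resolved_se(self) -> float:
        """SE directly, from the 95% CI, or reconstructed from the Wald P."""
        if self.se is not None:
            return self.se
        if self.ci95 is not None:
            lo, hi = self.ci95
            return (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054)
        if self.p is not None:
            return se_from_wald_p(self.estimate, self.p)
        raise ValueError(
            f"cohort {self.cohort}: need one of se, ci95 or p to pool"
        )

    @classmethod
    def from_ratio(
        cls,
        cohort: str,
        ratio: float,
        effect_scale: Literal["log_or", "log_shr"] = "log_or",
        p: float | None = None,
        se: float | None = None,
        ci95: tuple[float, float] | None = None,
    ) -> "CohortEstimate":
        return cls(cohort, effect_scale, float(np.log(ratio)), se, ci95, p)


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance fixed-effects pooled estimate on the log scale."""

    pooled_estimate: float
    pooled_se: float
    ratio: float
    ci95: tuple[float, float]
    p: float
    weights: tuple[float, ...]  # normalized to sum 1
    cohorts: tuple[str, ...]


def fixed_effects_meta(estimates: Sequence[CohortEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis of log-scale estimates.

    pooled = Σ θᵢ/sᵢ² / Σ 1/sᵢ²,  pooled SE = (Σ 1/sᵢ²)^(-1/2), two-sided
    Wald P from the standard normal.
    """
    if len(estimates) < 2:
        raise ValueError("meta-analysis needs at least 2 estimates")
    scales = {e.effect_scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"mixed effect scales {scales}; pool within one scale")
    theta = np.array([e.estimate for e in estimates])
    se = np.array([e.resolved_se() for e in estimates])
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * pooled_se
    return MetaResult(
        pooled_estimate=pooled,
        pooled_se=pooled_se,
        ratio=float(np.exp(pooled)),
        ci95=(float(np.exp(pooled - half)), float(np.exp(pooled + half))),
        p=p,
        weights=tuple(w / np.sum(w)),
        cohorts=tuple(e.cohort for e in estimates),
    )


# ---------------------------------------------------------------------------
# Regression models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Per-coefficient estimates from a regression fit."""

    params: pd.Series
    se: pd.Series
    p: pd.Series  # two-sided, standard normal reference
    converged: bool
    n: int

    def coef(self, name: str) -> tuple[float, float, float]:
        return float(self.params[name]), float(self.se[name]), float(self.p[name])


def _check_separation(params: pd.Series) -> None:
    bad = params[params.abs() > SEPARATION_THRESHOLD]
    bad = bad[~bad.index.str.contains("Intercept|const|/")]
    if len(bad):
        raise SeparationError(
            f"separation detected for covariate(s): {list(bad.index)}"
        )


def fit_logistic(design: pd.DataFrame, outcome: Sequence[int]) -> FitResult:
    """Maximum-likelihood logistic regression (adds an intercept).

    Wald P-values are two-sided against the standard normal. Raises
    SeparationError when a covariate's log-odds coefficient diverges.
    """
    X = sm.add_constant(pd.DataFrame(design).astype(float), has_constant="add")
    y = np.asarray(outcome, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
    except np.linalg.LinAlgError:
        # singular information matrix: name any perfectly separating covariate
        suspects = []
        for col in X.columns:
            if col == "const":
                continue
            x0, x1 = X.loc[y == 0, col], X.loc[y == 1, col]
            if len(x0) and len(x1) and (x0.max() <= x1.min()
                                        or x1.max() <= x0.min()):
                suspects.append(col)
        raise SeparationError(
            f"separation detected for covariate(s): {suspects or 'unknown'}"
        ) from None
    params = res.params
    _check_separation(params)
    se = pd.Series(res.bse, index=params.index)
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index)
    return FitResult(params=params, se=se, p=p,
                     converged=bool(res.mle_retvals.get("converged", True)),
                     n=len(y))


def fit_ordinal_logistic(
    design: pd.DataFrame, outcome: Sequence[int]
) -> FitResult:
    """Proportional-odds (ordinal logistic) regression.

    P-values compare the t-statistic of each coefficient to the standard
    normal (the convention used for autopsy-grade models here), not a
    t-distribution. With only two observed outcome levels the model reduces
    to ordinary logistic regression.
    """
    y = pd.Series(list(outcome))
    levels = sorted(y.unique())
    if len(levels) < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    if len(levels) == 2:
        binary = (y == levels[1]).astype(int)
        res = fit_logistic(design, binary)
        keep = [i for i in res.params.index if i != "const"]
        return FitResult(res.params[keep], res.se[keep], res.p[keep],
                         res.converged, res.n)
    X = pd.DataFrame(design).astype(float)
    y_cat = pd.Categorical(y, categories=levels, ordered=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = OrderedModel(y_cat, X, distr="logit").fit(
            method="bfgs", maxiter=200, disp=0
        )
    params = res.params[: X.shape[1]]
    _check_separation(params)
    se = pd.Series(np.asarray(res.bse)[: X.shape[1]], index=params.index)
    t = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(t)), index=params.index)
    return FitResult(params=params, se=se, p=p, converged=res.mle_retvals is not None,
                     n=len(y))


def composite_adnc_score(cerad: int, braak_group: int) -> int:
    """Composite neuropathologic-change score: CERAD (0–3) plus grouped Braak
    stage (1–3), yielding an integer in 1..6."""
    if cerad not in (0, 1, 2, 3):
        raise ValueError(f"cerad must be 0..3, got {cerad}")
    if braak_group not in (1, 2, 3):
        raise ValueError(f"braak_group must be 1..3, got {braak_group}")
    return cerad + braak_group


def braak_group_from_stage(stage: int) -> int:
    """Group Braak stages: 0/I/II → 1, III/IV → 2, V/VI → 3."""
    if stage not in range(7):
        raise ValueError(f"Braak stage must be 0..6, got {stage}")
    return 1 if stage <= 2 else (2 if stage <= 4 else 3)


# ---------------------------------------------------------------------------
# Survival: Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

def kaplan_meier(
    times: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame with columns ``time`` and ``survival``; the step
    function is right-continuous, non-increasing, with S(0) = 1.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
    )


def log_rank_test(
    times: Sequence[float], events: Sequence[int], group: Sequence
) -> tuple[float, float]:
    """Two-sided log-rank test between two groups.

    Returns (chi-square statistic on 1 df, two-sided P). Tied event times are
    aggregated within each distinct time (Breslow-style).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {len(labels)}")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Stratified analyses
# ---------------------------------------------------------------------------

def apoe_bin(genotype: str) -> str:
    """Bin an APOE genotype: neutral (ε3ε3), low (ε2ε2/ε2ε3), high (any ε4)."""
    try:
        return APOE_BINS[genotype]
    except KeyError:
        raise ValueError(f"unknown APOE genotype {genotype!r}") from None


@dataclass
class StratifiedMetaResult:
    per_stratum: dict[str, MetaResult]
    per_cohort: dict[str, list[CohortEstimate]]  # stratum -> cohort estimates
    skipped: list[tuple[str, str, str]]  # (stratum, cohort, reason)


def _default_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Dummy-code the standard covariates into a numeric design matrix."""
    cols = {}
    for cov in covariates:
        if cov == "chip":
            cols["chip"] = df["chip"].astype(int)
        elif cov == "age":
            cols["age"] = df["age"].astype(float)
        elif cov == "sex":
            cols["sex_female"] = (df["sex"] == "female").astype(int)
        elif cov == "apoe":
            for g in APOE_GENOTYPES:
                if g == "e3e3":  # reference level
                    continue
                if (df["apoe"] == g).any():
                    cols[f"apoe_{g}"] = (df["apoe"] == g).astype(int)
        else:
            cols[cov] = df[cov].astype(float)
    return pd.DataFrame(cols, index=df.index)


def run_stratified_meta(
    subjects: pd.DataFrame,
    strata_def: Literal["apoe_bins", "sex", "driver_gene", "all"] = "apoe_bins",
    covariates: Sequence[str] = ("chip", "age", "sex"),
    outcome_col: str = "ad_status",
) -> StratifiedMetaResult:
    """Fit the configured logistic model per stratum per cohort, then pool
    across cohorts within each stratum by fixed-effects meta-analysis.

    ``subjects`` is one row per subject with columns: cohort, chip (bool),
    age, sex, apoe, the outcome column, and driver_genes (semicolon-joined)
    when stratifying by gene. Strata where a cohort lacks both outcome
    classes or where the fit separates are skipped and recorded.
    """
    df = subjects.copy()
    if strata_def == "apoe_bins":
        df["_stratum"] = df["apoe"].map(apoe_bin)
        strat_covs = [c for c in covariates if c != "apoe"]
    elif strata_def == "sex":
        df["_stratum"] = df["sex"]
        strat_covs = [c for c in covariates if c != "sex"]
    elif strata_def == "driver_gene":
        df = df.assign(
            _stratum=df["driver_genes"].fillna("").str.split(";")
        ).explode("_stratum")
        df = df[(df["_stratum"] != "") | ~df["chip"].astype(bool)]
        # noncarriers serve as the comparison group in every gene stratum
        carriers = df[df["_stratum"] != ""]
        noncarriers = df[df["_stratum"] == ""]
        frames = []
        for gene in sorted(carriers["_stratum"].unique()):
            frames.append(
                pd.concat(
                    [carriers[carriers["_stratum"] == gene],
                     noncarriers.assign(_stratum=gene)]
                )
            )
        df = pd.concat(frames) if frames else df.iloc[:0]
        strat_covs = list(covariates)
    elif strata_def == "all":
        df["_stratum"] = "all"
        strat_covs = list(covariates)
    else:
        raise ValueError(f"unknown strata_def {strata_def!r}")

    per_stratum: dict[str, MetaResult] = {}
    per_cohort: dict[str, list[CohortEstimate]] = {}
    skipped: list[tuple[str, str, str]] = []
    for stratum, sdf in df.groupby("_stratum"):
        ests: list[CohortEstimate] = []
        for cohort, cdf in sdf.groupby("cohort"):
            y = cdf[outcome_col].astype(int)
            if y.nunique() < 2 or cdf["chip"].astype(int).nunique() < 2:
                skipped.append((str(stratum), str(cohort), "degenerate"))
                warnings.warn(
                    f"stratum {stratum}/cohort {cohort}: degenerate, skipped",
                    stacklevel=2,
                )
                continue
            design = _default_design(cdf, strat_covs)
            try:
                fit = fit_logistic(design, y)
            except (SeparationError, np.linalg.LinAlgError) as exc:
                skipped.append((str(stratum), str(cohort), str(exc)))
                continue
            est, se, p = fit.coef("chip")
            ests.append(
                CohortEstimate(str(cohort), "log_or", est, se=se, p=p)
            )
        per_cohort[str(stratum)] = ests
        if len(ests) >= 2:
            per_stratum[str(stratum)] = fixed_effects_meta(ests)
        elif len(ests) == 1:
            e = ests[0]
            half = 1.959963984540054 * e.se
            per_stratum[str(stratum)] = MetaResult(
                e.estimate, e.se, float(np.exp(e.estimate)),
                (float(np.exp(e.estimate - half)), float(np.exp(e.estimate + half))),
                float(2 * stats.norm.sf(abs(e.estimate / e.se))),
                (1.0,), (e.cohort,),
            )
    return StratifiedMetaResult(per_stratum, per_cohort, skipped)
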