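"""Two-sample Mendelian randomization from GWAS summary statistics.

Estimates the causal effect of an exposure (here, genetic liability to clonal
hematopoiesis) on an outcome (Alzheimer's disease) from per-variant summary
statistics: exposure association γⱼ and outcome association Γⱼ with standard
errors, over k instruments. Four estimators are provided:

* per-instrument ratio estimates βⱼ = Γⱼ/γⱼ with first-order delta-method
  standard errors σⱼ = se(Γⱼ)/|γⱼ|;
* inverse-variance-weighted (IVW) pooling under a multiplicative
  random-effects model (SE inflated by √φ when the dispersion φ exceeds 1);
* the weighted median — the 50th percentile of the inverse-variance-weighted
  empirical distribution of ratio estimates, consistent as long as at least
  half the instrument weight is valid; SE by parametric bootstrap;
* MR-Egger weighted least squares with an intercept that absorbs average
  directional pleiotropy.

The reverse direction (outcome as exposure) uses the same machinery with the
roles of the traits swapped. Estimates from multiple outcome studies are
pooled by inverse-variance fixed-effects meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import CohortEstimate, MetaResult, fixed_effects_meta

DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_SEED = 1234

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class InstrumentRecord:
    """One genetic instrument's exposure and outcome associations."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(
                f"{self.variant_id}: standard errors must be positive"
            )


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate: log-odds of outcome per 1 log-odds of
    exposure, with Wald-normal CI and P."""

    method: Literal["ratio_single", "ivw_mre", "weighted_median", "egger"]
    estimate: float
    se: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    dispersion: float | None = None  # IVW φ, a crude pleiotropy signal
    warnings: tuple[str, ...] = ()

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.estimate - _Z95 * self.se)),
                float(np.exp(self.estimate + _Z95 * self.se)))


def _as_arrays(
    instruments: Sequence[InstrumentRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([i.beta_exposure for i in instruments])
    sg = np.array([i.se_exposure for i in instruments])
    G = np.array([i.beta_outcome for i in instruments])
    sG = np.array([i.se_outcome for i in instruments])
    return g, sg, G, sG


def _wald_p(theta: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(theta) / se))


def ratio_estimates(
    instruments: Sequence[InstrumentRecord],
) -> tuple[np.ndarray, np.ndarray, list[InstrumentRecord]]:
    """Per-instrument ratio estimates βⱼ = Γⱼ/γⱼ, σⱼ = se(Γⱼ)/|γⱼ|.

    Instruments with γ = 0 are dropped with a warning; returns (β, σ, kept).
    """
    kept = []
    for inst in instruments:
        if inst.beta_exposure == 0:
            warnings.warn(
                f"instrument {inst.variant_id}: zero exposure beta, dropped",
                stacklevel=2,
            )
            continue
        kept.append(inst)
    g, _, G, sG = _as_arrays(kept)
    return G / g, sG / np.abs(g), kept


def ivw_estimate(instruments: Sequence[InstrumentRecord]) -> MREstimate:
    """Inverse-variance-weighted estimate, multiplicative random effects.

    θ = Σ βⱼ/σⱼ² / Σ 1/σⱼ²; fixed-effects SE inflated by √φ where
    φ = Σ (βⱼ−θ)²/σⱼ² / (k−1), floored at no inflation (φ ≤ 1).
    """
    beta, sigma, kept = ratio_estimates(instruments)
    k = len(kept)
    if k < 2:
        warnings.warn("fewer than 2 usable instruments; single-ratio estimate",
                      stacklevel=2)
        theta, se = float(beta[0]), float(sigma[0])
        return MREstimate("ratio_single", theta, se, _wald_p(theta, se), 1)
    w = 1.0 / sigma**2
    theta = float(np.sum(w * beta) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    phi = float(np.sum(w * (beta - theta) ** 2) / (k - 1))
    se = se_fe * max(1.0, np.sqrt(phi))
    return MREstimate("ivw_mre", theta, se, _wald_p(theta, se), k,
                      dispersion=phi)


def weighted_median(beta: np.ndarray, weights: np.ndarray) -> float:
    """The weighted median of β with normalized weights.

    Sort β ascending (stable), form the centered cumulative weights
    sⱼ = Σ_{i≤j} wᵢ − wⱼ/2, and linearly interpolate β at s = 0.5.
    """
    order = np.argsort(beta, kind="stable")
    b = beta[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    return float(np.interp(0.5, s, b))


def weighted_median_estimate(
    instruments: Sequence[InstrumentRecord],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Inverse-variance weights on the ratio estimates; the SE resamples each
    βⱼ ~ Normal(βⱼ, σⱼ) ``n_boot`` times (seeded) and takes the standard
    deviation of the recomputed medians. Robust to invalid instruments
    carrying up to half the total weight.
    """
    beta, sigma, kept = ratio_estimates(instruments)
    if len(kept) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    w = 1.0 / sigma**2
    theta = weighted_median(beta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bb = rng.normal(beta, sigma)
        boots[i] = weighted_median(bb, w)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", theta, se, _wald_p(theta, se),
                      len(kept))


def egger_estimate(instruments: Sequence[InstrumentRecord]) -> MREstimate:
    """MR-Egger: weighted least squares of Γ on γ with an intercept.

    Instruments are oriented so every γ > 0; weights 1/se(Γ)². The slope is
    the causal estimate; the intercept estimates average directional
    pleiotropy, reported with its own SE and P.
    """
    kept = [i for i in instruments if i.beta_exposure != 0]
    if len(kept) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    g, _, G, sG = _as_arrays(kept)
    flip = np.sign(g)
    g, G = g * flip, G * flip
    w = 1.0 / sG**2
    wmsgs: tuple[str, ...] = ()
    gbar = np.sum(w * g) / np.sum(w)
    if np.sum(w * (g - gbar) ** 2) / np.sum(w) < 1e-12 * max(gbar**2, 1e-30):
        wmsgs = ("near-zero spread in exposure betas: weak Egger identification",)
    X = np.column_stack([np.ones_like(g), g])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ W @ G)
    resid = G - X @ coef
    k = len(g)
    # multiplicative dispersion, floored at 1 (as in the IVW-MRE convention)
    phi = max(1.0, float(resid @ (w * resid) / (k - 2)))
    cov = np.linalg.inv(xtwx) * phi
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MREstimate(
        "egger", slope, se_slope, _wald_p(slope, se_slope), k,
        egger_intercept=intercept, intercept_se=se_int,
        intercept_p=_wald_p(intercept, se_int),
        dispersion=phi, warnings=wmsgs,
    )


# ---------------------------------------------------------------------------
# Multi-study orchestration
# ---------------------------------------------------------------------------

def match_instruments(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> list[InstrumentRecord]:
    """Join exposure and outcome summary statistics on variant_id.

    Expects columns variant_id, beta, se in each table; an optional boolean
    ``flip`` column in the outcome table negates that variant's outcome beta
    (pre-computed allele harmonization).
    """
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exp", "_out")
    )
    records = []
    for _, row in merged.iterrows():
        b_out = float(row["beta_out"])
        if "flip" in merged.columns and bool(row.get("flip", False)):
            b_out = -b_out
        records.append(
            InstrumentRecord(
                variant_id=str(row["variant_id"]),
                beta_exposure=float(row["beta_exp"]),
                se_exposure=float(row["se_exp"]),
                beta_outcome=b_out,
                se_outcome=float(row["se_out"]),
            )
        )
    return records


@dataclass
class MRResult:
    direction: str
    per_study: dict[str, dict[str, MREstimate]]  # study -> method -> estimate
    pooled: MetaResult | None
    primary_method: str
    skipped_studies: list[tuple[str, str]]


def run_mr(
    exposure_stats: pd.DataFrame,
    outcome_stats_list: dict[str, pd.DataFrame],
    direction: Literal["forward", "reverse"] = "forward",
    primary: str = "weighted_median",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MRResult:
    """All MR estimators per outcome study, with the primary estimator pooled
    across studies by fixed-effects meta-analysis.

    Studies matching fewer than half the exposure instruments are skipped
    with a warning. ``direction`` is bookkeeping: callers pass swapped
    summary statistics for the reverse analysis.
    """
    per_study: dict[str, dict[str, MREstimate]] = {}
    skipped: list[tuple[str, str]] = []
    pooled_inputs: list[CohortEstimate] = []
    k_total = len(exposure_stats)
    for study, out_stats in outcome_stats_list.items():
        instruments = match_instruments(exposure_stats, out_stats)
        if len(instruments) < 0.5 * k_total:
            msg = (f"only {len(instruments)}/{k_total} instruments matched")
            warnings.warn(f"study {study}: {msg}; skipped", stacklevel=2)
            skipped.append((study, msg))
            continue
        ests = {
            "ivw_mre": ivw_estimate(instruments),
            "weighted_median": weighted_median_estimate(
                instruments, n_boot=n_boot, seed=seed
            ),
            "egger": egger_estimate(instruments),
        }
        per_study[study] = ests
        prim = ests[primary]
        pooled_inputs.append(
            CohortEstimate(study, "log_or", prim.estimate, se=prim.se)
        )
    if len(pooled_inputs) >= 2:
        pooled = fixed_effects_meta(pooled_inputs)
    elif len(pooled_inputs) == 1:
        e = pooled_inputs[0]
        half = _Z95 * e.se
        pooled = MetaResult(
            e.estimate, e.se, float(np.exp(e.estimate)),
            (float(np.exp(e.estimate - half)), float(np.exp(e.estimate + half))),
            _wald_p(e.estimate, e.se), (1.0,), (e.cohort,),
        )
    else:
        pooled = None
    return MRResult(direction, per_study, pooled, primary, skipped)
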