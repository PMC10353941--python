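"""Seeded synthetic-data generators for every input the pipeline consumes.

The study data behind a CHIP–Alzheimer's analysis are controlled-access,
so every stage here is exercised on synthetic inputs whose statistical
structure mirrors the real ones:

* cohorts with age-dependent CHIP prevalence, APOE genotype frequencies
  anchored to published cohort counts, and AD outcomes either as
  case-control labels or as time-to-event with competing death;
* clone-size (VAF) spectra drawn from a right-skewed Beta distribution with
  depth-dependent binomial read sampling, so a deeper platform (~80× exome)
  detects smaller clones than a shallower one (~38× genome);
* GWAS summary statistics for a configurable number of instruments with a
  planted causal effect and optional balanced or directional pleiotropy;
* brain samples: a multinomial single-nucleus cell-type composition plus
  binomial amplicon read counts whose bulk VAF is implied by a planted
  mutant-microglia fraction (the exact inverse of the chimerism estimator).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd


# APOE genotype frequencies anchored to a published 2,437-person cohort
# breakdown (310 ε2ε2/ε2ε3, 46 ε2ε4, 1,584 ε3ε3, 458 ε3ε4, 39 ε4ε4); the
# pooled ε2 group is split ~1:20 between ε2ε2 and ε2ε3.
DEFAULT_APOE_FREQS = {
    "e2e2": 15 / 2437,
    "e2e3": 295 / 2437,
    "e2e4": 46 / 2437,
    "e3e3": 1584 / 2437,
    "e3e4": 458 / 2437,
    "e4e4": 39 / 2437,
}

DEPTH_BY_PLATFORM = {"wgs": 38, "wes": 80}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators."""

    seed: int = 0
    n_subjects: int = 5000
    # CHIP prevalence rises with age; logistic in years. Defaults give ~5%
    # at age 60 and ~15% at age 75, the range reported for aging cohorts.
    chip_prev_intercept: float = -7.6
    chip_prev_slope: float = 0.08
    # clone-size spectrum: right-skewed Beta truncated to (0, 0.5)
    clone_vaf_alpha: float = 1.5
    clone_vaf_beta: float = 20.0
    depth_mean: dict = field(
        default_factory=lambda: dict(DEPTH_BY_PLATFORM)
    )
    min_alt_reads: int = 3  # somatic-calling detection floor
    true_or_chip_ad: float = 0.64
    true_shr_chip_ad: float = 0.63
    ad_base_rate: float = 0.30           # case-control baseline case fraction
    ad_baseline_hazard: float = 0.012    # per-year, longitudinal mode
    death_hazard: float = 0.035          # per-year competing death
    followup_years: float = 20.0
    age_mean: float = 70.0
    age_sd: float = 8.0
    apoe_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_APOE_FREQS)
    )
    # log-odds AD effects for APOE bins relative to e3e3
    apoe_effect: dict = field(
        default_factory=lambda: {"low": -0.5, "neutral": 0.0, "high": 1.0}
    )
    # MR block
    mr_k_instruments: int = 24
    mr_gamma_scale: float = 0.08
    mr_se_exposure: float = 0.008
    mr_se_outcome: float = 0.012
    mr_theta_true: float = float(np.log(0.90))
    mr_pleiotropy: Literal["none", "balanced", "directional"] = "none"
    mr_pleiotropy_frac: float = 0.3
    mr_pleiotropy_scale: float = 0.02
    # brain block
    brain_true_mutant_mg_frac: float = 0.5
    brain_pct_mg: float = 0.07
    brain_non_mg_frac: float = 0.005
    brain_total_nuclei: int = 8000
    # amplicon read depth at the template-genome count, so template sampling
    # (the noise source the CI simulation models) is the limiting stage
    brain_amplicon_depth: int = 200_000
    brain_error_rate: float = 1e-4


def _rng(config: SimConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed + salt) % 2**31)


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, size: int, upper: float = 0.5
) -> np.ndarray:
    """Beta(a, b) draws rejected above ``upper``."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=size)
        draw = draw[(draw > 0) & (draw < upper)]
        take = min(size - filled, draw.size)
        out[filled: filled + take] = draw[:take]
        filled += take
    return out


def gen_cohort(
    config: SimConfig,
    mode: Literal["case_control", "longitudinal"] = "case_control",
    cohort: str = "SIM",
) -> pd.DataFrame:
    """Generate one synthetic cohort of subjects.

    Ages are normal (truncated to 45–90, with 90 as a ceiling code), sex and
    APOE are categorical draws, CHIP status follows the age-dependent
    logistic prevalence, and carriers receive a clone VAF from the truncated
    Beta. Outcomes: case-control mode draws AD from a logistic model with
    the configured covariate effects and the planted CHIP odds ratio;
    longitudinal mode draws exponential AD and death times whose AD hazard
    is scaled by the planted subdistribution-style hazard ratio for
    carriers, with administrative censoring at the follow-up horizon.
    """
    rng = _rng(config, salt=11)
    n = config.n_subjects
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 45, 90)
    sex = np.where(rng.random(n) < 0.55, "female", "male")
    genos = list(config.apoe_frequencies)
    probs = np.array([config.apoe_frequencies[g] for g in genos])
    apoe = rng.choice(genos, size=n, p=probs / probs.sum())

    p_chip = 1 / (1 + np.exp(-(config.chip_prev_intercept
                               + config.chip_prev_slope * age)))
    chip = rng.random(n) < p_chip
    vaf = np.where(
        chip,
        _truncated_beta(rng, config.clone_vaf_alpha, config.clone_vaf_beta, n),
        0.0,
    )

    from .association import apoe_bin  # local import avoids cycle at import time

    apoe_lp = np.array([config.apoe_effect[apoe_bin(g)] for g in apoe])
    df = pd.DataFrame(
        {
            "subject_id": [f"{cohort}-{i:05d}" for i in range(n)],
            "cohort": cohort,
            "age": np.round(age, 1),
            "sex": sex,
            "apoe": apoe,
            "chip": chip,
            "max_vaf": np.round(vaf, 4),
        }
    )
    if mode == "case_control":
        base = np.log(config.ad_base_rate / (1 - config.ad_base_rate))
        lp = (
            base
            + 0.06 * (age - config.age_mean)
            + 0.15 * (sex == "female")
            + apoe_lp
            + np.log(config.true_or_chip_ad) * chip
        )
        df["ad_status"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    elif mode == "longitudinal":
        haz_mult = (
            np.exp(0.04 * (age - config.age_mean) + 0.5 * apoe_lp)
            * np.where(chip, config.true_shr_chip_ad, 1.0)
        )
        t_ad = rng.exponential(1.0 / (config.ad_baseline_hazard * haz_mult))
        t_death = rng.exponential(1.0 / config.death_hazard, n)
        t_obs = np.minimum.reduce([t_ad, t_death,
                                   np.full(n, config.followup_years)])
        event = np.where(
            (t_ad <= t_death) & (t_ad < config.followup_years), "ad",
            np.where(t_death < config.followup_years, "death", "censored"),
        )
        df["time"] = np.round(t_obs, 3)
        df["event"] = event
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return df


def gen_vaf_observations(
    config: SimConfig,
    platform: Literal["wgs", "wes"],
    n_clones: int | None = None,
) -> pd.DataFrame:
    """Observed VAFs for a set of true clones sequenced on one platform.

    True clone VAFs come from the truncated Beta; read depth per site is
    Poisson around the platform mean; alt reads are binomial. A clone is
    detected only when it yields at least ``min_alt_reads`` alt reads, so
    deeper sequencing detects more (and smaller) clones.
    """
    if platform not in config.depth_mean:
        raise ValueError(f"unknown platform {platform!r}")
    rng = _rng(config, salt=23)
    n = n_clones if n_clones is not None else config.n_subjects
    true_vaf = _truncated_beta(
        rng, config.clone_vaf_alpha, config.clone_vaf_beta, n
    )
    depth = rng.poisson(config.depth_mean[platform], n).clip(min=1)
    alt = rng.binomial(depth, true_vaf)
    detected = alt >= config.min_alt_reads
    return pd.DataFrame(
        {
            "true_vaf": true_vaf,
            "depth": depth,
            "alt_reads": alt,
            "observed_vaf": np.where(depth > 0, alt / depth, np.nan),
            "detected": detected,
            "platform": platform,
        }
    )


def gen_mr_summary_stats(
    config: SimConfig, direction: Literal["forward", "reverse"] = "forward"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome GWAS summary-statistic tables for MR.

    Exposure betas γⱼ are drawn half-normal at the configured scale (all
    oriented positive, the effect-allele convention); outcome betas are
    Γⱼ = θ·γⱼ + αⱼ + noise with αⱼ the pleiotropy term: zero under "none",
    symmetric around zero under "balanced", and positive for a random
    ``mr_pleiotropy_frac`` of instruments under "directional". The reverse
    direction has no planted causal effect (θ_rev = 0).
    """
    if config.mr_k_instruments < 3:
        raise ValueError("need at least 3 instruments")
    rng = _rng(config, salt=37)
    k = config.mr_k_instruments
    gamma = np.abs(rng.normal(0, config.mr_gamma_scale, k)) + 0.02
    theta = config.mr_theta_true if direction == "forward" else 0.0
    alpha = np.zeros(k)
    if config.mr_pleiotropy != "none":
        m = max(1, int(round(config.mr_pleiotropy_frac * k)))
        idx = rng.choice(k, size=m, replace=False)
        mag = np.abs(rng.normal(0, config.mr_pleiotropy_scale, m)) \
            + config.mr_pleiotropy_scale
        if config.mr_pleiotropy == "balanced":
            mag *= rng.choice([-1.0, 1.0], size=m)
        alpha[idx] = mag
    gamma_hat = rng.normal(gamma, config.mr_se_exposure)
    Gamma_hat = rng.normal(theta * gamma + alpha, config.mr_se_outcome)
    ids = [f"rs{100000 + j}" for j in range(k)]
    exposure = pd.DataFrame(
        {"variant_id": ids, "beta": gamma_hat,
         "se": config.mr_se_exposure}
    )
    outcome = pd.DataFrame(
        {"variant_id": ids, "beta": Gamma_hat,
         "se": config.mr_se_outcome}
    )
    return exposure, outcome


def gen_brain_sample(
    config: SimConfig, sample_id: str = "SIM-BRAIN"
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """One synthetic brain specimen: amplicon counts + nuclei composition.

    The cell-type composition is multinomial over microglia, non-microglial
    hematopoietic clusters and brain parenchyma; the bulk VAF is the exact
    inverse of the chimerism estimator at the planted truth
    (vaf = (mutant_mg + non_mg)/(2·total), since all non-MG hematopoietic
    nuclei are taken as mutant), and amplicon reads are binomial at that
    VAF. A matched negative control is drawn at the background error rate.

    Returns (amplicon count table, composition Series, truth dict).
    """
    rng = _rng(config, salt=53)
    p_mg = config.brain_pct_mg
    p_heme = config.brain_non_mg_frac
    rest = 1.0 - p_mg - p_heme
    # brain parenchyma split: mostly neurons/oligodendrocytes/astrocytes
    cluster_p = {
        "MG": p_mg,
        "monocyte": p_heme * 0.4,
        "DC": p_heme * 0.1,
        "T_cell": p_heme * 0.4,
        "B_cell": p_heme * 0.1,
        "neuron": rest * 0.45,
        "oligodendrocyte": rest * 0.40,
        "astrocyte": rest * 0.13,
        "other": rest * 0.02,
    }
    labels = list(cluster_p)
    counts = rng.multinomial(
        config.brain_total_nuclei, np.array([cluster_p[c] for c in labels])
    )
    composition = pd.Series(counts, index=labels, name=sample_id)
    total = int(composition.sum())
    mg = int(composition["MG"])
    non_mg = int(sum(composition[c] for c in
                     ("monocyte", "DC", "T_cell", "B_cell")))
    mutant_mg = config.brain_true_mutant_mg_frac * mg
    if mutant_mg > 0:
        # carrier: all non-MG hematopoietic nuclei mutant (the estimator's
        # conservative assumption holds exactly in the generator)
        true_vaf = (mutant_mg + non_mg) / (2.0 * total)
    else:
        true_vaf = 0.0  # non-carrier: only background error reads
    depth = config.brain_amplicon_depth
    rows = []
    for replicate in (1, 2):
        alt = int(rng.binomial(depth, max(true_vaf, config.brain_error_rate)))
        rows.append(
            dict(sample_id=sample_id, region="occipital", gate="unsorted",
                 variant_id="chip_var", ref_reads=depth - alt, alt_reads=alt,
                 replicate=replicate)
        )
    nc_alt = int(rng.binomial(depth, config.brain_error_rate))
    rows.append(
        dict(sample_id=f"{sample_id}-NC", region="occipital", gate="unsorted",
             variant_id="chip_var", ref_reads=depth - nc_alt, alt_reads=nc_alt,
             replicate=1)
    )
    amplicons = pd.DataFrame(rows)
    truth = {
        "true_mutant_mg_frac": config.brain_true_mutant_mg_frac,
        "true_vaf": true_vaf,
        "total": total,
        "mg": mg,
        "non_mg": non_mg,
    }
    return amplicons, composition, truth
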