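"""Brain chimerism: estimating the fraction of mutant microglia.

A CHIP clone's somatic variant can be re-measured in brain tissue by deep
amplicon sequencing of nuclei, and the cellular make-up of the same tissue by
single-nucleus ATAC cell-type composition. Under the assumptions that the
variant is heterozygous (so 2×VAF ≈ fraction of mutant cells) and that every
non-microglial hematopoietic nucleus is mutant (a conservative ceiling on
their contribution), the number of mutant microglia is

    mut_mg = round(total · VAF · 2 − non_mg)

and the proportion of mutant microglia is mut_mg / mg, where total is the
nuclei profiled, mg the microglial count and non_mg the non-microglial
hematopoietic count. This module implements that estimator, the binomial
simulation that puts a confidence interval around it, amplicon VAF calling
with a negative-control detection limit, the microglia-to-glia fraction and
its quasibinomial group test, blood–brain correlation, and sorting fold
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

DEFAULT_AMPLICON_MIN_DEPTH = 500
DEFAULT_N_GENOMES = 200_000  # haploid genomes entering amplification
DEFAULT_N_NUCLEI = 8_000     # nuclei profiled by snATAC (median-scale default)
DEFAULT_N_SIMS = 1_000_000

HEMATOPOIETIC_NON_MG = ("monocyte", "DC", "T_cell", "B_cell")
GLIAL_CLUSTERS = ("MG", "oligodendrocyte", "astrocyte")


# ---------------------------------------------------------------------------
# Amplicon VAF with detection limit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconVaf:
    vaf: float
    detected: bool
    detection_limit: float
    depth: int


def amplicon_vaf(
    alt_reads: int,
    ref_reads: int,
    min_depth: int = DEFAULT_AMPLICON_MIN_DEPTH,
    negative_control: tuple[int, int] | None = None,
) -> AmpliconVaf:
    """Amplicon-sequencing VAF with a detection-limit check.

    The detection limit is the larger of 3/depth (a minimum-read floor) and
    the upper 95% Clopper–Pearson bound on the negative control's alt
    fraction (sequencing/PCR error ceiling measured on a known non-carrier).
    VAFs at or below the limit are reported as not detected.
    """
    depth = alt_reads + ref_reads
    if depth < min_depth:
        raise ValueError(f"amplicon depth {depth} < min_depth {min_depth}")
    vaf = alt_reads / depth
    limit = 3.0 / depth
    if negative_control is not None:
        nc_alt, nc_ref = negative_control
        nc_depth = nc_alt + nc_ref
        if nc_depth > 0:
            # Clopper–Pearson upper 95% bound for the control error fraction
            upper = stats.beta.ppf(0.95, nc_alt + 1, nc_depth - nc_alt)
            limit = max(limit, float(upper))
    else:
        warnings.warn(
            "no negative control: detection limit falls back to 3/depth",
            stacklevel=2,
        )
    return AmpliconVaf(vaf=vaf, detected=vaf > limit, detection_limit=limit,
                       depth=depth)


def percent_mutant_cells(vaf: float) -> float:
    """Fraction of cells carrying a heterozygous variant, as a percentage:
    2 × VAF × 100. VAFs above 0.5 violate the heterozygous assumption and
    draw a warning."""
    if vaf < 0:
        raise ValueError("vaf must be non-negative")
    if vaf > 0.5:
        warnings.warn(
            f"VAF {vaf:g} > 0.5 is inconsistent with a heterozygous variant",
            stacklevel=2,
        )
    return 2.0 * vaf * 100.0


# ---------------------------------------------------------------------------
# The mutant-microglia estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutantMGEstimate:
    vaf: float
    total: int
    mg: int
    non_mg: int
    mut_mg: int
    prop_mut_mg: float        # adjusted; may exceed 1, see `clamped`
    prop_unadjusted: float    # 2·vaf·total/mg, no non-MG subtraction
    clamped: bool

    @property
    def prop_mut_mg_clamped(self) -> float:
        return min(self.prop_mut_mg, 1.0)

    @property
    def prop_unadjusted_clamped(self) -> float:
        return min(self.prop_unadjusted, 1.0)


def estimate_mutant_mg(
    vaf: float, total: int, mg: int, non_mg: int
) -> MutantMGEstimate:
    """Estimate the count and proportion of mutant microglia in one sample.

    mut_mg = round(total·vaf·2 − non_mg), floored at 0 (the all-non-MG-mutant
    assumption can overshoot at low VAF); prop_mut_mg = mut_mg/mg. Rounding
    is banker's (round-half-to-even). Proportions above 1 are reported raw
    with ``clamped`` set; the clamped values are available as properties.
    """
    if mg <= 0:
        raise ValueError("mg must be positive")
    if total < mg + non_mg:
        raise ValueError("total must be at least mg + non_mg")
    if not 0 <= vaf <= 0.5:
        raise ValueError(f"vaf must be in [0, 0.5], got {vaf}")
    burden = total * vaf * 2.0
    raw = burden - non_mg
    if raw < 0:
        warnings.warn(
            "total mutant burden below non-MG hematopoietic count; "
            "mut_mg floored at 0",
            stacklevel=2,
        )
    mut_mg = max(0, round(raw))
    prop = mut_mg / mg
    prop_unadj = burden / mg
    return MutantMGEstimate(
        vaf=vaf, total=total, mg=mg, non_mg=non_mg, mut_mg=mut_mg,
        prop_mut_mg=prop, prop_unadjusted=prop_unadj,
        clamped=bool(prop > 1 or prop_unadj > 1),
    )


def simulate_mutant_mg_ci(
    vaf: float,
    pct_mg: float,
    non_mg_frac: float,
    n_genomes: int = DEFAULT_N_GENOMES,
    n_nuclei: int = DEFAULT_N_NUCLEI,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Simulated 95% CI for the proportion of mutant microglia.

    Both measured ingredients are resampled binomially around their point
    values: the alt-allele count over ``n_genomes`` haploid genomes at the
    observed VAF, and the microglial count over ``n_nuclei`` profiled nuclei
    at the observed microglial fraction. The non-microglial hematopoietic
    fraction is held fixed. Each replicate recomputes

        prop = (2·vaf* − non_mg_frac) / pct_mg*

    and the 2.5/97.5 percentiles of the replicate distribution are returned
    together with the replicate values themselves.
    """
    if pct_mg <= 0:
        raise ValueError("pct_mg must be positive")
    if not 0 <= vaf <= 0.5:
        raise ValueError(f"vaf must be in [0, 0.5], got {vaf}")
    rng = np.random.default_rng(seed)
    vaf_sim = rng.binomial(n_genomes, vaf, size=n_sims) / n_genomes
    mg_sim = rng.binomial(n_nuclei, pct_mg, size=n_sims)
    # replicates with zero sampled microglia carry no information on the ratio
    mg_frac = np.where(mg_sim > 0, mg_sim / n_nuclei, np.nan)
    props = np.clip(2.0 * vaf_sim - non_mg_frac, 0.0, None) / mg_frac
    props = props[np.isfinite(props)]
    lo, hi = np.percentile(props, [2.5, 97.5])
    return float(lo), float(hi), props


# ---------------------------------------------------------------------------
# Composition-level statistics
# ---------------------------------------------------------------------------

def mg_glia_fraction(composition: pd.Series | dict) -> float:
    """Microglia as a fraction of the total glial pool
    (microglia + oligodendrocytes + astrocytes)."""
    comp = pd.Series(composition)
    mg = float(comp.get("MG", 0))
    denom = float(sum(comp.get(c, 0) for c in GLIAL_CLUSTERS))
    if denom <= 0:
        raise ValueError("glial pool is empty")
    return mg / denom


def quasibinomial_group_test(
    compositions: Sequence[pd.Series | dict], group: Sequence[int]
) -> tuple[float, float, float]:
    """Quasibinomial test for a group difference in the MG/glia fraction.

    Fits a binomial-family GLM of (MG successes out of glia trials) on the
    group indicator, estimates the dispersion by Pearson χ²/df, and returns
    (group coefficient on the log-odds scale, two-sided Wald P with the
    dispersion-inflated SE, dispersion).
    """
    g = np.asarray(group, dtype=float)
    if len(set(g.tolist())) != 2:
        raise ValueError("group must have exactly 2 levels")
    mg = np.array([float(pd.Series(c).get("MG", 0)) for c in compositions])
    glia = np.array(
        [float(sum(pd.Series(c).get(k, 0) for k in GLIAL_CLUSTERS))
         for c in compositions]
    )
    if np.any(glia <= 0):
        raise ValueError("every sample needs a non-empty glial pool")
    for lvl in np.unique(g):
        if mg[g == lvl].sum() == 0:
            raise ValueError(f"all-zero MG counts in group {lvl:g}")
    X = sm.add_constant((g == np.max(g)).astype(float))
    endog = np.column_stack([mg, glia - mg])
    res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    # quasibinomial: Pearson chi-square / residual df, SE inflated by sqrt(phi)
    phi = float(res.pearson_chi2 / res.df_resid)
    coef = float(res.params[1])
    se = float(res.bse[1]) * np.sqrt(phi)
    p = float(2 * stats.norm.sf(abs(coef) / se))
    return coef, p, phi


def blood_brain_correlation(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Pearson correlation between blood and microglial mutant fractions.

    Returns (r, r², two-sided P) with P from t = r·√((n−2)/(1−r²)) on n−2
    degrees of freedom.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def fold_enrichment(sorted_frac: float, unsorted_frac: float) -> float:
    """Fold enrichment of a cell population achieved by sorting:
    sorted fraction / unsorted fraction."""
    if unsorted_frac <= 0:
        raise ValueError("unsorted fraction must be positive")
    return sorted_frac / unsorted_frac
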