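"""CHIP variant classification, carrier calling and cross-cohort VAF harmonization.

Clonal hematopoiesis of indeterminate potential (CHIP) is detected from blood
sequencing as somatic variants in a curated set of driver genes. This module
turns per-sample somatic variant calls into carrier status: it computes variant
allele fractions (VAFs), matches calls against a user-supplied gene/variant
whitelist, assigns each sample a carrier call with its maximum driver VAF, and
harmonizes VAF cutoffs between cohorts sequenced at different depths (deeper
platforms detect smaller clones, so raw prevalence is not comparable).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import ks_2samp

DEFAULT_MIN_DEPTH = 20
DEFAULT_VAF_CUTOFF = 0.08
DEFAULT_HARMONIZATION_GRID = np.round(np.arange(0.02, 0.20 + 1e-9, 0.005), 4)

# Protein-change notation treated as truncating: nonsense (Ter/*/X at the end),
# frameshift, or splice-site annotations.
_TRUNCATING_RE = re.compile(
    r"(\*$|Ter$|X$|fs\*?\d*$|fs$|splice)", re.IGNORECASE
)


class InsufficientDepthError(ValueError):
    """Total read depth at a site is below the configured minimum."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observation in one sample, with read support."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str
    ref_reads: int
    alt_reads: int
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


class WhitelistRule(str, Enum):
    ANY_TRUNCATING = "any_truncating"
    LISTED_POSITIONS = "listed_positions"
    LISTED_PROTEIN_CHANGES = "listed_protein_changes"


@dataclass(frozen=True)
class WhitelistEntry:
    gene: str
    rule: WhitelistRule
    detail: tuple = ()

    def __post_init__(self) -> None:
        if self.rule is not WhitelistRule.ANY_TRUNCATING and not self.detail:
            raise ValueError(
                f"whitelist entry for {self.gene}: rule {self.rule.value} "
                "requires a non-empty detail list"
            )


@dataclass(frozen=True)
class ChipWhitelist:
    """Per-gene rules defining which somatic variants count as CHIP drivers."""

    entries: tuple[WhitelistEntry, ...]

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        if len(genes) != len(set(genes)):
            raise ValueError("whitelist gene names must be unique")
        object.__setattr__(
            self, "_by_gene", {e.gene: e for e in self.entries}
        )

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, str, Sequence]]
    ) -> "ChipWhitelist":
        return cls(
            tuple(
                WhitelistEntry(gene, WhitelistRule(rule), tuple(detail))
                for gene, rule, detail in entries
            )
        )

    def matches(self, call: VariantCall) -> bool:
        entry = getattr(self, "_by_gene").get(call.gene)
        if entry is None:
            return False
        if entry.rule is WhitelistRule.ANY_TRUNCATING:
            return is_truncating(call.protein_change)
        if entry.rule is WhitelistRule.LISTED_POSITIONS:
            return (call.chrom, call.pos) in entry.detail or call.pos in entry.detail
        return call.protein_change in entry.detail


class VafCategory(str, Enum):
    NONE = "none"
    LOW = "low"   # carrier with max VAF <= cutoff
    HIGH = "high"  # carrier with max VAF > cutoff (strict)


@dataclass(frozen=True)
class ChipStatus:
    """Per-subject CHIP carrier call."""

    sample_id: str
    is_carrier: bool
    max_vaf: float
    driver_genes: tuple[str, ...]
    vaf_category: VafCategory
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.is_carrier and (self.max_vaf <= 0 or not self.driver_genes):
            raise ValueError("carrier requires max_vaf > 0 and driver genes")


def is_truncating(protein_change: str | None) -> bool:
    """Whether a protein-change string denotes a truncating variant
    (nonsense, frameshift or splice)."""
    if not protein_change:
        return False
    return bool(_TRUNCATING_RE.search(protein_change))


def compute_vaf(
    alt_reads: int, ref_reads: int, min_depth: int = DEFAULT_MIN_DEPTH
) -> float:
    """Variant allele fraction alt/(alt+ref).

    Raises
    ------
    InsufficientDepthError
        If total depth is below ``min_depth``; no VAF is emitted for such
        sites because binomial sampling noise dominates the estimate.
    """
    depth = alt_reads + ref_reads
    if depth < min_depth:
        raise InsufficientDepthError(
            f"insufficient depth: {depth} < min_depth {min_depth}"
        )
    return alt_reads / depth


def classify_chip_variants(
    calls: Sequence[VariantCall], whitelist: ChipWhitelist
) -> list[tuple[VariantCall, bool]]:
    """Flag each call as CHIP or not against the whitelist.

    A call is CHIP iff its gene appears in the whitelist and satisfies that
    gene's rule. Calls with a missing gene annotation are retained as
    non-CHIP with a warning.
    """
    out: list[tuple[VariantCall, bool]] = []
    for call in calls:
        if not call.gene:
            warnings.warn(
                f"call at {call.chrom}:{call.pos} has no gene annotation; "
                "classified non-CHIP",
                stacklevel=2,
            )
            out.append((call, False))
            continue
        out.append((call, whitelist.matches(call)))
    return out


def assign_carrier_status(
    classified: Sequence[tuple[VariantCall, bool]],
    cutoff: float = DEFAULT_VAF_CUTOFF,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict[str, ChipStatus]:
    """Collapse classified calls to one ChipStatus per sample.

    max_vaf is the maximum VAF over the sample's CHIP calls with adequate
    depth (0 if none). The three-level category follows the strict cutoff:
    ``none`` (no CHIP), ``low`` (max VAF <= cutoff), ``high`` (max VAF >
    cutoff). VAFs above 0.5 (possible loss of heterozygosity or copy-number
    change) are retained but flagged.
    """
    if not 0 < cutoff <= 0.5:
        raise ValueError(f"cutoff must be in (0, 0.5], got {cutoff}")
    samples: dict[str, list[VariantCall]] = {}
    for call, is_chip in classified:
        samples.setdefault(call.sample_id, [])
        if is_chip:
            samples[call.sample_id].append(call)

    statuses: dict[str, ChipStatus] = {}
    for sample_id in sorted(samples):
        vafs: list[tuple[float, str]] = []
        flags: list[str] = []
        for call in samples[sample_id]:
            try:
                vaf = compute_vaf(call.alt_reads, call.ref_reads, min_depth)
            except InsufficientDepthError:
                flags.append(f"insufficient_depth:{call.gene}:{call.pos}")
                continue
            vafs.append((vaf, call.gene))
            if vaf > 0.5:
                flags.append(f"vaf_gt_0.5:{call.gene}:{call.pos}")
        carrier_vafs = [(v, g) for v, g in vafs if v > 0]
        if carrier_vafs:
            max_vaf = max(v for v, _ in carrier_vafs)
            genes = tuple(sorted({g for _, g in carrier_vafs}))
            category = VafCategory.HIGH if max_vaf > cutoff else VafCategory.LOW
            status = ChipStatus(sample_id, True, max_vaf, genes, category,
                                tuple(flags))
        else:
            status = ChipStatus(sample_id, False, 0.0, (), VafCategory.NONE,
                                tuple(flags))
        statuses[sample_id] = status
    return statuses


@dataclass(frozen=True)
class HarmonizationResult:
    cutoff: float
    ks_distance: float
    grid: tuple[float, ...]
    ks_by_cutoff: tuple[float, ...]  # NaN where the filtered set was empty


def harmonize_vaf_cutoff(
    vafs_reference: Sequence[float],
    vafs_deeper: Sequence[float],
    grid: Sequence[float] | None = None,
) -> HarmonizationResult:
    """Choose the VAF cutoff that best aligns a deep-sequenced cohort's
    carrier VAF distribution with a shallower reference cohort's.

    Deeper sequencing detects smaller clones, so the deep cohort's VAF
    spectrum has extra low-VAF mass the reference cannot see. For each
    candidate cutoff c the deep set is truncated to {v > c} and compared to
    the reference by the two-sample Kolmogorov-Smirnov distance; the cutoff
    minimizing the distance wins, ties broken toward the smaller cutoff.
    """
    ref = np.asarray(vafs_reference, dtype=float)
    deep = np.asarray(vafs_deeper, dtype=float)
    if ref.size == 0 or deep.size == 0:
        raise ValueError("both VAF sets must be non-empty")
    if grid is None:
        grid = DEFAULT_HARMONIZATION_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted strictly ascending")

    distances = np.full(grid.size, np.nan)
    for i, c in enumerate(grid):
        filtered = deep[deep > c]
        if filtered.size == 0:
            warnings.warn(
                f"cutoff {c:g} leaves no deep-cohort VAFs; excluded",
                stacklevel=2,
            )
            continue
        distances[i] = ks_2samp(ref, filtered).statistic
    if np.all(np.isnan(distances)):
        raise ValueError("no candidate cutoff leaves a non-empty filtered set")
    # argmin over non-NaN; ties to the smallest cutoff (first index)
    best = int(np.nanargmin(distances))
    return HarmonizationResult(
        cutoff=float(grid[best]),
        ks_distance=float(distances[best]),
        grid=tuple(float(c) for c in grid),
        ks_by_cutoff=tuple(float(d) for d in distances),
    )
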