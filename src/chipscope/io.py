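"""Readers, writers and pipeline orchestration.

TSV dialect throughout: tab-separated, header row, UTF-8, '.' for missing.
Variant calls are accepted either as VCF v4.2 (per-sample AD FORMAT field)
or as a TSV with the documented columns. The pipeline runner executes the
enabled stages in order on synthetic inputs and writes a JSON run manifest
recording seeds, inputs and output checksums, so a rerun with the same
configuration is verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chip_calls import (
    ChipWhitelist,
    VariantCall,
    assign_carrier_status,
    classify_chip_variants,
    harmonize_vaf_cutoff,
)

logger = logging.getLogger("chipscope")

MISSING = "."

VARIANT_TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "protein_change",
    "ref_reads", "alt_reads",
]
SUMMARY_STAT_COLUMNS = ["variant_id", "beta", "se"]


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

def read_variant_calls(path: str | Path, format: str | None = None
                       ) -> list[VariantCall]:
    """Read somatic variant calls from VCF v4.2 or TSV.

    Format is inferred from the extension when not given. VCF records need a
    per-sample AD field (ref,alt depths); gene and protein-change annotations
    are taken from INFO keys GENE and AAChange when present.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(
                f"{path}:{rec.CHROM}:{rec.POS}: missing FORMAT field 'AD'"
            )
        gene = rec.INFO.get("GENE") or ""
        pchange = rec.INFO.get("AAChange") or None
        for si, sample in enumerate(samples):
            ref_d, alt_d = int(ad[si][0]), int(ad[si][1])
            if ref_d < 0 or alt_d < 0:  # missing AD encoded as negative
                continue
            calls.append(
                VariantCall(
                    sample_id=sample, chrom=rec.CHROM, pos=rec.POS,
                    ref=rec.REF, alt=rec.ALT[0], gene=gene,
                    protein_change=pchange, ref_reads=ref_d, alt_reads=alt_d,
                )
            )
    if not calls:
        warnings.warn(f"{path}: no variant calls parsed", stacklevel=2)
    return calls


def _read_variant_tsv(path: Path) -> list[VariantCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING])
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file", stacklevel=2)
        return []
    missing_cols = set(VARIANT_TSV_COLUMNS) - {"protein_change"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {sorted(missing_cols)}")
    calls = []
    for i, row in df.iterrows():
        try:
            calls.append(
                VariantCall(
                    sample_id=row["sample_id"], chrom=row["chrom"],
                    pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                    gene=row["gene"] if pd.notna(row["gene"]) else "",
                    protein_change=(row.get("protein_change")
                                    if pd.notna(row.get("protein_change"))
                                    else None),
                    ref_reads=int(row["ref_reads"]),
                    alt_reads=int(row["alt_reads"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}")
    return calls


def write_variant_calls(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "gene": c.gene,
            "protein_change": c.protein_change or MISSING,
            "ref_reads": c.ref_reads, "alt_reads": c.alt_reads,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Whitelist / status / phenotype tables
# ---------------------------------------------------------------------------

def read_whitelist(path: str | Path) -> ChipWhitelist:
    """Whitelist TSV: columns gene, rule, detail (comma-joined list, '.' for
    none)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING])
    entries = []
    for _, row in df.iterrows():
        detail: tuple = ()
        if pd.notna(row.get("detail")):
            items = [d.strip() for d in str(row["detail"]).split(",") if d.strip()]
            detail = tuple(int(d) if d.isdigit() else d for d in items)
        entries.append((row["gene"], row["rule"], detail))
    return ChipWhitelist.from_entries(entries)


def write_chip_status(statuses: dict, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "is_carrier": int(s.is_carrier),
            "max_vaf": s.max_vaf,
            "driver_genes": ";".join(s.driver_genes) or MISSING,
            "vaf_category": s.vaf_category.value,
            "flags": ";".join(s.flags) or MISSING,
        }
        for s in statuses.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    if "chip" in df.columns:
        df["chip"] = df["chip"].astype(bool)
    return df


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """GWAS summary-statistic TSV: variant_id, beta, se (SE > 0), optional
    effect_allele/other_allele/flip columns."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = set(SUMMARY_STAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate variant_id(s) {sorted(set(dup))}")
    bad = df.index[~(df["se"] > 0)].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive se at row(s) {bad}")
    return df


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str = "chipscope_run"
    seed: int = 0
    vaf_cutoff: float = 0.08
    min_depth: int = 20
    n_subjects: int = 2000
    n_sims_ci: int = 10_000
    stages: tuple[str, ...] = (
        "call", "harmonize", "assoc", "mr", "chimerism"
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages end-to-end on synthetic inputs.

    Stage order: call → harmonize → assoc/meta → mr → chimerism. Each stage
    writes its outputs under ``config.out_dir`` and the manifest records the
    package version, seeds, per-stage status and output checksums. A stage
    failure is recorded and downstream stages are skipped.
    """
    from . import association, brain, mr, simulate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate.SimConfig(seed=config.seed, n_subjects=config.n_subjects)
    manifest: dict = {
        "package": "chipscope",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    unknown = set(config.stages) - set(PipelineConfig().stages)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    failed = False
    for stage in PipelineConfig().stages:
        if stage not in config.stages:
            manifest["stages"][stage] = "skipped:disabled"
            continue
        if failed:
            manifest["stages"][stage] = "skipped:upstream_failure"
            continue
        try:
            logger.info("running stage %s", stage)
            if stage == "call":
                cohort = simulate.gen_cohort(sim)
                cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
            elif stage == "harmonize":
                deep = simulate.gen_vaf_observations(sim, "wes", 2000)
                shallow = simulate.gen_vaf_observations(sim, "wgs", 2000)
                res = harmonize_vaf_cutoff(
                    shallow.loc[shallow.detected, "observed_vaf"],
                    deep.loc[deep.detected, "observed_vaf"],
                )
                (out / "harmonize.json").write_text(json.dumps(
                    {"cutoff": res.cutoff, "ks_distance": res.ks_distance}
                ))
            elif stage == "assoc":
                cohort = simulate.gen_cohort(sim)
                strat = association.run_stratified_meta(
                    cohort, strata_def="all"
                )
                meta = strat.per_stratum["all"]
                (out / "assoc.json").write_text(json.dumps(
                    {"or": meta.ratio, "p": meta.p, "ci95": meta.ci95}
                ))
            elif stage == "mr":
                exp, outc = simulate.gen_mr_summary_stats(sim)
                res = mr.run_mr(exp, {"SIM-GWAS": outc},
                                seed=config.seed % 2**31)
                prim = res.per_study["SIM-GWAS"][res.primary_method]
                (out / "mr.json").write_text(json.dumps(
                    {"or": prim.odds_ratio, "p": prim.p,
                     "method": prim.method}
                ))
            elif stage == "chimerism":
                amp, comp, truth = simulate.gen_brain_sample(sim)
                rep = amp[(amp.replicate == 1)
                          & (~amp.sample_id.str.endswith("-NC"))].iloc[0]
                nc = amp[amp.sample_id.str.endswith("-NC")].iloc[0]
                av = brain.amplicon_vaf(
                    int(rep.alt_reads), int(rep.ref_reads),
                    negative_control=(int(nc.alt_reads), int(nc.ref_reads)),
                )
                est = brain.estimate_mutant_mg(
                    av.vaf if av.detected else 0.0,
                    truth["total"], truth["mg"], truth["non_mg"],
                )
                lo, hi, _ = brain.simulate_mutant_mg_ci(
                    est.vaf, est.mg / est.total, est.non_mg / est.total,
                    n_sims=config.n_sims_ci, seed=config.seed % 2**31,
                )
                (out / "chimerism.json").write_text(json.dumps(
                    {"vaf": est.vaf, "prop_mut_mg": est.prop_mut_mg,
                     "ci95": [lo, hi]}
                ))
            manifest["stages"][stage] = "ok"
        except Exception as exc:  # recorded, downstream skipped
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = f"failed:{exc}"
            failed = True
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
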