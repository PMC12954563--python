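"""The V0/V1 variant-filtering cascade.

Joint-genotyped callsets are split into SNPs and invariant sites and
filtered separately, then re-merged:

1.  SNP hard site filters: fail when QD < 2.0, MQ < 40.0 or
    MQRankSum < -12.5 (missing annotations pass, following the GATK
    convention that an uncomputable annotation is uninformative).
2.  HDplot paralog removal: sites with heterozygote excess (H > 0.6),
    skewed summed allele-read ratio (outside [0.2, 0.8]) or extreme
    read-ratio deviation (|D| > 10) are flagged as collapsed paralogs.
3.  Genotype filters: biallelic SNPs only; genotypes with DP < 6 or
    GQ < 20 set missing; a locus is kept only when at least half of the
    samples have depth strictly above six reads and the locus minor
    allele is supported by at least three reads in total.
4.  Samples with over 80% missing genotypes are removed (strict >).
5.  Invariant sites: DP < 6 genotypes masked; site kept when at least
    half the samples have DP > 6.
6.  Filtered SNPs and invariants merge into a coordinate-sorted V0;
    removing curated outlier/duplicate samples yields V1.

Sites failing a rule are *flagged*, not silently deleted, until the
merge — the per-stage report accounts for every input site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from spetkit.variants import (
    SITE_CLASS_INVARIANT,
    SITE_CLASS_SNP,
    VariantTable,
    concat_tables,
    read_vcf,
)


@dataclass
class HDplotConfig:
    h_max: float = 0.6
    raf_min: float = 0.2
    raf_max: float = 0.8
    d_min: float = -10.0
    d_max: float = 10.0


@dataclass
class FilterConfig:
    """All thresholds of the cascade (defaults per the workflow above)."""

    qd_min: float = 2.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    dp_min: int = 6
    gq_min: int = 20
    half_sample_dp: int = 6  # strict >, in at least half the samples
    minor_reads_min: int = 3
    sample_missing_max: float = 0.80
    hdplot: HDplotConfig = field(default_factory=HDplotConfig)

    def header_lines(self) -> list[str]:
        d = asdict(self)
        hd = d.pop("hdplot")
        parts = [f"{k}={v}" for k, v in d.items()]
        parts += [f"hdplot_{k}={v}" for k, v in hd.items()]
        return [f"##spetkit_filter=<{','.join(parts)}>"]


def split_sites(table: VariantTable) -> tuple[VariantTable, VariantTable, dict[str, int]]:
    """Separate SNPs from invariant sites.

    Returns (snps, invariants, discarded_counts).  Records of other
    classes (indels, MNPs, mixed) were already excluded and counted at
    VCF read time; any present in the table are counted here too.
    """
    snp_mask = table.is_snp()
    inv_mask = table.is_invariant()
    discarded = {"other": int((~snp_mask & ~inv_mask).sum())}
    return table.take_sites(snp_mask), table.take_sites(inv_mask), discarded


def hard_site_filter(snps: VariantTable, cfg: FilterConfig) -> np.ndarray:
    """Flag SNP sites failing any GATK-style hard annotation threshold.

    Strict inequalities per the filter expression: a site at exactly
    QD = 2.0, MQ = 40.0, MQRankSum = -12.5 passes.  NaN annotations
    never fail; sites passing only because every annotation is missing
    get an audit flag ``hard_filter_na``.
    """
    qd = snps.sites["qd"].to_numpy(float)
    mq = snps.sites["mq"].to_numpy(float)
    mqrs = snps.sites["mqranksum"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        fail = (
            (qd < cfg.qd_min) | (mq < cfg.mq_min) | (mqrs < cfg.mqranksum_min)
        )
    fail = np.where(np.isnan(qd) & np.isnan(mq) & np.isnan(mqrs), False, fail)
    all_na = np.isnan(qd) & np.isnan(mq) & np.isnan(mqrs)
    snps.flags["hard_filter"] = fail
    snps.flags["hard_filter_na"] = all_na
    return fail


@dataclass
class HDplotStats:
    """Per-site heterozygosity and read-ratio statistics.

    H is the proportion of genotyped samples called heterozygous; A and
    B the allele read counts summed over heterozygotes; ratio = A/(A+B);
    D = (A - B)/sqrt(A + B), the z-score of A against Binomial(A+B, ½).
    ratio and D are NaN when no heterozygote reads exist.
    """

    h: np.ndarray
    a: np.ndarray
    b: np.ndarray
    ratio: np.ndarray
    d: np.ndarray


def hdplot(snps: VariantTable) -> HDplotStats:
    gt = snps.gt
    called = gt >= 0
    het = gt == 1
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_called > 0, het.sum(axis=1) / np.maximum(n_called, 1), np.nan)
    adr = np.where(het & (snps.ad_ref >= 0), snps.ad_ref, 0)
    ada = np.where(het & (snps.ad_alt >= 0), snps.ad_alt, 0)
    a = adr.sum(axis=1).astype(float)
    b = ada.sum(axis=1).astype(float)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, a / np.where(tot > 0, tot, 1), np.nan)
        d = np.where(tot > 0, (a - b) / np.sqrt(np.where(tot > 0, tot, 1)), np.nan)
    return HDplotStats(h=h, a=a, b=b, ratio=ratio, d=d)


def hdplot_filter(snps: VariantTable, cfg: FilterConfig) -> np.ndarray:
    """Flag putative paralog-collapsed SNPs.

    A site is kept only when every defined sub-rule passes: H <= Hmax,
    ratio within [RAFmin, RAFmax] and D within [Dmin, Dmax].  When a
    site has no heterozygote reads, ratio and D are undefined and only
    the H rule applies.
    """
    hd = cfg.hdplot
    s = hdplot(snps)
    with np.errstate(invalid="ignore"):
        fail_h = s.h > hd.h_max
        fail_ratio = (s.ratio < hd.raf_min) | (s.ratio > hd.raf_max)
        fail_d = (s.d < hd.d_min) | (s.d > hd.d_max)
    fail = np.nan_to_num(fail_h) | np.nan_to_num(fail_ratio) | np.nan_to_num(fail_d)
    fail = fail.astype(bool)
    snps.flags["hdplot"] = fail
    return fail


def genotype_filter(
    snps: VariantTable, cfg: FilterConfig
) -> tuple[VariantTable, dict[str, int]]:
    """Apply per-genotype and per-locus support filters to SNPs.

    Returns a new table with genotypes below the DP/GQ thresholds set
    missing, plus per-locus drop flags:

    * ``multiallelic`` — not a biallelic SNP;
    * ``low_half_depth`` — fewer than half the samples with DP > 6;
    * ``low_minor_reads`` — locus minor allele supported by fewer than
      3 reads summed over non-missing genotypes.
    """
    out = snps.copy()
    n = out.n_samples
    low = (out.dp >= 0) & (out.dp < cfg.dp_min) | (out.gq >= 0) & (out.gq < cfg.gq_min)
    masked = int(((out.gt >= 0) & low).sum())
    out.gt[low] = -1

    multi = out.sites["multiallelic"].to_numpy(bool)
    deep_enough = (out.dp > cfg.half_sample_dp).sum(axis=1) * 2 >= n

    called = out.gt >= 0
    alt_count = np.where(called, out.gt, 0).sum(axis=1)
    n_called_alleles = 2 * called.sum(axis=1)
    ref_count = n_called_alleles - alt_count
    minor_is_alt = alt_count <= ref_count
    ad_ref_ok = np.where(called & (out.ad_ref >= 0), out.ad_ref, 0)
    ad_alt_ok = np.where(called & (out.ad_alt >= 0), out.ad_alt, 0)
    minor_reads = np.where(
        minor_is_alt, ad_alt_ok.sum(axis=1), ad_ref_ok.sum(axis=1)
    )
    out.flags["multiallelic"] = multi
    out.flags["low_half_depth"] = ~deep_enough
    out.flags["low_minor_reads"] = minor_reads < cfg.minor_reads_min
    report = {
        "genotypes_masked": masked,
        "sites_multiallelic": int(multi.sum()),
        "sites_low_half_depth": int((~deep_enough & ~multi).sum()),
        "sites_low_minor_reads": int(
            ((minor_reads < cfg.minor_reads_min) & deep_enough & ~multi).sum()
        ),
    }
    return out, report


def snp_retained_mask(snps: VariantTable) -> np.ndarray:
    """Sites carrying no fail flag from any stage."""
    keep = np.ones(snps.n_sites, dtype=bool)
    for name, flag in snps.flags.items():
        if name.endswith("_na"):
            continue
        keep &= ~flag
    return keep


def sample_missingness_filter(
    table: VariantTable, cfg: FilterConfig
) -> tuple[list[str], pd.DataFrame]:
    """Samples to retain: missing fraction must not exceed 80% (strict >)."""
    if table.n_sites == 0:
        raise ValueError("empty table")
    missing_frac = (table.gt < 0).mean(axis=0)
    keep = missing_frac <= cfg.sample_missing_max
    if not keep.any():
        raise ValueError("all samples exceed the missingness threshold")
    report = pd.DataFrame(
        {"sample_id": table.samples, "missing_frac": missing_frac, "retained": keep}
    )
    return [s for s, k in zip(table.samples, keep) if k], report


def invariant_filter(
    invariants: VariantTable, cfg: FilterConfig
) -> tuple[VariantTable, dict[str, int]]:
    """Mask DP < 6 genotypes; keep sites with DP > 6 in at least half."""
    out = invariants.copy()
    low = (out.dp >= 0) & (out.dp < cfg.dp_min)
    out.gt[low] = -1
    deep_enough = (out.dp > cfg.half_sample_dp).sum(axis=1) * 2 >= out.n_samples
    out.flags["low_half_depth"] = ~deep_enough
    return out, {"invariant_sites_dropped": int((~deep_enough).sum())}


def merge_v0(
    snps: VariantTable, invariants: VariantTable, cfg: FilterConfig
) -> VariantTable:
    """Combine retained SNPs and invariants into a sorted V0 table.

    Only unflagged sites enter the merge; the audit flags stay behind
    on the stage tables.  Threshold provenance is attached for VCF
    output via :meth:`FilterConfig.header_lines`.
    """
    if snps.samples != invariants.samples:
        raise ValueError("sample sets differ between SNPs and invariants")
    s = snps.take_sites(snp_retained_mask(snps))
    v = invariants.take_sites(snp_retained_mask(invariants))
    s.flags.clear()
    v.flags.clear()
    return concat_tables(s, v).sort()


def build_v1(v0: VariantTable, removal_list: list[str]) -> VariantTable:
    """Drop curated outlier/duplicate samples from V0.

    Sites left with no called genotype after the removal are dropped.
    """
    unknown = set(removal_list) - set(v0.samples)
    if unknown:
        raise KeyError(f"unknown sample ids in removal list: {sorted(unknown)}")
    keep = [s for s in v0.samples if s not in set(removal_list)]
    v1 = v0.take_samples(keep)
    if removal_list:
        any_called = (v1.gt >= 0).any(axis=1)
        v1 = v1.take_sites(any_called)
    return v1


@dataclass
class FilterResult:
    v0: VariantTable
    snps: VariantTable  # flagged SNP stage table (audit trail)
    invariants: VariantTable
    retained_samples: list[str]
    report: pd.DataFrame


def apply_filter_workflow(
    table: VariantTable, cfg: FilterConfig | None = None
) -> FilterResult:
    """Run the full cascade on a joint-genotyped table.

    Convenience wrapper chaining split, hard filters, HDplot, genotype
    filters, sample missingness and the V0 merge; the per-stage report
    accounts for every input site.
    """
    cfg = cfg or FilterConfig()
    snps, invariants, discarded = split_sites(table)
    n_in = table.n_sites
    hard_site_filter(snps, cfg)
    hdplot_filter(snps, cfg)
    snps, gt_report = genotype_filter(snps, cfg)
    inv, inv_report = invariant_filter(invariants, cfg)
    keep_samples, missing_report = sample_missingness_filter(
        snps.take_sites(snp_retained_mask(snps)) if snp_retained_mask(snps).any() else snps,
        cfg,
    )
    snps_kept = snps.take_samples(keep_samples)
    inv_kept = inv.take_samples(keep_samples)
    v0 = merge_v0(snps_kept, inv_kept, cfg)
    rows = [
        {"stage": "input_sites", "count": n_in},
        {"stage": "discarded_other", "count": discarded["other"]},
        {"stage": "snps_in", "count": snps.n_sites},
        {"stage": "snps_hard_filtered", "count": int(snps.flags["hard_filter"].sum())},
        {"stage": "snps_hdplot_flagged", "count": int(snps.flags["hdplot"].sum())},
        {"stage": "genotypes_masked", "count": gt_report["genotypes_masked"]},
        {"stage": "sites_multiallelic", "count": gt_report["sites_multiallelic"]},
        {"stage": "sites_low_half_depth", "count": gt_report["sites_low_half_depth"]},
        {"stage": "sites_low_minor_reads", "count": gt_report["sites_low_minor_reads"]},
        {"stage": "invariants_in", "count": invariants.n_sites},
        {"stage": "invariants_dropped", "count": inv_report["invariant_sites_dropped"]},
        {"stage": "samples_removed", "count": len(table.samples) - len(keep_samples)},
        {"stage": "v0_sites", "count": v0.n_sites},
    ]
    return FilterResult(
        v0=v0,
        snps=snps,
        invariants=inv,
        retained_samples=keep_samples,
        report=pd.DataFrame(rows),
    )


def filter_vcf(path, cfg: FilterConfig | None = None) -> FilterResult:
    """Read a VCF/gVCF and run :func:`apply_filter_workflow`."""
    table, discarded = read_vcf(path)
    res = apply_filter_workflow(table, cfg)
    res.report.loc[res.report["stage"] == "discarded_other", "count"] += discarded["other"]
    return res
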