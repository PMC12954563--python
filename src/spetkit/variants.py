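"""In-memory variant table and VCF 4.2 interchange.

The table holds biallelic SNPs and invariant sites jointly, the way a
joint-genotyped gVCF-derived callset does: genotypes as alt-allele
dosage (0/1/2, -1 missing), per-genotype DP/GQ and allele depths, and
the GATK-style site annotations (QD, MQ, MQRankSum) used by the hard
site filters.  Multiallelic SNPs are carried with a flag (their
genotypes are not dosage-codable) so the filter cascade can count and
drop them explicitly; indels/MNPs are excluded at read time and only
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SITE_CLASS_SNP = "snp"
SITE_CLASS_INVARIANT = "invariant"
SITE_CLASS_OTHER = "other"


@dataclass
class VariantTable:
    """Sites x samples genotype matrix with metadata.

    Attributes
    ----------
    sites:
        DataFrame with columns chrom, pos (1-based), ref, alt (''
        for invariant sites), qd, mq, mqranksum (NaN when absent),
        site_class, multiallelic (bool).
    gt:
        int8 (n_sites, n_samples); alt dosage 0/1/2, -1 missing.
    dp, gq:
        int32 / int16 matrices; -1 where absent.
    ad_ref, ad_alt:
        int32 matrices of per-genotype allele depths; -1 where absent.
    flags:
        site-level boolean filter flags keyed by name (audit trail).
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sites, n_samples = self.gt.shape
        if len(self.sites) != n_sites:
            raise ValueError("sites/gt row mismatch")
        if len(self.samples) != n_samples:
            raise ValueError("samples/gt column mismatch")
        for name in ("dp", "gq", "ad_ref", "ad_alt"):
            if getattr(self, name).shape != self.gt.shape:
                raise ValueError(f"{name} shape mismatch")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def is_snp(self) -> np.ndarray:
        return (self.sites["site_class"] == SITE_CLASS_SNP).to_numpy()

    def is_invariant(self) -> np.ndarray:
        return (self.sites["site_class"] == SITE_CLASS_INVARIANT).to_numpy()

    def take_sites(self, mask_or_idx) -> "VariantTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return VariantTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            flags={k: v[idx] for k, v in self.flags.items()},
        )

    def take_samples(self, keep: list[str]) -> "VariantTable":
        unknown = set(keep) - set(self.samples)
        if unknown:
            raise KeyError(f"unknown samples: {sorted(unknown)}")
        cols = [self.samples.index(s) for s in keep]
        return VariantTable(
            sites=self.sites.copy(),
            samples=list(keep),
            gt=self.gt[:, cols],
            dp=self.dp[:, cols],
            gq=self.gq[:, cols],
            ad_ref=self.ad_ref[:, cols],
            ad_alt=self.ad_alt[:, cols],
            flags={k: v.copy() for k, v in self.flags.items()},
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            sites=self.sites.copy(),
            samples=list(self.samples),
            gt=self.gt.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            ad_ref=self.ad_ref.copy(),
            ad_alt=self.ad_alt.copy(),
            flags={k: v.copy() for k, v in self.flags.items()},
        )

    def sort(self) -> "VariantTable":
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return self.take_sites(order)


def concat_tables(a: VariantTable, b: VariantTable) -> VariantTable:
    if a.samples != b.samples:
        raise ValueError("sample sets differ; cannot concatenate")
    flags = {}
    for k in set(a.flags) | set(b.flags):
        fa = a.flags.get(k, np.zeros(a.n_sites, dtype=bool))
        fb = b.flags.get(k, np.zeros(b.n_sites, dtype=bool))
        flags[k] = np.concatenate([fa, fb])
    return VariantTable(
        sites=pd.concat([a.sites, b.sites], ignore_index=True),
        samples=list(a.samples),
        gt=np.concatenate([a.gt, b.gt]),
        dp=np.concatenate([a.dp, b.dp]),
        gq=np.concatenate([a.gq, b.gq]),
        ad_ref=np.concatenate([a.ad_ref, b.ad_ref]),
        ad_alt=np.concatenate([a.ad_alt, b.ad_alt]),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# VCF writing (text, 4.2)
# ---------------------------------------------------------------------------

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
]

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(table: VariantTable, path, extra_header: list[str] | None = None) -> None:
    """Write the table as uncompressed VCF 4.2.

    SNP rows carry GT:DP:GQ:AD; invariant rows GT:DP.  Sites are written
    in the table's current order (call :meth:`VariantTable.sort` first
    if coordinate order is required).
    """
    path = Path(path)
    chroms = list(dict.fromkeys(table.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write(_HEADER_LINES[0] + "\n")
        for line in extra_header or []:
            fh.write(line.rstrip("\n") + "\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        for line in _HEADER_LINES[1:]:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        sites = table.sites
        for i in range(table.n_sites):
            row = sites.iloc[i]
            invariant = row.site_class == SITE_CLASS_INVARIANT
            alt = "." if invariant or not row.alt else row.alt
            info_parts = []
            for tag, key in (("QD", "qd"), ("MQ", "mq"), ("MQRankSum", "mqranksum")):
                v = row[key]
                if pd.notna(v):
                    info_parts.append(f"{tag}={v:.2f}")
            info = ";".join(info_parts) if info_parts else "."
            fmt = "GT:DP" if invariant else "GT:DP:GQ:AD"
            cells = []
            for j in range(table.n_samples):
                g = _GT_STRINGS[int(table.gt[i, j])]
                d = table.dp[i, j]
                dstr = str(d) if d >= 0 else "."
                if invariant:
                    cells.append(f"{g}:{dstr}")
                else:
                    q = table.gq[i, j]
                    qstr = str(q) if q >= 0 else "."
                    ar, aa = table.ad_ref[i, j], table.ad_alt[i, j]
                    adstr = f"{ar},{aa}" if ar >= 0 else "."
                    cells.append(f"{g}:{dstr}:{qstr}:{adstr}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{alt}\t.\t.\t{info}\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF reading (cyvcf2)
# ---------------------------------------------------------------------------

_SYMBOLIC = {"<NON_REF>", "<*>"}


def classify_alleles(ref: str, alts: list[str]) -> str:
    """Site class per the SNP/invariant split convention.

    invariant: no observed alternate allele (empty ALT or symbolic
    NON_REF only); snp: all observed alts are single-base substitutions
    of a single-base REF; other: indels, MNPs and mixed records.
    """
    real_alts = [a for a in alts if a and a != "." and a not in _SYMBOLIC and a != "*"]
    if not real_alts:
        return SITE_CLASS_INVARIANT
    if len(ref) == 1 and all(len(a) == 1 for a in real_alts):
        return SITE_CLASS_SNP
    return SITE_CLASS_OTHER


def read_vcf(path) -> tuple[VariantTable, dict[str, int]]:
    """Load a VCF/gVCF into a :class:`VariantTable`.

    Returns the table (SNPs + invariant sites; multiallelic SNPs kept
    with the ``multiallelic`` flag and genotypes coded against the first
    alt) and a dict counting discarded records by reason (indel, mnp or
    mixed records are not loaded).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    rows = []
    gt_l, dp_l, gq_l, adr_l, ada_l = [], [], [], [], []
    discarded = {"other": 0}
    for v in vcf:
        alts = list(v.ALT)
        cls = classify_alleles(v.REF, alts)
        if cls == SITE_CLASS_OTHER:
            discarded["other"] += 1
            continue
        real_alts = [a for a in alts if a and a != "." and a not in _SYMBOLIC and a != "*"]
        multi = len(real_alts) > 1
        info = dict(v.INFO)
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": ",".join(real_alts),
                "qd": float(info["QD"]) if "QD" in info else np.nan,
                "mq": float(info["MQ"]) if "MQ" in info else np.nan,
                "mqranksum": float(info["MQRankSum"]) if "MQRankSum" in info else np.nan,
                "site_class": cls,
                "multiallelic": multi,
            }
        )
        gts = v.genotype.array()  # (n, ploidy+1)
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        dosage = np.clip(alleles, 0, None).sum(axis=1).astype(np.int8)
        dosage[missing] = -1
        if multi:
            # dosage over >2 alleles is not meaningful; mark missing
            dosage[(alleles > 1).any(axis=1)] = -1
        gt_l.append(dosage)
        dp = v.format("DP")
        dp_l.append(
            dp[:, 0].astype(np.int32) if dp is not None else np.full(n, -1, np.int32)
        )
        gq = v.format("GQ")
        if gq is not None:
            col = gq[:, 0].astype(np.int64)
            col[(col < 0) | (col > 10**9)] = -1  # int32 missing sentinel
            gq_l.append(col.astype(np.int16))
        else:
            gq_l.append(np.full(n, -1, np.int16))
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2:
            adr_l.append(ad[:, 0].astype(np.int32))
            ada_l.append(ad[:, 1].astype(np.int32))
        else:
            adr_l.append(np.full(n, -1, np.int32))
            ada_l.append(np.full(n, -1, np.int32))
    sites = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "qd",
            "mq",
            "mqranksum",
            "site_class",
            "multiallelic",
        ],
    )

    def _stack(lst, dtype):
        if lst:
            return np.vstack(lst).astype(dtype)
        return np.empty((0, n), dtype=dtype)

    table = VariantTable(
        sites=sites,
        samples=samples,
        gt=_stack(gt_l, np.int8),
        dp=_stack(dp_l, np.int32),
        gq=_stack(gq_l, np.int16),
        ad_ref=_stack(adr_l, np.int32),
        ad_alt=_stack(ada_l, np.int32),
    )
    # sanitise: cyvcf2 returns large sentinel values for missing ints
    for arr in (table.dp, table.gq, table.ad_ref, table.ad_alt):
        np.copyto(arr, -1, where=(arr < 0) | (arr > 10**9))
    return table, discarded
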