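"""Cohort-level quality control: kinship, PCA, replicate concordance.

Sample handling errors (mislabelled duplicates, contaminated or
misassigned individuals) distort diversity estimates, so before any
population statistic is trusted the cohort is screened with the
KING-robust pairwise kinship estimator (duplicates sit at φ ≈ 0.5),
a light genotype PCA for outlier detection, and — where technical
replicates were genotyped — per-pair concordance with a breakdown of
discordance classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spetkit.variants import VariantTable

DUPLICATE_PHI = 0.354  # 2^(-3/2), the standard monozygotic/duplicate cutoff


@dataclass
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    n_het_het: int  # both heterozygous
    n_opp_hom: int  # opposite homozygotes
    n_het_i: int
    n_het_j: int
    n_loci_used: int


def king_kinship(
    table: VariantTable, min_loci: int = 100
) -> list[KinshipEstimate]:
    """KING-robust kinship for every sample pair.

    φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j)) over co-called
    biallelic loci, robust to population structure.  Duplicates give
    φ̂ = 0.5, parent-offspring ≈ 0.25, unrelated ≈ 0.  Pairs sharing
    fewer than ``min_loci`` co-called loci are omitted with a warning.
    """
    snp = table.take_sites(table.is_snp())
    gt = snp.gt
    n = snp.n_samples
    out: list[KinshipEstimate] = []
    called = gt >= 0
    for i in range(n):
        for j in range(i + 1, n):
            co = called[:, i] & called[:, j]
            n_co = int(co.sum())
            if n_co < min_loci:
                warnings.warn(
                    f"pair ({snp.samples[i]}, {snp.samples[j]}): only {n_co} "
                    f"co-called loci (< {min_loci}); estimate omitted"
                )
                continue
            gi, gj = gt[co, i], gt[co, j]
            het_het = int(((gi == 1) & (gj == 1)).sum())
            opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
            het_i = int((gi == 1).sum())
            het_j = int((gj == 1).sum())
            denom = het_i + het_j
            phi = (het_het - 2.0 * opp) / denom if denom > 0 else float("nan")
            out.append(
                KinshipEstimate(
                    snp.samples[i], snp.samples[j], phi, het_het, opp, het_i, het_j, n_co
                )
            )
    return out


def flag_duplicates(
    estimates: list[KinshipEstimate], threshold: float = DUPLICATE_PHI
) -> list[tuple[str, str]]:
    """Pairs whose kinship exceeds the duplicate threshold (2^-3/2)."""
    return [
        (e.sample_i, e.sample_j) for e in estimates if np.isfinite(e.phi) and e.phi > threshold
    ]


def kinship_frame(estimates: list[KinshipEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


def genotype_pca(table: VariantTable, n_components: int = 10) -> pd.DataFrame:
    """PCA of the centred, scaled dosage matrix (mean-imputed missing).

    Axes are orthonormal, variance-sorted and deterministic up to sign.
    Returns a samples x components score frame with explained-variance
    fractions in ``attrs['explained_variance_ratio']``.
    """
    snp = table.take_sites(table.is_snp())
    if snp.n_samples < 3 or snp.n_sites < 10:
        raise ValueError("PCA needs >= 3 samples and >= 10 loci")
    g = snp.gt.astype(float).T  # samples x loci
    g[g < 0] = np.nan
    mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mean, inds[1])
    g -= mean
    sd = g.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("zero-variance genotype matrix")
    g = g[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    # sign convention: largest-magnitude loading positive per axis
    for c in range(k):
        imax = np.argmax(np.abs(scores[:, c]))
        if scores[imax, c] < 0:
            scores[:, c] = -scores[:, c]
    df = pd.DataFrame(
        scores, index=snp.samples, columns=[f"PC{c + 1}" for c in range(k)]
    )
    var = s**2
    df.attrs["explained_variance_ratio"] = (var / var.sum())[:k]
    return df


# ---------------------------------------------------------------------------
# technical replicate concordance
# ---------------------------------------------------------------------------

DISCORDANCE_CLASSES = ("homref_het", "het_homalt", "homref_homalt")


def _discordance_class(a: int, b: int) -> str:
    lo, hi = min(a, b), max(a, b)
    if (lo, hi) == (0, 1):
        return "homref_het"
    if (lo, hi) == (1, 2):
        return "het_homalt"
    return "homref_homalt"


@dataclass
class ConcordanceReport:
    sample_a: str
    sample_b: str
    n_co_called: int
    n_concordant: int
    concordance: float
    class_counts: dict[str, int]
    mean_dp_concordant: float
    mean_dp_discordant: float


def replicate_concordance(
    table: VariantTable, replicate_map: list[tuple[str, str]]
) -> tuple[list[ConcordanceReport], ConcordanceReport | None]:
    """Genotype concordance between technical replicate pairs.

    Concordance is matches over co-called SNP loci; discordances are
    classified into the three unordered genotype-pair classes.  Mean
    depth (averaged over both replicates) is reported separately for
    concordant and discordant calls — discordances concentrate at low
    depth, where a heterozygote is sampled as a homozygote.  Returns
    per-pair reports and a pooled report (NaN-free pairs only); pairs
    with no co-called loci are omitted with a warning.
    """
    snp = table.take_sites(table.is_snp())
    reports: list[ConcordanceReport] = []
    pooled_counts = {c: 0 for c in DISCORDANCE_CLASSES}
    pooled_co = pooled_match = 0
    dp_con, dp_dis = [], []
    for sa, sb in replicate_map:
        if sa not in snp.samples or sb not in snp.samples:
            warnings.warn(f"replicate pair ({sa}, {sb}) not in table; skipped")
            continue
        ia, ib = snp.samples.index(sa), snp.samples.index(sb)
        ga, gb = snp.gt[:, ia], snp.gt[:, ib]
        co = (ga >= 0) & (gb >= 0)
        n_co = int(co.sum())
        if n_co == 0:
            warnings.warn(f"replicate pair ({sa}, {sb}): no co-called loci; omitted")
            continue
        match = co & (ga == gb)
        n_match = int(match.sum())
        counts = {c: 0 for c in DISCORDANCE_CLASSES}
        mism = np.nonzero(co & (ga != gb))[0]
        for k in mism:
            counts[_discordance_class(int(ga[k]), int(gb[k]))] += 1
        dpa = snp.dp[:, ia].astype(float)
        dpb = snp.dp[:, ib].astype(float)
        pair_dp = (np.where(dpa >= 0, dpa, np.nan) + np.where(dpb >= 0, dpb, np.nan)) / 2
        con_dp = pair_dp[np.nonzero(match)[0]]
        dis_dp = pair_dp[mism]
        reports.append(
            ConcordanceReport(
                sample_a=sa,
                sample_b=sb,
                n_co_called=n_co,
                n_concordant=n_match,
                concordance=n_match / n_co,
                class_counts=counts,
                mean_dp_concordant=float(np.nanmean(con_dp)) if len(con_dp) else float("nan"),
                mean_dp_discordant=float(np.nanmean(dis_dp)) if len(dis_dp) else float("nan"),
            )
        )
        pooled_co += n_co
        pooled_match += n_match
        for c in DISCORDANCE_CLASSES:
            pooled_counts[c] += counts[c]
        dp_con.extend(con_dp.tolist())
        dp_dis.extend(dis_dp.tolist())
    pooled = None
    if pooled_co:
        pooled = ConcordanceReport(
            sample_a="pooled",
            sample_b="pooled",
            n_co_called=pooled_co,
            n_concordant=pooled_match,
            concordance=pooled_match / pooled_co,
            class_counts=pooled_counts,
            mean_dp_concordant=float(np.nanmean(dp_con)) if dp_con else float("nan"),
            mean_dp_discordant=float(np.nanmean(dp_dis)) if dp_dis else float("nan"),
        )
    return reports, pooled


def concordance_frame(reports: list[ConcordanceReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "sample_a": r.sample_a,
            "sample_b": r.sample_b,
            "n_co_called": r.n_co_called,
            "concordance": r.concordance,
            "mean_dp_concordant": r.mean_dp_concordant,
            "mean_dp_discordant": r.mean_dp_discordant,
        }
        row.update(r.class_counts)
        rows.append(row)
    return pd.DataFrame(rows)
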