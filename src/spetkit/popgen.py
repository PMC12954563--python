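"""Diversity and differentiation statistics for filtered callsets.

Implements the estimators a forest-genetics cohort analysis needs:

* per-locus observed heterozygosity (Ho) and minor allele frequency;
* Nei & Chesser's unbiased within-population gene diversity
  Ĥs = ñ/(ñ-1) · [1 - Σ p̄² - Ho/(2ñ)], averaged over populations and
  then loci (the hierfstat convention);
* Weir & Cockerham's θ (FST) from per-locus variance components a
  (among populations), b (among individuals within populations) and c
  (within individuals), combined as a ratio of sums over loci, with a
  seeded locus-bootstrap percentile confidence interval;
* nucleotide diversity π computed the missing-data-robust way: summed
  pairwise differences over summed comparable allele pairs, with
  invariant sites contributing comparisons but no differences — so
  missing data and unsequenced sites do not bias π;
* the ascertainment comparison between marker classes (known/array
  sites pre-selected for intermediate frequency versus de novo random
  sites), with one-sided rank-sum tests and the FST underestimation
  ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from spetkit.variants import VariantTable


def _pop_indices(samples: list[str], labels: dict[str, str]) -> dict[str, np.ndarray]:
    unlabelled = [s for s in samples if s not in labels]
    if unlabelled:
        raise KeyError(f"samples without population label: {unlabelled[:5]}")
    pops: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        pops.setdefault(labels[s], []).append(j)
    return {p: np.asarray(ix) for p, ix in pops.items()}


# ---------------------------------------------------------------------------
# per-locus summaries
# ---------------------------------------------------------------------------


def locus_stats(
    table: VariantTable,
    panel_class: dict[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """Per-locus MAF and observed heterozygosity over called genotypes.

    Only SNP rows are summarised; loci with zero calls are excluded
    (reported via the returned frame's attrs['n_no_calls']).
    ``panel_class`` optionally maps (chrom, pos) to a probe class
    (random / known) attached as the ``probe_class`` column.
    """
    snp = table.take_sites(table.is_snp())
    called = snp.gt >= 0
    n_called = called.sum(axis=1)
    alt = np.where(called, snp.gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = alt / np.maximum(2 * n_called, 1)
        ho = (snp.gt == 1).sum(axis=1) / np.maximum(n_called, 1)
    maf = np.minimum(p_alt, 1 - p_alt)
    ok = n_called > 0
    df = pd.DataFrame(
        {
            "chrom": snp.sites["chrom"],
            "pos": snp.sites["pos"],
            "n_called": n_called,
            "p_alt": p_alt,
            "maf": maf,
            "ho": ho,
        }
    )[ok].reset_index(drop=True)
    if panel_class is not None:
        df["probe_class"] = [
            panel_class.get((c, p), "unknown")
            for c, p in zip(df["chrom"], df["pos"])
        ]
    df.attrs["n_no_calls"] = int((~ok).sum())
    return df


# ---------------------------------------------------------------------------
# expected heterozygosity (Nei & Chesser unbiased)
# ---------------------------------------------------------------------------


def expected_heterozygosity(
    table: VariantTable, labels: dict[str, str]
) -> tuple[float, pd.DataFrame]:
    """Unbiased within-population gene diversity, hierfstat-style.

    Per locus and population with ñ called diploids, alt frequency p
    and observed heterozygosity Ho:

        Ĥs = ñ/(ñ-1) · (1 - p² - (1-p)² - Ho/(2ñ))

    Populations with fewer than 2 called diploids at a locus are
    skipped for that locus.  The species-level value averages over
    populations within each locus, then over loci.
    """
    snp = table.take_sites(table.is_snp())
    pops = _pop_indices(snp.samples, labels)
    per_pop = {}
    for pop, ix in pops.items():
        g = snp.gt[:, ix]
        called = g >= 0
        n = called.sum(axis=1).astype(float)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / np.maximum(2 * n, 1)
            ho = (g == 1).sum(axis=1) / np.maximum(n, 1)
            hs = n / (n - 1) * (1 - p**2 - (1 - p) ** 2 - ho / (2 * n))
        hs[n < 2] = np.nan
        per_pop[pop] = hs
    mat = pd.DataFrame(per_pop)
    locus_mean = mat.mean(axis=1, skipna=True)
    overall = float(locus_mean.mean(skipna=True))
    return overall, mat


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    theta: float
    a: np.ndarray  # per-locus among-population component
    abc: np.ndarray  # per-locus total a+b+c
    n_loci: int


def wc_fst(table_or_gt, labels: dict[str, str] | None = None) -> FstResult:
    """Weir & Cockerham (1984) θ for biallelic diploid data.

    Accepts a :class:`VariantTable` plus a sample→population map, or a
    raw (loci x samples) dosage matrix with ``labels`` a same-length
    array of population codes.  Per locus, with r populations of size
    n_i, alt frequency p_i and heterozygote frequency h_i:

        n̄  = Σnᵢ/r
        n_c = (r·n̄ - Σnᵢ²/(r·n̄)) / (r-1)
        p̄  = Σnᵢpᵢ/(r·n̄),  s² = Σnᵢ(pᵢ-p̄)²/((r-1)·n̄),  h̄ = Σnᵢhᵢ/(r·n̄)
        a = n̄/n_c · [s² - (p̄(1-p̄) - (r-1)/r·s² - h̄/4)/(n̄-1)]
        b = n̄/(n̄-1) · [p̄(1-p̄) - (r-1)/r·s² - (2n̄-1)/(4n̄)·h̄]
        c = h̄/2

    θ̂ = Σa / Σ(a+b+c) over loci (ratio of sums, never the mean of
    per-locus ratios).  Loci with fewer than two populations having at
    least two called diploids, or with zero total variance, are skipped
    from both sums.
    """
    if isinstance(table_or_gt, VariantTable):
        snp = table_or_gt.take_sites(table_or_gt.is_snp())
        gt = snp.gt
        pops = _pop_indices(snp.samples, labels)
    else:
        gt = np.asarray(table_or_gt)
        codes = np.asarray(labels)
        pops = {c: np.nonzero(codes == c)[0] for c in np.unique(codes)}
    if len(pops) < 2:
        raise ValueError("FST requires >= 2 populations; use Hs for one population")
    pop_ix = list(pops.values())
    n_loci = gt.shape[0]
    n_i = np.zeros((n_loci, len(pop_ix)))
    p_i = np.zeros_like(n_i)
    h_i = np.zeros_like(n_i)
    for k, ix in enumerate(pop_ix):
        g = gt[:, ix]
        called = g >= 0
        n = called.sum(axis=1).astype(float)
        n_i[:, k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[:, k] = np.where(n > 0, np.where(called, g, 0).sum(axis=1) / (2 * np.maximum(n, 1)), np.nan)
            h_i[:, k] = np.where(n > 0, (g == 1).sum(axis=1) / np.maximum(n, 1), np.nan)

    usable_pop = n_i >= 2
    r = usable_pop.sum(axis=1).astype(float)
    ok = r >= 2
    n_i = np.where(usable_pop, n_i, 0.0)
    p_i = np.where(usable_pop, np.nan_to_num(p_i), 0.0)
    h_i = np.where(usable_pop, np.nan_to_num(h_i), 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.sum(axis=1) / r
        sum_n2 = (n_i**2).sum(axis=1)
        nc = (r * nbar - sum_n2 / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=1) / (r * nbar)
        s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=1) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    abc = a + b + c
    ok &= np.isfinite(abc) & np.isfinite(a) & (nbar > 1)
    a = np.where(ok, a, 0.0)
    abc = np.where(ok, abc, 0.0)
    denom = abc.sum()
    theta = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstResult(theta=theta, a=a, abc=abc, n_loci=int(ok.sum()))


def bootstrap_ci(
    fst: FstResult, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile CI for θ by resampling loci with replacement."""
    rng = np.random.default_rng(seed)
    n = len(fst.a)
    idx = rng.integers(0, n, size=(n_boot, n))
    num = fst.a[idx].sum(axis=1)
    den = fst.abc[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = num / den
    thetas = thetas[np.isfinite(thetas)]
    lo, hi = np.quantile(thetas, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# nucleotide diversity (missing-data aware, invariant sites included)
# ---------------------------------------------------------------------------


def _pi_components(table: VariantTable, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (differences, comparisons) over the given sample columns.

    At a site with n called allele copies of which n_alt carry the
    alternate allele: differences D = n_ref * n_alt and comparisons
    C = n(n-1)/2.  Invariant sites have D = 0.  Sites with < 2 called
    copies contribute nothing.
    """
    gt = table.gt[:, cols]
    called = gt >= 0
    n_copies = 2 * called.sum(axis=1)
    n_alt = np.where(called, gt, 0).sum(axis=1)
    n_alt = np.where(table.is_invariant(), 0, n_alt)
    n_ref = n_copies - n_alt
    diffs = (n_ref * n_alt).astype(float)
    comps = (n_copies * (n_copies - 1) / 2).astype(float)
    zero = n_copies < 2
    diffs[zero] = 0.0
    comps[zero] = 0.0
    return diffs, comps


def pi_pixy(
    table: VariantTable,
    labels: dict[str, str] | None = None,
    window: int | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity from variant AND invariant sites.

    π = Σ_sites D_s / Σ_sites C_s per population (or over all samples
    when ``labels`` is None), optionally per non-overlapping genomic
    window of ``window`` bp.  Windows with zero comparable sites report
    NaN, not 0 — absence of data is not absence of diversity.  Window
    rows aggregate exactly to the global value through the summed
    numerator and denominator columns.
    """
    if labels is None:
        groups = {"all": np.arange(table.n_samples)}
    else:
        groups = _pop_indices(table.samples, labels)
    chroms = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    rows = []
    for pop, cols in groups.items():
        diffs, comps = _pi_components(table, cols)
        if window is None:
            keys = pd.Series(["global"] * table.n_sites)
            win_start = np.zeros(table.n_sites, dtype=int)
        else:
            win_start = ((pos - 1) // window) * window + 1
            keys = pd.Series([f"{c}:{w}" for c, w in zip(chroms, win_start)])
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "window_start": win_start,
                "key": keys,
                "diffs": diffs,
                "comps": comps,
            }
        )
        agg = df.groupby("key", sort=False).agg(
            chrom=("chrom", "first"),
            window_start=("window_start", "first"),
            diffs=("diffs", "sum"),
            comps=("comps", "sum"),
            n_sites=("diffs", "size"),
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            agg["pi"] = np.where(agg["comps"] > 0, agg["diffs"] / agg["comps"], np.nan)
        agg["population"] = pop
        rows.append(agg.reset_index(drop=True))
    return pd.concat(rows, ignore_index=True)


def pi_global(table: VariantTable, labels: dict[str, str] | None = None) -> float:
    df = pi_pixy(table, labels=labels, window=None)
    return float(df["diffs"].sum() / df["comps"].sum())


# ---------------------------------------------------------------------------
# ascertainment comparison between marker classes
# ---------------------------------------------------------------------------


@dataclass
class AscertainmentReport:
    per_class: pd.DataFrame  # class, n_loci, median MAF/Ho, theta
    p_maf: float  # one-sided rank-sum, known > random
    p_ho: float
    fst_underestimation: float  # (theta_random - theta_known)/theta_random


def ascertainment_comparison(
    stats_df: pd.DataFrame,
    table: VariantTable,
    labels: dict[str, str],
    known_class: str = "known",
    random_class: str = "random",
    min_loci: int = 2,
) -> AscertainmentReport:
    """Compare the known/array SNP class against the random class.

    Markers pre-selected for intermediate frequency (arrays, earlier
    panels) show higher MAF and Ho than randomly ascertained de novo
    SNPs and *underestimate* differentiation.  One-sided Wilcoxon
    rank-sum tests use the alternative known > random; the FST
    underestimation ratio is (θ_random - θ_known)/θ_random.
    """
    if "probe_class" not in stats_df.columns:
        raise ValueError("stats_df needs a probe_class column")
    counts = stats_df["probe_class"].value_counts()
    for cls in (known_class, random_class):
        if counts.get(cls, 0) < min_loci:
            warnings.warn(f"class {cls!r} has fewer than {min_loci} loci; excluded")
    known = stats_df[stats_df["probe_class"] == known_class]
    rand = stats_df[stats_df["probe_class"] == random_class]
    p_maf = sps.mannwhitneyu(known["maf"], rand["maf"], alternative="greater").pvalue
    p_ho = sps.mannwhitneyu(known["ho"], rand["ho"], alternative="greater").pvalue

    snp = table.take_sites(table.is_snp())
    site_keys = list(zip(snp.sites["chrom"], snp.sites["pos"]))
    class_of = {
        (c, p): cl
        for c, p, cl in zip(stats_df["chrom"], stats_df["pos"], stats_df["probe_class"])
    }
    thetas = {}
    rows = []
    for cls, sub in (("known", known), ("random", rand)):
        mask = np.array([class_of.get(k) == (known_class if cls == "known" else random_class) for k in site_keys])
        theta = wc_fst(snp.take_sites(mask), labels).theta if mask.sum() >= min_loci else np.nan
        thetas[cls] = theta
        rows.append(
            {
                "probe_class": known_class if cls == "known" else random_class,
                "n_loci": int(mask.sum()),
                "median_maf": float(sub["maf"].median()),
                "median_ho": float(sub["ho"].median()),
                "theta": theta,
            }
        )
    under = (thetas["random"] - thetas["known"]) / thetas["random"]
    return AscertainmentReport(
        per_class=pd.DataFrame(rows),
        p_maf=float(p_maf),
        p_ho=float(p_ho),
        fst_underestimation=float(under),
    )
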