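"""Species-discriminant SNP discovery from multi-species cohorts.

Closely related, hybridising species (the white oaks are the canonical
case) need diagnostic loci to confirm species assignment.  The
procedure: merge per-species callsets on shared coordinates, compute
per-species alternate-allele frequencies from quality-filtered calls
(DP >= 6, GQ >= 20, site present in at least 80% of each species'
individuals), and retain sites where some species pair differs in
frequency by at least 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spetkit.variants import VariantTable, concat_tables


@dataclass
class FreqFilters:
    dp_min: int = 6
    gq_min: int = 20
    call_rate_min: float = 0.8


def merge_species_cohorts(
    tables: dict[str, VariantTable],
) -> tuple[VariantTable, dict[str, str]]:
    """Union of sites across per-species tables, samples concatenated.

    Sites are matched on (chrom, pos); a position with conflicting REF
    alleles across cohorts is dropped with a warning.  Returns the
    merged table and a sample -> species assignment map.
    """
    if len(tables) < 2:
        raise ValueError("need at least two species cohorts")
    # collect the union of site keys, checking REF consistency
    ref_of: dict[tuple[str, int], str] = {}
    alt_of: dict[tuple[str, int], str] = {}
    conflicts: set[tuple[str, int]] = set()
    for sp, t in tables.items():
        for chrom, pos, ref, alt in zip(
            t.sites["chrom"], t.sites["pos"], t.sites["ref"], t.sites["alt"]
        ):
            key = (chrom, int(pos))
            if key in ref_of and ref_of[key] != ref:
                conflicts.add(key)
            ref_of.setdefault(key, ref)
            if alt:
                if key in alt_of and alt_of[key] != alt:
                    conflicts.add(key)
                alt_of.setdefault(key, alt)
    if conflicts:
        warnings.warn(f"{len(conflicts)} sites with conflicting alleles dropped")
    keys = sorted(k for k in ref_of if k not in conflicts)
    key_ix = {k: i for i, k in enumerate(keys)}
    species_list = list(tables)
    all_samples: list[str] = []
    assignments: dict[str, str] = {}
    for sp in species_list:
        for s in tables[sp].samples:
            name = s if s not in assignments else f"{sp}:{s}"
            assignments[name] = sp
            all_samples.append(name)
    n_sites, n_samp = len(keys), len(all_samples)
    gt = np.full((n_sites, n_samp), -1, dtype=np.int8)
    dp = np.full((n_sites, n_samp), -1, dtype=np.int32)
    gq = np.full((n_sites, n_samp), -1, dtype=np.int16)
    adr = np.full((n_sites, n_samp), -1, dtype=np.int32)
    ada = np.full((n_sites, n_samp), -1, dtype=np.int32)
    col0 = 0
    for sp in species_list:
        t = tables[sp]
        cols = slice(col0, col0 + t.n_samples)
        for i in range(t.n_sites):
            key = (t.sites["chrom"].iat[i], int(t.sites["pos"].iat[i]))
            if key in conflicts:
                continue
            row = key_ix[key]
            gt[row, cols] = t.gt[i]
            dp[row, cols] = t.dp[i]
            gq[row, cols] = t.gq[i]
            adr[row, cols] = t.ad_ref[i]
            ada[row, cols] = t.ad_alt[i]
        col0 += t.n_samples
    sites = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "pos": [k[1] for k in keys],
            "ref": [ref_of[k] for k in keys],
            "alt": [alt_of.get(k, "") for k in keys],
            "qd": np.nan,
            "mq": np.nan,
            "mqranksum": np.nan,
            "site_class": ["snp" if alt_of.get(k) else "invariant" for k in keys],
            "multiallelic": False,
        }
    )
    merged = VariantTable(
        sites=sites, samples=all_samples, gt=gt, dp=dp, gq=gq, ad_ref=adr, ad_alt=ada
    )
    return merged, assignments


def species_allele_freqs(
    merged: VariantTable,
    assignments: dict[str, str],
    filters: FreqFilters | None = None,
) -> pd.DataFrame:
    """Per-species alternate-allele frequencies from filtered calls.

    Genotypes failing DP/GQ thresholds are excluded; a site must be
    called in at least ``call_rate_min`` of the individuals of *every*
    species to be retained.  Returns a frame with chrom, pos and one
    ``freq_<species>`` / ``callrate_<species>`` column pair per species.
    """
    filters = filters or FreqFilters()
    snp = merged.take_sites(merged.is_snp())
    species = sorted(set(assignments.values()))
    cols_of = {
        sp: np.array([j for j, s in enumerate(snp.samples) if assignments[s] == sp])
        for sp in species
    }
    for sp, cols in cols_of.items():
        if len(cols) == 0:
            raise ValueError(f"species {sp!r} has zero samples")
    out = {"chrom": snp.sites["chrom"], "pos": snp.sites["pos"]}
    keep = np.ones(snp.n_sites, dtype=bool)
    for sp in species:
        cols = cols_of[sp]
        g = snp.gt[:, cols]
        ok = (g >= 0) & (snp.dp[:, cols] >= filters.dp_min) & (
            snp.gq[:, cols] >= filters.gq_min
        )
        n_ok = ok.sum(axis=1)
        call_rate = n_ok / len(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(g * ok >= 0, np.where(ok, g, 0), 0).sum(axis=1) / np.maximum(
                2 * n_ok, 1
            )
        freq = np.where(n_ok > 0, freq, np.nan)
        out[f"freq_{sp}"] = freq
        out[f"callrate_{sp}"] = call_rate
        keep &= call_rate >= filters.call_rate_min
    df = pd.DataFrame(out)[keep].reset_index(drop=True)
    df.attrs["species"] = species
    return df


@dataclass
class DiscriminantMarker:
    chrom: str
    pos: int
    freqs: dict[str, float]
    max_delta: float
    pairs: list[tuple[str, str]] = field(default_factory=list)


def discriminant_sites(
    freqs: pd.DataFrame, delta_min: float = 0.9
) -> list[DiscriminantMarker]:
    """Sites where some species pair differs in frequency by >= delta_min.

    The boundary is inclusive (with a 1e-9 tolerance so that binary
    floating point cannot exclude an exact boundary difference); the
    comparison uses |Δ| of the alternate allele frequency, which is
    symmetric in ref/alt labelling of a fixed difference.  All
    qualifying pairs are listed per marker.
    """
    species = freqs.attrs.get("species") or sorted(
        c[len("freq_") :] for c in freqs.columns if c.startswith("freq_")
    )
    if len(species) < 2:
        raise ValueError("need frequency columns for at least two species")
    markers: list[DiscriminantMarker] = []
    f = {sp: freqs[f"freq_{sp}"].to_numpy(float) for sp in species}
    for i in range(len(freqs)):
        best, pairs = 0.0, []
        for a_i in range(len(species)):
            for b_i in range(a_i + 1, len(species)):
                sa, sb = species[a_i], species[b_i]
                d = abs(f[sa][i] - f[sb][i])
                if np.isnan(d):
                    continue
                if d >= delta_min - 1e-9:
                    pairs.append((sa, sb))
                best = max(best, 0.0 if np.isnan(d) else d)
        if pairs:
            markers.append(
                DiscriminantMarker(
                    chrom=str(freqs["chrom"].iat[i]),
                    pos=int(freqs["pos"].iat[i]),
                    freqs={sp: float(f[sp][i]) for sp in species},
                    max_delta=float(best),
                    pairs=pairs,
                )
            )
    return markers


def markers_frame(markers: list[DiscriminantMarker]) -> pd.DataFrame:
    rows = []
    for m in markers:
        row = {"chrom": m.chrom, "pos": m.pos, "max_delta": m.max_delta,
               "pairs": ";".join(f"{a}|{b}" for a, b in m.pairs)}
        row.update({f"freq_{sp}": v for sp, v in m.freqs.items()})
        rows.append(row)
    return pd.DataFrame(rows)
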