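"""Shared fixtures: small simulated genomes, panels and cohorts."""

import numpy as np
import pandas as pd
import pytest

from spetkit import kmer, panel as pnl, simulate
from spetkit.variants import VariantTable


@pytest.fixture(scope="session")
def small_genome():
    return simulate.simulate_genome(
        30_000, n_genes=3, repeat_spec=[(800, 2)], seed=101
    )


@pytest.fixture(scope="session")
def small_panel(small_genome):
    ref = small_genome.reference
    idx = kmer.build_kmer_index(ref)
    track = kmer.mappability_track(idx, ref)
    regions = kmer.eligible_regions(track)
    sites = pnl.select_random_sites(regions, 20, seed=5, min_spacing=800)
    return pnl.emit_probe_manifest(sites, [ref])


@pytest.fixture(scope="session")
def medium_cohort():
    """4 populations x 15 diploids, 400 SNPs + invariants + replicates."""
    model = simulate.PopulationModel(
        n_pops=4,
        n_per_pop=15,
        n_loci=400,
        F=0.10,
        missingness=0.05,
        paralog_fraction=0.05,
        n_invariant=400,
        n_replicates=3,
        seed=202,
    )
    return simulate.simulate_population_vcf(model)


def make_table(rows, samples):
    """Build a VariantTable from per-site dicts (test convenience).

    Each row: chrom, pos, ref, alt ('' = invariant), qd/mq/mqranksum
    (None = absent), multiallelic (bool), and per-sample lists gt, dp,
    gq, ad_ref, ad_alt (-1 = missing).
    """
    n = len(samples)
    site_rows = []
    gt, dp, gq, adr, ada = [], [], [], [], []
    for r in rows:
        invariant = r.get("alt", "") in ("", None)
        ref = r.get("ref", "A")
        if invariant:
            cls = "invariant"
        elif len(ref) == 1 and all(len(a) == 1 for a in r["alt"].split(",")):
            cls = "snp"
        else:
            cls = "other"
        site_rows.append(
            {
                "chrom": r.get("chrom", "chr1"),
                "pos": r["pos"],
                "ref": ref,
                "alt": "" if invariant else r["alt"],
                "qd": np.nan if r.get("qd") is None else r.get("qd"),
                "mq": np.nan if r.get("mq") is None else r.get("mq"),
                "mqranksum": np.nan if r.get("mqranksum") is None else r.get("mqranksum"),
                "site_class": cls,
                "multiallelic": bool(r.get("multiallelic", False)),
            }
        )
        gt.append(r.get("gt", [0] * n))
        dp.append(r.get("dp", [30] * n))
        gq.append(r.get("gq", [99] * n))
        adr.append(r.get("ad_ref", [-1] * n))
        ada.append(r.get("ad_alt", [-1] * n))
    return VariantTable(
        sites=pd.DataFrame(site_rows),
        samples=list(samples),
        gt=np.array(gt, dtype=np.int8),
        dp=np.array(dp, dtype=np.int32),
        gq=np.array(gq, dtype=np.int16),
        ad_ref=np.array(adr, dtype=np.int32),
        ad_alt=np.array(ada, dtype=np.int32),
    )
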