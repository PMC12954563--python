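"""Synthetic data with known truth for every stage of the toolkit.

Four generators cover the pipeline end to end:

* :func:`simulate_genome` — genomes with exact repeat families and
  multi-exon genes (whose spliced transcripts form a transcriptome);
* :func:`simulate_perfect_read_pairs` — error-free 150 bp FR pairs with
  insert ~ Normal(400, 25), the substrate for mappability anchoring;
* :func:`simulate_capture_reads` — SPET capture reads with 6 bp UMIs
  and PCR duplication, with a truth table of duplicate structure;
* :func:`simulate_population_vcf` — island-model genotype matrices with
  a target differentiation F under the Balding-Nichols model, realistic
  depth/GQ noise, missingness, paralog-collapsed loci and technical
  replicates.

Everything is reproducible bit-for-bit given a seed.  The generators
emulate clean, well-behaved data (no sequencing errors, no indels, no
linkage); what passing tests show about messy real data is discussed in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from spetkit.dedup import AlignedReadRecord
from spetkit.kmer import (
    PerfectReadPair,
    ReadPairSource,
    ReferenceSequence,
    RefKind,
    revcomp,
)
from spetkit.panel import PanelManifest
from spetkit.variants import (
    SITE_CLASS_INVARIANT,
    SITE_CLASS_SNP,
    VariantTable,
)

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class RepeatPlacement:
    family: str
    copy_index: int
    start: int
    end: int


@dataclass
class GenomeTruth:
    """A simulated genome plus everything the tests need to know."""

    seq_id: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatPlacement] = field(default_factory=list)
    repeat_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def reference(self) -> ReferenceSequence:
        return ReferenceSequence(self.seq_id, self.sequence, RefKind.genome)

    def transcripts(self) -> list[ReferenceSequence]:
        """Spliced transcripts (exon concatenation, forward strand)."""
        out = []
        for g in self.genes:
            seq = "".join(self.sequence[a:b] for a, b in g.exons)
            out.append(ReferenceSequence(f"{g.gene_id}_t", seq, RefKind.transcriptome))
        return out

    def junctions(self, gene: GeneModel) -> list[int]:
        """Transcript coordinates of exon-exon junctions of one gene."""
        out, acc = [], 0
        for a, b in gene.exons[:-1]:
            acc += b - a
            out.append(acc)
        return out


def simulate_genome(
    length: int,
    n_genes: int = 0,
    repeat_spec: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    seq_id: str = "chr1",
    exon_len_range: tuple[int, int] = (300, 600),
    intron_len_range: tuple[int, int] = (800, 1500),
    n_exons_range: tuple[int, int] = (1, 3),
) -> GenomeTruth:
    """Generate a random genome with exact repeats and gene models.

    ``repeat_spec`` is a sequence of (unit_length, n_copies) families;
    every copy is an exact duplicate so copy-number truth is unambiguous
    for the mapping round-trip tests.  Genes and repeat copies never
    overlap.  Intron lengths default to >= 800 bp so that a properly
    paired fragment can never straddle a junction collinearly.
    """
    rng = np.random.default_rng(seed)
    feature_len = sum(ln * cp for ln, cp in repeat_spec)
    if feature_len > 0.5 * length:
        raise ValueError(
            f"repeat content {feature_len} exceeds half the genome length {length}"
        )
    base = list(_random_dna(rng, length))
    occupied: list[tuple[int, int]] = []

    def place(flen: int) -> int:
        if flen >= length:
            raise ValueError(f"feature of length {flen} exceeds genome length {length}")
        for _ in range(1000):
            start = int(rng.integers(0, length - flen + 1))
            if all(start + flen <= a or start >= b for a, b in occupied):
                occupied.append((start, start + flen))
                return start
        raise ValueError("could not place features; genome too crowded")

    repeats: list[RepeatPlacement] = []
    mask = np.zeros(length, dtype=bool)
    for fam_i, (unit_len, copies) in enumerate(repeat_spec):
        unit = _random_dna(rng, unit_len)
        for c in range(copies):
            start = place(unit_len)
            base[start : start + unit_len] = list(unit)
            repeats.append(RepeatPlacement(f"rep{fam_i}", c, start, start + unit_len))
            mask[start : start + unit_len] = True

    genes: list[GeneModel] = []
    for gi in range(n_genes):
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        ex_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1, size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        start = place(span)
        exons, p = [], start
        for k in range(n_ex):
            exons.append((p, p + int(ex_lens[k])))
            p += int(ex_lens[k])
            if k < n_ex - 1:
                p += int(in_lens[k])
        genes.append(GeneModel(f"gene{gi}", tuple(exons)))

    # avoid splice-site micro-homology: the first/last intron base must
    # differ from the adjacent exon base, so a junction-crossing read can
    # never find an exact genomic placement extending past the junction
    order = "ACGT"
    for gene in genes:
        for (a, b), (a2, _b2) in zip(gene.exons[:-1], gene.exons[1:]):
            if base[b] == base[a2]:
                base[b] = order[(order.index(base[b]) + 1) % 4]
            if base[a2 - 1] == base[b - 1]:
                base[a2 - 1] = order[(order.index(base[a2 - 1]) + 1) % 4]

    return GenomeTruth(
        seq_id=seq_id,
        sequence="".join(base),
        genes=genes,
        repeats=repeats,
        repeat_mask=mask,
    )


# ---------------------------------------------------------------------------
# perfect read pairs
# ---------------------------------------------------------------------------


def simulate_perfect_read_pairs(
    refs: Sequence[ReferenceSequence] | ReferenceSequence | GenomeTruth,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: int = 400,
    insert_sd: int = 25,
    seed: int = 0,
) -> list[PerfectReadPair]:
    """Error-free FR pairs from a reference set.

    Fragment starts are uniform; insert lengths are Normal(mean, sd)
    rounded and truncated to [2 * read_len, sequence length].  The
    sequenced strand of each fragment is random.  Source records carry
    the true mate placements for round-trip and contiguity checks.
    """
    if isinstance(refs, GenomeTruth):
        refs = [refs.reference]
    elif isinstance(refs, ReferenceSequence):
        refs = [refs]
    rng = np.random.default_rng(seed)
    usable = [r for r in refs if len(r) >= 2 * read_len]
    if not usable:
        raise ValueError("no reference sequence long enough for a read pair")
    lengths = np.array([len(r) for r in usable], dtype=float)
    probs = lengths / lengths.sum()
    seq_choice = rng.choice(len(usable), size=n_pairs, p=probs)
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    flip = rng.random(n_pairs) < 0.5
    pairs: list[PerfectReadPair] = []
    for i in range(n_pairs):
        ref = usable[seq_choice[i]]
        L = len(ref)
        insert = int(np.clip(inserts[i], 2 * read_len, L))
        start = int(rng.integers(0, L - insert + 1))
        frag = ref.residues[start : start + insert]
        if flip[i]:
            frag = revcomp(frag)
        mate1 = frag[:read_len]
        mate2 = revcomp(frag[-read_len:])
        if not flip[i]:
            src = ReadPairSource(
                ref.seq_id, start, "+", start + insert - read_len, "-", start, insert
            )
        else:
            src = ReadPairSource(
                ref.seq_id, start + insert - read_len, "-", start, "+", start, insert
            )
        pairs.append(PerfectReadPair(f"pair{i}", mate1, mate2, src))
    return pairs


def write_fastq_pairs(pairs: Sequence[PerfectReadPair], path1, path2, qual: str = "I") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.mate1}\n+\n{qual * len(p.mate1)}\n")
            f2.write(f"@{p.pair_id}/2\n{p.mate2}\n+\n{qual * len(p.mate2)}\n")


# ---------------------------------------------------------------------------
# capture reads with UMIs
# ---------------------------------------------------------------------------


@dataclass
class CaptureModel:
    """Per-probe capture efficiency and duplication behaviour.

    ``efficiency`` may be a scalar applied to all probes or a mapping
    probe_id -> value in [0, 1].  Each captured original fragment is
    sequenced ``1 + Poisson(duplication_rate)`` times; all copies share
    the fragment's UMI (drawn uniformly over 4^umi_len) and alignment
    start, which is fixed by the SPET probe geometry.
    """

    efficiency: float | Mapping[str, float] = 1.0
    mean_fragments_per_probe: float = 20.0
    umi_len: int = 6
    duplication_rate: float = 0.5
    read_len: int = 150

    def __post_init__(self) -> None:
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")

    def probe_efficiency(self, probe_id: str) -> float:
        if isinstance(self.efficiency, Mapping):
            return float(self.efficiency.get(probe_id, 1.0))
        return float(self.efficiency)


@dataclass
class CaptureResult:
    records: list[AlignedReadRecord]
    truth: pd.DataFrame  # read_id, probe_id, fragment_id, umi, is_duplicate
    sequences: dict[str, str]  # read_id -> read sequence

    def write_fastq(self, path) -> None:
        """Single-end FASTQ; the UMI rides on the name after ':'."""
        with open(path, "w") as fh:
            for r in self.records:
                seq = self.sequences[r.read_id]
                fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_capture_reads(
    panel: PanelManifest,
    genome: Mapping[str, str] | GenomeTruth,
    capture: CaptureModel,
    sample_id: str = "s0",
    seed: int = 0,
) -> CaptureResult:
    """SPET capture reads for one sample.

    Reads start at the probe's 3' end and run into the target: on a '+'
    probe the read covers ``[target, target + read_len)``; on a '-'
    probe ``[target - read_len + 1, target + 1)`` on the minus strand.
    Every read therefore overlaps its target position.  The truth table
    marks all copies of a fragment beyond the first as duplicates.
    """
    if isinstance(genome, GenomeTruth):
        seqs = {genome.seq_id: genome.sequence}
    else:
        seqs = dict(genome)
    rng = np.random.default_rng(seed)
    records: list[AlignedReadRecord] = []
    rows = []
    sequences: dict[str, str] = {}
    rlen = capture.read_len
    for probe in panel.probes:
        seq = seqs.get(probe.seq_id)
        if seq is None:
            raise KeyError(f"probe {probe.probe_id} on unknown sequence {probe.seq_id!r}")
        eff = capture.probe_efficiency(probe.probe_id)
        n_frags = rng.poisson(capture.mean_fragments_per_probe * eff)
        if probe.strand == "+":
            start = probe.target_pos
            read_seq = seq[start : start + rlen]
        else:
            start = max(0, probe.target_pos - rlen + 1)
            read_seq = revcomp(seq[start : probe.target_pos + 1])
        if len(read_seq) < rlen // 2:
            continue
        for f in range(int(n_frags)):
            umi = "".join(_BASES[rng.integers(0, 4, size=capture.umi_len)])
            n_copies = 1 + rng.poisson(capture.duplication_rate)
            frag_id = f"{sample_id}:{probe.probe_id}:frag{f}"
            for c in range(int(n_copies)):
                read_id = f"{frag_id}:c{c}:{umi}"
                records.append(
                    AlignedReadRecord(
                        read_id=read_id,
                        umi=umi,
                        seq_id=probe.seq_id,
                        start=start,
                        strand=probe.strand,
                        mean_qual=37.0,
                        length=len(read_seq),
                    )
                )
                sequences[read_id] = read_seq
                rows.append(
                    {
                        "read_id": read_id,
                        "probe_id": probe.probe_id,
                        "fragment_id": frag_id,
                        "umi": umi,
                        "is_duplicate": c > 0,
                    }
                )
    truth = pd.DataFrame(
        rows, columns=["read_id", "probe_id", "fragment_id", "umi", "is_duplicate"]
    )
    return CaptureResult(records=records, truth=truth, sequences=sequences)


# ---------------------------------------------------------------------------
# population genotype matrices
# ---------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Island-model cohort under Balding-Nichols differentiation.

    Population allele frequencies are drawn around an ancestral
    frequency p as Beta(p(1-F)/F, (1-p)(1-F)/F), whose among-population
    variance is F·p(1-p) — exactly the quantity Weir-Cockerham's θ
    estimates, giving the estimators a known truth.  Genotypes are
    Hardy-Weinberg draws within populations.

    Depth is negative binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``: var = m + m²/r), loosely matching the 18-150x
    range of real SPET target depths.  GQ is derived from genotype
    likelihoods under a binomial allele-depth model.  A fraction of
    loci are paralog-collapsed: reads of two latent loci pool into one
    site and genotypes are re-called from the pooled allele balance,
    producing the excess-heterozygosity / skewed-ratio signature that
    HDplot detects.
    """

    n_pops: int = 10
    n_per_pop: int = 25
    n_loci: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.95)
    F: float = 0.10
    missingness: float = 0.0
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    base_error: float = 0.005
    paralog_fraction: float = 0.0
    n_invariant: int = 0
    n_replicates: int = 0
    genotype_error: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.F < 1:
            raise ValueError("F must be in [0, 1)")
        for name in ("missingness", "paralog_fraction", "genotype_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


@dataclass
class SimulatedCohort:
    table: VariantTable
    pop_labels: dict[str, str]
    replicate_pairs: list[tuple[str, str]]
    locus_truth: pd.DataFrame  # chrom, pos, p_anc, is_paralog
    pop_freqs: np.ndarray  # (n_loci, n_pops) per-population alt frequencies

    def write_labels_tsv(self, path) -> None:
        pd.DataFrame(
            [{"sample_id": s, "population_id": p} for s, p in self.pop_labels.items()]
        ).to_csv(path, sep="\t", index=False)

    def write_replicates_tsv(self, path) -> None:
        pd.DataFrame(
            self.replicate_pairs, columns=["sample_a", "sample_b"]
        ).to_csv(path, sep="\t", index=False)

    def write_truth_tsv(self, path) -> None:
        self.locus_truth.to_csv(path, sep="\t", index=False)


def ascertained_class_labels(
    table: VariantTable,
    pop_labels: Mapping[str, str],
    discovery_pop: str,
    n_per_class: int,
    seed: int = 0,
    maf_window: tuple[float, float] = (0.35, 0.5),
) -> dict[tuple[str, int], str]:
    """Emulate array-style marker ascertainment for bias studies.

    SNP arrays are designed from markers found at intermediate frequency
    in a small discovery panel, typically from one population.  This
    helper labels ``n_per_class`` loci whose minor allele frequency in
    ``discovery_pop`` falls inside ``maf_window`` as the ``known``
    class, and ``n_per_class`` unconditioned loci as ``random``,
    returning a (chrom, pos) -> class map for
    :func:`spetkit.popgen.ascertainment_comparison`.
    """
    snp = table.take_sites(table.is_snp())
    cols = np.array(
        [j for j, s in enumerate(snp.samples) if pop_labels[s] == discovery_pop]
    )
    if len(cols) == 0:
        raise ValueError(f"no samples in discovery population {discovery_pop!r}")
    g = snp.gt[:, cols]
    called = g >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=1) / np.maximum(2 * called.sum(axis=1), 1)
    maf = np.minimum(p, 1 - p)
    pool = np.nonzero((maf >= maf_window[0]) & (maf <= maf_window[1]))[0]
    if len(pool) < n_per_class or snp.n_sites - n_per_class < n_per_class:
        raise ValueError("not enough loci for the requested class sizes")
    rng = np.random.default_rng(seed)
    known = rng.choice(pool, n_per_class, replace=False)
    rest = np.setdiff1d(np.arange(snp.n_sites), known)
    rand = rng.choice(rest, n_per_class, replace=False)
    chroms = snp.sites["chrom"].to_numpy()
    pos = snp.sites["pos"].to_numpy()
    out: dict[tuple[str, int], str] = {}
    for i in known:
        out[(chroms[i], int(pos[i]))] = "known"
    for i in rand:
        out[(chroms[i], int(pos[i]))] = "random"
    return out


def _nb_draw(rng, mean, dispersion, size):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int32)


def _alt_read_prob(g: np.ndarray, e: float) -> np.ndarray:
    """Per-read alt probability given dosage 0/1/2 (error e for homs)."""
    probs = np.array([e, 0.5, 1.0 - e])
    return probs[np.clip(g, 0, 2)]


def _gq_from_ad(dp: np.ndarray, alt: np.ndarray, e: float) -> np.ndarray:
    """GQ = second-best phred-scaled likelihood gap, capped at 99."""
    with np.errstate(divide="ignore"):
        ll = np.stack(
            [stats.binom.logpmf(alt, dp, p) for p in (e, 0.5, 1.0 - e)]
        )  # (3, ...)
    pl = -10.0 / np.log(10.0) * (ll - ll.max(axis=0))
    pl_sorted = np.sort(pl, axis=0)
    gq = np.rint(pl_sorted[1]).astype(np.int16)
    return np.minimum(gq, 99)


def _call_from_balance(dp: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Threshold genotype caller on pooled allele balance (paralog sites)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(dp > 0, alt / np.maximum(dp, 1), np.nan)
    g = np.full(dp.shape, -1, dtype=np.int8)
    g[(dp > 0) & (frac <= 0.15)] = 0
    g[(dp > 0) & (frac > 0.15) & (frac < 0.85)] = 1
    g[(dp > 0) & (frac >= 0.85)] = 2
    return g


def simulate_population_vcf(
    model: PopulationModel,
    panel: PanelManifest | None = None,
    chrom: str = "chr1",
) -> SimulatedCohort:
    """Generate a joint-genotyped cohort with known truth.

    When a panel is supplied, SNP loci take the panel's target
    coordinates (first ``n_loci`` targets); otherwise sites are laid
    out every 10 bp on a synthetic chromosome.  Invariant sites carry
    GT/DP only.  Technical replicates of the first ``n_replicates``
    samples are appended as ``<sample>_rep`` columns with independent
    read draws and genotype flips at rate ``genotype_error``.
    """
    rng = np.random.default_rng(model.seed)
    n_loci, n_pops, npp = model.n_loci, model.n_pops, model.n_per_pop
    n_base = n_pops * npp
    samples = [f"pop{k}_ind{i}" for k in range(n_pops) for i in range(npp)]
    pop_of = np.repeat(np.arange(n_pops), npp)
    pop_labels = {s: f"pop{k}" for s, k in zip(samples, pop_of)}

    lo, hi = model.maf_range
    p_anc = rng.uniform(lo, hi, size=n_loci)
    if model.F > 0:
        a = p_anc * (1 - model.F) / model.F
        b = (1 - p_anc) * (1 - model.F) / model.F
        pop_freqs = rng.beta(a[:, None], b[:, None], size=(n_loci, n_pops))
    else:
        pop_freqs = np.tile(p_anc[:, None], (1, n_pops))

    # true genotypes for base samples: HWE within populations
    g_true = rng.binomial(2, pop_freqs[:, pop_of]).astype(np.int8)

    # paralog-collapsed loci: an independent latent duplicate locus
    is_paralog = rng.random(n_loci) < model.paralog_fraction
    p_anc_b = rng.uniform(lo, hi, size=n_loci)
    if model.F > 0:
        ab = p_anc_b * (1 - model.F) / model.F
        bb = (1 - p_anc_b) * (1 - model.F) / model.F
        pop_freqs_b = rng.beta(ab[:, None], bb[:, None], size=(n_loci, n_pops))
    else:
        pop_freqs_b = np.tile(p_anc_b[:, None], (1, n_pops))
    g_true_b = rng.binomial(2, pop_freqs_b[:, pop_of]).astype(np.int8)

    # replicate columns: copy truth of the first n_replicates samples,
    # flip genotypes at rate genotype_error (uniformly to another class)
    n_rep = min(model.n_replicates, n_base)
    rep_sources = list(range(n_rep))
    rep_names = [samples[i] + "_rep" for i in rep_sources]
    replicate_pairs = [(samples[i], samples[i] + "_rep") for i in rep_sources]

    def _with_flips(g_cols: np.ndarray) -> np.ndarray:
        g = g_cols.copy()
        flip = rng.random(g.shape) < model.genotype_error
        shift = rng.integers(1, 3, size=g.shape)
        g[flip] = (g[flip] + shift[flip]) % 3
        return g

    g_all = np.concatenate([g_true, _with_flips(g_true[:, rep_sources])], axis=1)
    g_b_all = np.concatenate([g_true_b, g_true_b[:, rep_sources]], axis=1)
    all_samples = samples + rep_names
    n_samp = len(all_samples)
    for s in rep_names:
        pop_labels[s] = pop_labels[s[: -len("_rep")]]

    # reads
    dp_a = _nb_draw(rng, model.depth_mean, model.depth_dispersion, (n_loci, n_samp))
    alt_a = rng.binomial(dp_a, _alt_read_prob(g_all, model.base_error)).astype(np.int32)
    dp_b = _nb_draw(rng, model.depth_mean, model.depth_dispersion, (n_loci, n_samp))
    alt_b = rng.binomial(dp_b, _alt_read_prob(g_b_all, model.base_error)).astype(np.int32)

    dp = np.where(is_paralog[:, None], dp_a + dp_b, dp_a).astype(np.int32)
    alt = np.where(is_paralog[:, None], alt_a + alt_b, alt_a).astype(np.int32)

    gt = np.where(is_paralog[:, None], _call_from_balance(dp, alt), g_all).astype(np.int8)
    gt[dp == 0] = -1
    if model.missingness > 0:
        gt[rng.random(gt.shape) < model.missingness] = -1

    gq = _gq_from_ad(dp, alt, model.base_error)
    gq[gt < 0] = -1
    ad_ref = (dp - alt).astype(np.int32)
    ad_alt = alt
    ad_ref[gt < 0] = -1
    ad_alt2 = ad_alt.copy()
    ad_alt2[gt < 0] = -1

    # site coordinates and annotations
    if panel is not None:
        targets = sorted(panel.probes, key=lambda p: (p.seq_id, p.target_pos))
        if len(targets) < n_loci:
            raise ValueError(
                f"panel has {len(targets)} probes but n_loci={n_loci}"
            )
        snp_chroms = [t.seq_id for t in targets[:n_loci]]
        snp_pos = np.array([t.target_pos + 1 for t in targets[:n_loci]])
    else:
        snp_chroms = [chrom] * n_loci
        snp_pos = 10 * np.arange(1, n_loci + 1)

    qd = np.clip(rng.normal(25.0, 5.0, size=n_loci), 2.5, 40.0)
    mq = np.clip(rng.normal(59.0, 1.0, size=n_loci), 40.5, 60.0)
    mqrs = rng.normal(0.0, 1.0, size=n_loci)
    refs_ = _BASES[rng.integers(0, 4, size=n_loci)]
    alts_ = np.array(
        [_BASES[(list(_BASES).index(r) + 1 + rng.integers(0, 3)) % 4] for r in refs_]
    )

    sites = pd.DataFrame(
        {
            "chrom": snp_chroms,
            "pos": snp_pos,
            "ref": refs_,
            "alt": alts_,
            "qd": qd,
            "mq": mq,
            "mqranksum": mqrs,
            "site_class": SITE_CLASS_SNP,
            "multiallelic": False,
        }
    )
    table = VariantTable(
        sites=sites,
        samples=all_samples,
        gt=gt,
        dp=dp,
        gq=gq,
        ad_ref=ad_ref,
        ad_alt=ad_alt2,
    )

    if model.n_invariant > 0:
        n_inv = model.n_invariant
        inv_dp = _nb_draw(rng, model.depth_mean, model.depth_dispersion, (n_inv, n_samp))
        inv_gt = np.zeros((n_inv, n_samp), dtype=np.int8)
        inv_gt[inv_dp == 0] = -1
        if model.missingness > 0:
            inv_gt[rng.random(inv_gt.shape) < model.missingness] = -1
        if panel is not None:
            base_pos = np.asarray(snp_pos)
            inv_pos = base_pos[np.arange(n_inv) % n_loci] + 2 + 2 * (np.arange(n_inv) // n_loci)
            inv_chroms = [snp_chroms[i % n_loci] for i in range(n_inv)]
        else:
            inv_pos = 10 * np.arange(1, n_inv + 1) + 5
            inv_chroms = [chrom] * n_inv
        inv_sites = pd.DataFrame(
            {
                "chrom": inv_chroms,
                "pos": inv_pos,
                "ref": _BASES[rng.integers(0, 4, size=n_inv)],
                "alt": "",
                "qd": np.nan,
                "mq": np.nan,
                "mqranksum": np.nan,
                "site_class": SITE_CLASS_INVARIANT,
                "multiallelic": False,
            }
        )
        minus1 = np.full((n_inv, n_samp), -1)
        inv_table = VariantTable(
            sites=inv_sites,
            samples=all_samples,
            gt=inv_gt,
            dp=inv_dp,
            gq=minus1.astype(np.int16),
            ad_ref=minus1.astype(np.int32),
            ad_alt=minus1.astype(np.int32),
        )
        from spetkit.variants import concat_tables

        table = concat_tables(table, inv_table).sort()

    locus_truth = pd.DataFrame(
        {
            "chrom": snp_chroms,
            "pos": snp_pos,
            "p_anc": p_anc,
            "is_paralog": is_paralog,
        }
    )
    return SimulatedCohort(
        table=table,
        pop_labels=pop_labels,
        replicate_pairs=replicate_pairs,
        locus_truth=locus_truth,
        pop_freqs=pop_freqs,
    )
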