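"""k-mer mappability, eligible regions, and exact mapping of perfect reads.

SPET probes must avoid repetitive sequence, otherwise capture products
align ambiguously and genotypes are unusable.  The standard proxy for
local repetitiveness is the per-position occurrence count of the k-mer
(k = 20 by default) starting at that position, computed over the whole
reference.  Regions whose average 20-mer count stays below 2 over at
least 200 bp are considered eligible for random target placement.

When only a transcriptome is available, eligibility is established by
simulating error-free read pairs from the transcripts, placing them
exactly on the genome of a related species, and keeping transcript
intervals where transcriptome and genome are collinear — this excludes
both repeats (ambiguous placement) and exon-intron junctions (no exact
full-length placement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class RefKind(str, Enum):
    genome = "genome"
    transcriptome = "transcriptome"


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference sequence (chromosome, scaffold or transcript)."""

    seq_id: str
    residues: str
    kind: RefKind = RefKind.genome

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.residues.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.seq_id!r}: non-DNA symbols {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path, kind: RefKind = RefKind.genome) -> list[ReferenceSequence]:
    """Load a FASTA file into :class:`ReferenceSequence` records."""
    refs = [
        ReferenceSequence(rec.id, str(rec.seq).upper(), kind)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not refs:
        raise ValueError(f"no sequences found in {path}")
    seen: set[str] = set()
    for r in refs:
        if r.seq_id in seen:
            raise ValueError(f"duplicate seq_id {r.seq_id!r} in {path}")
        seen.add(r.seq_id)
    return refs


def write_fasta(refs: Iterable[ReferenceSequence], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.seq_id}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


@dataclass
class KmerIndex:
    """Occurrence counts of every k-mer of a reference set.

    With ``canonical=True`` (the default) a k-mer and its reverse
    complement are folded into one class, so the count of ``AACC``
    includes occurrences of ``GGTT``; mappability is strand-symmetric
    for capture design.  Windows containing N are not counted.
    """

    k: int
    counts: dict[str, int]
    canonical: bool = True

    def lookup(self, kmer: str) -> int:
        key = canonical(kmer) if self.canonical else kmer
        return self.counts.get(key, 0)


def _iter_windows(seq: str, k: int):
    for p in range(len(seq) - k + 1):
        yield p, seq[p : p + k]


def build_kmer_index(
    refs: Sequence[ReferenceSequence] | ReferenceSequence,
    k: int = 20,
    canonical_mode: bool = True,
) -> KmerIndex:
    """Count every k-length window (without N) over a reference set.

    Parameters
    ----------
    refs:
        One or more reference sequences.
    k:
        Window size; 20 balances uniqueness against index size for
        plant-sized genomes.
    canonical_mode:
        Fold each window with its reverse complement (default).  Set
        False for single-strand counting.
    """
    if isinstance(refs, ReferenceSequence):
        refs = [refs]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not any(len(r) >= k for r in refs):
        raise ValueError(f"all sequences shorter than k={k}; empty index")
    counts: dict[str, int] = {}
    for ref in refs:
        seq = ref.residues.upper()
        for _, win in _iter_windows(seq, k):
            if "N" in win:
                continue
            key = canonical(win) if canonical_mode else win
            counts[key] = counts.get(key, 0) + 1
    return KmerIndex(k=k, counts=counts, canonical=canonical_mode)


@dataclass
class MappabilityTrack:
    """Per-position k-mer occurrence counts for one sequence.

    ``values[p]`` is the index count of the window starting at 0-based
    position ``p``; ``defined[p]`` is False where the window contains N
    (``values`` holds 0 there).  Length is ``L - k + 1``.
    """

    seq_id: str
    k: int
    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise ValueError("values/defined shape mismatch")

    def __len__(self) -> int:
        return len(self.values)


def mappability_track(index: KmerIndex, ref: ReferenceSequence) -> MappabilityTrack:
    """Evaluate the index along one sequence.

    Raises if a window (without N) is absent from the index, which would
    mean the index was not built over a superset of ``ref``.
    """
    k = index.k
    seq = ref.residues.upper()
    n = len(seq) - k + 1
    if n < 1:
        raise ValueError(f"{ref.seq_id!r} shorter than k={k}")
    values = np.zeros(n, dtype=np.int64)
    defined = np.ones(n, dtype=bool)
    for p, win in _iter_windows(seq, k):
        if "N" in win:
            defined[p] = False
            continue
        c = index.lookup(win)
        if c < 1:
            raise ValueError(
                f"{ref.seq_id!r} pos {p}: k-mer absent from index "
                "(index not built over this sequence?)"
            )
        values[p] = c
    return MappabilityTrack(seq_id=ref.seq_id, k=k, values=values, defined=defined)


@dataclass(frozen=True)
class EligibleRegion:
    """Half-open interval of k-mer start positions eligible for targets."""

    seq_id: str
    start: int
    end: int
    mean_kmer: float

    def __len__(self) -> int:
        return self.end - self.start


def eligible_regions(
    track: MappabilityTrack,
    min_len: int = 200,
    mean_max: float = 2.0,
    pos_cap: int = 4,
) -> list[EligibleRegion]:
    """Detect low-repetitiveness regions on a mappability track.

    A region must be at least ``min_len`` positions long and have a mean
    k-mer count strictly below ``mean_max``.  In addition every position
    must satisfy ``value <= pos_cap`` — without the per-position cap a
    single massive repeat spike could be averaged away by flanking
    unique sequence.  Undefined (N-window) positions always break
    regions.

    Within each maximal cap-respecting run, regions are emitted by a
    left-to-right greedy scan: from the current start the longest
    qualifying segment is taken; if none qualifies the start advances
    one position.  The result is sorted and non-overlapping.
    """
    ok = track.defined & (track.values <= pos_cap)
    values = track.values.astype(np.float64)
    out: list[EligibleRegion] = []
    n = len(ok)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        out.extend(
            _regions_in_run(track.seq_id, values, i, j, min_len, mean_max)
        )
        i = j
    return out


def _regions_in_run(
    seq_id: str,
    values: np.ndarray,
    lo: int,
    hi: int,
    min_len: int,
    mean_max: float,
) -> list[EligibleRegion]:
    """Greedy longest-first segmentation of one run [lo, hi).

    mean(values[s:e]) < mean_max  <=>  g[e] < g[s]  with
    g[i] = prefix_sum[i] - mean_max * i, which lets both the existence
    check (via suffix minima of g) and the longest-e search run on
    vectorised arrays.
    """
    run = values[lo:hi]
    m = len(run)
    if m < min_len:
        return []
    prefix = np.concatenate([[0.0], np.cumsum(run)])
    g = prefix - mean_max * np.arange(m + 1)
    # suffix_min[i] = min(g[i:]) over the run's g array
    suffix_min = np.minimum.accumulate(g[::-1])[::-1]
    out: list[EligibleRegion] = []
    s = 0
    while s + min_len <= m:
        first_e = s + min_len
        if suffix_min[first_e] >= g[s]:
            s += 1
            continue
        candidates = np.nonzero(g[first_e:] < g[s])[0]
        e = first_e + int(candidates[-1])
        mean = (prefix[e] - prefix[s]) / (e - s)
        out.append(
            EligibleRegion(seq_id=seq_id, start=lo + s, end=lo + e, mean_kmer=float(mean))
        )
        s = e
    return out


def write_regions_bed(regions: Sequence[EligibleRegion], path) -> None:
    """BED with the region mean k-mer count (x100, rounded) as score."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = int(round(r.mean_kmer * 100)) if math.isfinite(r.mean_kmer) else 0
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\tregion_{i}\t{score}\n")


def read_regions_bed(path) -> list[EligibleRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            mean = int(f[4]) / 100.0 if len(f) > 4 else float("nan")
            regions.append(EligibleRegion(f[0], int(f[1]), int(f[2]), mean))
    return regions


def write_track_bedgraph(track: MappabilityTrack, path) -> None:
    with open(path, "w") as fh:
        vals = np.where(track.defined, track.values, -1)
        start = 0
        for p in range(1, len(vals) + 1):
            if p == len(vals) or vals[p] != vals[start]:
                if vals[start] >= 0:
                    fh.write(f"{track.seq_id}\t{start}\t{p}\t{vals[start]}\n")
                start = p


# ---------------------------------------------------------------------------
# exact mapping of error-free read pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadPairSource:
    """Ground-truth placement of a simulated pair on its source sequence.

    ``start1``/``start2`` are the leftmost 0-based positions of the two
    mates on the source; strands are '+'/'-'.
    """

    seq_id: str
    start1: int
    strand1: str
    start2: int
    strand2: str
    fragment_start: int
    insert: int


@dataclass(frozen=True)
class PerfectReadPair:
    pair_id: str
    mate1: str
    mate2: str
    source: ReadPairSource | None = None

    def __post_init__(self) -> None:
        if len(self.mate1) != len(self.mate2):
            raise ValueError(f"{self.pair_id}: mate length mismatch")


@dataclass(frozen=True)
class PairPlacement:
    seq_id: str
    pos1: int
    strand1: str
    pos2: int
    strand2: str
    insert: int


@dataclass
class PairAlignment:
    """All consistent FR placements of one pair, plus summary flags."""

    pair_id: str
    placements: list[PairPlacement] = field(default_factory=list)
    unique: bool = False
    proper: bool = False

    @property
    def n_hits(self) -> int:
        return len(self.placements)

    @property
    def primary(self) -> PairPlacement | None:
        return self.placements[0] if self.placements else None


class ExactMapper:
    """Seed-and-verify exact matcher for error-free reads.

    All k-length seeds of the reference set are indexed once; a read is
    placed wherever its leading seed matches and the full read verifies
    as an exact substring.  Valid only for error-free reads — real-read
    alignment with mismatches is a different problem entirely.
    """

    def __init__(self, refs: Sequence[ReferenceSequence], seed_len: int = 20):
        self.refs = {r.seq_id: r.residues.upper() for r in refs}
        self.seed_len = seed_len
        self._seed_index: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.refs.items():
            for p in range(len(seq) - seed_len + 1):
                s = seq[p : p + seed_len]
                if "N" in s:
                    continue
                self._seed_index.setdefault(s, []).append((sid, p))

    def occurrences(self, read: str) -> list[tuple[str, int, str]]:
        """All exact placements of ``read`` as (seq_id, leftmost, strand)."""
        read = read.upper()
        if set(read) - DNA_ALPHABET:
            raise ValueError("read contains non-ACGTN symbols")
        hits: list[tuple[str, int, str]] = []
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            seed = oriented[: self.seed_len]
            for sid, p in self._seed_index.get(seed, ()):
                if self.refs[sid][p : p + len(oriented)] == oriented:
                    hits.append((sid, p, strand))
        return hits


def map_perfect_reads(
    pairs: Sequence[PerfectReadPair],
    refs: Sequence[ReferenceSequence],
    insert_mean: int = 400,
    insert_sd: int = 25,
    sd_window: int = 4,
    max_span: int | None = None,
    mapper: ExactMapper | None = None,
) -> list[PairAlignment]:
    """Place error-free pairs exactly, enumerating FR placements.

    A placement is consistent when both mates sit on the same sequence
    in forward-reverse orientation with a positive insert (outer span)
    no larger than ``max_span`` (default ``insert_mean + 10·insert_sd``,
    generous enough for any simulated fragment while excluding spurious
    pairings between far-apart repeat copies).  ``unique`` means exactly
    one consistent placement exists; ``proper`` additionally requires
    the primary placement's insert to lie within
    ``insert_mean ± sd_window * insert_sd``.  A chimeric pair whose
    mates sit beyond ``max_span`` has no consistent placement.
    """
    if mapper is None:
        mapper = ExactMapper(refs, seed_len=min(20, min(len(p.mate1) for p in pairs)))
    if max_span is None:
        max_span = insert_mean + 10 * insert_sd
    lo = insert_mean - sd_window * insert_sd
    hi = insert_mean + sd_window * insert_sd
    out: list[PairAlignment] = []
    for pair in pairs:
        hits1 = mapper.occurrences(pair.mate1)
        hits2 = mapper.occurrences(pair.mate2)
        rlen = len(pair.mate1)
        placements: list[PairPlacement] = []
        for sid1, p1, s1 in hits1:
            for sid2, p2, s2 in hits2:
                if sid1 != sid2 or s1 == s2:
                    continue
                # FR: the forward mate must be leftmost
                fwd_pos = p1 if s1 == "+" else p2
                rev_pos = p2 if s1 == "+" else p1
                if fwd_pos > rev_pos:
                    continue
                insert = rev_pos + rlen - fwd_pos
                if insert > max_span:
                    continue
                placements.append(PairPlacement(sid1, p1, s1, p2, s2, insert))
        placements.sort(key=lambda pl: (pl.seq_id, pl.pos1, pl.pos2, pl.strand1))
        aln = PairAlignment(pair_id=pair.pair_id, placements=placements)
        aln.unique = len(placements) == 1
        if placements:
            aln.proper = lo <= placements[0].insert <= hi
        out.append(aln)
    return out


def contiguity_regions(
    alignments: Sequence[PairAlignment],
    pairs: Sequence[PerfectReadPair],
    min_len: int = 200,
    max_gap: int | None = None,
    insert_mean: int = 400,
    insert_sd: int = 25,
    sd_window: int = 4,
) -> list[EligibleRegion]:
    """Transcript intervals collinear with a genome, from mapped pairs.

    Pairs must have been simulated FROM transcripts (their source record
    carries transcript coordinates) and mapped TO a genome.  A pair
    contributes when it is uniquely and properly placed and its two
    mates are collinear: the genomic distance between the mates equals
    the transcript distance, so both mates share one transcript-to-
    genome offset.  Pairs straddling an exon-intron junction fail this
    (the junction-crossing mate has no exact full-length placement, or
    the genomic gap jumps by the intron length), so junctions split the
    reported regions.

    Fragment spans are unioned per (transcript, genome sequence, offset,
    orientation) group and intervals >= ``min_len`` are returned in
    transcript coordinates, with ``mean_kmer`` set to NaN.
    """
    if max_gap is None:
        max_gap = insert_mean + sd_window * insert_sd
    if not alignments:
        import warnings

        warnings.warn("contiguity_regions: empty alignment set")
        return []
    by_id = {p.pair_id: p for p in pairs}
    # group key -> list of (t_start, t_end) fragment spans
    groups: dict[tuple, list[tuple[int, int]]] = {}
    for aln in alignments:
        if not (aln.unique and aln.proper):
            continue
        pair = by_id.get(aln.pair_id)
        if pair is None or pair.source is None:
            continue
        src = pair.source
        pl = aln.primary
        rlen = len(pair.mate1)
        t_delta = src.start2 - src.start1
        g_delta = pl.pos2 - pl.pos1
        if g_delta == t_delta:
            orient = "+"
            offset = pl.pos1 - src.start1
        elif g_delta == -t_delta:
            orient = "-"
            offset = pl.pos1 + src.start1
        else:
            continue  # not collinear: junction or rearrangement
        g_inner = abs(g_delta) - rlen
        if g_inner > max_gap:
            continue
        t_lo = min(src.start1, src.start2)
        t_hi = max(src.start1, src.start2) + rlen
        key = (src.seq_id, pl.seq_id, orient, offset)
        groups.setdefault(key, []).append((t_lo, t_hi))
    out: list[EligibleRegion] = []
    for (t_id, _gid, _orient, _off), spans in groups.items():
        spans.sort()
        cur_lo, cur_hi = spans[0]
        merged = []
        for lo2, hi2 in spans[1:]:
            if lo2 <= cur_hi:
                cur_hi = max(cur_hi, hi2)
            else:
                merged.append((cur_lo, cur_hi))
                cur_lo, cur_hi = lo2, hi2
        merged.append((cur_lo, cur_hi))
        for lo2, hi2 in merged:
            if hi2 - lo2 >= min_len:
                out.append(EligibleRegion(t_id, lo2, hi2, float("nan")))
    out.sort(key=lambda r: (r.seq_id, r.start))
    return out


def write_alignments_sam(
    alignments: Sequence[PairAlignment],
    pairs: Sequence[PerfectReadPair],
    refs: Sequence[ReferenceSequence],
    path,
) -> None:
    """Minimal SAM-text dump of primary placements, for inspection."""
    by_id = {p.pair_id: p for p in pairs}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for r in refs:
            fh.write(f"@SQ\tSN:{r.seq_id}\tLN:{len(r)}\n")
        for aln in alignments:
            pair = by_id[aln.pair_id]
            pl = aln.primary
            if pl is None:
                continue
            rlen = len(pair.mate1)
            for mate_i, (pos, strand, seq) in enumerate(
                [(pl.pos1, pl.strand1, pair.mate1), (pl.pos2, pl.strand2, pair.mate2)]
            ):
                flag = 0x1 | 0x2 | (0x40 if mate_i == 0 else 0x80)
                if strand == "-":
                    flag |= 0x10
                else:
                    flag |= 0x20
                fh.write(
                    f"{aln.pair_id}\t{flag}\t{pl.seq_id}\t{pos + 1}\t"
                    f"{60 if aln.unique else 0}\t{rlen}M\t=\t"
                    f"{(pl.pos2 if mate_i == 0 else pl.pos1) + 1}\t"
                    f"{pl.insert if mate_i == 0 else -pl.insert}\t{seq}\t*\n"
                )
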