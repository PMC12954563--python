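"""k-mer counting, mappability, eligible regions and exact mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spetkit import kmer, simulate
from spetkit.kmer import (
    EligibleRegion,
    MappabilityTrack,
    PerfectReadPair,
    ReferenceSequence,
    build_kmer_index,
    canonical,
    contiguity_regions,
    eligible_regions,
    map_perfect_reads,
    mappability_track,
    revcomp,
)


def naive_kmer_counts(seqs, k, canonical_mode=True):
    """Dictionary-count oracle, independent window loop."""
    counts = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            key = min(w, revcomp(w)) if canonical_mode else w
            counts[key] = counts.get(key, 0) + 1
    return counts


dna = st.text(alphabet="ACGT", min_size=8, max_size=200)


class TestKmerIndex:
    def test_homopolymer_single_strand(self):
        idx = build_kmer_index(ReferenceSequence("s", "AAAAA"), k=4, canonical_mode=False)
        assert idx.counts == {"AAAA": 2}

    def test_palindromic_window(self):
        idx = build_kmer_index(ReferenceSequence("s", "ACGT"), k=4)
        assert idx.counts == {"ACGT": 1}

    def test_canonical_folding(self):
        idx = build_kmer_index(ReferenceSequence("s", "AACCGGTT"), k=4)
        assert idx.counts["AACC"] == 2  # AACC and its revcomp GGTT

    def test_n_windows_skipped(self):
        idx = build_kmer_index(ReferenceSequence("s", "AANAA"), k=2, canonical_mode=False)
        assert sum(idx.counts.values()) == 2  # AA, AA only

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter than k"):
            build_kmer_index(ReferenceSequence("s", "ACG"), k=10)

    @settings(deadline=None, max_examples=30)
    @given(seq=dna, k=st.sampled_from([4, 8, 20]), canon=st.booleans())
    def test_matches_naive_oracle(self, seq, k, canon):
        if len(seq) < k:
            seq = seq + "A" * k
        idx = build_kmer_index(ReferenceSequence("s", seq), k=k, canonical_mode=canon)
        assert idx.counts == naive_kmer_counts([seq], k, canon)

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        idx = build_kmer_index(ReferenceSequence("s", seq), k=8)
        assert sum(idx.counts.values()) == len(seq) - 8 + 1


class TestMappabilityTrack:
    def test_homopolymer_track(self):
        ref = ReferenceSequence("s", "AAAAA")
        idx = build_kmer_index(ref, k=4, canonical_mode=False)
        track = mappability_track(idx, ref)
        assert track.values.tolist() == [2, 2]

    def test_unique_sequence_all_ones(self):
        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        ref = ReferenceSequence("s", seq)
        track = mappability_track(build_kmer_index(ref, k=20), ref)
        assert len(track) == 41
        assert (track.values[track.defined] == 1).all()

    def test_n_window_undefined(self):
        ref = ReferenceSequence("s", "ACGTNACGTACG")
        track = mappability_track(build_kmer_index(ref, k=4), ref)
        assert not track.defined[1:5].any()
        assert track.defined[5:].all()

    def test_foreign_sequence_errors(self):
        idx = build_kmer_index(ReferenceSequence("a", "ACGTACGTACGT"), k=4)
        with pytest.raises(ValueError, match="absent from index"):
            mappability_track(idx, ReferenceSequence("b", "TTTTTTTT"))


def naive_eligible_regions(values, defined, min_len, mean_max, pos_cap):
    """Literal re-statement of the region rule with O(n^2) means."""
    ok = [d and v <= pos_cap for v, d in zip(values, defined)]
    regions = []
    i, n = 0, len(values)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        s = i
        while s + min_len <= j:
            found = None
            for e in range(j, s + min_len - 1, -1):
                seg = values[s:e]
                if sum(seg) / len(seg) < mean_max:
                    found = e
                    break
            if found is None:
                s += 1
                continue
            seg = values[s:found]
            regions.append((s, found, sum(seg) / len(seg)))
            s = found
        i = j
    return regions


class TestEligibleRegions:
    def _track(self, values, defined=None):
        values = np.asarray(values)
        if defined is None:
            defined = np.ones(len(values), dtype=bool)
        return MappabilityTrack("s", 20, values, np.asarray(defined))

    def test_uniform_unique_track(self):
        regs = eligible_regions(self._track([1] * 281))
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end, regs[0].mean_kmer) == (0, 281, 1.0)

    def test_mean_boundary_is_strict(self):
        # "lower than 2" is strict: a track uniformly at 2 yields nothing
        assert eligible_regions(self._track([2] * 500)) == []

    def test_min_length_rule(self):
        assert eligible_regions(self._track([1] * 150)) == []

    def test_pos_cap_splits(self):
        values = [1] * 250 + [5] + [1] * 250
        regs = eligible_regions(self._track(values))
        assert [(r.start, r.end) for r in regs] == [(0, 250), (251, 501)]

    def test_n_breaks_regions(self):
        defined = [True] * 250 + [False] + [True] * 250
        regs = eligible_regions(self._track([1] * 501, defined))
        assert [(r.start, r.end) for r in regs] == [(0, 250), (251, 501)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 5, size=1200)
        spikes = rng.random(1200) < 0.02
        values[spikes] = rng.integers(5, 50, size=spikes.sum())
        defined = rng.random(1200) > 0.01
        regs = eligible_regions(self._track(values, defined), min_len=50, mean_max=2.0)
        expected = naive_eligible_regions(values.tolist(), defined.tolist(), 50, 2.0, 4)
        assert [(r.start, r.end) for r in regs] == [(s, e) for s, e, _ in expected]
        for r, (_, _, m) in zip(regs, expected):
            assert r.mean_kmer == pytest.approx(m)
            assert r.mean_kmer < 2.0
            assert len(r) >= 50

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        values = rng.integers(1, 4, size=2000)
        t = self._track(values)
        assert eligible_regions(t) == eligible_regions(t)


class TestMapPerfectReads:
    def test_round_trip_unique_region(self, small_genome):
        ref = small_genome.reference
        pairs = simulate.simulate_perfect_read_pairs(ref, 300, seed=3)
        alns = map_perfect_reads(pairs, [ref])
        assert all(a.n_hits >= 1 for a in alns)
        for p, a in zip(pairs, alns):
            if a.unique:
                src = p.source
                pl = a.primary
                assert (pl.pos1, pl.strand1) == (src.start1, src.strand1)
                assert (pl.pos2, pl.strand2) == (src.start2, src.strand2)

    def test_repeat_copy_number(self):
        rng = np.random.default_rng(11)
        unit = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        spacer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        seq = spacer + unit + spacer[::-1] + unit + spacer.replace("A", "C")
        ref = ReferenceSequence("s", seq)
        # pair wholly inside the repeated unit
        frag = unit[50:450]
        pair = PerfectReadPair("p", frag[:150], revcomp(frag[-150:]))
        (aln,) = map_perfect_reads([pair], [ref])
        assert aln.n_hits == 2 and not aln.unique

    def test_chimeric_pair_improper(self):
        rng = np.random.default_rng(12)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 12000)])
        ref = ReferenceSequence("s", seq)
        pair = PerfectReadPair("p", seq[0:150], revcomp(seq[10000:10150]))
        (aln,) = map_perfect_reads([pair], [ref])
        assert not aln.proper

    def test_bad_symbol_rejected(self):
        ref = ReferenceSequence("s", "ACGT" * 100)
        pair = PerfectReadPair("p", "ACXT" * 10, "ACGT" * 10)
        with pytest.raises(ValueError, match="non-ACGTN"):
            map_perfect_reads([pair], [ref])


@pytest.fixture(scope="module")
def anchored():
    g = simulate.simulate_genome(80_000, n_genes=6, repeat_spec=[(900, 2)], seed=31)
    tx = g.transcripts()
    pairs = simulate.simulate_perfect_read_pairs(tx, 5000, seed=32)
    alns = map_perfect_reads(pairs, [g.reference])
    return g, tx, pairs, contiguity_regions(alns, pairs)


class TestContiguityRegions:
    def test_single_exon_covered_one_region(self, anchored):
        g, tx, _, regs = anchored
        for gene, t in zip(g.genes, tx):
            if len(gene.exons) == 1:
                mine = [r for r in regs if r.seq_id == t.seq_id]
                assert len(mine) == 1
                assert len(mine[0]) >= 0.9 * len(t)

    def test_junctions_never_spanned(self, anchored):
        g, tx, _, regs = anchored
        for gene, t in zip(g.genes, tx):
            juncs = g.junctions(gene)
            for r in (r for r in regs if r.seq_id == t.seq_id):
                assert not any(r.start < j < r.end for j in juncs)

    def test_multi_exon_split_per_junction(self, anchored):
        g, tx, _, regs = anchored
        for gene, t in zip(g.genes, tx):
            if len(gene.exons) > 1:
                mine = [r for r in regs if r.seq_id == t.seq_id]
                # one region per sufficiently long exon at most
                assert len(mine) <= len(gene.exons)
                assert len(mine) >= 2  # junction split occurred

    def test_duplicated_gene_family_excluded(self):
        rng = np.random.default_rng(41)
        gene = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1500)])
        spacer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        genome = ReferenceSequence("g", spacer + gene + spacer[::-1] + gene)
        transcript = ReferenceSequence("t", gene, kmer.RefKind.transcriptome)
        pairs = simulate.simulate_perfect_read_pairs(transcript, 500, seed=42)
        alns = map_perfect_reads(pairs, [genome])
        assert contiguity_regions(alns, pairs) == []

    def test_empty_alignments_warn(self):
        with pytest.warns(UserWarning, match="empty alignment"):
            assert contiguity_regions([], []) == []
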